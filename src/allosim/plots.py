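"""Optional matplotlib figures for simulation output.

Each function returns the figure; callers save or show it.  These are
convenience views, not publication layouts.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe; callers may switch backends first
import matplotlib.pyplot as plt
import pandas as pd

from .analytics import FLOW_CATEGORIES, FlowTable, _extract
from .engine import MatchRecord


def score_distribution_boxplot(
    matches_by_label: Mapping[str, Sequence[MatchRecord]], which: str = "sum5"
):
    """Boxplots of match scores per labelled run (e.g. base-case vs deliberate)."""
    fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(matches_by_label), 4))
    labels = list(matches_by_label)
    ax.boxplot([_extract(matches_by_label[k], which) for k in labels], tick_labels=labels)
    ax.set_ylabel(f"mismatch score ({which})")
    fig.tight_layout()
    return fig


def probability_curves(curves: pd.DataFrame):
    """Mean +/- SD probability vs waitlist size, one panel per ratio."""
    ratios = sorted(curves["ratio"].unique())
    fig, axes = plt.subplots(1, len(ratios), figsize=(4 * len(ratios), 3.5), squeeze=False)
    for ax, ratio in zip(axes[0], ratios):
        sub = curves[curves["ratio"] == ratio]
        for (strategy, key), grp in sub.groupby(["strategy", "threshold_or_stratum"]):
            grp = grp.sort_values("W")
            ax.errorbar(grp["W"], grp["mean"], yerr=grp["sd"], label=f"{strategy} {key}",
                        marker="o", capsize=2)
        ax.set_xlabel("waitlist size")
        ax.set_ylabel("probability")
        ax.set_title(f"ratio {ratio}:1")
        ax.legend(fontsize=6)
    fig.tight_layout()
    return fig


def flow_heatmap(flow: FlowTable):
    """Baseline-to-deliberate flow matrix as an annotated heatmap."""
    fig, ax = plt.subplots(figsize=(5, 4))
    mat = flow.counts.loc[list(FLOW_CATEGORIES), list(FLOW_CATEGORIES)].to_numpy()
    im = ax.imshow(mat, cmap="Blues")
    ax.set_xticks(range(len(FLOW_CATEGORIES)), FLOW_CATEGORIES)
    ax.set_yticks(range(len(FLOW_CATEGORIES)), FLOW_CATEGORIES)
    ax.set_xlabel("deliberate category")
    ax.set_ylabel("baseline category")
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            ax.text(j, i, str(mat[i, j]), ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="patients")
    fig.tight_layout()
    return fig
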