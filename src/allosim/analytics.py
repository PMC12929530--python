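"""Post-simulation analytics.

Three analyses sit downstream of the allocation engine:

* score-distribution summaries (median, range, zero-score probability) of
  the match list, per locus or for the 5-locus sum;
* patient-flow accounting between a base-case run and a deliberate run over
  identical person streams -- baseline match scores define quartile
  categories, and every tracked patient is assigned a baseline and a
  deliberate category (or "Waiting" if still on the list), yielding a flow
  matrix;
* static matchability profiling: each patient's mismatch-score distribution
  against every ABO-identical donor, and detection of the hard-to-match
  tail as the patients where the smoothed ordered-median curve steepens
  beyond a threshold relative to the maximum median.

Integer scores use the lower-middle median convention throughout (the lower
of the two central values for even counts), so summaries are reproducible
integers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import Candidate, Donor, LOCI
from .engine import MatchRecord, SimulationResult

QUARTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")
WAITING = "Waiting"
FLOW_CATEGORIES = QUARTILE_LABELS + (WAITING,)


def _extract(matches: Sequence[MatchRecord], which: str) -> list[int]:
    if which == "sum5":
        return [m.score_vector.sum5 for m in matches]
    if which in LOCI:
        return [m.score_vector[which] for m in matches]
    raise ValueError(f"which must be one of {LOCI} or 'sum5', got {which!r}")


def lower_median(values: Sequence[float]) -> float:
    """Median using the lower of the two middle values for even counts."""
    if len(values) == 0:
        raise ValueError("median of empty sequence")
    ordered = sorted(values)
    return ordered[(len(ordered) - 1) // 2]


@dataclass(frozen=True)
class DistributionSummary:
    median: float
    min: float
    max: float
    zero_probability: float
    n: int


def summarize_scores(matches: Sequence[MatchRecord], which: str = "sum5") -> DistributionSummary:
    """Median (lower-middle convention), range and zero-score fraction of
    the match list at one locus or the 5-locus sum."""
    if not matches:
        raise ValueError("cannot summarize an empty match list")
    scores = _extract(matches, which)
    return DistributionSummary(
        median=lower_median(scores),
        min=min(scores),
        max=max(scores),
        zero_probability=sum(s == 0 for s in scores) / len(scores),
        n=len(scores),
    )


@dataclass(frozen=True)
class QuartileCategories:
    """Four half-open score intervals [0,e1), [e1,e2), [e2,e3), [e3,inf)
    exhausting the non-negative scores."""

    edges: tuple[float, float, float]

    def assign(self, score: float) -> str:
        for label, edge in zip(QUARTILE_LABELS[:3], self.edges):
            if score < edge:
                return label
        return QUARTILE_LABELS[3]

    def intervals(self) -> list[tuple[float, float | None]]:
        e1, e2, e3 = self.edges
        return [(0, e1), (e1, e2), (e2, e3), (e3, None)]


def quartile_categories(
    baseline: Sequence[MatchRecord] | Sequence[float], which: str = "sum5"
) -> QuartileCategories:
    """Quartile score categories from baseline match scores.

    Edges sit at the empirical 25/50/75 percentiles (next-observation
    convention, so integer scores give integer edges).  Degenerate all-equal
    inputs collapse to a single effective category with a warning.
    """
    if len(baseline) and isinstance(baseline[0], MatchRecord):
        scores = np.asarray(_extract(baseline, which), dtype=float)
    else:
        scores = np.asarray(baseline, dtype=float)
    if len(scores) < 4:
        raise ValueError("need at least 4 baseline scores to form quartiles")
    edges = tuple(float(e) for e in np.percentile(scores, [25, 50, 75], method="higher"))
    if len(set(scores.tolist())) == 1:
        warnings.warn("all baseline scores equal; quartile categories collapse", stacklevel=2)
    return QuartileCategories(edges)


@dataclass
class FlowTable:
    """Baseline-to-deliberate patient flows.  ``counts`` is indexed by
    baseline category (rows) and deliberate category (columns)."""

    counts: pd.DataFrame
    categories: QuartileCategories
    n_tracked: int

    def validate(self) -> None:
        total = int(self.counts.to_numpy().sum())
        if total != self.n_tracked:
            raise AssertionError("flow table does not conserve tracked patients")


def patient_flow(
    baseline: SimulationResult, deliberate: SimulationResult, which: str = "sum5"
) -> FlowTable:
    """Track every patient from a paired base-case/deliberate run pair.

    Both results must come from identical person streams (checked via the
    stream fingerprint).  Each tracked patient gets a baseline category
    (quartile of their baseline matched score, or Waiting) and a deliberate
    category using the same baseline-derived quartile edges.
    """
    if baseline.config.get("stream_fingerprint") != deliberate.config.get("stream_fingerprint"):
        raise ValueError("paired results must share identical person streams")
    base_scores = {m.recipient_id: s for m, s in zip(baseline.matches, _extract(baseline.matches, which))}
    delib_scores = {m.recipient_id: s for m, s in zip(deliberate.matches, _extract(deliberate.matches, which))}
    tracked = set(base_scores) | {c.id for c in baseline.final_waitlist}
    tracked_d = set(delib_scores) | {c.id for c in deliberate.final_waitlist}
    if tracked != tracked_d:
        raise ValueError("paired results track different patient sets")

    cats = quartile_categories(list(base_scores.values()))
    counts = pd.DataFrame(
        0, index=list(FLOW_CATEGORIES), columns=list(FLOW_CATEGORIES), dtype=int
    )
    for pid in tracked:
        b = cats.assign(base_scores[pid]) if pid in base_scores else WAITING
        d = cats.assign(delib_scores[pid]) if pid in delib_scores else WAITING
        counts.loc[b, d] += 1
    table = FlowTable(counts, cats, len(tracked))
    table.validate()
    return table


def static_score_profile(
    patients: Sequence[Candidate],
    donors: Sequence[Donor],
    scorer,
    which: str = "sum5",
) -> pd.DataFrame:
    """Per-patient score distribution against all ABO-identical donors.

    Returns one row per patient: ``patient_id, abo, n_donors, median, q1,
    q3, scorable``.  A patient with no ABO-identical donor is flagged
    unscorable (NaN quantiles).
    """
    rows = []
    for patient in patients:
        eligible = [d for d in donors if d.abo == patient.abo]
        if not eligible:
            rows.append(
                {"patient_id": patient.id, "abo": patient.abo, "n_donors": 0,
                 "median": np.nan, "q1": np.nan, "q3": np.nan, "scorable": False}
            )
            continue
        vals = []
        for d in eligible:
            vec = scorer.score_pair(d, patient)
            vals.append(vec.sum5 if which == "sum5" else vec[which])
        q1, q3 = np.percentile(vals, [25, 75], method="lower")
        rows.append(
            {"patient_id": patient.id, "abo": patient.abo, "n_donors": len(eligible),
             "median": float(lower_median(vals)), "q1": float(q1), "q3": float(q3),
             "scorable": True}
        )
    return pd.DataFrame(
        rows, columns=["patient_id", "abo", "n_donors", "median", "q1", "q3", "scorable"]
    )


@dataclass
class HardToMatchReport:
    """Per-patient smoothed-median slope analysis.  ``table`` is ordered by
    ascending median with columns ``patient_id, median, smoothed, diff,
    flagged``; ``threshold`` is the absolute flagging threshold used."""

    table: pd.DataFrame
    threshold: float
    window_halfwidth: int

    @property
    def flagged_fraction(self) -> float:
        return float(self.table["flagged"].mean())


def flag_hard_to_match(
    profiles: pd.DataFrame,
    window_halfwidth: int = 5,
    rel_threshold: float = 0.002,
) -> HardToMatchReport:
    """Detect the hard-to-match tail of the cohort.

    Patients are ordered by ascending median static score; the median curve
    is smoothed with a centred moving average over +/- ``window_halfwidth``
    positions (truncated at the edges); a patient is flagged when the first
    difference of the smoothed curve at their position exceeds
    ``rel_threshold`` times the maximum median.  Doubling all scores doubles
    the absolute threshold and leaves the flagged set unchanged.
    """
    usable = profiles[profiles["scorable"]] if "scorable" in profiles else profiles
    if len(usable) < len(profiles):
        warnings.warn(
            f"dropping {len(profiles) - len(usable)} unscorable patients", stacklevel=2
        )
    if len(usable) == 0:
        raise ValueError("no scorable patients")
    if len(usable) < 2 * window_halfwidth + 1:
        warnings.warn("fewer patients than the smoothing window; window truncated", stacklevel=2)
    ordered = usable.sort_values(["median", "patient_id"], kind="stable").reset_index(drop=True)
    med = ordered["median"].to_numpy(dtype=float)
    n = len(med)
    smoothed = np.array(
        [med[max(0, i - window_halfwidth) : i + window_halfwidth + 1].mean() for i in range(n)]
    )
    diff = np.zeros(n)
    diff[1:] = np.diff(smoothed)
    threshold = rel_threshold * float(med.max())
    flagged = diff > threshold
    table = pd.DataFrame(
        {
            "patient_id": ordered["patient_id"],
            "median": med,
            "smoothed": smoothed,
            "diff": diff,
            "flagged": flagged,
        }
    )
    return HardToMatchReport(table, threshold, window_halfwidth)


# ---------------------------------------------------------------------------
# TSV writers

def write_flow_table(flow: FlowTable, path: str | Path) -> None:
    """Long-form TSV: baseline_cat, deliberate_cat, count."""
    rows = [
        {"baseline_cat": b, "deliberate_cat": d, "count": int(flow.counts.loc[b, d])}
        for b in FLOW_CATEGORIES
        for d in FLOW_CATEGORIES
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_hard_to_match(report: HardToMatchReport, path: str | Path) -> None:
    report.table.to_csv(path, sep="\t", index=False)
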