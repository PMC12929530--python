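"""Scenario grids and replicate aggregation.

Runs the simulation over a grid of waitlist sizes x candidate-to-donor
ratios x strategies, with a configurable number of replicates per cell
(same scenario, different random orderings of people).  Per-replicate
summaries -- cumulative probabilities of score thresholds and risk-stratum
frequencies -- are averaged across replicates with their standard
deviation, producing the probability-vs-waitlist-size curves used to judge
how matchability scales with program size.

Replicate seeds are derived per cell from the master seed by hashing the
cell key, so adding grid cells never perturbs existing cells' results and
disjoint cells never share person streams.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import DEFAULT_ABO_FREQS, HaplotypePool, generate_streams
from .engine import (
    BASE_CASE,
    DELIBERATE_5LOCI,
    MatchRecord,
    SimulationResult,
    Strategy,
    run_replicate,
)
from .scoring import STRATUM_LABELS

#: Default waitlist-size grid: provincial program sizes 100-800, a
#: representative provincial benchmark of 290, the national list of ~2,000
#: and the 2,286 national-scale replicate, up to 2,500.
DEFAULT_WAITLIST_SIZES = (100, 200, 290, 400, 800, 1600, 2000, 2286, 2500)
#: Candidate-to-donor ratios 2:1 to 4:1 including the national ~2.6:1.
DEFAULT_RATIOS = (2.0, 2.6, 3.0, 4.0)


@dataclass(frozen=True)
class ScenarioConfig:
    waitlist_sizes: tuple[int, ...] = DEFAULT_WAITLIST_SIZES
    ratios: tuple[float, ...] = DEFAULT_RATIOS
    strategies: tuple[Strategy, ...] = (BASE_CASE, DELIBERATE_5LOCI)
    replicates: int = 10
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(w < 2 for w in self.waitlist_sizes):
            raise ValueError("all waitlist sizes must be >= 2")

    def cells(self) -> Iterable[tuple[int, float, Strategy, int]]:
        for w in self.waitlist_sizes:
            for r in self.ratios:
                for s in self.strategies:
                    for rep in range(self.replicates):
                        yield w, r, s, rep


def cell_seed(
    master_seed: int, waitlist_size: int, ratio: float, strategy_label: str, replicate: int
) -> int:
    """Deterministic per-cell replicate seed (stable under grid extension)."""
    key = f"{master_seed}|{waitlist_size}|{ratio!r}|{strategy_label}|{replicate}".encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=4).digest(), "big") % (2**31)


ResultKey = tuple[int, float, str, int]  # (W, ratio, strategy label, replicate)


def run_grid(
    config: ScenarioConfig,
    pool: HaplotypePool,
    scorer,
    abo_freqs: Mapping[str, float] = DEFAULT_ABO_FREQS,
    progress: bool = False,
) -> dict[ResultKey, SimulationResult]:
    """One :class:`~allosim.engine.SimulationResult` per grid cell per replicate."""
    results: dict[ResultKey, SimulationResult] = {}
    for w, r, strat, rep in config.cells():
        seed = cell_seed(config.master_seed, w, r, strat.label, rep)
        prefix = f"s{seed:08x}-"
        streams = generate_streams(pool, abo_freqs, w, r, seed, id_prefix=prefix)
        if progress:  # pragma: no cover - cosmetic
            print(f"running W={w} ratio={r} {strat.label} rep={rep}", flush=True)
        results[(w, r, strat.label, rep)] = run_replicate(streams, strat, scorer, seed=seed)
        if hasattr(scorer, "clear_pair_cache"):
            scorer.clear_pair_cache()
    return results


def cumulative_probability(
    matches: Sequence[MatchRecord], threshold: int, mode: str = "strict_less"
) -> float:
    """Fraction of match records whose objective score is below (``strict_less``)
    or at most (``less_equal``) the threshold."""
    if not matches:
        raise ValueError("cumulative probability undefined for an empty match list")
    if mode == "strict_less":
        hits = sum(m.objective_score < threshold for m in matches)
    elif mode == "less_equal":
        hits = sum(m.objective_score <= threshold for m in matches)
    else:
        raise ValueError(f"mode must be 'strict_less' or 'less_equal', got {mode!r}")
    return hits / len(matches)


def stratum_frequencies(matches: Sequence[MatchRecord]) -> dict[str, float]:
    """Relative frequency of each clinical risk stratum (sums to 1)."""
    if not matches:
        raise ValueError("stratum frequencies undefined for an empty match list")
    counts = {label: 0 for label in STRATUM_LABELS}
    for m in matches:
        counts[m.stratum] += 1
    return {label: counts[label] / len(matches) for label in STRATUM_LABELS}


def _replicate_sd(values: Sequence[float]) -> float:
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1))


def aggregate_curves(
    results: Mapping[ResultKey, SimulationResult],
    thresholds: Sequence[int] | None = None,
    strata: bool = False,
    mode: str = "strict_less",
) -> pd.DataFrame:
    """Mean and SD over replicates of threshold probabilities and/or
    stratum frequencies, per (strategy, ratio, waitlist size).

    Returns a long-form frame with columns ``strategy, ratio, W,
    threshold_or_stratum, mean, sd, n_replicates`` -- one curve per
    (strategy, ratio, threshold-or-stratum) as a function of W.
    """
    if thresholds is None and not strata:
        raise ValueError("request thresholds, strata, or both")
    by_cell: dict[tuple[int, float, str], list[SimulationResult]] = {}
    for (w, r, label, _rep), res in results.items():
        by_cell.setdefault((w, r, label), []).append(res)

    op = "<" if mode == "strict_less" else "<="
    rows = []
    for (w, r, label), cell_results in sorted(by_cell.items(), key=lambda kv: kv[0]):
        keys: list[tuple[str, object]] = []
        if thresholds is not None:
            keys += [(f"{op}{t}", t) for t in thresholds]
        if strata:
            keys += [(s, None) for s in STRATUM_LABELS]
        for key_label, t in keys:
            if t is not None:
                vals = [cumulative_probability(res.matches, t, mode) for res in cell_results]
            else:
                vals = [stratum_frequencies(res.matches)[key_label] for res in cell_results]
            rows.append(
                {
                    "strategy": label,
                    "ratio": r,
                    "W": w,
                    "threshold_or_stratum": key_label,
                    "mean": float(np.mean(vals)),
                    "sd": _replicate_sd(vals),
                    "n_replicates": len(vals),
                }
            )
    return pd.DataFrame(
        rows, columns=["strategy", "ratio", "W", "threshold_or_stratum", "mean", "sd", "n_replicates"]
    )


def saturation_point(
    x: Sequence[float], y: Sequence[float], tolerance: float = 0.01
) -> tuple[float, bool]:
    """Plateau onset of a probability-vs-waitlist-size curve.

    Returns ``(x_value, saturated)`` where ``x_value`` is the smallest x
    from which every subsequent step of the mean curve changes by less than
    ``tolerance`` times the curve's range.  A curve that never flattens
    returns the largest x with ``saturated=False``.  A constant curve
    saturates at the first x.
    """
    x = list(x)
    y = list(y)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 curve points")
    rng = max(y) - min(y)
    if rng == 0:
        return x[0], True
    diffs = [abs(y[i + 1] - y[i]) for i in range(len(y) - 1)]
    limit = tolerance * rng
    for i in range(len(diffs)):
        if all(d < limit for d in diffs[i:]):
            return x[i], True
    return x[-1], False


def write_curves(curves: pd.DataFrame, path: str | Path) -> None:
    curves.to_csv(path, sep="\t", index=False)


def read_curves(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
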