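"""Greedy allocation engine.

One replicate walks the donor sequence in order.  Each donor offers two
kidneys, allocated one after the other against the current waitlist; after
both offers two replenishment candidates join the bottom of the waitlist,
keeping its size constant.  Eligibility is ABO identity.  Under the
base-case strategy (current practice) the longest-waiting eligible
candidate wins; under deliberate matching the eligible candidate with the
lowest mismatch score at the strategy's loci wins, with waiting time
breaking ties.  All offers are accepted.

Every transplant is recorded in a match list for post-simulation analysis.
A kidney with no ABO-identical candidate is recorded as unallocated and the
simulation proceeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import LOCI, Candidate, Donor, Streams
from .scoring import ScoreVector, classify_stratum

logger = logging.getLogger(__name__)

_VALID_MODES = ("base_case", "deliberate")


@dataclass(frozen=True)
class Strategy:
    """Allocation strategy: base-case (waiting time only) or deliberate
    (lowest score at ``objective_loci``, waiting time breaking ties)."""

    mode: str
    objective_loci: tuple[str, ...] = LOCI

    def __post_init__(self) -> None:
        if self.mode not in _VALID_MODES:
            raise ValueError(f"mode must be one of {_VALID_MODES}, got {self.mode!r}")
        loci = tuple(self.objective_loci)
        if not loci or any(l not in LOCI for l in loci) or len(set(loci)) != len(loci):
            raise ValueError(f"objective_loci must be a non-empty subset of {LOCI}")
        object.__setattr__(self, "objective_loci", tuple(l for l in LOCI if l in loci))

    @property
    def label(self) -> str:
        if self.mode == "base_case":
            return "base_case"
        if self.objective_loci == LOCI:
            return "deliberate-5LOCI"
        return "deliberate-" + "+".join(self.objective_loci)


BASE_CASE = Strategy("base_case")
DELIBERATE_5LOCI = Strategy("deliberate")


def objective_score(vec: ScoreVector, loci: Sequence[str]) -> int:
    """Sum of the score vector over the strategy's loci."""
    return sum(vec[locus] for locus in loci)


@dataclass(frozen=True)
class MatchRecord:
    """One allocated kidney.  ``stratum`` classifies the 5-locus sum into
    the clinical risk categories; ``objective_score`` is the score the
    strategy ranked on."""

    donor_id: str
    recipient_id: str
    donor_seq: int
    score_vector: ScoreVector
    objective_score: int
    stratum: str
    recipient_arrival_index: int


@dataclass
class SimulationResult:
    matches: list[MatchRecord]
    final_waitlist: list[Candidate]
    unallocated_kidneys: list[tuple[str, str]]
    config: dict
    seed: int | None


def select_recipient(
    waitlist: Sequence[Candidate], donor: Donor, strategy: Strategy, scorer
) -> Candidate | None:
    """The candidate this donor's kidney goes to, or ``None`` if no
    ABO-identical candidate exists.

    Deliberate mode minimises the objective score; ties go to the smallest
    arrival index (longest waiting), then to the smallest id (unreachable
    when arrival indices are unique, kept for full determinism).
    """
    eligible = [c for c in waitlist if c.abo == donor.abo]
    if not eligible:
        return None
    if strategy.mode == "base_case":
        return min(eligible, key=lambda c: (c.arrival_index, c.id))
    loci = strategy.objective_loci
    return min(
        eligible,
        key=lambda c: (objective_score(scorer.score_pair(donor, c), loci), c.arrival_index, c.id),
    )


def run_replicate(
    streams: Streams, strategy: Strategy, scorer, seed: int | None = None
) -> SimulationResult:
    """Run one allocation replicate over the given person streams."""
    waitlist = list(streams.waitlist)
    if not waitlist:
        raise ValueError("waitlist must be nonempty")
    W = len(waitlist)
    matches: list[MatchRecord] = []
    unallocated: list[tuple[str, str]] = []
    matched_ids: set[str] = set()
    repl_pos = 0
    replenishment = streams.replenishment

    for seq, donor in enumerate(streams.donors, start=1):
        chosen_ids = []
        for _kidney in (1, 2):
            chosen = select_recipient(waitlist, donor, strategy, scorer)
            if chosen is None:
                unallocated.append((donor.id, "no ABO-identical candidate"))
                continue
            waitlist.remove(chosen)
            vec = scorer.score_pair(donor, chosen)
            assert chosen.id not in matched_ids, "recipient transplanted twice"
            matched_ids.add(chosen.id)
            matches.append(
                MatchRecord(
                    donor_id=donor.id,
                    recipient_id=chosen.id,
                    donor_seq=seq,
                    score_vector=vec,
                    objective_score=objective_score(vec, strategy.objective_loci),
                    stratum=classify_stratum(vec.sum5),
                    recipient_arrival_index=chosen.arrival_index,
                )
            )
            chosen_ids.append(chosen.id)
        if repl_pos + 2 > len(replenishment):
            raise RuntimeError(f"replenishment stream exhausted at donor {donor.id}")
        waitlist.extend(replenishment[repl_pos : repl_pos + 2])
        repl_pos += 2
        # Constant-size waitlist, up to kidneys that found no recipient.
        assert len(waitlist) == W + len(unallocated), "waitlist size drifted"
        if logger.isEnabledFor(logging.DEBUG):
            logger.debug(
                "donor=%s abo=%s eligible=%d chosen=%s",
                donor.id, donor.abo,
                sum(c.abo == donor.abo for c in waitlist), chosen_ids,
            )

    assert len(matches) + len(unallocated) == 2 * len(streams.donors), "kidney conservation"
    config = {
        "waitlist_size": streams.waitlist_size,
        "ratio": streams.ratio,
        "n_donors": len(streams.donors),
        "strategy": strategy.label,
        "stream_seed": streams.seed,
        "stream_fingerprint": streams.fingerprint,
    }
    return SimulationResult(matches, waitlist, unallocated, config, seed)


def run_base_and_deliberate_paired(
    streams: Streams,
    strategies: tuple[Strategy, Strategy] = (BASE_CASE, DELIBERATE_5LOCI),
    scorer=None,
    seed: int | None = None,
) -> tuple[SimulationResult, SimulationResult]:
    """Run two strategies over byte-identical person streams, so that only
    the selection logic differs between the paired results."""
    first = run_replicate(streams, strategies[0], scorer, seed=seed)
    second = run_replicate(streams, strategies[1], scorer, seed=seed)
    assert first.config["stream_fingerprint"] == second.config["stream_fingerprint"]
    return first, second


# ---------------------------------------------------------------------------
# Match-List round-tripping

_MATCH_COLUMNS = (
    ["donor_id", "recipient_id", "donor_seq"]
    + [f"score_{locus}" for locus in LOCI]
    + ["sum5", "objective_score", "stratum", "recipient_arrival_index"]
)


def write_match_list(matches: Iterable[MatchRecord], path: str | Path) -> None:
    rows = []
    for m in matches:
        row = {"donor_id": m.donor_id, "recipient_id": m.recipient_id, "donor_seq": m.donor_seq}
        for locus in LOCI:
            row[f"score_{locus}"] = m.score_vector[locus]
        row["sum5"] = m.score_vector.sum5
        row["objective_score"] = m.objective_score
        row["stratum"] = m.stratum
        row["recipient_arrival_index"] = m.recipient_arrival_index
        rows.append(row)
    pd.DataFrame(rows, columns=_MATCH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_match_list(path: str | Path) -> list[MatchRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))
        vec = ScoreVector(tuple(int(row_d[f"score_{locus}"]) for locus in LOCI))
        records.append(
            MatchRecord(
                donor_id=str(row_d["donor_id"]),
                recipient_id=str(row_d["recipient_id"]),
                donor_seq=int(row_d["donor_seq"]),
                score_vector=vec,
                objective_score=int(row_d["objective_score"]),
                stratum=str(row_d["stratum"]),
                recipient_arrival_index=int(row_d["recipient_arrival_index"]),
            )
        )
    return records
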