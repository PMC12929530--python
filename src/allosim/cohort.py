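"""Synthetic transplant cohorts.

This module generates the populations consumed by the allocation engine:
a pool of 5-locus HLA haplotypes with a skewed (few-common / many-rare)
frequency spectrum, diploid genotypes formed by Hardy-Weinberg pairing of
haplotypes, ABO blood groups, and the three ordered person streams of one
simulation replicate -- an arrival-ordered waitlist, a donor sequence, and
a replenishment stream that keeps the waitlist at constant size.

Allele protein sequences are synthetic: per locus a random backbone with
allele-specific substitutions at a designated set of polymorphic positions.
Distinct alleles therefore yield non-self peptides while alleles shared
between donor and recipient yield none, which is the structural property
molecular-mismatch scoring depends on.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

LOCI = ("A", "B", "C", "DRB1", "DQB1")
ABO_GROUPS = ("O", "A", "B", "AB")

#: Approximate Canadian ABO blood-group distribution; overridable everywhere.
DEFAULT_ABO_FREQS: dict[str, float] = {"O": 0.46, "A": 0.42, "B": 0.09, "AB": 0.03}

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default haplotype-pool shape: ~120 haplotypes covers the diversity of a
#: provincial cohort of ~1,000 patients; Dirichlet concentration 0.3 gives
#: the few-common/many-rare spectrum typical of HLA haplotype tables.
DEFAULT_POOL_PARAMS: dict[str, float | int] = {
    "n_haplotypes": 120,
    "n_polymorphic_sites": 24,
    "concentration": 0.3,
}


class CohortFormatError(ValueError):
    """A cohort or pool table failed validation."""


@dataclass(frozen=True)
class HLAGenotype:
    """Diploid genotype at the five classical loci A, B, C, DRB1, DQB1.

    ``alleles`` is a 5-tuple aligned with :data:`LOCI`; each entry is an
    unordered pair of allele identifiers, normalised to sorted order so that
    genotypes compare and hash by content.  Homozygosity (identical pair)
    is allowed.
    """

    alleles: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(LOCI):
            raise ValueError(f"genotype needs {len(LOCI)} loci, got {len(self.alleles)}")
        normalised = tuple(tuple(sorted(pair)) for pair in self.alleles)
        object.__setattr__(self, "alleles", normalised)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, tuple[str, str]]) -> "HLAGenotype":
        return cls(tuple(tuple(mapping[locus]) for locus in LOCI))

    def pair(self, locus: str) -> tuple[str, str]:
        return self.alleles[LOCI.index(locus)]

    @property
    def drb1_pair(self) -> tuple[str, str]:
        return self.alleles[LOCI.index("DRB1")]

    def all_alleles(self) -> tuple[str, ...]:
        """All ten allele identifiers (with repeats for homozygous loci)."""
        return tuple(a for pair in self.alleles for a in pair)


@dataclass(frozen=True)
class Candidate:
    """A transplant candidate; lower ``arrival_index`` = longer waiting."""

    id: str
    abo: str
    genotype: HLAGenotype
    arrival_index: int


@dataclass(frozen=True)
class Donor:
    """A deceased donor providing ``kidneys`` (two by default) for allocation."""

    id: str
    abo: str
    genotype: HLAGenotype
    kidneys: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.kidneys <= 2:
            raise ValueError(f"kidneys must be in [0, 2], got {self.kidneys}")


@dataclass
class HaplotypePool:
    """A frequency-weighted pool of 5-locus haplotypes plus allele sequences.

    ``haplotypes[i]`` is a 5-tuple of allele identifiers aligned with
    :data:`LOCI`; ``frequencies[i]`` is its population frequency;
    ``allele_sequences`` maps every allele identifier to its synthetic
    protein sequence.
    """

    haplotypes: list[tuple[str, ...]]
    frequencies: np.ndarray
    allele_sequences: dict[str, str]

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.validate()

    def validate(self) -> None:
        if len(self.haplotypes) == 0:
            raise ValueError("empty haplotype pool")
        if len(self.haplotypes) != len(self.frequencies):
            raise ValueError("haplotype/frequency length mismatch")
        if np.any(self.frequencies < 0):
            raise ValueError("negative haplotype frequency")
        if abs(float(self.frequencies.sum()) - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1 within 1e-9")
        lengths: dict[str, int] = {}
        for hap in self.haplotypes:
            if len(hap) != len(LOCI):
                raise ValueError("haplotype must cover all 5 loci")
            for locus, allele in zip(LOCI, hap):
                if allele not in self.allele_sequences:
                    raise ValueError(f"allele {allele!r} has no sequence")
                n = len(self.allele_sequences[allele])
                if lengths.setdefault(locus, n) != n:
                    raise ValueError(f"unequal sequence lengths at locus {locus}")

    @staticmethod
    def allele_locus(allele_id: str) -> str:
        """Locus encoded in an allele identifier such as ``DRB1*012``."""
        locus = allele_id.split("*", 1)[0]
        if locus not in LOCI:
            raise ValueError(f"cannot infer locus from allele id {allele_id!r}")
        return locus

    def sample_haplotype_indices(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(len(self.haplotypes), size=size, p=self.frequencies)

    def genotype_from_haplotypes(self, i: int, j: int) -> HLAGenotype:
        hi, hj = self.haplotypes[i], self.haplotypes[j]
        return HLAGenotype(tuple((hi[l], hj[l]) for l in range(len(LOCI))))


def build_haplotype_pool(
    n_haplotypes: int,
    n_polymorphic_sites: int,
    concentration: float,
    seed: int,
    *,
    alleles_per_locus: int | None = None,
    sequence_length: int = 60,
) -> HaplotypePool:
    """Build a synthetic haplotype pool.

    Parameters
    ----------
    n_haplotypes
        Number of distinct haplotypes (>= 2).
    n_polymorphic_sites
        Number of positions per locus at which alleles may differ from the
        locus backbone.
    concentration
        Symmetric Dirichlet concentration for the haplotype frequency
        spectrum; values < 1 give the skewed few-common/many-rare profile
        typical of HLA.
    seed
        Seed for the internal generator; identical seeds reproduce identical
        pools.
    alleles_per_locus
        Distinct alleles per locus; defaults to ``max(2, round(0.3 * n_haplotypes))``.
    sequence_length
        Length of every synthetic protein sequence.
    """
    if n_haplotypes < 2:
        raise ValueError("n_haplotypes must be >= 2 (no diversity otherwise)")
    if n_polymorphic_sites < 1:
        raise ValueError("n_polymorphic_sites must be positive")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if sequence_length < n_polymorphic_sites:
        raise ValueError("sequence_length must be >= n_polymorphic_sites")

    rng = np.random.default_rng(seed)
    if alleles_per_locus is None:
        alleles_per_locus = max(2, round(0.3 * n_haplotypes))
    if alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")

    aa = np.array(list(AMINO_ACIDS))
    allele_sequences: dict[str, str] = {}
    alleles_by_locus: dict[str, list[str]] = {}
    for locus in LOCI:
        backbone = rng.choice(aa, size=sequence_length)
        sites = np.sort(rng.choice(sequence_length, size=n_polymorphic_sites, replace=False))
        seen: set[str] = set()
        ids: list[str] = []
        for idx in range(alleles_per_locus):
            for _attempt in range(100):
                seq = backbone.copy()
                substituted = False
                for s in sites:
                    if rng.random() < 0.5:
                        choices = [r for r in AMINO_ACIDS if r != backbone[s]]
                        seq[s] = choices[rng.integers(len(choices))]
                        substituted = True
                if not substituted:
                    s = sites[rng.integers(len(sites))]
                    choices = [r for r in AMINO_ACIDS if r != backbone[s]]
                    seq[s] = choices[rng.integers(len(choices))]
                text = "".join(seq)
                if text not in seen:
                    break
            else:  # pragma: no cover - probabilistically unreachable
                raise RuntimeError("could not generate a unique allele sequence")
            seen.add(text)
            allele_id = f"{locus}*{idx + 1:03d}"
            allele_sequences[allele_id] = text
            ids.append(allele_id)
        alleles_by_locus[locus] = ids

    haplotypes = [
        tuple(alleles_by_locus[locus][rng.integers(alleles_per_locus)] for locus in LOCI)
        for _ in range(n_haplotypes)
    ]
    freqs = rng.dirichlet(np.full(n_haplotypes, concentration))
    freqs = np.sort(freqs)[::-1]
    freqs = freqs / freqs.sum()
    return HaplotypePool(haplotypes, freqs, allele_sequences)


def default_pool(seed: int) -> HaplotypePool:
    """The shipped default pool (see :data:`DEFAULT_POOL_PARAMS`)."""
    return build_haplotype_pool(
        int(DEFAULT_POOL_PARAMS["n_haplotypes"]),
        int(DEFAULT_POOL_PARAMS["n_polymorphic_sites"]),
        float(DEFAULT_POOL_PARAMS["concentration"]),
        seed,
    )


def _validate_abo_freqs(abo_freqs: Mapping[str, float]) -> tuple[list[str], np.ndarray]:
    groups = [g for g in ABO_GROUPS if g in abo_freqs]
    if set(abo_freqs) - set(ABO_GROUPS):
        raise ValueError(f"unknown ABO groups: {sorted(set(abo_freqs) - set(ABO_GROUPS))}")
    probs = np.array([abo_freqs[g] for g in groups], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError("ABO frequencies must be non-negative and sum to 1")
    return groups, probs / probs.sum()


def sample_person(
    pool: HaplotypePool,
    abo_freqs: Mapping[str, float],
    role: str,
    rng: np.random.Generator,
    *,
    person_id: str | None = None,
    arrival_index: int = 0,
) -> Candidate | Donor:
    """Draw one person: two independent haplotypes plus an independent ABO group."""
    if role not in ("candidate", "donor"):
        raise ValueError(f"role must be 'candidate' or 'donor', got {role!r}")
    groups, probs = _validate_abo_freqs(abo_freqs)
    i, j = pool.sample_haplotype_indices(rng, 2)
    genotype = pool.genotype_from_haplotypes(int(i), int(j))
    abo = groups[int(rng.choice(len(groups), p=probs))]
    if role == "candidate":
        pid = person_id if person_id is not None else f"C{arrival_index:06d}"
        return Candidate(pid, abo, genotype, arrival_index)
    pid = person_id if person_id is not None else "D000000"
    return Donor(pid, abo, genotype)


@dataclass(frozen=True)
class Streams:
    """The person streams of one replicate: initial waitlist (arrival order),
    donor sequence, and the replenishment candidates (two per donor)."""

    waitlist: tuple[Candidate, ...]
    donors: tuple[Donor, ...]
    replenishment: tuple[Candidate, ...]
    seed: int | None
    waitlist_size: int
    ratio: float

    @property
    def fingerprint(self) -> str:
        """Stable digest of all person ids, used to verify paired runs."""
        ids = [p.id for p in self.waitlist + self.donors + self.replenishment]
        return hashlib.blake2b("|".join(ids).encode(), digest_size=8).hexdigest()


def generate_streams(
    pool: HaplotypePool,
    abo_freqs: Mapping[str, float],
    waitlist_size: int,
    ratio: float,
    seed: int,
    *,
    id_prefix: str = "",
) -> Streams:
    """Generate the streams of one replicate.

    The donor count is ``floor(waitlist_size / ratio)`` (candidate-to-donor
    ratio); the replenishment stream supplies exactly two candidates per
    donor, with arrival indices continuing the initial waitlist sequence.
    """
    if waitlist_size < 2:
        raise ValueError("waitlist_size must be >= 2")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    n_donors = math.floor(waitlist_size / ratio)
    rng = np.random.default_rng(seed)
    waitlist = tuple(
        sample_person(
            pool, abo_freqs, "candidate", rng,
            person_id=f"{id_prefix}C{i:05d}", arrival_index=i,
        )
        for i in range(waitlist_size)
    )
    donors = tuple(
        sample_person(pool, abo_freqs, "donor", rng, person_id=f"{id_prefix}D{i:04d}")
        for i in range(n_donors)
    )
    replenishment = tuple(
        sample_person(
            pool, abo_freqs, "candidate", rng,
            person_id=f"{id_prefix}C{waitlist_size + i:05d}",
            arrival_index=waitlist_size + i,
        )
        for i in range(2 * n_donors)
    )
    return Streams(waitlist, donors, replenishment, seed, waitlist_size, float(ratio))


# ---------------------------------------------------------------------------
# TSV round-tripping

_COHORT_COLUMNS = ["id", "role", "abo", "arrival_index"] + [
    f"{locus}_{i}" for locus in LOCI for i in (1, 2)
]


def write_cohort(path: str | Path, candidates: Iterable[Candidate], donors: Iterable[Donor]) -> None:
    rows = []
    for c in candidates:
        row = {"id": c.id, "role": "candidate", "abo": c.abo, "arrival_index": c.arrival_index}
        for locus in LOCI:
            a1, a2 = c.genotype.pair(locus)
            row[f"{locus}_1"], row[f"{locus}_2"] = a1, a2
        rows.append(row)
    for d in donors:
        row = {"id": d.id, "role": "donor", "abo": d.abo, "arrival_index": ""}
        for locus in LOCI:
            a1, a2 = d.genotype.pair(locus)
            row[f"{locus}_1"], row[f"{locus}_2"] = a1, a2
        rows.append(row)
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> tuple[list[Candidate], list[Donor]]:
    """Read a cohort TSV, validating row by row (errors report line numbers,
    counting the header as line 1)."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pandas parse failure
        raise CohortFormatError(f"{path}: not a readable TSV ({exc})") from exc
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing columns {missing}")
    candidates: list[Candidate] = []
    donors: list[Donor] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        row_d = dict(zip(df.columns, row))
        role = row_d["role"]
        if role not in ("candidate", "donor"):
            raise CohortFormatError(f"{path}: line {line}: bad role {role!r}")
        if row_d["abo"] not in ABO_GROUPS:
            raise CohortFormatError(f"{path}: line {line}: bad ABO group {row_d['abo']!r}")
        pairs = []
        for locus in LOCI:
            a1, a2 = row_d[f"{locus}_1"], row_d[f"{locus}_2"]
            if not a1 or not a2:
                raise CohortFormatError(f"{path}: line {line}: missing allele at {locus}")
            pairs.append((a1, a2))
        genotype = HLAGenotype(tuple(pairs))
        if role == "candidate":
            try:
                arrival = int(row_d["arrival_index"])
            except ValueError:
                raise CohortFormatError(
                    f"{path}: line {line}: bad arrival_index {row_d['arrival_index']!r}"
                ) from None
            candidates.append(Candidate(row_d["id"], row_d["abo"], genotype, arrival))
        else:
            donors.append(Donor(row_d["id"], row_d["abo"], genotype))
    arrivals = [c.arrival_index for c in candidates]
    if len(set(arrivals)) != len(arrivals):
        raise CohortFormatError(f"{path}: duplicate candidate arrival indices")
    return candidates, donors


def write_pool(pool: HaplotypePool, alleles_path: str | Path, haplotypes_path: str | Path) -> None:
    allele_rows = [
        {"allele_id": aid, "locus": HaplotypePool.allele_locus(aid), "sequence": seq}
        for aid, seq in sorted(pool.allele_sequences.items())
    ]
    pd.DataFrame(allele_rows, columns=["allele_id", "locus", "sequence"]).to_csv(
        alleles_path, sep="\t", index=False
    )
    hap_rows = []
    for i, (hap, freq) in enumerate(zip(pool.haplotypes, pool.frequencies)):
        row = {"haplotype_id": f"H{i:04d}"}
        row.update(dict(zip(LOCI, hap)))
        row["frequency"] = repr(float(freq))  # full precision round-trip
        hap_rows.append(row)
    pd.DataFrame(hap_rows, columns=["haplotype_id", *LOCI, "frequency"]).to_csv(
        haplotypes_path, sep="\t", index=False
    )


def read_pool(alleles_path: str | Path, haplotypes_path: str | Path) -> HaplotypePool:
    alleles = pd.read_csv(alleles_path, sep="\t", dtype=str)
    haps = pd.read_csv(haplotypes_path, sep="\t", dtype={"frequency": float})
    sequences = dict(zip(alleles["allele_id"], alleles["sequence"]))
    haplotypes = [tuple(str(row[locus]) for locus in LOCI) for _, row in haps.iterrows()]
    freqs = haps["frequency"].to_numpy(dtype=float)
    return HaplotypePool(haplotypes, freqs / freqs.sum(), sequences)
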