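"""Mismatch scoring: peptides, presenter, strata, surrogate and matrix scorers."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from allosim import (
    LOCI,
    HaplotypePool,
    HLAGenotype,
    MatrixScorer,
    PresenterModel,
    ScoreVector,
    SurrogateScorer,
    classify_stratum,
    derive_peptides,
    load_score_matrix,
    locus_score,
    score_pair,
    write_score_matrix,
)
from allosim.scoring import ScoreMatrixFormatError

from conftest import make_toy_pool, random_genotype
from helpers import brute_locus_score, brute_score_vector


# -- peptides ----------------------------------------------------------------

@pytest.mark.parametrize(
    "seq,k,expected",
    [
        ("ABCDE", 5, {"ABCDE"}),
        ("ABCDE", 3, {"ABC", "BCD", "CDE"}),
        ("AAAA", 2, {"AA"}),
    ],
)
def test_derive_peptides_enumeration(seq, k, expected):
    assert derive_peptides(seq, k) == expected


def test_derive_peptides_rejects_short_sequence():
    with pytest.raises(ValueError):
        derive_peptides("AB", 3)


@given(st.text(alphabet="ACDEF", min_size=1, max_size=30), st.integers(1, 30))
def test_derive_peptides_properties(seq, k):
    if k > len(seq):
        with pytest.raises(ValueError):
            derive_peptides(seq, k)
        return
    peps = derive_peptides(seq, k)
    assert all(len(p) == k for p in peps)
    assert 1 <= len(peps) <= len(seq) - k + 1
    assert all(p in seq for p in peps)


# -- strata ------------------------------------------------------------------

@pytest.mark.parametrize(
    "score,label",
    [(0, "low"), (8, "low"), (9, "elevated"), (34, "elevated"),
     (35, "intermediate"), (89, "intermediate"), (90, "high"), (500, "high")],
)
def test_stratum_boundaries(score, label):
    assert classify_stratum(score) == label


def test_stratum_rejects_negative():
    with pytest.raises(ValueError):
        classify_stratum(-1)


@given(st.integers(0, 10_000))
def test_strata_partition_nonnegative_integers(score):
    from allosim import STRATUM_BOUNDS, STRATUM_LABELS

    label = classify_stratum(score)
    containing = [
        l for l, (lo, hi) in zip(STRATUM_LABELS, STRATUM_BOUNDS)
        if score >= lo and (hi is None or score < hi)
    ]
    assert containing == [label]


# -- presenter ---------------------------------------------------------------

def test_presenter_is_pure_and_symmetric():
    p = PresenterModel(acceptance_rate=0.4, seed=3)
    assert p.accepts("PEPTIDEKL", ("DRB1*001", "DRB1*002")) == p.accepts(
        "PEPTIDEKL", ("DRB1*002", "DRB1*001")
    )
    first = [p.accepts("AAAA", ("x", "y")) for _ in range(5)]
    assert len(set(first)) == 1


def test_presenter_rejects_bad_rate():
    with pytest.raises(ValueError):
        PresenterModel(acceptance_rate=0.0)
    with pytest.raises(ValueError):
        PresenterModel(acceptance_rate=1.5)


@pytest.mark.parametrize("rate", [0.1, 0.5, 0.9])
def test_presenter_calibration(rate):
    # fraction of accepted random peptide/DRB1 queries within 3 binomial SE
    p = PresenterModel(acceptance_rate=rate, seed=1)
    rng = np.random.default_rng(7)
    letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    n = 10_000
    hits = 0
    for i in range(n):
        pep = "".join(rng.choice(letters, size=9))
        pair = (f"DRB1*{rng.integers(50):03d}", f"DRB1*{rng.integers(50):03d}")
        hits += p.accepts(pep, pair)
    se = np.sqrt(rate * (1 - rate) / n)
    assert abs(hits / n - rate) < 3 * se


# -- surrogate scorer --------------------------------------------------------

def _toy_two_allele_pool():
    """One scored locus with two nearly identical alleles; other loci shared."""
    sequences = {"A*001": "AAAAAAAAAA", "A*002": "AAAACAAAAA"}
    for locus, ch in zip(("B", "C", "DRB1", "DQB1"), "FGHK"):
        sequences[f"{locus}*001"] = ch * 10
    h1 = ("A*001", "B*001", "C*001", "DRB1*001", "DQB1*001")
    h2 = ("A*002", "B*001", "C*001", "DRB1*001", "DQB1*001")
    return HaplotypePool([h1, h2], np.array([0.5, 0.5]), sequences)


class _AcceptAll:
    def accepts(self, peptide, drb1_pair):
        return True


class _AcceptNone:
    def accepts(self, peptide, drb1_pair):
        return False


def test_two_allele_toy_matches_brute_force_count():
    pool = _toy_two_allele_pool()
    donor = pool.genotype_from_haplotypes(1, 1)     # homozygous A*002
    recipient = pool.genotype_from_haplotypes(0, 0)  # homozygous A*001
    scorer = SurrogateScorer(pool, _AcceptAll(), k=9)
    # brute force: A*002 has 9-mers {AAAACAAAA, AAACAAAAA} absent from self
    assert scorer.locus_score(donor, recipient, "A") == 2
    assert SurrogateScorer(pool, _AcceptNone(), k=9).locus_score(donor, recipient, "A") == 0


def test_identical_genotypes_score_zero(toy_pool):
    scorer = SurrogateScorer(toy_pool, PresenterModel(acceptance_rate=1.0))
    rng = np.random.default_rng(0)
    for _ in range(20):
        g = random_genotype(toy_pool, rng)
        vec = scorer.score_genotypes(g, g)
        assert vec.per_locus == (0, 0, 0, 0, 0)
        assert vec.sum5 == 0


def test_locus_score_equals_exhaustive_enumeration():
    rng = np.random.default_rng(5)
    for seed in range(20):
        pool = make_toy_pool(seed, alleles_per_locus=4, length=30)
        presenter = PresenterModel(acceptance_rate=0.6, seed=seed)
        scorer = SurrogateScorer(pool, presenter, k=9)
        donor, recipient = random_genotype(pool, rng), random_genotype(pool, rng)
        for locus in LOCI:
            assert scorer.locus_score(donor, recipient, locus) == brute_locus_score(
                pool, donor, recipient, locus, presenter, 9
            )


def test_score_pair_cache_matches_fresh_recomputation(toy_pool):
    presenter = PresenterModel(seed=2)
    scorer = SurrogateScorer(toy_pool, presenter)
    rng = np.random.default_rng(3)
    donor, recipient = random_genotype(toy_pool, rng), random_genotype(toy_pool, rng)
    cached_twice = (scorer.score_genotypes(donor, recipient),
                    scorer.score_genotypes(donor, recipient))
    fresh = SurrogateScorer(toy_pool, presenter).score_genotypes(donor, recipient)
    free_fn = score_pair(donor, recipient, presenter, toy_pool)
    assert cached_twice[0] == cached_twice[1] == fresh == free_fn
    assert locus_score(donor, recipient, "B", presenter, toy_pool) == fresh["B"]


def test_allele_replacement_monotonicity(toy_pool):
    # replacing a donor allele with a recipient allele never raises any score
    presenter = PresenterModel(seed=4)
    scorer = SurrogateScorer(toy_pool, presenter)
    rng = np.random.default_rng(8)
    for _ in range(30):
        donor, recipient = random_genotype(toy_pool, rng), random_genotype(toy_pool, rng)
        locus_i = int(rng.integers(len(LOCI)))
        new_alleles = list(donor.alleles)
        pair = list(new_alleles[locus_i])
        pair[int(rng.integers(2))] = recipient.alleles[locus_i][int(rng.integers(2))]
        new_alleles[locus_i] = tuple(pair)
        modified = HLAGenotype(tuple(new_alleles))
        before = scorer.score_genotypes(donor, recipient)
        after = scorer.score_genotypes(modified, recipient)
        assert all(a <= b for a, b in zip(after.per_locus, before.per_locus))


def test_missing_allele_sequence_raises(toy_pool):
    scorer = SurrogateScorer(toy_pool, PresenterModel())
    rng = np.random.default_rng(1)
    g = random_genotype(toy_pool, rng)
    alien = HLAGenotype(tuple(
        (a1, "A*999") if locus == "A" else (a1, a2)
        for locus, (a1, a2) in zip(LOCI, g.alleles)
    ))
    with pytest.raises(LookupError, match="A\\*999"):
        scorer.score_genotypes(alien, g)


@given(st.tuples(*[st.integers(0, 50)] * 5))
def test_sum5_is_sum_of_locus_scores(scores):
    vec = ScoreVector(scores)
    assert vec.sum5 == sum(scores)
    assert [vec[l] for l in LOCI] == list(scores)


def test_score_vector_rejects_negative():
    with pytest.raises(ValueError):
        ScoreVector((1, 2, -1, 0, 0))


# -- matrix scorer -----------------------------------------------------------

def test_matrix_sum_recomputed_and_lookup_errors(tmp_path):
    path = tmp_path / "scores.tsv"
    write_score_matrix(path, [("d1", "r1", ScoreVector((15, 14, 13, 14, 20)))])
    matrix = load_score_matrix(path)
    assert matrix.score_ids("d1", "r1").sum5 == 76
    with pytest.raises(LookupError):
        matrix.score_ids("d1", "r2")


def test_matrix_round_trip_reproduces_surrogate(toy_pool, tmp_path):
    from allosim import DEFAULT_ABO_FREQS, generate_streams

    scorer = SurrogateScorer(toy_pool, PresenterModel(seed=9))
    streams = generate_streams(toy_pool, DEFAULT_ABO_FREQS, 6, 2, seed=14)
    records = [
        (d.id, c.id, scorer.score_pair(d, c))
        for d in streams.donors
        for c in streams.waitlist
    ]
    path = tmp_path / "scores.tsv"
    write_score_matrix(path, records)
    matrix = load_score_matrix(path)
    for d in streams.donors:
        for c in streams.waitlist:
            assert matrix.score_pair(d, c) == scorer.score_pair(d, c)


@pytest.mark.parametrize("bad_value", ["-3", "2.5", "x"])
def test_matrix_rejects_bad_scores(tmp_path, bad_value):
    path = tmp_path / "bad.tsv"
    header = "donor_id\trecipient_id\t" + "\t".join(f"score_{l}" for l in LOCI)
    row = f"d1\tr1\t{bad_value}\t1\t1\t1\t1"
    path.write_text(header + "\n" + row + "\n")
    with pytest.raises(ScoreMatrixFormatError):
        load_score_matrix(path)
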