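"""Independent oracles used by the test suite.

Each oracle materialises the full object it checks (peptide sets, the
entire eligible candidate list) instead of using the package's indexed or
cached paths, so it stays an independent reference implementation.
"""

from allosim import HLAGenotype, ScoreVector, derive_peptides
from allosim.cohort import LOCI, Streams


def brute_locus_score(pool, donor_g, recipient_g, locus, presenter, k):
    """Mismatch score by exhaustive k-mer enumeration and set difference."""
    donor_peps = set()
    for allele in donor_g.pair(locus):
        donor_peps |= derive_peptides(pool.allele_sequences[allele], k)
    self_peps = set()
    for allele in recipient_g.all_alleles():
        self_peps |= derive_peptides(pool.allele_sequences[allele], k)
    drb1 = recipient_g.drb1_pair
    return sum(presenter.accepts(p, drb1) for p in donor_peps - self_peps)


def brute_score_vector(pool, donor_g, recipient_g, presenter, k):
    return ScoreVector(
        tuple(brute_locus_score(pool, donor_g, recipient_g, locus, presenter, k) for locus in LOCI)
    )


def oracle_allocate(streams: Streams, strategy, scorer):
    """Greedy allocation by explicit per-kidney minimum search.

    Returns (matched pairs as (donor_id, recipient_id), unallocated donor ids).
    """
    waitlist = list(streams.waitlist)
    matched, unallocated = [], []
    pos = 0
    for donor in streams.donors:
        for _kidney in (1, 2):
            eligible = [c for c in waitlist if c.abo == donor.abo]
            if not eligible:
                unallocated.append(donor.id)
                continue
            if strategy.mode == "base_case":
                best = min(eligible, key=lambda c: c.arrival_index)
            else:
                def rank(c):
                    vec = scorer.score_pair(donor, c)
                    return (sum(vec[l] for l in strategy.objective_loci), c.arrival_index)
                best = min(eligible, key=rank)
            waitlist.remove(best)
            matched.append((donor.id, best.id))
        waitlist.extend(streams.replenishment[pos : pos + 2])
        pos += 2
    return matched, unallocated
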