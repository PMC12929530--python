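import numpy as np
import pytest
from hypothesis import settings

from allosim import PresenterModel, SurrogateScorer, build_haplotype_pool, default_pool

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def pool():
    """The shipped default haplotype pool."""
    return default_pool(seed=7)


@pytest.fixture(scope="session")
def scorer(pool):
    """Default surrogate scorer over the default pool."""
    return SurrogateScorer(pool, PresenterModel())


def make_toy_pool(seed, n_haplotypes=6, alleles_per_locus=3, sites=6, length=20):
    """A small pool suitable for exhaustive oracles."""
    return build_haplotype_pool(
        n_haplotypes, sites, 0.5, seed,
        alleles_per_locus=alleles_per_locus, sequence_length=length,
    )


@pytest.fixture()
def toy_pool():
    return make_toy_pool(seed=11)


def random_genotype(pool, rng):
    i, j = pool.sample_haplotype_indices(rng, 2)
    return pool.genotype_from_haplotypes(int(i), int(j))
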