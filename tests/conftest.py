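import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitonuc.seqdata import AlignedDataset, Ploidy, SampleRecord

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_haploid(seqs, isolates=None, locus="mito"):
    """Small haploid dataset from raw sequence strings."""
    n = len(seqs)
    isolates = isolates or ["ISO1"] * n
    samples = tuple(
        SampleRecord(f"i{k:02d}", isolates[k], "domestic") for k in range(n)
    )
    return AlignedDataset(
        locus_name=locus,
        ploidy=Ploidy.haploid,
        alignment_length=len(seqs[0]),
        sequences=tuple((f"i{k:02d}", 0, s) for k, s in enumerate(seqs)),
        samples=samples,
    )


def make_diploid(pairs, isolates=None, locus="nuclear"):
    """Diploid dataset from (allele0, allele1) string pairs."""
    n = len(pairs)
    isolates = isolates or ["ISO1"] * n
    samples = tuple(
        SampleRecord(f"i{k:02d}", isolates[k], "domestic") for k in range(n)
    )
    seqs = []
    for k, (a, b) in enumerate(pairs):
        seqs.append((f"i{k:02d}", 0, a))
        seqs.append((f"i{k:02d}", 1, b))
    return AlignedDataset(
        locus_name=locus,
        ploidy=Ploidy.diploid,
        alignment_length=len(pairs[0][0]),
        sequences=tuple(seqs),
        samples=samples,
    )


@pytest.fixture(scope="session")
def two_pop_data():
    """Well-separated two-population simulation shared across tests."""
    from mitonuc import simulate as sm

    sc = sm.two_population_scenario(split_time=4000, n_per_pop=15, seed=5)
    mito, nuc, truth = sm.simulate(sc)
    return sc, mito, nuc, truth


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
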