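import numpy as np
import pytest

from neanderscan import (
    ArchaicGenome,
    HaplotypePanel,
    SimulationParams,
    VariantRecord,
    simulate_panel,
)


def make_panel(
    haplotypes,
    positions=None,
    populations=None,
    african_pop="AFR",
    chrom="1",
    info_scores=None,
):
    """Build a small panel from a (n_variants, n_haplotypes) 0/1/-1 array.

    Haplotype columns are paired into diploid samples; ``populations``
    gives one label per sample.
    """
    h = np.asarray(haplotypes, dtype=np.int8)
    n_var, n_hap = h.shape
    assert n_hap % 2 == 0
    n_samp = n_hap // 2
    if positions is None:
        positions = np.arange(n_var) * 1000 + 100
    if populations is None:
        populations = ["AFR"] * (n_samp // 2) + ["EUR"] * (n_samp - n_samp // 2)
    variants = [
        VariantRecord(
            chrom=chrom,
            pos=int(p),
            id=f"v{i}",
            ref="A",
            alt="G",
            info_score=None if info_scores is None else info_scores[i],
        )
        for i, p in enumerate(positions)
    ]
    samples = [f"{populations[i]}_{i}" for i in range(n_samp)]
    return HaplotypePanel(
        chrom=chrom,
        variants=variants,
        samples=samples,
        populations=list(populations),
        genotypes=h.reshape(n_var, n_samp, 2),
        african_pop=african_pop,
    )


def make_archaic(allele_pairs):
    return ArchaicGenome(sample="Archaic", genotypes=np.asarray(allele_pairs, dtype=np.int8))


@pytest.fixture(scope="session")
def default_sim():
    """The default simulated study panel: 10 Mb, 50 diploids per population."""
    return simulate_panel(SimulationParams(seed=2024))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
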