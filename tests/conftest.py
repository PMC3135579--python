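import numpy as np
import pytest

from mirchrom import (
    CoverageTrack,
    GeneModel,
    GenomeSequence,
    GenomicInterval,
    SyntheticConfig,
    generate_bundle,
)


@pytest.fixture
def two_exon_gene():
    """One gene with exons [1000,1100) and [2000,2100) -> intron [1100,2000)."""
    return GeneModel(
        "geneA",
        "chr1",
        "+",
        [GenomicInterval("chr1", 1000, 1100, "+"),
         GenomicInterval("chr1", 2000, 2100, "+")],
    )


@pytest.fixture
def constant_track():
    def make(value: float, length: int = 30_000, chrom: str = "chr1"):
        return CoverageTrack({chrom: np.full(length, float(value))})

    return make


@pytest.fixture
def random_track():
    def make(seed: int, length: int = 30_000, chrom: str = "chr1"):
        rng = np.random.default_rng(seed)
        return CoverageTrack({chrom: rng.uniform(0, 10, size=length)})

    return make


@pytest.fixture
def tiny_genome():
    rng = np.random.default_rng(7)
    seq = "".join(rng.choice(list("ACGT"), size=20_000))
    return GenomeSequence({"chr1": seq})


@pytest.fixture(scope="session")
def small_bundle():
    """Small but complete synthetic bundle shared across tests."""
    cfg = SyntheticConfig(
        seed=11,
        n_intronic=6,
        n_intergenic=6,
        n_exonic=4,
        chromosome_length=250_000,
        marks=("RNAPII",),
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The generator's default study conditions (50/50/25 loci)."""
    return generate_bundle(SyntheticConfig(seed=1))
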