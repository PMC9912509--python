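import numpy as np
import pytest

from k27shared.genome import GeneModel, GenomicInterval, make_gene_regions
from k27shared.simulate import SimConfig


@pytest.fixture
def toy_genes():
    """Four well-separated genes on two chromosomes, both strands."""
    return [
        GeneModel("geneA", "chr1", "+", 10_000, 20_000),
        GeneModel("geneB", "chr1", "-", 40_000, 52_000),
        GeneModel("geneC", "chr2", "+", 10_000, 18_000),
        GeneModel("geneD", "chr2", "-", 50_000, 64_000),
    ]


@pytest.fixture
def toy_regions(toy_genes):
    return make_gene_regions(toy_genes, promoter_bp=2000)


@pytest.fixture
def rng():
    return np.random.default_rng(7)


@pytest.fixture
def small_sim():
    """A scaled-down study for generator tests: fast, same structure."""
    return SimConfig(
        seed=0,
        n_genes=30,
        n_shared_retained=8,
        n_specific_retained=4,
        background_peaks_per_sample=5,
        enhancers_per_sample=12,
        n_shared_enhancer_loci=3,
        n_specific_enhancer_loci=2,
        n_cells=120,
        n_sc_genes=100,
        subgroup_sizes={"H3.3": 12, "H3.1": 8, "EZHIP": 6, "PFA": 14},
    )


def interval(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)
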