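import numpy as np
import pytest

from cistromics.intervals import GeneModel, GenomicInterval, Peak, Workspace


def make_peak(chrom, start, end, height=1.0, name=""):
    return Peak(GenomicInterval(chrom, start, end), height, name)


def make_gene(gene_id, chrom, start, end, strand):
    return GeneModel(gene_id, GenomicInterval(chrom, start, end, strand))


@pytest.fixture
def toy_workspace():
    """Single 100-bp segment: the exactly enumerable association toy."""
    return Workspace([GenomicInterval("chr1", 0, 100)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
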