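import numpy as np
import pytest
from hypothesis import settings

from m6akit.annotation import GeneModel

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def two_exon_plus():
    """Plus-strand model with exons [(100,200),(300,400)); 200-nt transcript."""
    return GeneModel(
        gene_id="G1",
        transcript_id="T1",
        chrom="chr1",
        strand="+",
        exons=((100, 200), (300, 400)),
        cds_start_tx=50,
        cds_end_tx=150,
    )


@pytest.fixture
def two_exon_minus():
    return GeneModel(
        gene_id="G2",
        transcript_id="T2",
        chrom="chr1",
        strand="-",
        exons=((100, 200), (300, 400)),
        cds_start_tx=50,
        cds_end_tx=150,
    )


@pytest.fixture
def segment_model():
    """Single-exon coding model with 100/300/200 nt 5'UTR/CDS/3'UTR."""
    return GeneModel(
        gene_id="G3",
        transcript_id="T3",
        chrom="chr1",
        strand="+",
        exons=((0, 600),),
        cds_start_tx=100,
        cds_end_tx=400,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
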