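import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from mircontext import (
    GeneModel,
    GenomicInterval,
    MatureMirna,
    MirnaPrecursor,
    Transcript,
)


def make_precursor(mirna_id, chrom, start, end, strand="+", matures=()):
    return MirnaPrecursor(
        mirna_id=mirna_id,
        interval=GenomicInterval(chrom, start, end, strand),
        matures=tuple(matures),
    )


def make_gene(gene_id, chrom, start, end, strand="+", exons=None, cds=(), utr5=(), utr3=(), age=None):
    """Single-transcript gene; exons default to the full span."""
    if exons is None:
        exons = [(start, end)]
    tx = Transcript(
        transcript_id=f"{gene_id}.t1",
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        cds=tuple(GenomicInterval(chrom, s, e, strand) for s, e in cds),
        utr5=tuple(GenomicInterval(chrom, s, e, strand) for s, e in utr5),
        utr3=tuple(GenomicInterval(chrom, s, e, strand) for s, e in utr3),
    )
    return GeneModel(
        gene_id=gene_id,
        span=GenomicInterval(chrom, start, end, strand),
        transcripts=(tx,),
        gene_age=age,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def two_exon_gene():
    """Gene chr1:500-10000(+), longest transcript exons 500-600 and 9000-10000."""
    return make_gene("geneA", "chr1", 500, 10_000, "+", exons=[(500, 600), (9_000, 10_000)])
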