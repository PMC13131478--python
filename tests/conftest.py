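import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from outronscan.coverage_engine import CoverageTrack
from outronscan.genome_model import (
    AnnotationSet,
    GeneModel,
    GenomicInterval,
    TranscriptModel,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_gene(gene_id, start, end, strand="+", biotype="protein_coding",
              chrom="chrT", exons=None):
    """Single-transcript gene helper for hand-built fixtures."""
    span = GenomicInterval(chrom, start, end, strand)
    if exons is None:
        exons = (span,)
    tx = TranscriptModel(gene_id + ".1", gene_id, strand, tuple(exons))
    return GeneModel(gene_id, biotype, strand, span, (tx,), tx)


def constant_track(value, length=10000, chrom="chrT", strand="+"):
    return CoverageTrack(values={chrom: np.full(length, float(value))}, strand=strand)


def array_track(values, chrom="chrT", strand="+"):
    return CoverageTrack(
        values={chrom: np.asarray(values, dtype=float)}, strand=strand
    )


@pytest.fixture
def toy_annotation():
    """Three well-separated genes on both strands plus an snRNA."""
    genes = [
        make_gene("gA", 1000, 2600, "+"),
        make_gene("gB", 4000, 6000, "-"),
        make_gene("gC", 8000, 9600, "+"),
        make_gene("sn1", 12000, 12150, "+", biotype="snRNA"),
    ]
    return AnnotationSet(genes, chrom_sizes={"chrT": 40000})
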