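import numpy as np
import pytest

from annoweave.genomic_model import GenomicInterval, TranscriptModel
from annoweave.isoseq_processing import AlignedIsoform
from annoweave.orf_finder import Orf
from annoweave.synthetic_data import FixtureConfig, generate_annotation_fixture


@pytest.fixture(scope="session")
def annotation_fixture():
    """A 40-gene synthetic fixture shared by read-only tests."""
    cfg = FixtureConfig(seed=20, n_genes=40, genome_length_bp=200_000)
    return generate_annotation_fixture(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_transcript(
    exon_coords,
    strand="+",
    seq_id="chr1",
    tid="t1",
    gene_id=None,
    cds_coords=None,
    source="prediction",
    attributes=None,
):
    """Helper to build transcript models from (start, end) pairs."""
    exons = tuple(GenomicInterval(seq_id, s, e, strand) for s, e in exon_coords)
    cds = tuple(
        GenomicInterval(seq_id, s, e, strand) for s, e in (cds_coords or [])
    )
    return TranscriptModel(
        id=tid,
        gene_id=gene_id or tid,
        exons=exons,
        cds=cds,
        source=source,
        attributes=attributes or {},
    )


def make_isoform(
    exon_coords,
    lorf_len,
    strand="+",
    seq_id="chr1",
    tid="iso1",
    identity=1.0,
    coverage=1.0,
):
    """AlignedIsoform with a fabricated ORF of the given length."""
    t = make_transcript(exon_coords, strand, seq_id, tid, source="isoseq")
    lorf = Orf(tid, 0, lorf_len) if lorf_len else None
    return AlignedIsoform(t, identity, coverage, lorf)
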