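import numpy as np
import pytest

from txevents.annotation_io import GeneModel, GenomicInterval, TranscriptModel
from txevents.simulate import GeneStructureSpec, TranscriptOptions, make_gene


def iv(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def tx(tid, exons, gene_id="G1", strand="+", biotype="protein_coding", tags=()):
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id,
        strand=strand,
        exons=list(exons),
        biotype=biotype,
        tags=set(tags),
    )


def mirror_gene(g: GeneModel, origin: int = 10_000_000) -> GeneModel:
    """Coordinate-mirrored copy of a gene (strand flipped)."""
    flipped = []
    for t in g.transcripts:
        strand = "-" if t.strand == "+" else "+"
        exons = [
            GenomicInterval(e.chrom, origin - e.end, origin - e.start, strand)
            for e in t.exons
        ]
        flipped.append(
            TranscriptModel(t.transcript_id, t.gene_id, strand, exons, t.biotype, set(t.tags))
        )
    return GeneModel(g.gene_id, flipped)


def mirror_chain(chain, origin: int = 10_000_000):
    return tuple(sorted((origin - e, origin - s) for s, e in chain))


@pytest.fixture
def canonical_two_transcript_spec():
    """Two transcripts differing at the first exon, one internal exon and
    the last exon — the textbook case yielding all three event types."""
    return GeneStructureSpec(
        transcripts=[
            TranscriptOptions(),
            TranscriptOptions(alt_first=1, skip_internal=2, alt_last=1),
        ],
        n_core_exons=5,
        seed=11,
    )


@pytest.fixture
def canonical_gene(canonical_two_transcript_spec):
    gene, truth = make_gene(canonical_two_transcript_spec)
    return gene, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
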