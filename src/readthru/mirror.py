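"""Strand-reversal + coordinate-reflection of annotations and reads.

Mirroring maps position x to L − x (L = chromosome length) and flips the
strand, turning a − strand gene into an equivalent + strand gene.  Every
strand-aware quantity in the pipeline (TSS, PAS, readthrough boundary,
read 5′/3′ ends) must be invariant under this transformation; the test
suite exercises that symmetry, and the simulator uses mirroring to
generate − strand reads with single-strand logic.
"""

from __future__ import annotations

from typing import Iterable, Mapping

from readthru.annotation import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    TranscriptModel,
)
from readthru.reads import LongRead

_FLIP = {"+": "-", "-": "+"}


def mirror_interval(iv: Interval, length: int) -> Interval:
    return Interval(iv.chrom, length - iv.end, length - iv.start, _FLIP[iv.strand])


def mirror_transcript(t: TranscriptModel, length: int) -> TranscriptModel:
    return TranscriptModel(
        t.transcript_id,
        t.gene_id,
        tuple(mirror_interval(e, length) for e in t.exons),
        is_canonical=t.is_canonical,
    )


def mirror_gene(g: GeneModel, length: int) -> GeneModel:
    return GeneModel(
        g.gene_id,
        g.biotype,
        tuple(mirror_transcript(t, length) for t in g.transcripts),
    )


def mirror_annotation(
    annotation: GenomeAnnotation,
    chrom_lengths: Mapping[str, int] | None = None,
) -> GenomeAnnotation:
    lengths = dict(chrom_lengths or annotation.chrom_lengths)
    if not lengths:
        raise ValueError("chromosome lengths required to mirror an annotation")
    return GenomeAnnotation(
        (mirror_gene(g, lengths[g.chrom]) for g in annotation),
        chrom_lengths=lengths,
    )


def mirror_read(read: LongRead, length: int) -> LongRead:
    return LongRead(
        read.read_id, tuple(mirror_interval(b, length) for b in read.blocks)
    )


def mirror_reads(
    reads: Iterable[LongRead], length: int
) -> list[LongRead]:
    return [mirror_read(r, length) for r in reads]
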