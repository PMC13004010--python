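"""Long-read parsing and per-read classification.

A nascent RNA long read is modelled as its aligned blocks; the gaps between
blocks are candidate splice junctions.  The strand-aware 3′ end of a read is
the position of RNA polymerase II at the moment of capture, which is what
makes readthrough classification possible: a polymerase that failed to
terminate has its 3′ end past the readthrough boundary (PAS + 100 nt).

Classification of one read answers four questions: which gene does it
belong to (greatest block overlap wins), is it spliced (per annotated
intron: spliced / retained / not informative), did it read through (3′ end
at or beyond the boundary while touching the last exon), and does it start
at the TSS (5′ end within a window of the annotated start).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from readthru.annotation import (
    GeneModel,
    GenomeAnnotation,
    Interval,
    ParseError,
    TranscriptModel,
    parse_bed12_line,
)

logger = logging.getLogger(__name__)

SPLICING_STATUSES = (
    "all_spliced",
    "partially_spliced",
    "all_unspliced",
    "not_informative",
)
READTHROUGH_CLASSES = ("gene_body", "readthrough", "not_last_exon")


@dataclass(frozen=True)
class LongRead:
    """One aligned long read: ordered blocks plus derived junctions."""

    read_id: str
    blocks: tuple[Interval, ...]
    junctions: tuple[Interval, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError(f"read {self.read_id} has no blocks")
        blocks = tuple(sorted(self.blocks, key=lambda b: b.start))
        for a, b in zip(blocks, blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"read {self.read_id} has overlapping blocks")
        object.__setattr__(self, "blocks", blocks)
        juncs = tuple(
            Interval(a.chrom, a.end, b.start, a.strand)
            for a, b in zip(blocks, blocks[1:])
            if b.start > a.end
        )
        object.__setattr__(self, "junctions", juncs)

    @property
    def chrom(self) -> str:
        return self.blocks[0].chrom

    @property
    def strand(self) -> str:
        return self.blocks[0].strand

    @property
    def start(self) -> int:
        return self.blocks[0].start

    @property
    def end(self) -> int:
        return self.blocks[-1].end

    @property
    def five_prime(self) -> int:
        """Strand-aware 5′ end of the read."""
        return self.start if self.strand == "+" else self.end

    @property
    def three_prime(self) -> int:
        """Strand-aware 3′ end — the Pol II position for nascent RNA."""
        return self.end if self.strand == "+" else self.start

    def aligned_overlap(self, interval: Interval) -> int:
        """Aligned (block) bases shared with ``interval``."""
        return sum(b.overlap(interval) for b in self.blocks)


@dataclass(frozen=True)
class IntronCall:
    """Per-intron outcome for one read."""

    intron_index: int
    overlapped: bool
    spliced: bool


@dataclass(frozen=True)
class ReadCall:
    """Full classification of one read against its assigned gene."""

    read_id: str
    gene_id: Optional[str]
    splicing_status: str
    n_introns_overlapped: int
    n_introns_spliced: int
    readthrough_class: Optional[str]
    starts_at_tss: Optional[bool]
    intron_calls: tuple[IntronCall, ...] = ()


def read_long_reads(path: str | Path) -> list[LongRead]:
    """Parse a BED12 file of spliced long-read alignments."""
    reads = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            name, _span, blocks = parse_bed12_line(line, lineno)
            reads.append(LongRead(name, blocks))
    return reads


def assign_read_to_gene(
    read: LongRead, annotation: GenomeAnnotation
) -> Optional[str]:
    """Assign a read to the same-strand gene with the greatest aligned
    overlap (gene span extended to its readthrough boundary).

    Exact ties go to the lexicographically smaller gene_id so that the
    result does not depend on input order.  Returns ``None`` when no gene
    overlaps.
    """
    candidates = annotation.overlapping(read.chrom, read.strand, read.start, read.end)
    best_id: Optional[str] = None
    best_overlap = 0
    tied = False
    for gene in candidates:  # sorted by gene_id, so first max wins ties
        span = annotation.extended_span(gene.gene_id)
        ov = read.aligned_overlap(span)
        if ov > best_overlap:
            best_overlap, best_id = ov, gene.gene_id
            tied = False
        elif ov == best_overlap and ov > 0:
            tied = True
    if tied:
        logger.debug("read %s: tied gene overlap, chose %s", read.read_id, best_id)
    return best_id


def _junction_matches(
    junction: Interval, intron: Interval, tolerance: int
) -> bool:
    return (
        abs(junction.start - intron.start) <= tolerance
        and abs(junction.end - intron.end) <= tolerance
    )


def classify_splicing_status(
    read: LongRead,
    transcript: TranscriptModel,
    junction_tolerance: int = 0,
) -> tuple[str, tuple[IntronCall, ...]]:
    """Classify a read's splicing against one transcript's introns.

    An intron counts as *overlapped* when the read span covers the whole
    intron and the read has at least one aligned base in each flanking
    exon; it is *spliced* when one of the read's junctions matches both
    intron boundaries within ``junction_tolerance`` nt.  Junctions matching
    no annotated intron are ignored here (they are novel junctions, not
    evidence about annotated introns).

    Returns the status (all_spliced / partially_spliced / all_unspliced /
    not_informative) and the per-intron calls for overlapped introns.
    """
    introns = transcript.introns
    if not introns:
        return "not_informative", ()
    exons = transcript.exons
    calls = []
    for i, intron in enumerate(introns):
        spliced = any(
            _junction_matches(j, intron, junction_tolerance)
            for j in read.junctions
        )
        if spliced:
            overlapped = True
        else:
            overlapped = (
                read.start < intron.start
                and read.end > intron.end
                and read.aligned_overlap(exons[i]) > 0
                and read.aligned_overlap(exons[i + 1]) > 0
            )
        if overlapped:
            calls.append(IntronCall(i, True, spliced))
    n_over = len(calls)
    n_spliced = sum(c.spliced for c in calls)
    if n_over == 0:
        status = "not_informative"
    elif n_spliced == n_over:
        status = "all_spliced"
    elif n_spliced == 0:
        status = "all_unspliced"
    else:
        status = "partially_spliced"
    return status, tuple(calls)


def classify_readthrough(
    read: LongRead, gene: GeneModel, min_last_exon_overlap: int = 1
) -> str:
    """Readthrough / gene-body / not-last-exon call for an assigned read.

    Only reads touching the last exon (of the distal-most 3′ end
    transcript) enter the readthrough-vs-gene-body dichotomy; a read is
    readthrough when its 3′ end is at or beyond the boundary (PAS + 100 nt
    in the direction of transcription, inclusive).
    """
    if read.aligned_overlap(gene.last_exon) < min_last_exon_overlap:
        return "not_last_exon"
    boundary = gene.readthrough_boundary
    if gene.strand == "+":
        return "readthrough" if read.three_prime >= boundary else "gene_body"
    return "readthrough" if read.three_prime <= boundary else "gene_body"


def starts_at_tss(
    read: LongRead, transcript: TranscriptModel, window: int = 100
) -> bool:
    """True when the read's 5′ end lies within ``window`` nt of the TSS."""
    return abs(read.five_prime - transcript.tss) <= window


def classify_read(
    read: LongRead,
    annotation: GenomeAnnotation,
    junction_tolerance: int = 0,
    tss_window: int = 100,
    min_last_exon_overlap: int = 1,
) -> ReadCall:
    """Run the full per-read classification pipeline."""
    gene_id = assign_read_to_gene(read, annotation)
    if gene_id is None:
        return ReadCall(read.read_id, None, "not_informative", 0, 0, None, None)
    gene = annotation[gene_id]
    status, intron_calls = classify_splicing_status(
        read, gene.representative_splicing, junction_tolerance
    )
    rt_class = classify_readthrough(read, gene, min_last_exon_overlap)
    at_tss = starts_at_tss(read, gene.representative_splicing, tss_window)
    return ReadCall(
        read.read_id,
        gene_id,
        status,
        len(intron_calls),
        sum(c.spliced for c in intron_calls),
        rt_class,
        at_tss,
        intron_calls,
    )


def classify_reads(
    reads_by_replicate: dict[str, Sequence[LongRead]] | Sequence[LongRead],
    annotation: GenomeAnnotation,
    junction_tolerance: int = 0,
    tss_window: int = 100,
    min_last_exon_overlap: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify a collection of reads, returning two tidy frames.

    Parameters
    ----------
    reads_by_replicate
        Either a mapping replicate-label → reads, or a flat sequence (then
        every read is labelled replicate ``"rep1"``).

    Returns
    -------
    calls, intron_calls
        ``calls`` has one row per read (read_id, replicate, gene_id,
        splicing_status, n_introns_overlapped, n_introns_spliced,
        readthrough_class, starts_at_tss).  ``intron_calls`` has one row
        per read × overlapped intron (gene_id, intron_index, replicate,
        read_id, spliced).
    """
    if not isinstance(reads_by_replicate, dict):
        reads_by_replicate = {"rep1": list(reads_by_replicate)}
    call_rows = []
    intron_rows = []
    for rep in sorted(reads_by_replicate):
        for read in reads_by_replicate[rep]:
            call = classify_read(
                read,
                annotation,
                junction_tolerance=junction_tolerance,
                tss_window=tss_window,
                min_last_exon_overlap=min_last_exon_overlap,
            )
            call_rows.append(
                {
                    "read_id": call.read_id,
                    "replicate": rep,
                    "gene_id": call.gene_id,
                    "splicing_status": call.splicing_status,
                    "n_introns_overlapped": call.n_introns_overlapped,
                    "n_introns_spliced": call.n_introns_spliced,
                    "readthrough_class": call.readthrough_class,
                    "starts_at_tss": call.starts_at_tss,
                }
            )
            for ic in call.intron_calls:
                intron_rows.append(
                    {
                        "gene_id": call.gene_id,
                        "intron_index": ic.intron_index,
                        "replicate": rep,
                        "read_id": call.read_id,
                        "spliced": ic.spliced,
                    }
                )
    calls = pd.DataFrame(
        call_rows,
        columns=[
            "read_id",
            "replicate",
            "gene_id",
            "splicing_status",
            "n_introns_overlapped",
            "n_introns_spliced",
            "readthrough_class",
            "starts_at_tss",
        ],
    )
    intron_calls = pd.DataFrame(
        intron_rows,
        columns=["gene_id", "intron_index", "replicate", "read_id", "spliced"],
    )
    return calls, intron_calls
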