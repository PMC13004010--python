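"""Gene models, representative-transcript selection, and tandem gene pairs.

All coordinates are 0-based, half-open (BED convention); GTF input (1-based,
inclusive) is converted on load.  Strand-aware positions (``tss``, ``pas``)
are expressed in the same convention: on the + strand the PAS is the
half-open transcript end, on the − strand it is the transcript start.

Two representative transcripts are kept per gene, because they serve
different purposes: splicing metrics are computed against the canonical
transcript's introns, while readthrough is judged against the transcript
with the distal-most 3′ end so that annotated long 3′ UTR isoforms are not
mistaken for readthrough.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

#: Distance past the PAS, in nt along the direction of transcription, at
#: which a 3′ end stops counting as normal termination and becomes
#: readthrough.
BOUNDARY_OFFSET = 100


class ParseError(ValueError):
    """Raised when an input annotation or alignment file is malformed."""


@dataclass(frozen=True, order=True)
class Interval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"empty interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Number of shared bases with ``other`` (0 if different chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def _derive_introns(exons: Sequence[Interval]) -> tuple[Interval, ...]:
    introns = []
    for left, right in zip(exons, exons[1:]):
        if right.start < left.end:
            raise ValueError("exons overlap or are unsorted")
        if right.start > left.end:
            introns.append(
                Interval(left.chrom, left.end, right.start, left.strand)
            )
        else:
            # Abutting exons carry no intron; merge-style annotations do this.
            pass
    return tuple(introns)


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: ordered exons, derived introns, strand-aware ends."""

    transcript_id: str
    gene_id: str
    exons: tuple[Interval, ...]
    is_canonical: bool = False
    introns: tuple[Interval, ...] = field(init=False)

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        object.__setattr__(self, "introns", _derive_introns(exons))

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def interval(self) -> Interval:
        return Interval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def tss(self) -> int:
        """Strand-aware 5′ end (transcription start site)."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def pas(self) -> int:
        """Strand-aware 3′ end (polyadenylation site)."""
        return self.exons[-1].end if self.strand == "+" else self.exons[0].start

    @property
    def span_length(self) -> int:
        return self.exons[-1].end - self.exons[0].start


@dataclass(frozen=True)
class GeneModel:
    """A gene with its transcripts and the two representative choices."""

    gene_id: str
    biotype: str
    transcripts: tuple[TranscriptModel, ...]
    representative_splicing: TranscriptModel = field(init=False)
    representative_readthrough: TranscriptModel = field(init=False)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(f"gene {self.gene_id} spans chromosomes/strands")
        object.__setattr__(
            self, "representative_splicing", self._pick_splicing()
        )
        object.__setattr__(
            self, "representative_readthrough", self._pick_readthrough()
        )

    def _pick_splicing(self) -> TranscriptModel:
        canonical = [t for t in self.transcripts if t.is_canonical]
        if canonical:
            return min(canonical, key=lambda t: t.transcript_id)
        logger.warning(
            "gene %s has no canonical transcript flag; using longest",
            self.gene_id,
        )
        return max(
            self.transcripts, key=lambda t: (t.span_length, t.transcript_id)
        )

    def _pick_readthrough(self) -> TranscriptModel:
        # distal-most 3' end in the direction of transcription; canonical
        # breaks exact ties, then transcript_id for determinism
        if self.strand == "+":
            key = lambda t: (t.pas, t.is_canonical, t.transcript_id)
            return max(self.transcripts, key=key)
        key = lambda t: (-t.pas, t.is_canonical, t.transcript_id)
        return max(self.transcripts, key=key)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def interval(self) -> Interval:
        start = min(t.interval.start for t in self.transcripts)
        end = max(t.interval.end for t in self.transcripts)
        return Interval(self.chrom, start, end, self.strand)

    @property
    def tss(self) -> int:
        """5′-most transcription start over all transcripts."""
        return (
            self.interval.start if self.strand == "+" else self.interval.end
        )

    @property
    def pas(self) -> int:
        """PAS of the distal-most 3′ end transcript."""
        return self.representative_readthrough.pas

    @property
    def last_exon(self) -> Interval:
        exons = self.representative_readthrough.exons
        return exons[-1] if self.strand == "+" else exons[0]

    @property
    def readthrough_boundary(self) -> int:
        return readthrough_boundary(self)


def readthrough_boundary(gene: GeneModel) -> int:
    """Position 100 nt past the PAS in the direction of transcription.

    A nascent read whose 3′ end reaches this position (inclusive) is called
    readthrough; 3′ ends short of it are normal termination wobble.
    """
    if gene.strand == "+":
        return gene.pas + BOUNDARY_OFFSET
    return gene.pas - BOUNDARY_OFFSET


class GenomeAnnotation:
    """Collection of :class:`GeneModel` with strand-aware interval lookup."""

    def __init__(
        self,
        genes: Iterable[GeneModel],
        chrom_lengths: Optional[Mapping[str, int]] = None,
    ):
        self._genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self._genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            self._genes[g.gene_id] = g
        self.chrom_lengths = dict(chrom_lengths or {})
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._build_index()

    def _build_index(self) -> None:
        # Index the gene span extended to the readthrough boundary so that
        # reads mapping only in the post-PAS zone still find their gene.
        for g in self._genes.values():
            iv = g.interval
            if g.strand == "+":
                lo, hi = iv.start, max(iv.end, g.readthrough_boundary)
            else:
                lo, hi = min(iv.start, g.readthrough_boundary), iv.end
            tree = self._trees.setdefault((g.chrom, g.strand), IntervalTree())
            tree.addi(lo, hi, g.gene_id)

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(sorted(self._genes.values(), key=lambda g: g.gene_id))

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    def get(self, gene_id: str) -> Optional[GeneModel]:
        return self._genes.get(gene_id)

    def extended_span(self, gene_id: str) -> Interval:
        """Gene span including the 100-nt post-PAS readthrough zone."""
        g = self._genes[gene_id]
        iv = g.interval
        if g.strand == "+":
            return Interval(g.chrom, iv.start, max(iv.end, g.readthrough_boundary), "+")
        return Interval(g.chrom, min(iv.start, g.readthrough_boundary), iv.end, "-")

    def overlapping(self, chrom: str, strand: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        hits = {h.data for h in tree.overlap(start, end)}
        return [self._genes[g] for g in sorted(hits)]

    def summary_table(self):
        """Per-gene summary frame (gene_id, chrom, strand, tss, pas, boundary, n_introns)."""
        import pandas as pd

        rows = [
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "pas": g.pas,
                "boundary": g.readthrough_boundary,
                "n_introns": len(g.representative_splicing.introns),
                "biotype": g.biotype,
            }
            for g in self
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loading


def parse_bed12_line(line: str, lineno: int) -> tuple[str, Interval, tuple[Interval, ...]]:
    """Parse one BED12 row into (name, span, blocks); raises ParseError."""
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ParseError(f"line {lineno}: expected 12 BED fields, got {len(fields)}")
    chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5]
    try:
        start, end = int(start_s), int(end_s)
        block_count = int(fields[9])
        block_sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        block_starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"line {lineno}: non-numeric BED12 field ({exc})") from exc
    if strand not in STRANDS:
        raise ParseError(f"line {lineno}: bad strand {strand!r}")
    if len(block_sizes) != block_count or len(block_starts) != block_count:
        raise ParseError(
            f"line {lineno}: blockCount={block_count} inconsistent with "
            f"blockSizes/blockStarts lengths"
        )
    blocks = []
    for size, rel in zip(block_sizes, block_starts):
        if size <= 0:
            raise ParseError(f"line {lineno}: zero-length block")
        blocks.append(Interval(chrom, start + rel, start + rel + size, strand))
    if blocks[0].start != start or blocks[-1].end != end:
        raise ParseError(f"line {lineno}: blocks do not span chromStart-chromEnd")
    for a, b in zip(blocks, blocks[1:]):
        if b.start < a.end:
            raise ParseError(f"line {lineno}: overlapping/unsorted blocks")
    return name, Interval(chrom, start, end, strand), tuple(blocks)


def _transcripts_from_bed12(
    path: Path,
) -> list[tuple[str, str, bool, tuple[Interval, ...]]]:
    """Yield (transcript_id, gene_id, canonical, exons) from a BED12 file.

    The name column is ``transcript_id|gene_id`` with an optional third
    ``canonical`` token mimicking the Ensembl canonical tag.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            name, _span, blocks = parse_bed12_line(line, lineno)
            parts = name.split("|")
            if len(parts) < 2:
                raise ParseError(
                    f"line {lineno}: BED12 name must be 'transcript_id|gene_id'"
                )
            tx_id, gene_id = parts[0], parts[1]
            canonical = len(parts) > 2 and parts[2] in ("1", "canonical")
            out.append((tx_id, gene_id, canonical, blocks))
    return out


def _transcripts_from_gtf(
    path: Path,
) -> list[tuple[str, str, bool, tuple[Interval, ...], str]]:
    """Extract (transcript_id, gene_id, canonical, exons, biotype) from GTF."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    by_tx: dict[str, dict] = {}
    for exon in db.features_of_type("exon"):
        tx_id = exon.attributes["transcript_id"][0]
        gene_id = exon.attributes["gene_id"][0]
        if exon.start > exon.end:
            raise ParseError(f"exon with negative length in transcript {tx_id}")
        rec = by_tx.setdefault(
            tx_id,
            {
                "gene_id": gene_id,
                "canonical": False,
                "biotype": "protein_coding",
                "exons": [],
            },
        )
        # GTF is 1-based inclusive; convert to 0-based half-open
        rec["exons"].append(
            Interval(exon.seqid, exon.start - 1, exon.end, exon.strand)
        )
        tags = exon.attributes.get("tag", [])
        if "Ensembl_canonical" in tags:
            rec["canonical"] = True
        bt = exon.attributes.get("gene_biotype")
        if bt:
            rec["biotype"] = bt[0]
    # transcript-level records may carry the canonical tag instead
    try:
        for tx in db.features_of_type("transcript"):
            tx_id = tx.attributes["transcript_id"][0]
            if tx_id in by_tx:
                if "Ensembl_canonical" in tx.attributes.get("tag", []):
                    by_tx[tx_id]["canonical"] = True
                bt = tx.attributes.get("gene_biotype")
                if bt:
                    by_tx[tx_id]["biotype"] = bt[0]
    except Exception:  # no transcript features in the file
        pass
    return [
        (tx_id, rec["gene_id"], rec["canonical"], tuple(rec["exons"]), rec["biotype"])
        for tx_id, rec in by_tx.items()
    ]


def load_annotation(
    path: str | Path,
    biotype_table: Optional[Mapping[str, str]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> GenomeAnnotation:
    """Load gene models from a GTF (Ensembl dialect) or BED12 file.

    Parameters
    ----------
    path
        ``.gtf``/``.gff`` files are parsed through gffutils; anything else
        is treated as BED12 with name ``transcript_id|gene_id[|canonical]``.
    biotype_table
        Optional gene_id → biotype mapping (used for BED12 input, where the
        format carries no biotype; unlisted genes default to
        ``protein_coding``).
    """
    path = Path(path)
    biotypes: dict[str, str] = dict(biotype_table or {})
    tx_by_gene: dict[str, list[TranscriptModel]] = {}
    if path.suffix.lower() in (".gtf", ".gff", ".gff3"):
        for tx_id, gene_id, canonical, exons, biotype in _transcripts_from_gtf(path):
            biotypes.setdefault(gene_id, biotype)
            tx_by_gene.setdefault(gene_id, []).append(
                TranscriptModel(tx_id, gene_id, exons, is_canonical=canonical)
            )
    else:
        for tx_id, gene_id, canonical, exons in _transcripts_from_bed12(path):
            tx_by_gene.setdefault(gene_id, []).append(
                TranscriptModel(tx_id, gene_id, exons, is_canonical=canonical)
            )
    genes = [
        GeneModel(
            gene_id,
            biotypes.get(gene_id, "protein_coding"),
            tuple(sorted(txs, key=lambda t: t.transcript_id)),
        )
        for gene_id, txs in tx_by_gene.items()
    ]
    if not genes:
        raise ParseError(f"no transcripts found in {path}")
    return GenomeAnnotation(genes, chrom_lengths=chrom_lengths)


# ---------------------------------------------------------------------------
# tandem gene pairs


def gene_five_prime(gene: GeneModel) -> int:
    """5′-most coordinate of the gene in the direction of transcription."""
    return gene.tss


def pair_distance(up: GeneModel, down: GeneModel) -> int:
    """Gap from the upstream gene's distal 3′ end to the downstream gene's
    5′-most coordinate, measured along the direction of transcription."""
    if up.strand == "+":
        return gene_five_prime(down) - up.pas
    return up.pas - gene_five_prime(down)


def tandem_pairs(
    annotation: GenomeAnnotation, min_distance: int = 500
) -> list[tuple[str, str]]:
    """Ordered (upstream, downstream) pairs of adjacent same-strand genes.

    Adjacency is judged among genes of one strand on one chromosome —
    opposite-strand genes sitting between the two do not break a pair,
    because readthrough proceeds along a single strand.  Pairs closer than
    ``min_distance`` nt (3′ end of the upstream gene to 5′ end of the
    downstream gene) are dropped.
    """
    by_cs: dict[tuple[str, str], list[GeneModel]] = {}
    for g in annotation:
        by_cs.setdefault((g.chrom, g.strand), []).append(g)
    pairs: list[tuple[str, str]] = []
    for (chrom, strand), genes in sorted(by_cs.items()):
        genes.sort(key=lambda g: (g.interval.start, g.gene_id))
        if strand == "-":
            genes.reverse()  # transcription order on the minus strand
        for up, down in zip(genes, genes[1:]):
            if pair_distance(up, down) >= min_distance:
                pairs.append((up.gene_id, down.gene_id))
    return sorted(pairs)
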