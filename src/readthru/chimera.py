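"""Filtering fusion calls down to plausible readthrough chimeras.

A readthrough chimera is a spliced RNA joining exons of an upstream parent
gene to exons of the adjacent, same-strand downstream gene — the molecular
product of readthrough followed by splicing into the read-in gene.  Generic
fusion callers report many events that cannot be readthrough chimeras
(trans-chromosomal, antisense, distant, or structural-RNA partners); this
module applies the support and geometry filters that isolate the
readthrough-compatible subset, and links each surviving chimera to the
readthrough index of its upstream gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from readthru.annotation import GenomeAnnotation, pair_distance, tandem_pairs

logger = logging.getLogger(__name__)

MANDATORY_COLUMNS = (
    "up_gene",
    "down_gene",
    "chrom_up",
    "chrom_down",
    "strand_up",
    "strand_down",
    "span_reads",
    "junction_reads",
)
OPTIONAL_COLUMNS = ("breakpoint_up", "breakpoint_down", "sample")

DEFAULT_EXCLUDED_BIOTYPES = frozenset({"rRNA", "snoRNA", "snRNA"})


@dataclass(frozen=True)
class FusionCall:
    """One fusion-caller row, typed."""

    up_gene: str
    down_gene: str
    chrom_up: str
    chrom_down: str
    strand_up: str
    strand_down: str
    span_reads: int
    junction_reads: int
    breakpoint_up: Optional[int] = None
    breakpoint_down: Optional[int] = None
    sample: Optional[str] = None

    def __post_init__(self) -> None:
        if self.span_reads < 0 or self.junction_reads < 0:
            raise ValueError("support counts must be non-negative")


def parse_fusion_calls(
    path: str | Path,
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[FusionCall], list[dict]]:
    """Read a fusion-caller TSV into typed records.

    ``column_map`` maps the package's field names to the caller's header
    names (e.g. SOAPfuse's ``up_gene`` → ``up_Gene``); identity by
    default.  Rows that fail typing are collected in a reject report
    (row index, reason) and the run continues.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    colmap = {k: k for k in MANDATORY_COLUMNS + OPTIONAL_COLUMNS}
    colmap.update(column_map or {})
    for field in MANDATORY_COLUMNS:
        if colmap[field] not in table.columns:
            raise ValueError(f"fusion table missing mandatory column {colmap[field]!r}")
    calls: list[FusionCall] = []
    rejects: list[dict] = []
    if table.empty:
        logger.warning("fusion table %s is empty", path)
    for idx, row in table.iterrows():
        try:
            kwargs = {f: row[colmap[f]] for f in MANDATORY_COLUMNS}
            kwargs["span_reads"] = int(kwargs["span_reads"])
            kwargs["junction_reads"] = int(kwargs["junction_reads"])
            for f in OPTIONAL_COLUMNS:
                col = colmap.get(f)
                if col and col in table.columns and pd.notna(row[col]):
                    kwargs[f] = (
                        int(row[col]) if f.startswith("breakpoint") else row[col]
                    )
            calls.append(FusionCall(**kwargs))
        except (ValueError, TypeError) as exc:
            rejects.append({"row": int(idx), "reason": str(exc)})
    if rejects:
        logger.warning("rejected %d malformed fusion rows", len(rejects))
    return calls, rejects


def filter_readthrough_chimeras(
    calls: Sequence[FusionCall],
    annotation: GenomeAnnotation,
    min_span: int = 3,
    min_junction: int = 3,
    min_total: int = 6,
    min_distance: int = 500,
    excluded_biotypes: frozenset[str] = DEFAULT_EXCLUDED_BIOTYPES,
) -> pd.DataFrame:
    """Apply all readthrough-chimera rules to every fusion call.

    A call passes only when all of the following hold: both genes
    annotated; same chromosome; same strand; the (up, down) pair is
    adjacent on its strand in transcription order; span ≥ ``min_span`` and
    junction ≥ ``min_junction`` and span + junction ≥ ``min_total``; the
    genes are separated by ≥ ``min_distance`` nt; and neither partner has
    an excluded structural-RNA biotype.  ``fail_reasons`` enumerates every
    violated rule, so the filter doubles as a diagnostic.
    """
    # adjacency irrespective of distance; the distance rule is separate
    adjacent = set(tandem_pairs(annotation, min_distance=0))
    rows = []
    for call in calls:
        reasons: list[str] = []
        up = annotation.get(call.up_gene)
        down = annotation.get(call.down_gene)
        distance: float = np.nan
        if up is None or down is None:
            reasons.append("unannotated")
        else:
            if call.chrom_up != call.chrom_down:
                reasons.append("chrom_mismatch")
            if call.strand_up != call.strand_down:
                reasons.append("strand_mismatch")
            if (call.up_gene, call.down_gene) not in adjacent:
                reasons.append("not_adjacent")
            if up.chrom == down.chrom and up.strand == down.strand:
                distance = pair_distance(up, down)
                if distance < min_distance:
                    reasons.append("min_distance")
            if up.biotype in excluded_biotypes or down.biotype in excluded_biotypes:
                reasons.append("biotype")
        if call.span_reads < min_span:
            reasons.append("min_span")
        if call.junction_reads < min_junction:
            reasons.append("min_junction")
        if call.span_reads + call.junction_reads < min_total:
            reasons.append("min_total")
        rows.append(
            {
                "up_gene": call.up_gene,
                "down_gene": call.down_gene,
                "chrom_up": call.chrom_up,
                "chrom_down": call.chrom_down,
                "strand_up": call.strand_up,
                "strand_down": call.strand_down,
                "span_reads": call.span_reads,
                "junction_reads": call.junction_reads,
                "sample": call.sample,
                "genomic_distance": distance,
                "passes": not reasons,
                "fail_reasons": ";".join(sorted(reasons)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "up_gene",
            "down_gene",
            "chrom_up",
            "chrom_down",
            "strand_up",
            "strand_down",
            "span_reads",
            "junction_reads",
            "sample",
            "genomic_distance",
            "passes",
            "fail_reasons",
        ],
    )


def annotate_upstream_rti(
    chimeras: pd.DataFrame, rti_table: pd.DataFrame
) -> pd.DataFrame:
    """Join each chimera with the readthrough index of its upstream gene.

    Chimeras whose upstream gene is absent from the RTI table get NaN —
    readthrough chimeras are expected to show elevated upstream RTI, so
    this column is the link between chimera formation and readthrough.
    """
    rti = rti_table[["gene_id", "rti"]].rename(
        columns={"gene_id": "up_gene", "rti": "upstream_rti"}
    )
    return chimeras.merge(rti, on="up_gene", how="left")
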