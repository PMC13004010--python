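"""Summary metrics: RTI, CoSE, SPI, unspliced fractions, all-or-none genes,
PAS-downstream coverage, and ΔΔCt relative expression.

The three core metrics are all proportions in [0, 1]:

* **RTI** (readthrough index, per gene) — readthrough reads divided by all
  reads mapping to the gene's last exon.  A gene with RTI ≥ 0.2 is called a
  readthrough gene.
* **CoSE** (cotranscriptional splicing efficiency, per intron) — spliced
  reads spanning an intron divided by all reads spanning it, from long
  reads.
* **SPI** (splicing per intron) — split short-read coverage over both
  splice sites divided by total (split + unsplit) coverage.

Counts are pooled across replicates for the point estimate; per-replicate
filters and estimates are kept so dispersion across replicates can be
inspected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from readthru.annotation import GenomeAnnotation
from readthru.reads import LongRead

logger = logging.getLogger(__name__)

LAST_EXON_CLASSES = ("gene_body", "readthrough")
INFORMATIVE_STATUSES = ("all_spliced", "partially_spliced", "all_unspliced")


@dataclass(frozen=True)
class Thresholds:
    """Every numeric cutoff used by the pipeline, with study defaults.

    rti_high
        Minimum RTI to call a readthrough gene.
    cose_all_or_none_max
        Maximum gene-level CoSE for all-or-none processing calls.
    min_reads_per_replicate
        Minimum last-exon reads required in *every* replicate for a gene to
        enter RTI summaries.
    spi_min_pooled
        Minimum splice-site reads pooled over replicates for an intron to
        enter SPI analysis.
    delta_cose_min, alpha_cose
        Effect-size and adjusted-p cutoffs for calling a CoSE change.
    alpha_spi
        Adjusted-p cutoff for SPI-based significance calls.
    boundary_offset
        Distance (nt) past the PAS defining the readthrough boundary.
    tss_window
        Half-width (nt) of the TSS-start window.
    pas_norm_upstream
        Offset (nt upstream of the PAS) at which coverage profiles are
        normalized to 1.
    """

    rti_high: float = 0.2
    cose_all_or_none_max: float = 0.7
    min_reads_per_replicate: int = 10
    spi_min_pooled: int = 500
    delta_cose_min: float = 0.1
    alpha_cose: float = 0.05
    alpha_spi: float = 0.01
    boundary_offset: int = 100
    tss_window: int = 100
    pas_norm_upstream: int = 200

    def __post_init__(self) -> None:
        for name in (
            "rti_high",
            "cose_all_or_none_max",
            "min_reads_per_replicate",
            "spi_min_pooled",
            "delta_cose_min",
            "alpha_cose",
            "alpha_spi",
            "boundary_offset",
            "tss_window",
            "pas_norm_upstream",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")


def rti_category(rti: float, thresholds: Thresholds) -> str:
    if rti == 0:
        return "zero"
    return "high" if rti >= thresholds.rti_high else "low"


def compute_rti(
    calls: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    replicates: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-gene readthrough index from classified reads.

    Parameters
    ----------
    calls
        Per-read calls frame (from :func:`readthru.reads.classify_reads`)
        with columns gene_id, replicate, readthrough_class.
    replicates
        The full replicate set; defaults to the labels present in
        ``calls``.  A gene passes the read filter only if every replicate
        in this set has at least ``min_reads_per_replicate`` last-exon
        reads for it.

    Returns
    -------
    DataFrame with one row per gene that has ≥1 last-exon read:
    gene_id, n_readthrough, n_last_exon, rti (pooled across replicates),
    rti_mean_reps (mean of per-replicate RTIs), category
    (zero / low / high), passes_min_reads.
    """
    if replicates is None:
        replicates = sorted(calls["replicate"].dropna().unique())
    le = calls[calls["readthrough_class"].isin(LAST_EXON_CLASSES)].copy()
    if le.empty:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "n_readthrough",
                "n_last_exon",
                "rti",
                "rti_mean_reps",
                "category",
                "passes_min_reads",
            ]
        )
    le["is_rt"] = le["readthrough_class"] == "readthrough"
    per_rep = (
        le.groupby(["gene_id", "replicate"])
        .agg(n_rt=("is_rt", "sum"), n_le=("is_rt", "size"))
        .reset_index()
    )
    rows = []
    for gene_id, grp in per_rep.groupby("gene_id"):
        by_rep = grp.set_index("replicate")
        n_rt = int(by_rep["n_rt"].sum())
        n_le = int(by_rep["n_le"].sum())
        passes = all(
            rep in by_rep.index
            and by_rep.loc[rep, "n_le"] >= thresholds.min_reads_per_replicate
            for rep in replicates
        )
        rti = n_rt / n_le
        rep_rtis = by_rep["n_rt"] / by_rep["n_le"]
        rows.append(
            {
                "gene_id": gene_id,
                "n_readthrough": n_rt,
                "n_last_exon": n_le,
                "rti": rti,
                "rti_mean_reps": float(rep_rtis.mean()),
                "category": rti_category(rti, thresholds),
                "passes_min_reads": passes,
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


def rti_per_replicate(calls: pd.DataFrame) -> pd.DataFrame:
    """Long frame of per-replicate readthrough counts and RTIs."""
    le = calls[calls["readthrough_class"].isin(LAST_EXON_CLASSES)].copy()
    le["is_rt"] = le["readthrough_class"] == "readthrough"
    out = (
        le.groupby(["gene_id", "replicate"])
        .agg(n_readthrough=("is_rt", "sum"), n_last_exon=("is_rt", "size"))
        .reset_index()
    )
    out["rti"] = out["n_readthrough"] / out["n_last_exon"]
    return out


def compute_cose(
    intron_calls: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Per-intron cotranscriptional splicing efficiency.

    ``intron_calls`` holds one row per read × spanned intron with a
    boolean ``spliced`` column (from classification against the canonical
    transcript).  CoSE is spliced / total, pooled over replicates; introns
    with no spanning reads are simply absent.
    """
    if intron_calls.empty:
        return pd.DataFrame(
            columns=["gene_id", "intron_index", "n_spliced", "n_total", "cose"]
        )
    out = (
        intron_calls.groupby(["gene_id", "intron_index"])
        .agg(n_spliced=("spliced", "sum"), n_total=("spliced", "size"))
        .reset_index()
    )
    out["n_spliced"] = out["n_spliced"].astype(int)
    out["cose"] = out["n_spliced"] / out["n_total"]
    return out.sort_values(["gene_id", "intron_index"]).reset_index(drop=True)


def gene_level_cose(cose: pd.DataFrame, method: str = "pooled") -> pd.DataFrame:
    """Aggregate per-intron CoSE to gene level.

    ``pooled`` (default) divides total spliced spanning reads by total
    spanning reads over the gene's introns (count-weighted); ``mean``
    averages the per-intron CoSE values.
    """
    if method == "pooled":
        g = cose.groupby("gene_id").agg(
            n_spliced=("n_spliced", "sum"), n_total=("n_total", "sum")
        )
        g["cose"] = g["n_spliced"] / g["n_total"]
    elif method == "mean":
        g = cose.groupby("gene_id").agg(cose=("cose", "mean"))
    else:
        raise ValueError(f"unknown aggregation {method!r}")
    return g.reset_index()[["gene_id", "cose"]]


def unspliced_fraction(
    calls: pd.DataFrame,
    group_by: Sequence[str] = ("readthrough_class", "starts_at_tss"),
) -> pd.DataFrame:
    """Percentage of fully intron-retained ('all unspliced') reads per group.

    Reads overlapping no intron (not informative) are excluded before the
    percentage is taken.  Groups with no informative reads are omitted.
    """
    informative = calls[calls["splicing_status"].isin(INFORMATIVE_STATUSES)]
    if informative.empty:
        return pd.DataFrame(columns=[*group_by, "n_informative", "pct_all_unspliced"])
    grouped = informative.groupby(list(group_by), dropna=True)
    rows = []
    for key, grp in grouped:
        if not isinstance(key, tuple):
            key = (key,)
        rows.append(
            {
                **dict(zip(group_by, key)),
                "n_informative": len(grp),
                "pct_all_unspliced": 100.0
                * (grp["splicing_status"] == "all_unspliced").mean(),
            }
        )
    return pd.DataFrame(rows)


def all_or_none_genes(
    rti: pd.DataFrame,
    gene_cose: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
) -> list[str]:
    """Genes whose transcripts are either fully processed or not at all.

    A gene qualifies when it shows substantial readthrough (RTI ≥ 0.2) and
    inefficient cotranscriptional splicing (gene-level CoSE ≤ 0.7).  Genes
    missing from either table are excluded.
    """
    merged = rti.merge(gene_cose, on="gene_id", how="inner")
    hit = merged[
        (merged["rti"] >= thresholds.rti_high)
        & (merged["cose"] <= thresholds.cose_all_or_none_max)
    ]
    return sorted(hit["gene_id"])


def pas_downstream_coverage(
    reads: Iterable[LongRead],
    assignments: Mapping[str, Optional[str]],
    annotation: GenomeAnnotation,
    window_down: int = 4000,
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Base-level coverage around each PAS, normalized 200 nt upstream.

    For each gene, aligned-block coverage is collected at offsets
    ``-pas_norm_upstream`` … ``window_down`` relative to the PAS in the
    direction of transcription (offset 0 is the first downstream base) and
    divided by the coverage at offset ``-pas_norm_upstream``.  Genes with
    zero coverage there are dropped with a log entry.  Junction gaps
    contribute nothing (coverage counts aligned bases only).

    Returns
    -------
    per_gene, profile
        ``per_gene``: long frame (gene_id, offset, normalized_coverage);
        ``profile``: frame (offset, mean_normalized_coverage, n_genes)
        averaging the normalized per-gene profiles.
    """
    if window_down <= 0:
        raise ValueError("window_down must be positive")
    up = thresholds.pas_norm_upstream
    width = up + window_down + 1
    cov: dict[str, np.ndarray] = {}
    for read in reads:
        gene_id = assignments.get(read.read_id)
        if gene_id is None or gene_id not in annotation:
            continue
        gene = annotation[gene_id]
        arr = cov.setdefault(gene_id, np.zeros(width, dtype=np.int64))
        pas = gene.pas
        for b in read.blocks:
            if gene.strand == "+":
                # offset o <-> genomic pas + o
                lo = max(b.start - pas, -up)
                hi = min(b.end - pas, window_down + 1)
            else:
                # offset o <-> genomic pas - 1 - o
                lo = max(pas - b.end, -up)
                hi = min(pas - b.start, window_down + 1)
            if hi > lo:
                arr[lo + up : hi + up] += 1
    offsets = np.arange(-up, window_down + 1)
    per_gene_rows = []
    profiles = []
    for gene_id in sorted(cov):
        arr = cov[gene_id]
        anchor = arr[0]  # offset -up
        if anchor == 0:
            logger.info(
                "gene %s dropped from PAS profile: zero coverage at -%d nt",
                gene_id,
                up,
            )
            continue
        norm = arr / anchor
        profiles.append(norm)
        per_gene_rows.append(
            pd.DataFrame(
                {"gene_id": gene_id, "offset": offsets, "normalized_coverage": norm}
            )
        )
    if profiles:
        mean_profile = np.mean(profiles, axis=0)
        per_gene = pd.concat(per_gene_rows, ignore_index=True)
    else:
        mean_profile = np.full(width, np.nan)
        per_gene = pd.DataFrame(columns=["gene_id", "offset", "normalized_coverage"])
    profile = pd.DataFrame(
        {
            "offset": offsets,
            "mean_normalized_coverage": mean_profile,
            "n_genes": len(profiles),
        }
    )
    return per_gene, profile


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    spike_target_id: str,
    reference_target_id: str,
    control_sample_id: str,
) -> pd.DataFrame:
    """ΔΔCt quantification against a spike-in, referenced to a parent target.

    Per sample and target: ΔCt = Ct_target − Ct_spike; the
    relative-to-reference value is 2^−(ΔCt_target − ΔCt_reference) (e.g.
    chimera abundance relative to the upstream gene's last exon); the fold
    change divides that value by the control sample's, so the control sits
    at 1.0.  Samples missing the spike or reference Ct are skipped with a
    warning.
    """
    required = {"sample", "target", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct_table missing columns: {sorted(missing)}")
    table = ct_table.dropna(subset=["ct"])
    ct = table.set_index(["sample", "target"])["ct"]

    def _lookup(sample: str, target: str) -> Optional[float]:
        try:
            return float(ct.loc[(sample, target)])
        except KeyError:
            return None

    rows = []
    samples = sorted(table["sample"].unique())
    targets = sorted(
        t
        for t in table["target"].unique()
        if t not in (spike_target_id, reference_target_id)
    )
    rel: dict[tuple[str, str], float] = {}
    for sample in samples:
        ct_spike = _lookup(sample, spike_target_id)
        ct_ref = _lookup(sample, reference_target_id)
        if ct_spike is None or ct_ref is None:
            logger.warning("sample %s missing spike/reference Ct; skipped", sample)
            continue
        for target in targets:
            ct_t = _lookup(sample, target)
            if ct_t is None:
                logger.warning("sample %s target %s missing Ct; skipped", sample, target)
                continue
            delta = ct_t - ct_spike
            delta_ref = ct_ref - ct_spike
            rel[(sample, target)] = 2.0 ** -(delta - delta_ref)
    for (sample, target), value in sorted(rel.items()):
        control = rel.get((control_sample_id, target))
        rows.append(
            {
                "sample": sample,
                "target": target,
                "rel_to_reference": value,
                "fold_change_vs_control": value / control if control else np.nan,
            }
        )
    return pd.DataFrame(
        rows, columns=["sample", "target", "rel_to_reference", "fold_change_vs_control"]
    )


def compute_spi(
    counts: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> pd.DataFrame:
    """Per-intron splicing-per-intron index from splice-site coverage.

    ``counts`` is the tidy splice-site table (intron_id, replicate, site,
    split, unsplit) with one row per intron × replicate × site (5′ and 3′
    splice sites).  SPI = Σ split / Σ (split + unsplit) over both sites and
    all replicates; introns whose pooled total is below
    ``spi_min_pooled`` are flagged ``excluded`` rather than dropped.
    """
    required = {"intron_id", "replicate", "site", "split", "unsplit"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts missing columns: {sorted(missing)}")
    if (counts["split"] < 0).any() or (counts["unsplit"] < 0).any():
        raise ValueError("negative splice-site counts")
    agg = (
        counts.groupby("intron_id")
        .agg(n_split=("split", "sum"), n_unsplit=("unsplit", "sum"))
        .reset_index()
    )
    agg["pooled_total"] = agg["n_split"] + agg["n_unsplit"]
    agg = agg[agg["pooled_total"] > 0].copy()
    agg["spi"] = agg["n_split"] / agg["pooled_total"]
    agg["excluded"] = agg["pooled_total"] < thresholds.spi_min_pooled
    return agg.sort_values("intron_id").reset_index(drop=True)
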