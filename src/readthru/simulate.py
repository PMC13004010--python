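"""Synthetic nascent RNA data with known ground truth.

The generator emulates the *structure* of a stranded nascent RNA long-read
experiment — not any particular dataset's content.  Its model:

* An annotation of multi-exon genes on one chromosome, a configurable
  fraction arranged as tandem same-strand pairs (the substrate for
  readthrough chimeras), some genes with a second transcript whose 3′ end
  is more distal than the canonical one.
* Per gene, a readthrough probability ρ_g; per intron, a cotranscriptional
  splicing probability σ_i — the ground truth that recovery tests compare
  pipeline estimates against.
* Per read: the 3′ end is the anchored (Pol II-proximal) end.  A read is
  either an internal elongation snapshot (3′ end upstream of the last
  exon) or a terminal read; terminal reads are readthrough with
  probability ρ_g, in which case the 3′ end extends a geometric tail
  beyond the boundary (PAS + 100 nt), and otherwise sit exactly at the
  PAS.  ρ_g is therefore exactly the probability of readthrough among
  last-exon reads, which is what the readthrough index estimates.
* Reads start at the TSS with a configured probability (else uniformly
  within the gene) and are truncated from the 3′ end backwards at a length
  cap, emulating platform limits: truncation removes 5′ sequence, so
  TSS-anchored subsets are biased toward shorter genes — the same bias
  the TSS filter addresses on real libraries.
* Each intron fully covered by a read is excised with probability σ_i
  (emitting an exact junction) or retained (contiguous alignment).  There
  is no junction noise: coordinates are exact, matching tolerance 0.

Short-read splice-site count tables are Binomial(depth, σ_i) per site and
replicate; fusion tables contain rows for true chimera pairs plus decoy
rows violating each chimera filter rule; Ct tables encode configured fold
changes exactly (ΔCt differences of −log2 fold).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from readthru.annotation import (
    BOUNDARY_OFFSET,
    GeneModel,
    GenomeAnnotation,
    Interval,
    TranscriptModel,
)
from readthru.mirror import mirror_gene, mirror_read
from readthru.reads import LongRead


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the study conditions emulated.

    Lengths are nt; probabilities in [0, 1].  ``tail_decay`` is the
    per-nt stopping probability of the geometric readthrough tail (mean
    extension past the boundary ≈ 1/tail_decay); ``read_length_cap``
    truncates reads from the anchored 3′ end backwards (0 disables).
    """

    n_genes: int = 60
    exons_per_gene: tuple[int, int] = (3, 8)
    exon_length: tuple[int, int] = (120, 400)
    intron_length: tuple[int, int] = (200, 1500)
    two_transcript_fraction: float = 0.3
    extra_three_prime: tuple[int, int] = (200, 800)
    tandem_fraction: float = 0.3
    tandem_gap: tuple[int, int] = (500, 2000)
    intergenic_gap: tuple[int, int] = (2000, 6000)
    include_close_pair: bool = True
    close_pair_gap: int = 200
    n_decoy_biotype_genes: int = 1
    rho_range: tuple[float, float] = (0.0, 0.6)
    zero_rho_fraction: float = 0.1
    sigma_range: tuple[float, float] = (0.2, 1.0)
    tail_decay: float = 0.01
    max_tail: int = 4000
    tss_fraction: float = 0.7
    last_exon_fraction: float = 0.5
    read_length_cap: int = 2500
    min_read_span: int = 100
    reads_per_gene: int = 100
    n_replicates: int = 3
    chimera_fraction: float = 0.5
    chimera_support_mean: float = 8.0
    depth_per_site: int = 100
    ct_fold_cycle: tuple[float, ...] = (4.0, 2.0, 0.5)
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        for name in ("rho_range", "sigma_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 1):
                raise ValueError(f"{name} must be within [0, 1]")
        if not 0 < self.tail_decay <= 1:
            raise ValueError("tail_decay must be in (0, 1]")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need at least 2 exons to have introns")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        clean = {}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown simulation parameter {k!r}")
            clean[k] = tuple(v) if isinstance(v, list) else v
        return cls(**clean)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class GroundTruth:
    """Everything the generator knows, for recovery tests."""

    rho: dict[str, float] = field(default_factory=dict)
    sigma: dict[str, tuple[float, ...]] = field(default_factory=dict)
    tandem_pairs: list[tuple[str, str]] = field(default_factory=list)
    close_pair: Optional[tuple[str, str]] = None
    biotype_pair: Optional[tuple[str, str]] = None
    chimera_pairs: list[tuple[str, str]] = field(default_factory=list)
    fusion_expectations: pd.DataFrame = field(default_factory=pd.DataFrame)
    ct_folds: dict[str, float] = field(default_factory=dict)
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)
    chrom_length: int = 0

    def sigma_for(self, gene_id: str, intron_index: int) -> float:
        return self.sigma[gene_id][intron_index]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rho": self.rho,
            "sigma": {g: list(s) for g, s in self.sigma.items()},
            "tandem_pairs": self.tandem_pairs,
            "close_pair": self.close_pair,
            "biotype_pair": self.biotype_pair,
            "chimera_pairs": self.chimera_pairs,
            "ct_folds": self.ct_folds,
            "chrom_length": self.chrom_length,
            "reads": self.reads.to_dict(orient="list") if len(self.reads) else {},
            "fusion_expectations": self.fusion_expectations.to_dict(orient="list")
            if len(self.fusion_expectations)
            else {},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# annotation simulation


def _simulate_gene(
    gene_id: str,
    biotype: str,
    strand: str,
    cursor: int,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GeneModel, int]:
    """Lay one gene down starting at ``cursor``; returns (gene, right end).

    Exons are generated left to right in coordinate space; for − strand
    genes the same structure simply reads in the other direction.  A
    second, non-canonical transcript with a more distal 3′ end is added
    for a configured fraction of genes.
    """
    n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
    x = cursor
    exons = []
    for i in range(n_exons):
        ex_len = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
        exons.append(Interval(config.chrom, x, x + ex_len, strand))
        x += ex_len
        if i < n_exons - 1:
            x += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
    canonical = TranscriptModel(f"{gene_id}.t1", gene_id, tuple(exons), is_canonical=True)
    transcripts = [canonical]
    right_end = x
    if rng.random() < config.two_transcript_fraction:
        extra = int(
            rng.integers(config.extra_three_prime[0], config.extra_three_prime[1] + 1)
        )
        if strand == "+":
            last = exons[-1]
            distal_exons = exons[:-1] + [
                Interval(last.chrom, last.start, last.end + extra, strand)
            ]
            right_end = last.end + extra
        else:
            # the distal 3' end of a − strand gene lies further left; shift
            # the whole gene right by `extra` so the cursor never reverses,
            # then extend the distal transcript's first exon back to cursor
            exons = [
                Interval(e.chrom, e.start + extra, e.end + extra, strand) for e in exons
            ]
            canonical = TranscriptModel(
                f"{gene_id}.t1", gene_id, tuple(exons), is_canonical=True
            )
            transcripts = [canonical]
            first = exons[0]
            distal_exons = [
                Interval(first.chrom, first.start - extra, first.end, strand)
            ] + exons[1:]
            right_end = exons[-1].end
        transcripts.append(
            TranscriptModel(f"{gene_id}.t2", gene_id, tuple(distal_exons), is_canonical=False)
        )
    gene = GeneModel(gene_id, biotype, tuple(transcripts))
    return gene, right_end


def simulate_annotation(
    config: SimulationConfig, seed: int
) -> tuple[GenomeAnnotation, GroundTruth]:
    """Generate a gene annotation plus the ground-truth skeleton.

    Genes are placed left to right on one chromosome with no same-strand
    overlap.  The requested fraction of genes is arranged as tandem
    same-strand pairs separated by at least 500 nt; optionally one extra
    same-strand pair sits closer than 500 nt and one pair has a
    structural-RNA (snoRNA) partner, so that every chimera filter rule has
    a live test case in the data.
    """
    rng = np.random.default_rng(seed)
    n_pairs = int(round(config.n_genes * config.tandem_fraction / 2))
    n_singles = config.n_genes - 2 * n_pairs
    if n_singles < 0:
        raise ValueError("tandem_fraction too large for n_genes")
    units: list[tuple[str, ...]] = [("pair",)] * n_pairs + [("single",)] * n_singles
    rng.shuffle(units)

    genes: list[GeneModel] = []
    truth = GroundTruth()
    cursor = int(rng.integers(*config.intergenic_gap))
    idx = 0

    def next_id() -> str:
        nonlocal idx
        idx += 1
        return f"G{idx:04d}"

    biotype_pair_placed = config.n_decoy_biotype_genes <= 0
    for u, unit in enumerate(units):
        strand = "+" if rng.random() < 0.5 else "-"
        if unit[0] == "pair":
            g1, end1 = _simulate_gene(next_id(), "protein_coding", strand, cursor, config, rng)
            gap = int(rng.integers(config.tandem_gap[0], config.tandem_gap[1] + 1))
            # keep the readthrough boundary and geometric tails clear of
            # the 100-nt boundary zone accounting done by the distance rule
            start2 = end1 + gap
            biotype2 = "protein_coding"
            if not biotype_pair_placed:
                biotype2 = "snoRNA"
            g2, end2 = _simulate_gene(next_id(), biotype2, strand, start2, config, rng)
            if strand == "+":
                up, down = g1, g2
            else:
                up, down = g2, g1
            pair = (up.gene_id, down.gene_id)
            if not biotype_pair_placed:
                truth.biotype_pair = pair
                biotype_pair_placed = True
            else:
                truth.tandem_pairs.append(pair)
            genes.extend([g1, g2])
            cursor = end2 + int(rng.integers(*config.intergenic_gap))
        else:
            g, end = _simulate_gene(next_id(), "protein_coding", strand, cursor, config, rng)
            genes.append(g)
            cursor = end + int(rng.integers(*config.intergenic_gap))

    if config.include_close_pair:
        strand = "+"
        g1, end1 = _simulate_gene(next_id(), "protein_coding", strand, cursor, config, rng)
        g2, end2 = _simulate_gene(
            next_id(), "protein_coding", strand, end1 + config.close_pair_gap, config, rng
        )
        truth.close_pair = (g1.gene_id, g2.gene_id)
        genes.extend([g1, g2])
        cursor = end2 + int(rng.integers(*config.intergenic_gap))

    chrom_length = cursor + config.max_tail + 10_000
    truth.chrom_length = chrom_length

    for g in genes:
        rho = float(rng.uniform(*config.rho_range))
        if rng.random() < config.zero_rho_fraction:
            rho = 0.0
        truth.rho[g.gene_id] = rho
        n_introns = len(g.representative_splicing.introns)
        truth.sigma[g.gene_id] = tuple(
            float(rng.uniform(*config.sigma_range)) for _ in range(n_introns)
        )

    annotation = GenomeAnnotation(genes, chrom_lengths={config.chrom: chrom_length})
    return annotation, truth


# ---------------------------------------------------------------------------
# long-read simulation


def simulate_long_reads(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int,
) -> dict[str, list[LongRead]]:
    """Simulate reads for every gene and replicate; fills ``truth.reads``.

    Reads for − strand genes are generated in mirrored (+) space and
    reflected back, so a single direction of logic serves both strands.
    The per-read truth table records the labels a correct classifier
    should produce: splicing status against the canonical transcript's
    introns, readthrough class against the distal PAS, and the TSS flag.
    """
    rng = np.random.default_rng(seed)
    length = truth.chrom_length
    reads_by_rep: dict[str, list[LongRead]] = {
        f"rep{i + 1}": [] for i in range(config.n_replicates)
    }
    truth_rows = []
    for gene in annotation:
        rho = truth.rho[gene.gene_id]
        sigma = truth.sigma[gene.gene_id]
        minus = gene.strand == "-"
        work = mirror_gene(gene, length) if minus else gene
        # introns in work space run in transcription order; map σ indices
        n_int = len(sigma)
        sigma_work = tuple(reversed(sigma)) if minus else sigma
        tx = work.representative_splicing
        tss = tx.tss
        pas = work.pas
        boundary = work.readthrough_boundary
        last_exon = work.last_exon
        introns = tx.introns
        # with a length cap active, clamp the readthrough tail so that
        # truncation always leaves >= min_read_span aligned inside the gene
        tail_limit = config.max_tail
        if config.read_length_cap:
            tail_limit = min(
                tail_limit,
                config.read_length_cap - BOUNDARY_OFFSET - config.min_read_span,
            )
        for rep in sorted(reads_by_rep):
            for k in range(config.reads_per_gene):
                terminal = rng.random() < config.last_exon_fraction
                is_rt = False
                if terminal:
                    if rng.random() < rho:
                        is_rt = True
                        tail = int(rng.geometric(config.tail_decay)) - 1
                        end = boundary + min(tail, tail_limit)
                    else:
                        end = pas
                else:
                    lo = tss + config.min_read_span
                    hi = last_exon.start
                    end = int(rng.integers(lo, hi + 1)) if hi >= lo else hi
                if rng.random() < config.tss_fraction:
                    start = tss
                else:
                    # internal 5' starts stay within the transcribed gene
                    s_hi = min(end, pas) - config.min_read_span
                    start = int(rng.integers(tss, s_hi + 1)) if s_hi > tss else tss
                if config.read_length_cap and end - start > config.read_length_cap:
                    start = end - config.read_length_cap
                spliced_introns = []
                n_cov = n_spl = 0
                for i, intron in enumerate(introns):
                    if start < intron.start and end > intron.end:
                        n_cov += 1
                        if rng.random() < sigma_work[i]:
                            n_spl += 1
                            spliced_introns.append((i, intron))
                # assemble blocks: the span minus excised introns
                blocks = []
                x = start
                for _, intron in spliced_introns:
                    blocks.append(Interval(config.chrom, x, intron.start, "+"))
                    x = intron.end
                blocks.append(Interval(config.chrom, x, end, "+"))
                read_id = f"{rep}_{gene.gene_id}_{k:04d}"
                read = LongRead(read_id, tuple(blocks))
                if minus:
                    read = mirror_read(read, length)
                reads_by_rep[rep].append(read)
                if n_cov == 0:
                    status = "not_informative"
                elif n_spl == n_cov:
                    status = "all_spliced"
                elif n_spl == 0:
                    status = "all_unspliced"
                else:
                    status = "partially_spliced"
                overlaps_last = start < last_exon.end and end > last_exon.start
                if not overlaps_last:
                    rt_class = "not_last_exon"
                elif is_rt:
                    rt_class = "readthrough"
                else:
                    rt_class = "gene_body"
                # spliced intron indices back in coordinate order
                spliced_idx = sorted(
                    (n_int - 1 - i) if minus else i for i, _ in spliced_introns
                )
                covered_idx = sorted(
                    (n_int - 1 - i) if minus else i
                    for i, intron in enumerate(introns)
                    if start < intron.start and end > intron.end
                )
                truth_rows.append(
                    {
                        "read_id": read_id,
                        "replicate": rep,
                        "gene_id": gene.gene_id,
                        "true_status": status,
                        "true_class": rt_class,
                        "true_starts_at_tss": abs(start - tss) <= 100,  # TSS window
                        "n_introns_covered": n_cov,
                        "n_introns_spliced": n_spl,
                        "covered_introns": ",".join(map(str, covered_idx)),
                        "spliced_introns": ",".join(map(str, spliced_idx)),
                    }
                )
    truth.reads = pd.DataFrame(truth_rows)
    return reads_by_rep


# ---------------------------------------------------------------------------
# count tables, fusion tables, Ct tables


def intron_id(gene_id: str, index: int) -> str:
    return f"{gene_id}:i{index}"


def simulate_splice_site_counts(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    sigma_shift: Optional[dict[str, float]] = None,
) -> pd.DataFrame:
    """Splice-site coverage table: Binomial(depth, σ) split counts per
    intron × replicate × site (5′ and 3′), mimicking short-read
    splice-site quantification output.

    ``sigma_shift`` optionally adds a per-intron_id shift to σ (clipped to
    [0, 1]) — used to simulate a treated condition.
    """
    rows = []
    depth = config.depth_per_site
    if depth <= 0:
        return pd.DataFrame(columns=["intron_id", "replicate", "site", "split", "unsplit"])
    for gene_id in sorted(truth.sigma):
        for i, sig in enumerate(truth.sigma[gene_id]):
            iid = intron_id(gene_id, i)
            if sigma_shift and iid in sigma_shift:
                sig = float(np.clip(sig + sigma_shift[iid], 0.0, 1.0))
            for rep in range(1, config.n_replicates + 1):
                for site in ("5p", "3p"):
                    split = int(rng.binomial(depth, sig))
                    rows.append(
                        {
                            "intron_id": iid,
                            "replicate": f"rep{rep}",
                            "site": site,
                            "split": split,
                            "unsplit": depth - split,
                        }
                    )
    return pd.DataFrame(rows)


def _find_opposite_strand_neighbors(
    annotation: GenomeAnnotation,
) -> Optional[tuple[str, str]]:
    # protein-coding only, so the decoy fails on strand/adjacency alone
    genes = sorted(
        (g for g in annotation if g.biotype == "protein_coding"),
        key=lambda g: g.interval.start,
    )
    for a, b in zip(genes, genes[1:]):
        if a.chrom == b.chrom and a.strand != b.strand:
            return a.gene_id, b.gene_id
    return None


def _find_non_adjacent_pair(
    annotation: GenomeAnnotation,
) -> Optional[tuple[str, str]]:
    by_cs: dict[tuple[str, str], list[GeneModel]] = {}
    for g in annotation:
        if g.biotype != "protein_coding":
            continue
        by_cs.setdefault((g.chrom, g.strand), []).append(g)
    for (_, strand), genes in sorted(by_cs.items()):
        if len(genes) < 3:
            continue
        genes.sort(key=lambda g: g.interval.start)
        if strand == "-":
            genes.reverse()
        return genes[0].gene_id, genes[2].gene_id  # one gene in between
    return None


def simulate_fusion_calls(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fusion-caller table: true chimera rows plus one decoy per filter rule.

    True rows come from tandem pairs selected with probability
    ``chimera_fraction`` (at least one) and carry passing support counts.
    Decoys violate, in turn: span support, junction support (which also
    breaks the total-support rule), strand match, adjacency, distance,
    biotype, and annotation presence.  ``truth.fusion_expectations``
    records the expected verdict and fail reasons for each row.
    """
    rows = []
    expect = []

    def add_row(up_id, down_id, span, junction, expected_pass, expected_reasons, note):
        up = annotation.get(up_id)
        down = annotation.get(down_id)
        rows.append(
            {
                "up_gene": up_id,
                "down_gene": down_id,
                "chrom_up": up.chrom if up else config.chrom,
                "chrom_down": down.chrom if down else config.chrom,
                "strand_up": up.strand if up else "+",
                "strand_down": down.strand if down else "+",
                "breakpoint_up": up.pas if up else 0,
                "breakpoint_down": down.tss if down else 0,
                "span_reads": span,
                "junction_reads": junction,
                "sample": "pooled",
            }
        )
        expect.append(
            {
                "row": len(rows) - 1,
                "up_gene": up_id,
                "down_gene": down_id,
                "expected_pass": expected_pass,
                "expected_reasons": ";".join(sorted(expected_reasons)),
                "note": note,
            }
        )

    chimera_pairs = [
        p for p in truth.tandem_pairs if rng.random() < config.chimera_fraction
    ]
    if not chimera_pairs and truth.tandem_pairs:
        chimera_pairs = [truth.tandem_pairs[0]]
    truth.chimera_pairs = chimera_pairs
    mean = config.chimera_support_mean
    for up_id, down_id in chimera_pairs:
        span = 3 + int(rng.poisson(max(mean - 3, 0)))
        junction = 3 + int(rng.poisson(max(mean - 3, 0)))
        add_row(up_id, down_id, span, junction, True, [], "true_chimera")

    if truth.tandem_pairs:
        up_id, down_id = truth.tandem_pairs[0]
        add_row(up_id, down_id, 2, 6, False, ["min_span"], "decoy_low_span")
        add_row(
            up_id,
            down_id,
            3,
            2,
            False,
            ["min_junction", "min_total"],
            "decoy_low_junction_total",
        )
    opp = _find_opposite_strand_neighbors(annotation)
    if opp:
        reasons = ["strand_mismatch", "not_adjacent"]
        add_row(opp[0], opp[1], 8, 8, False, reasons, "decoy_strand")
    non_adj = _find_non_adjacent_pair(annotation)
    if non_adj:
        add_row(non_adj[0], non_adj[1], 8, 8, False, ["not_adjacent"], "decoy_non_adjacent")
    if truth.close_pair:
        add_row(
            truth.close_pair[0],
            truth.close_pair[1],
            8,
            8,
            False,
            ["min_distance"],
            "decoy_close_pair",
        )
    if truth.biotype_pair:
        add_row(
            truth.biotype_pair[0],
            truth.biotype_pair[1],
            8,
            8,
            False,
            ["biotype"],
            "decoy_biotype",
        )
    add_row("G_UNKNOWN", next(iter(annotation)).gene_id, 8, 8, False, ["unannotated"], "decoy_unannotated")
    truth.fusion_expectations = pd.DataFrame(expect)
    return pd.DataFrame(rows)


def simulate_ct_table(
    truth: GroundTruth,
    config: SimulationConfig,
    spike_ct: float = 15.0,
    reference_ct: float = 20.0,
    base_target_ct: float = 24.0,
) -> pd.DataFrame:
    """Noise-free qPCR Ct table encoding configured fold changes exactly.

    One target per true chimera, fold changes cycling through
    ``ct_fold_cycle``; every sample carries the spike-in and the
    upstream-gene reference, so ΔΔCt quantification recovers the folds
    with no error.
    """
    rows = []
    folds = {}
    targets = [f"chimera_{up}_{down}" for up, down in truth.chimera_pairs]
    for i, target in enumerate(targets):
        folds[target] = config.ct_fold_cycle[i % len(config.ct_fold_cycle)]
    truth.ct_folds = folds
    for sample in ("CTRL", "TREATED"):
        rows.append({"sample": sample, "target": "spike_in", "ct": spike_ct})
        rows.append({"sample": sample, "target": "parent_last_exon", "ct": reference_ct})
        for target, fold in folds.items():
            ct = base_target_ct
            if sample == "TREATED":
                ct = base_target_ct - float(np.log2(fold))
            rows.append({"sample": sample, "target": target, "ct": ct})
    return pd.DataFrame(rows)


def simulate_counts_and_fusions(
    annotation: GenomeAnnotation,
    truth: GroundTruth,
    config: SimulationConfig,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate the three table-level inputs: splice-site counts, fusion
    calls (with decoys), and a Ct table."""
    rng = np.random.default_rng(seed)
    counts = simulate_splice_site_counts(truth, config, rng)
    fusions = simulate_fusion_calls(annotation, truth, config, rng)
    ct = simulate_ct_table(truth, config)
    return counts, fusions, ct


# ---------------------------------------------------------------------------
# writers


def write_annotation_bed12(annotation: GenomeAnnotation, path: str | Path) -> None:
    """BED12 annotation; name = transcript_id|gene_id[|canonical]."""
    lines = []
    for gene in annotation:
        for tx in gene.transcripts:
            iv = tx.interval
            name = f"{tx.transcript_id}|{gene.gene_id}"
            if tx.is_canonical:
                name += "|canonical"
            sizes = ",".join(str(len(e)) for e in tx.exons)
            starts = ",".join(str(e.start - iv.start) for e in tx.exons)
            lines.append(
                "\t".join(
                    map(
                        str,
                        [
                            iv.chrom,
                            iv.start,
                            iv.end,
                            name,
                            0,
                            iv.strand,
                            iv.start,
                            iv.end,
                            "0,0,0",
                            len(tx.exons),
                            sizes + ",",
                            starts + ",",
                        ],
                    )
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_annotation_gtf(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Ensembl-dialect GTF with gene_biotype and Ensembl_canonical tags."""
    lines = []
    for gene in annotation:
        for tx in gene.transcripts:
            iv = tx.interval
            attrs = (
                f'gene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}"; '
                f'gene_biotype "{gene.biotype}";'
            )
            if tx.is_canonical:
                attrs += ' tag "Ensembl_canonical";'
            lines.append(
                "\t".join(
                    map(
                        str,
                        [
                            iv.chrom,
                            "sim",
                            "transcript",
                            iv.start + 1,
                            iv.end,
                            ".",
                            iv.strand,
                            ".",
                            attrs,
                        ],
                    )
                )
            )
            for e in tx.exons:
                lines.append(
                    "\t".join(
                        map(
                            str,
                            [
                                e.chrom,
                                "sim",
                                "exon",
                                e.start + 1,
                                e.end,
                                ".",
                                e.strand,
                                ".",
                                attrs,
                            ],
                        )
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def write_reads_bed12(reads: Sequence[LongRead], path: str | Path) -> None:
    lines = []
    for read in reads:
        sizes = ",".join(str(len(b)) for b in read.blocks)
        starts = ",".join(str(b.start - read.start) for b in read.blocks)
        lines.append(
            "\t".join(
                map(
                    str,
                    [
                        read.chrom,
                        read.start,
                        read.end,
                        read.read_id,
                        0,
                        read.strand,
                        read.start,
                        read.end,
                        "0,0,0",
                        len(read.blocks),
                        sizes + ",",
                        starts + ",",
                    ],
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def simulate_dataset(
    config: SimulationConfig, seed: int, outdir: Optional[str | Path] = None
) -> dict:
    """End-to-end simulation; optionally writes all files to ``outdir``.

    Returns a dict with annotation, truth, reads_by_rep, counts, fusions,
    and ct table.  Seeds for the three stages are derived from ``seed`` so
    the stages stay independently reproducible.
    """
    annotation, truth = simulate_annotation(config, seed)
    reads_by_rep = simulate_long_reads(annotation, truth, config, seed + 1)
    counts, fusions, ct = simulate_counts_and_fusions(annotation, truth, config, seed + 2)
    result = {
        "annotation": annotation,
        "truth": truth,
        "reads_by_rep": reads_by_rep,
        "counts": counts,
        "fusions": fusions,
        "ct": ct,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotation_gtf(annotation, outdir / "genes.gtf")
        write_annotation_bed12(annotation, outdir / "genes.bed12")
        for rep, reads in sorted(reads_by_rep.items()):
            write_reads_bed12(reads, outdir / f"reads_{rep}.bed12")
        counts.to_csv(outdir / "splice_counts.tsv", sep="\t", index=False)
        fusions.to_csv(outdir / "fusions.tsv", sep="\t", index=False)
        ct.to_csv(outdir / "ct.tsv", sep="\t", index=False)
        truth.to_json(outdir / "truth.json")
    return result
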