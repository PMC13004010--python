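"""End-to-end evaluation experiments on synthetic data.

Each function runs one recovery, calibration, or equivalence experiment
through the full pipeline — generate data with known truth, classify,
compute metrics, compare — and returns a small dict of summary numbers.
They are shared by the acceptance tests and the acceptance script, which
only differ in how they consume the results.

Problem sizes (gene counts, read depths, intron counts) are chosen so each
experiment has enough statistical resolution to be meaningful while running
in seconds on one core.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from readthru.annotation import pair_distance, tandem_pairs
from readthru.chimera import (
    DEFAULT_EXCLUDED_BIOTYPES,
    FusionCall,
    filter_readthrough_chimeras,
)
from readthru.metrics import (
    Thresholds,
    compute_cose,
    compute_rti,
    compute_spi,
    ddct_relative_expression,
    pas_downstream_coverage,
    rti_category,
)
from readthru.mirror import mirror_annotation, mirror_reads
from readthru.reads import assign_read_to_gene, classify_reads
from readthru.simulate import (
    SimulationConfig,
    intron_id,
    simulate_annotation,
    simulate_dataset,
    simulate_fusion_calls,
    simulate_splice_site_counts,
)
from readthru.stats import bh_adjust, replicate_chisq


def _ci_covers(k: np.ndarray, n: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Exact (Clopper-Pearson) 95% binomial CI containment of the truth."""
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return (lo <= truth) & (truth <= hi)


def rti_recovery(seed: int, n_genes: int = 200, reads_per_replicate: int = 100) -> dict:
    """Estimate per-gene RTI on a simulated cohort and check truth recovery.

    Genes draw readthrough probabilities from Uniform(0, 0.6) with a tenth
    of genes at exactly zero; every read is a last-exon read (TSS-anchored,
    untruncated), giving 3 × ``reads_per_replicate`` last-exon reads per
    gene.  Reports the fraction of genes whose exact binomial 95% CI covers
    the true probability, and whether zero-probability genes report an RTI
    of exactly zero.
    """
    config = SimulationConfig(
        n_genes=n_genes,
        reads_per_gene=reads_per_replicate,
        rho_range=(0.0, 0.6),
        zero_rho_fraction=0.1,
        tss_fraction=1.0,
        last_exon_fraction=1.0,
        read_length_cap=0,
        tandem_fraction=0.0,
        include_close_pair=False,
        n_decoy_biotype_genes=0,
    )
    res = simulate_dataset(config, seed)
    calls, _ = classify_reads(res["reads_by_rep"], res["annotation"])
    rti = compute_rti(calls)
    rho = rti["gene_id"].map(res["truth"].rho).to_numpy()
    covered = _ci_covers(
        rti["n_readthrough"].to_numpy(), rti["n_last_exon"].to_numpy(), rho
    )
    zero_mask = rho == 0
    zero_exact = rti.loc[zero_mask, "rti"].eq(0).all() if zero_mask.any() else True
    return {
        "n_genes": int(len(rti)),
        "n_zero_genes": int(zero_mask.sum()),
        "ci_coverage_pct": 100.0 * covered.mean(),
        "zero_exact_pct": 100.0 * float(zero_exact),
        "mean_error": float(np.mean(rti["rti"].to_numpy() - rho)),
    }


def cose_recovery(seed: int, n_genes: int = 100, reads_per_replicate: int = 134) -> dict:
    """Per-intron CoSE recovery from long reads (~400 spanning reads/intron)."""
    config = SimulationConfig(
        n_genes=n_genes,
        exons_per_gene=(5, 8),
        reads_per_gene=reads_per_replicate,
        sigma_range=(0.2, 1.0),
        tss_fraction=1.0,
        last_exon_fraction=1.0,
        read_length_cap=0,
        tandem_fraction=0.0,
        include_close_pair=False,
        n_decoy_biotype_genes=0,
    )
    res = simulate_dataset(config, seed)
    _, intron_calls = classify_reads(res["reads_by_rep"], res["annotation"])
    cose = compute_cose(intron_calls)
    truth = res["truth"]
    sigma = np.array(
        [truth.sigma[g][i] for g, i in zip(cose["gene_id"], cose["intron_index"])]
    )
    covered = _ci_covers(
        cose["n_spliced"].to_numpy(), cose["n_total"].to_numpy(), sigma
    )
    return {
        "n_introns": int(len(cose)),
        "mean_depth": float(cose["n_total"].mean()),
        "ci_coverage_pct": 100.0 * covered.mean(),
        "mean_error": float(np.mean(cose["cose"].to_numpy() - sigma)),
    }


def spi_recovery(seed: int, n_genes: int = 100, depth_per_site: int = 67) -> dict:
    """Per-intron SPI recovery from splice-site counts (~400 pooled/intron)."""
    config = SimulationConfig(
        n_genes=n_genes,
        exons_per_gene=(5, 8),
        sigma_range=(0.2, 1.0),
        depth_per_site=depth_per_site,
        include_close_pair=False,
        n_decoy_biotype_genes=0,
    )
    ann, truth = simulate_annotation(config, seed)
    counts = simulate_splice_site_counts(truth, config, np.random.default_rng(seed + 1))
    spi = compute_spi(counts, Thresholds(spi_min_pooled=1))
    sigma = {}
    for gene_id, sigmas in truth.sigma.items():
        for i, s in enumerate(sigmas):
            sigma[intron_id(gene_id, i)] = s
    truth_vals = spi["intron_id"].map(sigma).to_numpy()
    covered = _ci_covers(
        spi["n_split"].to_numpy(), spi["pooled_total"].to_numpy(), truth_vals
    )
    return {
        "n_introns": int(len(spi)),
        "mean_depth": float(spi["pooled_total"].mean()),
        "ci_coverage_pct": 100.0 * covered.mean(),
    }


def fdr_null_calibration(
    seed: int, n_introns: int = 1000, depth: int = 200, n_replicates: int = 3
) -> dict:
    """False-positive calibration under a complete splicing null.

    Both conditions share each intron's splicing probability; with
    delta_min 0 the fraction of introns significant at BH-adjusted
    alpha 0.05 must stay at or below 0.05 plus two Monte-Carlo standard
    errors (the max-over-pairs combination is conservative, so the
    realized fraction is typically far lower).
    """
    rng = np.random.default_rng(seed)
    combined = np.empty(n_introns)
    for i in range(n_introns):
        sigma = rng.uniform(0.2, 0.8)
        a = [(int(k), depth - int(k)) for k in rng.binomial(depth, sigma, n_replicates)]
        b = [(int(k), depth - int(k)) for k in rng.binomial(depth, sigma, n_replicates)]
        combined[i] = replicate_chisq(a, b)[1]
    adj = bh_adjust(combined)
    frac = float((adj < 0.05).mean())
    mc_se = np.sqrt(0.05 * 0.95 / n_introns)
    return {
        "n_introns": n_introns,
        "significant_fraction": frac,
        "bound": 0.05 + 2 * mc_se,
    }


def power_shifted(
    seed: int,
    n_introns: int = 500,
    shifted_fraction: float = 0.1,
    delta_sigma: float = 0.3,
    depth: int = 500,
) -> dict:
    """Detection power for a σ shift of 0.3 at depth 500 per replicate."""
    rng = np.random.default_rng(seed)
    n_shifted = int(round(n_introns * shifted_fraction))
    shifted = np.zeros(n_introns, dtype=bool)
    shifted[:n_shifted] = True
    combined = np.empty(n_introns)
    deltas = np.empty(n_introns)
    for i in range(n_introns):
        sigma_a = rng.uniform(0.3, 0.6)
        sigma_b = min(sigma_a + delta_sigma, 1.0) if shifted[i] else sigma_a
        a = [(int(k), depth - int(k)) for k in rng.binomial(depth, sigma_a, 3)]
        b = [(int(k), depth - int(k)) for k in rng.binomial(depth, sigma_b, 3)]
        combined[i] = replicate_chisq(a, b)[1]
        tot = 3 * depth
        deltas[i] = sum(s for s, _ in b) / tot - sum(s for s, _ in a) / tot
    adj = bh_adjust(combined)
    significant = (np.abs(deltas) >= 0.1) & (adj < 0.05)
    return {
        "n_shifted": n_shifted,
        "detected_pct": 100.0 * float(significant[shifted].mean()),
        "false_pct": 100.0 * float(significant[~shifted].mean()),
    }


# ---------------------------------------------------------------------------
# oracle equivalence


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    # brute-force step-up, independent of the statsmodels-backed path
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        out[idx] = running
    return out


def bh_oracle_agreement(seed: int, n_vectors: int = 1000) -> dict:
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_vectors):
        p = rng.random(int(rng.integers(1, 80)))
        if np.allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12):
            agree += 1
    return {"n_vectors": n_vectors, "agreement_pct": 100.0 * agree / n_vectors}


def _brute_force_pairs(annotation, min_distance):
    genes = list(annotation)

    def txo(g):
        return g.interval.start if g.strand == "+" else -g.interval.start

    pairs = []
    for up in genes:
        for down in genes:
            if up.gene_id == down.gene_id:
                continue
            if up.chrom != down.chrom or up.strand != down.strand:
                continue
            if txo(up) >= txo(down):
                continue
            if any(
                c.chrom == up.chrom
                and c.strand == up.strand
                and txo(up) < txo(c) < txo(down)
                for c in genes
            ):
                continue
            if pair_distance(up, down) < min_distance:
                continue
            pairs.append((up.gene_id, down.gene_id))
    return sorted(pairs)


def tandem_pairs_oracle_agreement(seed: int, n_genes: int = 50) -> dict:
    ann, _ = simulate_annotation(SimulationConfig(n_genes=n_genes), seed)
    checks = [
        tandem_pairs(ann, d) == _brute_force_pairs(ann, d) for d in (0, 500, 2000)
    ]
    return {"n_genes": len(ann), "agreement_pct": 100.0 * np.mean(checks)}


def _brute_force_chimera(call, annotation, oracle_pairs=None):
    if oracle_pairs is None:
        oracle_pairs = _brute_force_pairs(annotation, 0)
    reasons = set()
    up, down = annotation.get(call.up_gene), annotation.get(call.down_gene)
    if up is None or down is None:
        reasons.add("unannotated")
    else:
        if call.chrom_up != call.chrom_down:
            reasons.add("chrom_mismatch")
        if call.strand_up != call.strand_down:
            reasons.add("strand_mismatch")
        if (call.up_gene, call.down_gene) not in oracle_pairs:
            reasons.add("not_adjacent")
        if up.chrom == down.chrom and up.strand == down.strand:
            if pair_distance(up, down) < 500:
                reasons.add("min_distance")
        if (
            up.biotype in DEFAULT_EXCLUDED_BIOTYPES
            or down.biotype in DEFAULT_EXCLUDED_BIOTYPES
        ):
            reasons.add("biotype")
    if call.span_reads < 3:
        reasons.add("min_span")
    if call.junction_reads < 3:
        reasons.add("min_junction")
    if call.span_reads + call.junction_reads < 6:
        reasons.add("min_total")
    return (not reasons, ";".join(sorted(reasons)))


def chimera_filter_oracle_agreement(seed: int, n_rows: int = 1000) -> dict:
    config = SimulationConfig(n_genes=40)
    ann, truth = simulate_annotation(config, seed)
    rng = np.random.default_rng(seed + 1)
    gene_ids = [g.gene_id for g in ann] + ["MISSING"]
    calls = []
    for _ in range(n_rows):
        up, down = rng.choice(gene_ids, 2)
        gu, gd = ann.get(up), ann.get(down)
        calls.append(
            FusionCall(
                up_gene=up,
                down_gene=down,
                chrom_up=gu.chrom if gu else "chrX",
                chrom_down=gd.chrom if gd else "chrX",
                strand_up=gu.strand if gu else "+",
                strand_down=gd.strand if gd else "+",
                span_reads=int(rng.integers(0, 10)),
                junction_reads=int(rng.integers(0, 10)),
            )
        )
    # seed every rule at least once with the generator's designed table
    designed = simulate_fusion_calls(ann, truth, config, rng)
    calls.extend(FusionCall(**r) for r in designed.to_dict("records"))
    out = filter_readthrough_chimeras(calls, ann)
    oracle_pairs = set(_brute_force_pairs(ann, 0))
    agree = 0
    for row, call in zip(out.itertuples(), calls):
        exp_pass, exp_reasons = _brute_force_chimera(call, ann, oracle_pairs)
        agree += int(row.passes == exp_pass and row.fail_reasons == exp_reasons)
    return {"n_rows": len(calls), "agreement_pct": 100.0 * agree / len(calls)}


# ---------------------------------------------------------------------------
# exactness, identities, symmetry


def classification_exactness(seed: int, n_genes: int = 40, reads_per_replicate: int = 60) -> dict:
    """Noise-free reads at tolerance 0: classification equals generator truth."""
    config = SimulationConfig(n_genes=n_genes, reads_per_gene=reads_per_replicate)
    res = simulate_dataset(config, seed)
    calls, _ = classify_reads(res["reads_by_rep"], res["annotation"])
    merged = calls.merge(res["truth"].reads, on=["read_id", "replicate"])
    status_ok = (merged["splicing_status"] == merged["true_status"]).mean()
    class_ok = (merged["readthrough_class"] == merged["true_class"]).mean()
    informative = (calls["n_introns_overlapped"] > 0).sum()
    partition = calls["splicing_status"].isin(
        ["all_spliced", "partially_spliced", "all_unspliced"]
    ).sum()
    return {
        "n_reads": int(len(merged)),
        "status_exact_pct": 100.0 * float(status_ok),
        "class_exact_pct": 100.0 * float(class_ok),
        "partition_holds": bool(partition == informative),
    }


def boundary_and_normalization_identities(seed: int) -> dict:
    """Threshold and normalization edge cases, checked end to end."""
    checks = {}
    checks["rti_0.2_is_high"] = rti_category(0.2, Thresholds()) == "high"
    checks["rti_below_is_low"] = rti_category(0.19999, Thresholds()) == "low"
    checks["rti_zero_is_zero"] = rti_category(0.0, Thresholds()) == "zero"

    from readthru.annotation import GeneModel, GenomeAnnotation, Interval, TranscriptModel
    from readthru.reads import LongRead, classify_readthrough

    tx = TranscriptModel(
        "t1", "g", (Interval("chr1", 1000, 2000, "+"), Interval("chr1", 3000, 5000, "+")), True
    )
    gene = GeneModel("g", "protein_coding", (tx,))
    at_boundary = LongRead("r", (Interval("chr1", 4500, 5100, "+"),))
    just_short = LongRead("r", (Interval("chr1", 4500, 5099, "+"),))
    checks["boundary_inclusive"] = classify_readthrough(at_boundary, gene) == "readthrough"
    checks["below_boundary_gene_body"] = classify_readthrough(just_short, gene) == "gene_body"

    config = SimulationConfig(
        n_genes=20,
        exon_length=(250, 450),
        tss_fraction=1.0,
        last_exon_fraction=1.0,
        read_length_cap=0,
    )
    res = simulate_dataset(config, seed)
    reads = [r for v in res["reads_by_rep"].values() for r in v]
    assignments = {r.read_id: assign_read_to_gene(r, res["annotation"]) for r in reads}
    per_gene, _ = pas_downstream_coverage(reads, assignments, res["annotation"], window_down=500)
    anchor = per_gene.loc[per_gene["offset"] == -200, "normalized_coverage"]
    checks["pas_anchor_is_one"] = bool((anchor == 1.0).all()) and len(anchor) > 0

    out = ddct_relative_expression(res["ct"], "spike_in", "parent_last_exon", "CTRL")
    treated = out[out["sample"] == "TREATED"].set_index("target")
    fold_errors = [
        abs(treated.loc[t, "fold_change_vs_control"] - f)
        for t, f in res["truth"].ct_folds.items()
    ]
    checks["ddct_exact"] = bool(max(fold_errors, default=0.0) < 1e-12)
    return {
        "checks": checks,
        "pass_fraction": float(np.mean([v for v in checks.values()])),
        "ddct_max_abs_fold_error": float(max(fold_errors, default=0.0)),
        "n_profile_genes": int(anchor.shape[0]),
    }


def mirror_symmetry(seed: int, n_genes: int = 25, reads_per_replicate: int = 40) -> dict:
    """Strand-reversal + coordinate reflection leaves all metrics unchanged.

    RTI compares per gene; CoSE per intron after re-indexing (intron i maps
    to intron n−1−i when the coordinate order flips).
    """
    config = SimulationConfig(n_genes=n_genes, reads_per_gene=reads_per_replicate)
    res = simulate_dataset(config, seed)
    ann, truth = res["annotation"], res["truth"]
    length = truth.chrom_length
    m_ann = mirror_annotation(ann)
    m_reads = {
        rep: mirror_reads(reads, length) for rep, reads in res["reads_by_rep"].items()
    }
    calls, introns = classify_reads(res["reads_by_rep"], ann)
    m_calls, m_introns = classify_reads(m_reads, m_ann)
    rti = compute_rti(calls).set_index("gene_id")
    m_rti = compute_rti(m_calls).set_index("gene_id")
    rti_diff = float((rti["rti"] - m_rti["rti"]).abs().max())
    cose = compute_cose(introns)
    m_cose = compute_cose(m_introns)
    n_introns = {g: len(truth.sigma[g]) for g in truth.sigma}
    m_cose["intron_index"] = [
        n_introns[g] - 1 - i for g, i in zip(m_cose["gene_id"], m_cose["intron_index"])
    ]
    merged = cose.merge(
        m_cose, on=["gene_id", "intron_index"], suffixes=("", "_m"), how="outer"
    )
    cose_diff = float((merged["cose"] - merged["cose_m"]).abs().max())
    class_counts = calls["readthrough_class"].value_counts()
    m_class_counts = m_calls["readthrough_class"].value_counts()
    counts_equal = bool(class_counts.equals(m_class_counts))
    return {
        "n_genes": int(len(rti)),
        "rti_max_abs_diff": rti_diff,
        "cose_max_abs_diff": cose_diff,
        "class_counts_equal": counts_equal,
        "metric_max_abs_diff": max(rti_diff, cose_diff),
    }
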