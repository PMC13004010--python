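"""Fusion-call parsing and readthrough-chimera filtering."""

import numpy as np
import pandas as pd
import pytest

from readthru.annotation import pair_distance, tandem_pairs
from readthru.chimera import (
    DEFAULT_EXCLUDED_BIOTYPES,
    FusionCall,
    annotate_upstream_rti,
    filter_readthrough_chimeras,
    parse_fusion_calls,
)
from readthru.simulate import SimulationConfig, simulate_annotation, simulate_fusion_calls

from conftest import make_annotation, make_gene


def write_fusion_tsv(path, rows):
    cols = [
        "up_gene", "down_gene", "chrom_up", "chrom_down",
        "strand_up", "strand_down", "span_reads", "junction_reads",
    ]
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def fusion_row(up="A", down="B", span=3, junction=3, strand="+", chrom="chr1"):
    return {
        "up_gene": up, "down_gene": down, "chrom_up": chrom, "chrom_down": chrom,
        "strand_up": strand, "strand_down": strand,
        "span_reads": span, "junction_reads": junction,
    }


class TestParseFusionCalls:
    def test_well_formed_rows(self, tmp_path):
        p = tmp_path / "fusions.tsv"
        write_fusion_tsv(p, [fusion_row(up=f"g{i}") for i in range(5)])
        calls, rejects = parse_fusion_calls(p)
        assert len(calls) == 5 and not rejects

    def test_malformed_row_rejected_run_continues(self, tmp_path):
        p = tmp_path / "fusions.tsv"
        rows = [fusion_row(), fusion_row(span="many"), fusion_row()]
        write_fusion_tsv(p, rows)
        calls, rejects = parse_fusion_calls(p)
        assert len(calls) == 2
        assert rejects[0]["row"] == 1

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "fusions.tsv"
        write_fusion_tsv(p, [])
        calls, rejects = parse_fusion_calls(p)
        assert calls == [] and rejects == []

    def test_missing_mandatory_column_raises(self, tmp_path):
        p = tmp_path / "fusions.tsv"
        p.write_text("up_gene\tdown_gene\nA\tB\n")
        with pytest.raises(ValueError, match="chrom_up"):
            parse_fusion_calls(p)

    def test_column_map(self, tmp_path):
        p = tmp_path / "fusions.tsv"
        cols = ["up_Gene", "dw_Gene", "up_chr", "dw_chr", "up_strand", "dw_strand", "Span_reads_num", "Junc_reads_num"]
        p.write_text("\t".join(cols) + "\nA\tB\tchr1\tchr1\t+\t+\t4\t5\n")
        calls, _ = parse_fusion_calls(
            p,
            column_map={
                "up_gene": "up_Gene", "down_gene": "dw_Gene",
                "chrom_up": "up_chr", "chrom_down": "dw_chr",
                "strand_up": "up_strand", "strand_down": "dw_strand",
                "span_reads": "Span_reads_num", "junction_reads": "Junc_reads_num",
            },
        )
        assert calls[0].span_reads == 4 and calls[0].junction_reads == 5


@pytest.fixture()
def toy_annotation():
    a = make_gene("A", "chr1", "+", [(1000, 5000)])
    b = make_gene("B", "chr1", "+", [(5600, 9000)])  # 600 nt downstream of A
    sno = make_gene("S", "chr1", "+", [(9600, 10000)], biotype="snoRNA")
    return make_annotation(a, b, sno)


class TestFilter:
    def test_minimal_passing_call(self, toy_annotation):
        call = FusionCall(**fusion_row(span=3, junction=3))
        out = filter_readthrough_chimeras([call], toy_annotation)
        assert out.iloc[0]["passes"]
        assert out.iloc[0]["genomic_distance"] == 600

    def test_low_junction_fails_with_both_reasons(self, toy_annotation):
        call = FusionCall(**fusion_row(span=3, junction=2))
        out = filter_readthrough_chimeras([call], toy_annotation)
        assert not out.iloc[0]["passes"]
        assert out.iloc[0]["fail_reasons"] == "min_junction;min_total"

    def test_structural_rna_partner_fails(self, toy_annotation):
        call = FusionCall(**fusion_row(up="B", down="S", span=8, junction=8))
        out = filter_readthrough_chimeras([call], toy_annotation)
        assert out.iloc[0]["fail_reasons"] == "biotype"

    def test_unannotated_gene(self, toy_annotation):
        call = FusionCall(**fusion_row(up="NOPE"))
        out = filter_readthrough_chimeras([call], toy_annotation)
        assert out.iloc[0]["fail_reasons"] == "unannotated"

    def test_reversed_pair_not_adjacent(self, toy_annotation):
        # (B, A) is against the direction of transcription
        call = FusionCall(**fusion_row(up="B", down="A", span=8, junction=8))
        out = filter_readthrough_chimeras([call], toy_annotation)
        assert "not_adjacent" in out.iloc[0]["fail_reasons"]

    def test_idempotent(self, toy_annotation):
        calls = [
            FusionCall(**fusion_row(span=s, junction=j))
            for s, j in [(3, 3), (2, 9), (9, 2), (8, 8)]
        ]
        first = filter_readthrough_chimeras(calls, toy_annotation)
        passing = [calls[i] for i in first.index[first["passes"]]]
        second = filter_readthrough_chimeras(passing, toy_annotation)
        assert second["passes"].all()
        assert len(second) == int(first["passes"].sum())

    def test_tightening_thresholds_never_adds_passes(self, toy_annotation):
        rng = np.random.default_rng(5)
        calls = [
            FusionCall(**fusion_row(span=int(s), junction=int(j)))
            for s, j in rng.integers(0, 12, size=(50, 2))
        ]
        base = filter_readthrough_chimeras(calls, toy_annotation)
        for kwargs in (
            {"min_span": 5}, {"min_junction": 5}, {"min_total": 10},
            {"min_distance": 1000},
        ):
            tight = filter_readthrough_chimeras(calls, toy_annotation, **kwargs)
            assert not (tight["passes"] & ~base["passes"]).any()


def brute_force_filter(call, annotation, min_span=3, min_junction=3, min_total=6,
                       min_distance=500, excluded=DEFAULT_EXCLUDED_BIOTYPES):
    """Independent re-evaluation of every chimera rule for one call."""
    reasons = set()
    up, down = annotation.get(call.up_gene), annotation.get(call.down_gene)
    if up is None or down is None:
        reasons.add("unannotated")
    else:
        if call.chrom_up != call.chrom_down:
            reasons.add("chrom_mismatch")
        if call.strand_up != call.strand_down:
            reasons.add("strand_mismatch")
        if (call.up_gene, call.down_gene) not in tandem_pairs(annotation, 0):
            reasons.add("not_adjacent")
        if up.chrom == down.chrom and up.strand == down.strand:
            if pair_distance(up, down) < min_distance:
                reasons.add("min_distance")
        if up.biotype in excluded or down.biotype in excluded:
            reasons.add("biotype")
    if call.span_reads < min_span:
        reasons.add("min_span")
    if call.junction_reads < min_junction:
        reasons.add("min_junction")
    if call.span_reads + call.junction_reads < min_total:
        reasons.add("min_total")
    return not reasons, ";".join(sorted(reasons))


class TestAgainstBruteForceAndTruth:
    def test_simulated_fusion_table_expectations(self):
        config = SimulationConfig(n_genes=40)
        ann, truth = simulate_annotation(config, seed=9)
        rng = np.random.default_rng(9)
        table = simulate_fusion_calls(ann, truth, config, rng)
        calls = [FusionCall(**r) for r in table.to_dict("records")]
        out = filter_readthrough_chimeras(calls, ann)
        exp = truth.fusion_expectations
        assert list(out["passes"]) == list(exp["expected_pass"])
        assert list(out["fail_reasons"]) == list(exp["expected_reasons"])

    def test_matches_brute_force_on_random_calls(self):
        config = SimulationConfig(n_genes=30)
        ann, truth = simulate_annotation(config, seed=4)
        rng = np.random.default_rng(4)
        gene_ids = [g.gene_id for g in ann] + ["MISSING"]
        calls = []
        for _ in range(300):
            up, down = rng.choice(gene_ids, 2)
            gu, gd = ann.get(up), ann.get(down)
            calls.append(
                FusionCall(
                    up_gene=up, down_gene=down,
                    chrom_up=gu.chrom if gu else "chrX",
                    chrom_down=gd.chrom if gd else "chrX",
                    strand_up=gu.strand if gu else "+",
                    strand_down=gd.strand if gd else "+",
                    span_reads=int(rng.integers(0, 10)),
                    junction_reads=int(rng.integers(0, 10)),
                )
            )
        out = filter_readthrough_chimeras(calls, ann)
        for row, call in zip(out.itertuples(), calls):
            exp_pass, exp_reasons = brute_force_filter(call, ann)
            assert row.passes == exp_pass
            assert row.fail_reasons == exp_reasons


class TestUpstreamRti:
    def test_join_and_missing(self):
        chim = pd.DataFrame({"up_gene": ["A", "Z"], "down_gene": ["B", "Q"]})
        rti = pd.DataFrame({"gene_id": ["A"], "rti": [0.35]})
        out = annotate_upstream_rti(chim, rti)
        assert out.iloc[0]["upstream_rti"] == pytest.approx(0.35)
        assert np.isnan(out.iloc[1]["upstream_rti"])

    def test_chimera_parents_show_elevated_rti(self):
        # chimera-generating genes simulated with high readthrough
        config = SimulationConfig(n_genes=40)
        ann, truth = simulate_annotation(config, seed=21)
        rng = np.random.default_rng(21)
        table = simulate_fusion_calls(ann, truth, config, rng)
        chimera_ups = {up for up, _ in truth.chimera_pairs}
        rti = pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in ann],
                "rti": [0.4 if g.gene_id in chimera_ups else 0.05 for g in ann],
            }
        )
        calls = [FusionCall(**r) for r in table.to_dict("records")]
        out = annotate_upstream_rti(filter_readthrough_chimeras(calls, ann), rti)
        passing = out[out["passes"]]
        assert passing["upstream_rti"].mean() > rti["rti"].mean()
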