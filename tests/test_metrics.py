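"""RTI, CoSE, SPI, unspliced fractions, all-or-none calling, PAS coverage,
and ΔΔCt quantification."""

import numpy as np
import pandas as pd
import pytest

from readthru.annotation import Interval
from readthru.metrics import (
    Thresholds,
    all_or_none_genes,
    compute_cose,
    compute_rti,
    compute_spi,
    ddct_relative_expression,
    gene_level_cose,
    pas_downstream_coverage,
    rti_category,
    unspliced_fraction,
)
from readthru.reads import LongRead

from conftest import make_annotation, make_gene


def calls_frame(rows):
    """rows: (gene, replicate, readthrough_class) or full dict."""
    out = []
    for r in rows:
        if isinstance(r, dict):
            out.append(r)
        else:
            gene, rep, cls = r
            out.append(
                {
                    "read_id": f"r{len(out)}",
                    "replicate": rep,
                    "gene_id": gene,
                    "splicing_status": "not_informative",
                    "n_introns_overlapped": 0,
                    "n_introns_spliced": 0,
                    "readthrough_class": cls,
                    "starts_at_tss": True,
                }
            )
    return pd.DataFrame(out)


class TestRti:
    def test_two_of_ten_is_high(self):
        calls = calls_frame(
            [("g", "rep1", "readthrough")] * 2 + [("g", "rep1", "gene_body")] * 8
        )
        row = compute_rti(calls, Thresholds(min_reads_per_replicate=10)).iloc[0]
        assert row["rti"] == pytest.approx(0.2)
        assert row["category"] == "high"
        assert row["n_last_exon"] == 10

    def test_zero_readthrough_is_zero_category(self):
        calls = calls_frame([("g", "rep1", "gene_body")] * 30)
        row = compute_rti(calls).iloc[0]
        assert row["rti"] == 0 and row["category"] == "zero"

    def test_min_reads_filter_requires_every_replicate(self):
        rows = (
            [("g", "rep1", "gene_body")] * 12
            + [("g", "rep2", "gene_body")] * 11
            + [("g", "rep3", "gene_body")] * 9
        )
        row = compute_rti(calls_frame(rows)).iloc[0]
        assert not row["passes_min_reads"]

    def test_missing_replicate_fails_filter(self):
        rows = [("g", "rep1", "gene_body")] * 15
        row = compute_rti(calls_frame(rows), replicates=["rep1", "rep2"]).iloc[0]
        assert not row["passes_min_reads"]

    def test_not_last_exon_reads_excluded_from_denominator(self):
        rows = (
            [("g", "rep1", "readthrough")] * 2
            + [("g", "rep1", "gene_body")] * 8
            + [("g", "rep1", "not_last_exon")] * 50
        )
        row = compute_rti(calls_frame(rows)).iloc[0]
        assert row["rti"] == pytest.approx(0.2)

    def test_gene_with_no_last_exon_reads_omitted(self):
        calls = calls_frame([("g", "rep1", "not_last_exon")] * 5)
        assert compute_rti(calls).empty

    @pytest.mark.parametrize(
        "rti,expected", [(0.2, "high"), (0.19999, "low"), (0.0, "zero"), (1.0, "high")]
    )
    def test_category_boundaries(self, rti, expected):
        assert rti_category(rti, Thresholds()) == expected


class TestCose:
    def test_eight_of_ten(self):
        frame = pd.DataFrame(
            {
                "gene_id": "g",
                "intron_index": 0,
                "replicate": "rep1",
                "read_id": [f"r{i}" for i in range(10)],
                "spliced": [True] * 8 + [False] * 2,
            }
        )
        row = compute_cose(frame).iloc[0]
        assert row["cose"] == pytest.approx(0.8)

    def test_no_spanning_reads_absent(self):
        assert compute_cose(pd.DataFrame(columns=["gene_id", "intron_index", "replicate", "read_id", "spliced"])).empty

    def test_binomial_recovery(self):
        # spanning reads spliced with probability 0.6; CoSE within 3 SE
        rng = np.random.default_rng(14)
        n, p = 1000, 0.6
        frame = pd.DataFrame(
            {
                "gene_id": "g",
                "intron_index": 0,
                "replicate": "rep1",
                "read_id": [f"r{i}" for i in range(n)],
                "spliced": rng.random(n) < p,
            }
        )
        cose = compute_cose(frame).iloc[0]["cose"]
        se = np.sqrt(p * (1 - p) / n)
        assert abs(cose - p) < 3 * se

    def test_gene_level_pooled_vs_mean(self):
        cose = pd.DataFrame(
            {
                "gene_id": ["g", "g"],
                "intron_index": [0, 1],
                "n_spliced": [90, 10],
                "n_total": [100, 20],
                "cose": [0.9, 0.5],
            }
        )
        pooled = gene_level_cose(cose, "pooled").iloc[0]["cose"]
        mean = gene_level_cose(cose, "mean").iloc[0]["cose"]
        assert pooled == pytest.approx(100 / 120)
        assert mean == pytest.approx(0.7)


class TestUnsplicedFraction:
    def test_simple_percentage(self):
        rows = [
            {
                "read_id": f"r{i}",
                "replicate": "rep1",
                "gene_id": "g",
                "splicing_status": s,
                "n_introns_overlapped": 1,
                "n_introns_spliced": 0,
                "readthrough_class": "gene_body",
                "starts_at_tss": True,
            }
            for i, s in enumerate(
                ["all_unspliced"] * 3 + ["all_spliced"] * 5 + ["partially_spliced"] * 2
            )
        ]
        out = unspliced_fraction(pd.DataFrame(rows), group_by=("readthrough_class",))
        assert out.iloc[0]["pct_all_unspliced"] == pytest.approx(30.0)
        assert out.iloc[0]["n_informative"] == 10

    def test_all_spliced_group_is_zero(self):
        rows = calls_frame([("g", "rep1", "gene_body")] * 4)
        rows["splicing_status"] = "all_spliced"
        out = unspliced_fraction(rows, group_by=("readthrough_class",))
        assert out.iloc[0]["pct_all_unspliced"] == 0.0

    def test_not_informative_excluded(self):
        rows = calls_frame([("g", "rep1", "gene_body")] * 4)  # all not_informative
        assert unspliced_fraction(rows, group_by=("readthrough_class",)).empty


class TestAllOrNone:
    def test_threshold_conjunction(self):
        rti = pd.DataFrame(
            {"gene_id": ["a", "b", "c"], "rti": [0.25, 0.1, 0.3]}
        )
        cose = pd.DataFrame({"gene_id": ["a", "b", "c"], "cose": [0.6, 0.5, 0.9]})
        assert all_or_none_genes(rti, cose) == ["a"]

    def test_gene_missing_from_one_table_excluded(self):
        rti = pd.DataFrame({"gene_id": ["a", "b"], "rti": [0.5, 0.5]})
        cose = pd.DataFrame({"gene_id": ["a"], "cose": [0.1]})
        assert all_or_none_genes(rti, cose) == ["a"]


class TestPasCoverage:
    def _one_gene(self):
        return make_gene("g", "chr1", "+", [(1000, 2000), (3000, 5000)])  # pas 5000

    def test_normalized_to_one_at_minus_200(self):
        gene = self._one_gene()
        ann = make_annotation(gene)
        reads = [
            LongRead(f"r{i}", (Interval("chr1", 4000, 5600 + 100 * i, "+"),))
            for i in range(5)
        ]
        assignments = {r.read_id: "g" for r in reads}
        per_gene, profile = pas_downstream_coverage(reads, assignments, ann, window_down=500)
        at_anchor = per_gene[per_gene["offset"] == -200]["normalized_coverage"]
        assert (at_anchor == 1.0).all()

    def test_uniform_coverage_gives_flat_profile(self):
        gene = self._one_gene()
        ann = make_annotation(gene)
        reads = [LongRead("r", (Interval("chr1", 4000, 5600, "+"),))]
        _, profile = pas_downstream_coverage(
            reads, {"r": "g"}, ann, window_down=500
        )
        inside = profile[profile["offset"] <= 499]
        assert (inside["mean_normalized_coverage"] == 1.0).all()

    def test_zero_anchor_gene_dropped(self):
        gene = self._one_gene()
        ann = make_annotation(gene)
        reads = [LongRead("r", (Interval("chr1", 5000, 5400, "+"),))]  # nothing at -200
        _, profile = pas_downstream_coverage(reads, {"r": "g"}, ann, window_down=500)
        assert profile["n_genes"].iloc[0] == 0

    def test_bad_window_raises(self):
        ann = make_annotation(self._one_gene())
        with pytest.raises(ValueError):
            pas_downstream_coverage([], {}, ann, window_down=0)

    def test_minus_strand_profile_mirrors(self):
        plus = make_gene("g", "chr1", "+", [(1000, 2000), (3000, 5000)])
        minus = make_gene("g", "chr1", "-", [(5000, 7000), (8000, 9000)])  # pas 5000
        r_plus = LongRead("r", (Interval("chr1", 4000, 5600, "+"),))
        r_minus = LongRead("r", (Interval("chr1", 4400, 6000, "-"),))
        _, prof_plus = pas_downstream_coverage(
            [r_plus], {"r": "g"}, make_annotation(plus), window_down=400
        )
        _, prof_minus = pas_downstream_coverage(
            [r_minus], {"r": "g"}, make_annotation(minus), window_down=400
        )
        pd.testing.assert_frame_equal(prof_plus, prof_minus)


class TestDdct:
    def test_fold_change_of_four(self):
        table = pd.DataFrame(
            [
                ("ctrl", "spike", 10.0),
                ("ctrl", "ref", 15.0),
                ("ctrl", "tgt", 22.0),
                ("treated", "spike", 10.0),
                ("treated", "ref", 15.0),
                ("treated", "tgt", 20.0),
            ],
            columns=["sample", "target", "ct"],
        )
        out = ddct_relative_expression(table, "spike", "ref", "ctrl")
        fold = out[(out["sample"] == "treated")]["fold_change_vs_control"].iloc[0]
        assert fold == pytest.approx(4.0)

    def test_identical_ct_gives_fold_one(self):
        table = pd.DataFrame(
            [
                (s, t, ct)
                for s in ("ctrl", "treated")
                for t, ct in [("spike", 10.0), ("ref", 15.0), ("tgt", 20.0)]
            ],
            columns=["sample", "target", "ct"],
        )
        out = ddct_relative_expression(table, "spike", "ref", "ctrl")
        assert (out["fold_change_vs_control"] == 1.0).all()

    def test_target_equal_to_reference_gives_rel_one(self):
        table = pd.DataFrame(
            [("s", "spike", 10.0), ("s", "ref", 18.0), ("s", "tgt", 18.0)],
            columns=["sample", "target", "ct"],
        )
        out = ddct_relative_expression(table, "spike", "ref", "s")
        assert out["rel_to_reference"].iloc[0] == pytest.approx(1.0)

    def test_missing_ct_skipped(self):
        table = pd.DataFrame(
            [("s1", "spike", 10.0), ("s1", "ref", 15.0), ("s1", "tgt", 20.0),
             ("s2", "ref", 15.0), ("s2", "tgt", 20.0)],  # s2 lacks spike
            columns=["sample", "target", "ct"],
        )
        out = ddct_relative_expression(table, "spike", "ref", "s1")
        assert set(out["sample"]) == {"s1"}


class TestSpi:
    def _frame(self, split5, split3, unsplit_each):
        return pd.DataFrame(
            [
                {"intron_id": "i1", "replicate": "rep1", "site": "5p",
                 "split": split5, "unsplit": unsplit_each},
                {"intron_id": "i1", "replicate": "rep1", "site": "3p",
                 "split": split3, "unsplit": unsplit_each},
            ]
        )

    def test_formula(self):
        out = compute_spi(self._frame(200, 200, 50), Thresholds(spi_min_pooled=500))
        assert out.iloc[0]["spi"] == pytest.approx(0.8)
        assert not out.iloc[0]["excluded"]

    def test_pooled_minimum_excludes(self):
        out = compute_spi(self._frame(200, 199, 50), Thresholds(spi_min_pooled=500))
        assert out.iloc[0]["pooled_total"] == 499
        assert out.iloc[0]["excluded"]

    def test_all_split_is_one(self):
        out = compute_spi(self._frame(100, 100, 0))
        assert out.iloc[0]["spi"] == 1.0

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            compute_spi(self._frame(-1, 100, 0))
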