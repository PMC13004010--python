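"""Gene-model loading, representative-transcript selection, boundaries,
and tandem-pair detection."""

import itertools

import pytest

from readthru.annotation import (
    GeneModel,
    Interval,
    ParseError,
    load_annotation,
    pair_distance,
    readthrough_boundary,
    tandem_pairs,
)
from readthru.mirror import mirror_annotation
from readthru.simulate import (
    SimulationConfig,
    simulate_annotation,
    write_annotation_bed12,
    write_annotation_gtf,
)

from conftest import make_annotation, make_gene, make_transcript


class TestIntervalAndTranscript:
    def test_interval_rejects_empty_and_bad_strand(self):
        with pytest.raises(ValueError):
            Interval("chr1", 100, 100, "+")
        with pytest.raises(ValueError):
            Interval("chr1", 100, 200, ".")

    def test_three_exon_transcript_has_two_introns(self):
        tx = make_transcript(
            "t1", "g1", "chr1", "+", [(100, 200), (300, 400), (500, 600)]
        )
        assert len(tx.introns) == 2
        assert tx.introns[0] == Interval("chr1", 200, 300, "+")
        assert tx.introns[1] == Interval("chr1", 400, 500, "+")
        assert tx.tss == 100 and tx.pas == 600

    def test_minus_strand_tss_pas_swap(self):
        tx = make_transcript("t1", "g1", "chr1", "-", [(100, 200), (300, 400)])
        assert tx.tss == 400 and tx.pas == 100


class TestRepresentativeSelection:
    def test_distal_three_prime_wins_for_readthrough(self):
        t_short = make_transcript(
            "tA", "g1", "chr1", "+", [(1000, 2000), (3000, 5000)], canonical=True
        )
        t_long = make_transcript("tB", "g1", "chr1", "+", [(1000, 2000), (3000, 6000)])
        gene = GeneModel("g1", "protein_coding", (t_short, t_long))
        assert gene.representative_readthrough.transcript_id == "tB"
        assert gene.pas == 6000

    def test_canonical_and_distal_may_differ(self):
        t_canon = make_transcript(
            "tA", "g1", "chr1", "+", [(1000, 2000), (3000, 5000)], canonical=True
        )
        t_distal = make_transcript("tB", "g1", "chr1", "+", [(1000, 2000), (3000, 6000)])
        gene = GeneModel("g1", "protein_coding", (t_canon, t_distal))
        assert gene.representative_splicing.transcript_id == "tA"
        assert gene.representative_readthrough.transcript_id == "tB"

    def test_minus_strand_distal_is_leftmost(self):
        t_short = make_transcript(
            "tA", "g1", "chr1", "-", [(3000, 5000)], canonical=True
        )
        t_long = make_transcript("tB", "g1", "chr1", "-", [(2000, 5000)])
        gene = GeneModel("g1", "protein_coding", (t_short, t_long))
        assert gene.representative_readthrough.transcript_id == "tB"
        assert gene.pas == 2000


class TestBoundary:
    def test_plus_strand(self):
        gene = make_gene("g1", "chr1", "+", [(1000, 5000)])
        assert readthrough_boundary(gene) == 5100

    def test_minus_strand_mirror(self):
        gene = make_gene("g1", "chr1", "-", [(1000, 5000)])
        assert readthrough_boundary(gene) == 900

    def test_boundary_offset_invariant_on_random_annotation(self):
        ann, _ = simulate_annotation(SimulationConfig(n_genes=30), seed=3)
        for gene in ann:
            sign = 1 if gene.strand == "+" else -1
            assert sign * (gene.readthrough_boundary - gene.pas) == 100


class TestLoadAnnotation:
    def test_bed12_three_exon_gene(self, tmp_path):
        line = "\t".join(
            [
                "chr1", "100", "600", "t1|g1|canonical", "0", "+",
                "100", "600", "0,0,0", "3", "100,100,100,", "0,200,400,",
            ]
        )
        p = tmp_path / "genes.bed12"
        p.write_text(line + "\n")
        ann = load_annotation(p)
        gene = ann["g1"]
        assert len(gene.representative_splicing.introns) == 2
        assert gene.pas == 600
        assert gene.readthrough_boundary == 700

    def test_inconsistent_blocks_raise_with_line_number(self, tmp_path):
        line = "\t".join(
            [
                "chr1", "100", "600", "t1|g1", "0", "+",
                "100", "600", "0,0,0", "3", "100,100,", "0,200,400,",
            ]
        )
        p = tmp_path / "bad.bed12"
        p.write_text(line + "\n")
        with pytest.raises(ParseError, match="line 1"):
            load_annotation(p)

    def test_zero_length_exon_rejected(self, tmp_path):
        line = "\t".join(
            [
                "chr1", "100", "600", "t1|g1", "0", "+",
                "100", "600", "0,0,0", "2", "100,0,", "0,500,",
            ]
        )
        p = tmp_path / "bad.bed12"
        p.write_text(line + "\n")
        with pytest.raises(ParseError):
            load_annotation(p)

    def test_gtf_and_bed12_loaders_agree(self, tmp_path):
        config = SimulationConfig(n_genes=15)
        ann, _ = simulate_annotation(config, seed=5)
        write_annotation_gtf(ann, tmp_path / "genes.gtf")
        write_annotation_bed12(ann, tmp_path / "genes.bed12")
        from_gtf = load_annotation(tmp_path / "genes.gtf")
        from_bed = load_annotation(tmp_path / "genes.bed12")
        assert len(from_gtf) == len(from_bed) == len(ann)
        for gene in ann:
            for loaded in (from_gtf[gene.gene_id], from_bed[gene.gene_id]):
                assert loaded.pas == gene.pas
                assert loaded.tss == gene.tss
                assert loaded.readthrough_boundary == gene.readthrough_boundary
                assert (
                    loaded.representative_splicing.introns
                    == gene.representative_splicing.introns
                )

    def test_gtf_biotype_round_trip(self, tmp_path):
        config = SimulationConfig(n_genes=15)
        ann, truth = simulate_annotation(config, seed=5)
        write_annotation_gtf(ann, tmp_path / "genes.gtf")
        loaded = load_annotation(tmp_path / "genes.gtf")
        assert truth.biotype_pair is not None
        biotypes = {loaded[g].biotype for g in truth.biotype_pair}
        assert "snoRNA" in biotypes


def brute_force_tandem_pairs(annotation, min_distance):
    """O(n²) re-evaluation of the tandem-pair rules."""
    genes = list(annotation)
    pairs = []

    def txo(g):  # transcription-order coordinate
        return g.interval.start if g.strand == "+" else -g.interval.start

    for up, down in itertools.permutations(genes, 2):
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


class TestTandemPairs:
    def test_simple_pair(self):
        a = make_gene("A", "chr1", "+", [(1000, 5000)])
        b = make_gene("B", "chr1", "+", [(6000, 9000)])
        ann = make_annotation(a, b)
        assert tandem_pairs(ann, min_distance=500) == [("A", "B")]

    def test_strand_mismatch_is_no_pair(self):
        a = make_gene("A", "chr1", "+", [(1000, 5000)])
        b = make_gene("B", "chr1", "-", [(6000, 9000)])
        assert tandem_pairs(make_annotation(a, b), min_distance=500) == []

    def test_intervening_gene_breaks_pair(self):
        a = make_gene("A", "chr1", "+", [(1000, 5000)])
        c = make_gene("C", "chr1", "+", [(6000, 8000)])
        b = make_gene("B", "chr1", "+", [(9000, 12000)])
        ann = make_annotation(a, b, c)
        assert tandem_pairs(ann, min_distance=500) == [("A", "C"), ("C", "B")]

    def test_opposite_strand_gene_does_not_break_adjacency(self):
        a = make_gene("A", "chr1", "+", [(1000, 5000)])
        x = make_gene("X", "chr1", "-", [(6000, 7000)])
        b = make_gene("B", "chr1", "+", [(8000, 12000)])
        assert tandem_pairs(make_annotation(a, x, b), min_distance=500) == [("A", "B")]

    def test_min_distance_filter(self):
        a = make_gene("A", "chr1", "+", [(1000, 5000)])
        b = make_gene("B", "chr1", "+", [(5200, 9000)])
        assert tandem_pairs(make_annotation(a, b), min_distance=500) == []
        assert tandem_pairs(make_annotation(a, b), min_distance=100) == [("A", "B")]

    def test_minus_strand_transcription_order(self):
        # on the − strand the right gene is upstream
        a = make_gene("A", "chr1", "-", [(1000, 5000)])
        b = make_gene("B", "chr1", "-", [(6000, 9000)])
        assert tandem_pairs(make_annotation(a, b), min_distance=500) == [("B", "A")]

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_on_random_annotations(self, seed):
        ann, _ = simulate_annotation(SimulationConfig(n_genes=40), seed=seed)
        for min_d in (0, 500, 2000):
            assert tandem_pairs(ann, min_d) == brute_force_tandem_pairs(ann, min_d)

    def test_mirrored_annotation_same_pair_count(self):
        ann, _ = simulate_annotation(SimulationConfig(n_genes=30), seed=8)
        mirrored = mirror_annotation(ann)
        assert len(tandem_pairs(ann, 500)) == len(tandem_pairs(mirrored, 500))
        for gene in ann:
            m = mirrored[gene.gene_id]
            L = ann.chrom_lengths[gene.chrom]
            assert m.readthrough_boundary == L - gene.readthrough_boundary
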