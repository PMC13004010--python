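import pytest

from readthru.annotation import GeneModel, GenomeAnnotation, Interval, TranscriptModel
from readthru.simulate import SimulationConfig, simulate_dataset


def make_transcript(tid, gid, chrom, strand, exons, canonical=False):
    return TranscriptModel(
        tid,
        gid,
        tuple(Interval(chrom, s, e, strand) for s, e in exons),
        is_canonical=canonical,
    )


def make_gene(gid, chrom, strand, exons, biotype="protein_coding", canonical=True):
    """Single-transcript gene from (start, end) exon tuples."""
    tx = make_transcript(f"{gid}.t1", gid, chrom, strand, exons, canonical=canonical)
    return GeneModel(gid, biotype, (tx,))


def make_annotation(*genes, chrom_lengths=None):
    return GenomeAnnotation(genes, chrom_lengths=chrom_lengths)


@pytest.fixture(scope="session")
def small_sim():
    """A small synthetic dataset shared across read-level tests."""
    config = SimulationConfig(n_genes=20, reads_per_gene=30)
    return simulate_dataset(config, seed=14)
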