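import numpy as np
import pytest

from annotune.annotation_core import (AnnotationSet, GeneModel,
                                      GenomicInterval, TranscriptModel)
from annotune.synthetic_data import (SimulationConfig,
                                     simulate_genome_and_annotation)


def make_transcript(tx_id, gene_id, exons, contig="chr1", strand="+",
                    attributes=None):
    """Build a transcript from (start, end) pairs."""
    return TranscriptModel(
        tx_id, gene_id, contig, strand,
        tuple(GenomicInterval(contig, s, e, strand) for s, e in exons),
        attributes=attributes or {},
    )


def make_gene(gene_id, exon_lists, contig="chr1", strand="+"):
    """Build a gene whose i-th transcript has the i-th exon list."""
    txs = tuple(
        make_transcript(f"{gene_id}.t{i + 1}", gene_id, exons, contig, strand)
        for i, exons in enumerate(exon_lists)
    )
    return GeneModel(gene_id, txs)


def make_annotation(*genes):
    return AnnotationSet(genes)


def random_annotation(rng, n_genes=10, contig="chr1", max_pos=10_000):
    """Small random annotation with non-overlapping genes on both strands."""
    genes = []
    pos = int(rng.integers(0, 50))
    for i in range(n_genes):
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 5))
        exons = []
        for _ in range(n_exons):
            length = int(rng.integers(20, 120))
            exons.append((pos, pos + length))
            pos += length + int(rng.integers(30, 90))
        gid = f"rg{i + 1:03d}"
        n_iso = int(rng.integers(1, 3))
        iso_lists = [exons]
        if n_iso > 1 and len(exons) >= 3:
            iso_lists.append(exons[:1] + exons[2:])
        genes.append(make_gene(gid, iso_lists, contig, strand))
        pos += int(rng.integers(50, 200))
        if pos > max_pos:
            break
    return AnnotationSet(genes)


@pytest.fixture(scope="session")
def toy_genome_annotation():
    """A 2 x 100 kb synthetic genome with 50 planted genes (seeded)."""
    config = SimulationConfig(seed=11, n_genes=50)
    genome, ann = simulate_genome_and_annotation(config)
    lengths = {c: len(s) for c, s in genome.items()}
    return config, genome, ann, lengths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
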