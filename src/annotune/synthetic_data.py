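"""Seeded generators for every input the toolkit consumes, with planted
ground truth.

The generators emulate the statistical structure of a compact fly-like
genome: short introns, a few exons per gene, a handful of isoforms,
stranded expression, tissue-biased genes, legacy-annotation deficits
(truncated UTRs, split genes, missing genes), and a sister species with
diverged sequence and partially rearranged gene order.  Everything is
driven by one :class:`numpy.random.Generator` per call, so identical
config + seed gives identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .annotation_core import (AnnotationSet, GeneModel, GenomicInterval,
                              TranscriptModel)
from .expression_coverage import (EXPRESSION_TISSUES, SEXED_TISSUES,
                                  ExpressionMatrix, ReadBlockSet, SplicedRead)
from .ortholog_finder import HomologyTable

__all__ = [
    "SimulationConfig",
    "simulate_genome_and_annotation",
    "perturb_annotation",
    "simulate_reads",
    "simulate_expression_matrix",
    "simulate_matched_expression",
    "simulate_cdna_cohort_ends",
    "simulate_cdna_cohort_junctions",
    "simulate_ortholog_pair_species",
    "SyntheticAssembler",
    "write_fasta",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all generators; rates are probabilities in [0, 1].

    Defaults produce a toy fly-like genome — 2 contigs of 100 kb, 50
    compact genes with short (mostly GT-AG) introns — that exercises every
    code path in seconds.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length: int = 100_000
    gc_content: float = 0.45
    n_genes: int = 50
    mean_exons: float = 4.0            # exon count ~ 1 + Poisson(mean-1)
    exon_log_mean: float = 5.3         # exon length ~ LogNormal (≈200 bp)
    exon_log_sd: float = 0.4
    intron_log_mean: float = 4.3       # intron length ~ LogNormal (≈74 bp)
    intron_log_sd: float = 0.3
    min_exon: int = 30
    min_intron: int = 40
    isoform_geom_p: float = 0.6        # isoforms ~ 1 + Geometric(p) - 1
    max_isoforms: int = 4
    gtag_fraction: float = 0.9         # introns written with GT..AG boundaries
    intergenic_gap: int = 300
    # legacy-annotation perturbation rates
    utr_truncation: float = 0.0
    utr_trim_bp: int = 100
    gene_split: float = 0.0
    gene_drop: float = 0.0
    isoform_drop: float = 0.0
    noise_gene_rate: float = 0.0       # short mono-exonic noise genes, per gene
    noise_gene_length: int = 120
    # read simulation
    read_length: int = 100
    read_noise_rate: float = 0.0       # fraction of reads placed intergenic
    # expression simulation
    expr_log_mean: float = 4.5         # baseline ~ LogNormal (≈90 counts)
    expr_log_sd: float = 1.0
    replicates: int = 4
    tissue_bias_fraction: float = 0.2
    tissue_bias_fold: float = 8.0
    expr_noise_sd: float = 0.1         # replicate-level log-normal noise
    # ortholog pair species
    substitution_rate: float = 0.05
    rearrangement_rate: float = 0.05
    rbh_dropout: float = 0.0
    known_holdout: float = 0.2         # planted pairs withheld from training


def _rng(config: SimulationConfig, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng((config.seed, salt))


def _random_seq(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def write_fasta(sequences: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Genome + truth annotation
# ---------------------------------------------------------------------------

def _sample_gene_structure(rng, config: SimulationConfig):
    """Exon/intron lengths of one gene; returns (exon_lens, intron_lens)."""
    n_exons = 1 + rng.poisson(max(config.mean_exons - 1, 0.0))
    exon_lens = np.maximum(
        config.min_exon,
        np.round(rng.lognormal(config.exon_log_mean, config.exon_log_sd,
                               n_exons)).astype(int),
    )
    intron_lens = np.maximum(
        config.min_intron,
        np.round(rng.lognormal(config.intron_log_mean, config.intron_log_sd,
                               max(n_exons - 1, 0))).astype(int),
    )
    return list(exon_lens), list(intron_lens)


def _make_isoforms(rng, config, gene_id, contig, strand, offset,
                   exon_lens, intron_lens, tx_counter):
    """Primary isoform uses all exons; extras skip one internal exon."""
    starts = []
    pos = offset
    for i, el in enumerate(exon_lens):
        starts.append(pos)
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    all_exons = [
        GenomicInterval(contig, s, s + l, strand)
        for s, l in zip(starts, exon_lens)
    ]
    n_iso = min(1 + rng.geometric(config.isoform_geom_p) - 1,
                config.max_isoforms)
    txs = []
    skipped: set[int] = set()
    for k in range(n_iso):
        tx_id = f"tx{next(tx_counter):05d}"
        if k == 0 or len(all_exons) < 3:
            exons = tuple(all_exons)
        else:
            choices = [i for i in range(1, len(all_exons) - 1)
                       if i not in skipped]
            if not choices:
                break
            skip = int(rng.choice(choices))
            skipped.add(skip)
            exons = tuple(e for i, e in enumerate(all_exons) if i != skip)
        txs.append(TranscriptModel(tx_id, gene_id, contig, strand, exons))
    return txs, pos


def simulate_genome_and_annotation(
    config: SimulationConfig,
) -> tuple[dict[str, str], AnnotationSet]:
    """Random genome plus a planted truth annotation.

    Genes are packed left-to-right on alternating strands with intergenic
    gaps; GT-AG dinucleotides are written at a ``gtag_fraction`` of intron
    boundaries on the coding strand.  Raises if the requested genes do not
    fit the contigs.
    """
    rng = _rng(config, salt=1)
    seqs = {
        f"contig{c + 1}": _random_seq(rng, config.contig_length,
                                      config.gc_content)
        for c in range(config.n_contigs)
    }
    genes = []
    tx_counter = iter(range(1, 10 ** 6))
    contig_names = list(seqs)
    positions = {c: config.intergenic_gap for c in contig_names}
    ci = 0
    for gi in range(config.n_genes):
        gene_id = f"gene{gi + 1:04d}"
        strand = "+" if gi % 2 == 0 else "-"
        exon_lens, intron_lens = _sample_gene_structure(rng, config)
        span = sum(exon_lens) + sum(intron_lens)
        placed = False
        for _ in range(len(contig_names)):
            contig = contig_names[ci % len(contig_names)]
            if positions[contig] + span + config.intergenic_gap \
                    <= config.contig_length:
                placed = True
                break
            ci += 1
        if not placed:
            raise ValueError(
                f"cannot pack {config.n_genes} genes into "
                f"{config.n_contigs} x {config.contig_length} bp")
        offset = positions[contig]
        txs, end = _make_isoforms(rng, config, gene_id, contig, strand,
                                  offset, exon_lens, intron_lens, tx_counter)
        positions[contig] = end + config.intergenic_gap
        ci += 1
        genes.append(GeneModel(gene_id, tuple(txs)))
    ann = AnnotationSet(genes)

    # write splice dinucleotides on the coding strand
    code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for gene in ann:
        arr = seqs[gene.contig]
        for intron in gene.unique_introns():
            if rng.random() >= config.gtag_fraction:
                continue
            if gene.strand == "+":
                donor, acceptor = "GT", "AG"
                arr[intron.start] = code[donor[0]]
                arr[intron.start + 1] = code[donor[1]]
                arr[intron.end - 2] = code[acceptor[0]]
                arr[intron.end - 1] = code[acceptor[1]]
            else:  # revcomp(GT..AG) = CT..AC on the genome
                arr[intron.start] = code["C"]
                arr[intron.start + 1] = code["T"]
                arr[intron.end - 2] = code["A"]
                arr[intron.end - 1] = code["C"]
    genome = {name: "".join(_BASES[arr]) for name, arr in seqs.items()}
    return genome, ann


# ---------------------------------------------------------------------------
# Legacy-annotation perturbation
# ---------------------------------------------------------------------------

def _trim_transcript(t: TranscriptModel, trim: int) -> TranscriptModel:
    """Shorten both terminal exons by ``trim`` bp, floored at 1 bp."""
    exons = list(t.exons)
    first = exons[0]
    new_start = min(first.start + trim, first.end - 1)
    exons[0] = GenomicInterval(first.contig, new_start, first.end, first.strand)
    last = exons[-1]
    new_end = max(last.end - trim, exons[-1].start + 1 if len(exons) > 1
                  else new_start + 1)
    exons[-1] = GenomicInterval(last.contig, exons[-1].start, new_end,
                                last.strand)
    return TranscriptModel(t.transcript_id, t.gene_id, t.contig, t.strand,
                           tuple(exons))


def _split_gene(gene: GeneModel, rng) -> list[GeneModel]:
    """Split a multi-exon gene into two at a shared intron."""
    shared = set(gene.transcripts[0].intron_chain)
    for t in gene.transcripts[1:]:
        shared &= set(t.intron_chain)
    if not shared:
        return [gene]
    cut = sorted(shared)[int(rng.integers(len(shared)))]
    left_txs, right_txs = [], []
    for t in gene.transcripts:
        left = tuple(e for e in t.exons if e.end <= cut[0])
        right = tuple(e for e in t.exons if e.start >= cut[1])
        if left:
            left_txs.append(TranscriptModel(
                t.transcript_id + "a", gene.gene_id + "a", t.contig,
                t.strand, left))
        if right:
            right_txs.append(TranscriptModel(
                t.transcript_id + "b", gene.gene_id + "b", t.contig,
                t.strand, right))
    out = []
    if left_txs:
        out.append(GeneModel(gene.gene_id + "a", tuple(left_txs)))
    if right_txs:
        out.append(GeneModel(gene.gene_id + "b", tuple(right_txs)))
    return out or [gene]


def _intergenic_gaps(ann: AnnotationSet, contig_lengths: dict[str, int],
                     pad: int = 50) -> list[tuple[str, int, int]]:
    gaps = []
    for contig, length in contig_lengths.items():
        spans = sorted(
            (g.span.start, g.span.end) for g in ann
            if g.contig == contig
        )
        prev = 0
        for s, e in spans:
            if s - pad > prev + pad:
                gaps.append((contig, prev + pad, s - pad))
            prev = max(prev, e)
        if length - pad > prev + pad:
            gaps.append((contig, prev + pad, length - pad))
    return gaps


def perturb_annotation(
    truth: AnnotationSet, config: SimulationConfig,
    contig_lengths: dict[str, int] | None = None,
) -> tuple[AnnotationSet, pd.DataFrame]:
    """Degrade a truth annotation the way legacy annotations are degraded.

    Applies, per gene and at the configured rates: complete drop, split at
    a shared intron, UTR truncation of every transcript's terminal exons,
    and isoform removal; optionally adds short mono-exonic noise genes in
    intergenic space (requires ``contig_lengths``).  Returns the perturbed
    annotation and a change log with one row per gene
    (``gene_id``, ``action``) — noise genes are logged with action
    ``noise``.
    """
    rng = _rng(config, salt=2)
    out_genes: list[GeneModel] = []
    log = []
    for gene in truth:
        r = rng.random()
        if r < config.gene_drop:
            log.append((gene.gene_id, "drop"))
            continue
        action = "keep"
        g = gene
        if rng.random() < config.gene_split:
            parts = _split_gene(g, rng)
            if len(parts) > 1:
                action = "split"
                for p in parts:
                    out_genes.append(p)
                log.append((gene.gene_id, action))
                continue
        txs = list(g.transcripts)
        if len(txs) > 1 and rng.random() < config.isoform_drop:
            drop = int(rng.integers(len(txs)))
            txs.pop(drop)
            action = "isoform_drop"
        if rng.random() < config.utr_truncation:
            txs = [_trim_transcript(t, config.utr_trim_bp) for t in txs]
            action = "utr_truncation" if action == "keep" else action + "+utr"
        out_genes.append(GeneModel(g.gene_id, tuple(txs)))
        log.append((gene.gene_id, action))

    n_noise = int(round(config.noise_gene_rate * len(truth)))
    if n_noise and contig_lengths:
        gaps = _intergenic_gaps(truth, contig_lengths)
        for i in range(n_noise):
            contig, lo, hi = gaps[int(rng.integers(len(gaps)))]
            L = config.noise_gene_length
            if hi - lo <= L:
                continue
            s = int(rng.integers(lo, hi - L))
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"noise{i + 1:04d}"
            out_genes.append(GeneModel(gid, (TranscriptModel(
                gid + ".t1", gid, contig, strand,
                (GenomicInterval(contig, s, s + L, strand),)),)))
            log.append((gid, "noise"))
    return (AnnotationSet(out_genes),
            pd.DataFrame(log, columns=["gene_id", "action"]))


# ---------------------------------------------------------------------------
# Reads
# ---------------------------------------------------------------------------

def _read_blocks_from_transcript(t: TranscriptModel, tx_pos: int,
                                 read_len: int) -> tuple:
    """Genome blocks of a read starting at transcript coordinate tx_pos."""
    blocks = []
    remaining = read_len
    pos = tx_pos
    for e in t.exons:
        if remaining <= 0:
            break
        if pos >= e.length:
            pos -= e.length
            continue
        take = min(e.length - pos, remaining)
        blocks.append(GenomicInterval(e.contig, e.start + pos,
                                      e.start + pos + take, t.strand))
        remaining -= take
        pos = 0
    return tuple(blocks)


def simulate_reads(
    truth: AnnotationSet,
    expression: dict[str, float] | None,
    depth: int,
    config: SimulationConfig,
    contig_lengths: dict[str, int] | None = None,
) -> ReadBlockSet:
    """Sample uniquely-mapped stranded spliced reads from transcripts.

    ``depth`` is the total read count; reads are allocated to transcripts
    proportionally to ``expression[gene_id]`` (uniform if None) and placed
    uniformly along the spliced transcript, producing multi-block reads
    across introns.  A ``read_noise_rate`` fraction of reads is placed in
    intergenic space instead (single block, random strand).
    """
    rng = _rng(config, salt=3)
    if depth <= 0:
        return ReadBlockSet([])
    txs = [t for t in truth.transcripts()
           if t.exonic_length >= config.read_length]
    if not txs:
        raise ValueError("no transcript is long enough for the read length")
    weights = np.array([
        (expression.get(t.gene_id, 1.0) if expression else 1.0)
        for t in txs
    ], dtype=float)
    weights = weights / weights.sum()
    gaps = [
        g for g in (_intergenic_gaps(truth, contig_lengths)
                    if contig_lengths else [])
        if g[2] - g[1] > 20
    ]
    reads = []
    n_noise = rng.binomial(depth, config.read_noise_rate) if gaps else 0
    tx_idx = rng.choice(len(txs), size=depth - n_noise, p=weights)
    for i, k in enumerate(tx_idx):
        t = txs[k]
        start = int(rng.integers(0, t.exonic_length - config.read_length + 1))
        blocks = _read_blocks_from_transcript(t, start, config.read_length)
        reads.append(SplicedRead(f"read{i + 1:07d}", t.contig, t.strand,
                                 blocks))
    for j in range(n_noise):
        contig, lo, hi = gaps[int(rng.integers(len(gaps)))]
        L = max(1, min(config.read_length, hi - lo - 1))
        s = int(rng.integers(lo, max(hi - L, lo + 1)))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(SplicedRead(
            f"noise{j + 1:07d}", contig, strand,
            (GenomicInterval(contig, s, s + L, strand),)))
    return ReadBlockSet(reads)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def simulate_expression_matrix(
    gene_ids, config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Normalized counts for the 16 sexed tissues with planted biases.

    Each gene gets a log-normal baseline; a ``tissue_bias_fraction`` of
    genes is up-regulated ``tissue_bias_fold``-fold in one random sexed
    tissue; replicates add multiplicative log-normal noise.  Returns the
    matrix and a ground-truth bias table (``gene_id``, ``biased_tissue``).
    """
    rng = _rng(config, salt=4)
    gene_ids = list(gene_ids)
    baselines = rng.lognormal(config.expr_log_mean, config.expr_log_sd,
                              len(gene_ids))
    bias_rows = []
    profiles = np.tile(baselines[:, None], (1, len(SEXED_TISSUES)))
    for i, gid in enumerate(gene_ids):
        if rng.random() < config.tissue_bias_fraction:
            j = int(rng.integers(len(SEXED_TISSUES)))
            profiles[i, j] *= config.tissue_bias_fold
            bias_rows.append((gid, SEXED_TISSUES[j]))
        else:
            bias_rows.append((gid, ""))
    cols = {}
    meta_rows = []
    for j, tissue in enumerate(SEXED_TISSUES):
        sex, _, tname = tissue.partition("_")
        for r in range(1, config.replicates + 1):
            sample = f"{tissue}_rep{r}"
            noise = rng.lognormal(0.0, config.expr_noise_sd, len(gene_ids)) \
                if config.expr_noise_sd > 0 else 1.0
            cols[sample] = profiles[:, j] * noise
            meta_rows.append((sample, "sim", sex, tissue, r))
    values = pd.DataFrame(cols, index=gene_ids)
    samples = pd.DataFrame(
        meta_rows, columns=["sample", "species", "sex", "tissue", "replicate"]
    ).set_index("sample")
    return (ExpressionMatrix(values, samples),
            pd.DataFrame(bias_rows, columns=["gene_id", "biased_tissue"]))


def simulate_matched_expression(
    expr: ExpressionMatrix, gene_map: dict[str, str],
    config: SimulationConfig,
) -> ExpressionMatrix:
    """Expression for a sister species mirroring orthologous profiles.

    Each mapped gene copies its ortholog's profile with fresh replicate
    noise, so true pairs have near-perfect tissue-rank correlation while
    random pairs do not.
    """
    rng = _rng(config, salt=5)
    src = expr.values
    rows = {}
    for ref_gene, query_gene in gene_map.items():
        noise = rng.lognormal(0.0, config.expr_noise_sd, src.shape[1]) \
            if config.expr_noise_sd > 0 else 1.0
        rows[query_gene] = src.loc[ref_gene].values * noise
    values = pd.DataFrame.from_dict(rows, orient="index",
                                    columns=src.columns)
    return ExpressionMatrix(values, expr.samples)


# ---------------------------------------------------------------------------
# cDNA cohorts with planted categories
# ---------------------------------------------------------------------------

def _allocate(mix: dict[str, float], n: int) -> dict[str, int]:
    counts = {k: int(round(f * n)) for k, f in mix.items()}
    drift = n - sum(counts.values())
    first = next(iter(counts))
    counts[first] += drift
    return counts


def simulate_cdna_cohort_ends(
    truth: AnnotationSet, contig_lengths: dict[str, int],
    mix: dict[str, float], n: int, config: SimulationConfig,
    extension: int = 50,
) -> tuple[list, pd.DataFrame]:
    """Full-length cDNAs with a planted transcript-end category mix.

    ``mix`` maps ``within`` / ``ext5_only`` / ``ext3_only`` / ``ext_both`` /
    ``intergenic`` to fractions summing to 1.  Extensions protrude
    ``extension`` bp beyond the source transcript's span (kept well inside
    the intergenic gaps so categories cannot bleed into each other).
    Returns the cohort and a truth table (``cdna_id``, ``category``).
    """
    from .cdna_validation import CdnaAlignment

    rng = _rng(config, salt=7)
    txs = sorted(truth.transcripts(), key=lambda t: t.transcript_id)
    gaps = [g for g in _intergenic_gaps(truth, contig_lengths)
            if g[2] - g[1] > 120]
    counts = _allocate(mix, n)
    cdnas, labels = [], []
    idx = 1
    for category, count in counts.items():
        for _ in range(count):
            cid = f"cdna{idx:06d}"
            idx += 1
            if category == "intergenic":
                contig, lo, hi = gaps[int(rng.integers(len(gaps)))]
                s = int(rng.integers(lo, hi - 100))
                strand = "+" if rng.random() < 0.5 else "-"
                blocks = (GenomicInterval(contig, s, s + 100, strand),)
                cdnas.append(CdnaAlignment(cid, contig, strand, blocks))
            else:
                t = txs[int(rng.integers(len(txs)))]
                pairs = [(e.start, e.end) for e in t.exons]
                ext5 = category in ("ext5_only", "ext_both")
                ext3 = category in ("ext3_only", "ext_both")
                left = ext5 if t.strand == "+" else ext3
                right = ext3 if t.strand == "+" else ext5
                if left:
                    pairs[0] = (pairs[0][0] - extension, pairs[0][1])
                if right:
                    pairs[-1] = (pairs[-1][0], pairs[-1][1] + extension)
                blocks = tuple(GenomicInterval(t.contig, s, e, t.strand)
                               for s, e in pairs)
                cdnas.append(CdnaAlignment(cid, t.contig, t.strand, blocks))
            labels.append((cid, category))
    return cdnas, pd.DataFrame(labels, columns=["cdna_id", "category"])


def simulate_cdna_cohort_junctions(
    truth: AnnotationSet, contig_lengths: dict[str, int],
    mix: dict[str, float], n: int, config: SimulationConfig,
) -> tuple[list, pd.DataFrame]:
    """Intron-containing cDNAs with a planted junction category mix.

    ``mix`` maps ``all_present`` / ``called_annotated`` /
    ``partially_unannotated`` / ``all_unannotated`` / ``antisense`` to
    fractions summing to 1.  ``called_annotated`` combines one intron from
    each of two same-strand genes; ``partially_unannotated`` displaces one
    acceptor of a 2+-intron transcript; ``all_unannotated`` plants a novel
    junction in intergenic space; ``antisense`` copies a spliced transcript
    onto the opposite strand.
    """
    from .cdna_validation import CdnaAlignment

    rng = _rng(config, salt=8)
    multi = [t for t in truth.transcripts() if t.intron_chain]
    multi.sort(key=lambda t: t.transcript_id)
    rich = [t for t in multi
            if len(t.intron_chain) >= 2 and t.exons[-1].length > 20]
    gaps = [g for g in _intergenic_gaps(truth, contig_lengths)
            if g[2] - g[1] > 220]
    # ordered same-contig, same-strand multi-exon gene pairs
    pair_pool = []
    by_key: dict[tuple[str, str], list] = {}
    for g in truth:
        if any(t.intron_chain for t in g.transcripts):
            by_key.setdefault((g.contig, g.strand), []).append(g)
    for (contig, strand), genes in sorted(by_key.items()):
        genes.sort(key=lambda g: g.span.start)
        for a, b in zip(genes, genes[1:]):
            ia = a.unique_introns()[0]
            ib = b.unique_introns()[-1]
            if ia.end < ib.start and ia.start >= 30:
                pair_pool.append((contig, strand, ia, ib))
    counts = _allocate(mix, n)
    cdnas, labels = [], []
    idx = 1
    for category, count in counts.items():
        for _ in range(count):
            cid = f"jcdna{idx:06d}"
            idx += 1
            if category == "all_present":
                t = multi[int(rng.integers(len(multi)))]
                cdnas.append(CdnaAlignment(cid, t.contig, t.strand, t.exons))
            elif category == "antisense":
                t = multi[int(rng.integers(len(multi)))]
                flip = "-" if t.strand == "+" else "+"
                blocks = tuple(GenomicInterval(t.contig, e.start, e.end, flip)
                               for e in t.exons)
                cdnas.append(CdnaAlignment(cid, t.contig, flip, blocks))
            elif category == "called_annotated":
                contig, strand, ia, ib = pair_pool[
                    int(rng.integers(len(pair_pool)))]
                blocks = (
                    GenomicInterval(contig, ia.start - 30, ia.start, strand),
                    GenomicInterval(contig, ia.end, ib.start, strand),
                    GenomicInterval(contig, ib.end, ib.end + 30, strand),
                )
                cdnas.append(CdnaAlignment(cid, contig, strand, blocks))
            elif category == "partially_unannotated":
                t = rich[int(rng.integers(len(rich)))]
                pairs = [(e.start, e.end) for e in t.exons]
                # displace the last acceptor into the final exon
                pairs[-1] = (pairs[-1][0] + 15, pairs[-1][1])
                blocks = tuple(GenomicInterval(t.contig, s, e, t.strand)
                               for s, e in pairs)
                cdnas.append(CdnaAlignment(cid, t.contig, t.strand, blocks))
            elif category == "all_unannotated":
                contig, lo, hi = gaps[int(rng.integers(len(gaps)))]
                s = int(rng.integers(lo, hi - 200))
                strand = "+" if rng.random() < 0.5 else "-"
                blocks = (GenomicInterval(contig, s, s + 60, strand),
                          GenomicInterval(contig, s + 140, s + 200, strand))
                cdnas.append(CdnaAlignment(cid, contig, strand, blocks))
            else:
                raise ValueError(f"unknown junction category {category!r}")
            labels.append((cid, category))
    return cdnas, pd.DataFrame(labels, columns=["cdna_id", "category"])


# ---------------------------------------------------------------------------
# Sister species with planted orthologs
# ---------------------------------------------------------------------------

def simulate_ortholog_pair_species(
    truth: AnnotationSet, genome: dict[str, str], config: SimulationConfig,
) -> tuple[AnnotationSet, dict[str, str], HomologyTable, pd.DataFrame]:
    """Build a sister species by cassette relocation and point mutation.

    Each gene's genomic cassette (span plus flanks) is copied onto new
    contigs; a ``rearrangement_rate`` fraction of genes is relocated to
    random positions in the gene order, and every copied base mutates
    i.i.d. at ``substitution_rate``.  Returns the sister annotation, its
    genome, an RBH table (with ``rbh_dropout`` missing links), and the
    planted pair table with a ``known`` flag marking the
    (1 − ``known_holdout``) fraction available as training orthologs.
    """
    rng = _rng(config, salt=6)
    genes = list(truth)
    order = list(range(len(genes)))
    n_move = int(round(config.rearrangement_rate * len(genes)))
    if n_move:
        movers = rng.choice(len(genes), size=n_move, replace=False)
        moved = [order[i] for i in sorted(movers)]
        remaining = [x for i, x in enumerate(order) if i not in set(movers)]
        for m in moved:
            pos = int(rng.integers(len(remaining) + 1))
            remaining.insert(pos, m)
        order = remaining

    pad = config.intergenic_gap // 2
    new_contig = "contigB1"
    seq_parts: list[str] = []
    pos = 0
    new_genes = []
    pairs = []
    sub = config.substitution_rate
    for idx in order:
        gene = genes[idx]
        span = gene.span
        lo = max(0, span.start - pad)
        hi = min(len(genome[gene.contig]), span.end + pad)
        cassette = np.frombuffer(
            genome[gene.contig][lo:hi].encode(), dtype="S1").copy()
        if sub > 0:
            mask = rng.random(len(cassette)) < sub
            if mask.any():
                orig = cassette[mask]
                shift = rng.integers(1, 4, size=mask.sum())
                lut = {b"A": 0, b"C": 1, b"G": 2, b"T": 3}
                codes = np.array([lut.get(bytes(b), 0) for b in orig])
                cassette[mask] = _BASES[(codes + shift) % 4].astype("S1")
        offset = pos - lo
        new_id = "B_" + gene.gene_id
        txs = tuple(
            TranscriptModel(
                "B_" + t.transcript_id, new_id, new_contig, t.strand,
                tuple(GenomicInterval(new_contig, e.start + offset,
                                      e.end + offset, t.strand)
                      for e in t.exons),
            )
            for t in gene.transcripts
        )
        new_genes.append(GeneModel(new_id, txs))
        pairs.append((gene.gene_id, new_id))
        seq_parts.append(cassette.tobytes().decode())
        pos += len(cassette)
    genome_b = {new_contig: "".join(seq_parts)}
    ann_b = AnnotationSet(new_genes)

    rbh_rows = []
    for ref_g, query_g in pairs:
        if config.rbh_dropout > 0 and rng.random() < config.rbh_dropout:
            continue
        rbh_rows.append((ref_g, query_g, 1.0 - sub, True))
    homology = HomologyTable(pd.DataFrame(
        rbh_rows, columns=["gene_a", "gene_b", "score", "rbh"]))

    known = rng.random(len(pairs)) >= config.known_holdout
    planted = pd.DataFrame(pairs, columns=["ref_gene", "query_gene"])
    planted["known"] = known
    return ann_b, genome_b, homology, planted


# ---------------------------------------------------------------------------
# Synthetic assembler with a planted parameter optimum
# ---------------------------------------------------------------------------

class SyntheticAssembler:
    """A stand-in transcript assembler with a planted parameter optimum.

    Reconstructs the truth annotation degraded by an error level that
    grows monotonically with the normalized distance between the supplied
    parameters and ``planted_optimum``: terminal exons are truncated, the
    lowest-expressed transcripts dropped, and spurious mono-exonic
    fragments added.  At the optimum the output equals the truth exactly
    (exon Jaccard 1.0), and the Jaccard strictly decreases along any
    single-parameter ray away from the optimum.  Deterministic per
    (params, seed).
    """

    def __init__(self, truth: AnnotationSet,
                 planted_optimum: dict[str, float],
                 param_scales: dict[str, float] | None = None,
                 contig_lengths: dict[str, int] | None = None,
                 seed: int = 0,
                 max_truncation: int = 400,
                 drop_fraction: float = 0.5,
                 max_noise_genes: int = 20,
                 abundances: dict[str, tuple[float, float]] | None = None):
        self.truth = truth
        self.optimum = dict(planted_optimum)
        self.scales = param_scales or {
            k: abs(v) if v else 1.0 for k, v in self.optimum.items()
        }
        self.contig_lengths = contig_lengths or {}
        self.seed = seed
        self.max_truncation = max_truncation
        self.drop_fraction = drop_fraction
        self.max_noise_genes = max_noise_genes
        self.abundances = abundances or {}

    def distance(self, params: dict[str, float]) -> float:
        unknown = set(params) - set(self.optimum)
        if unknown:
            raise KeyError(f"unknown assembler parameters: {sorted(unknown)}")
        if not params:
            raise KeyError("no parameters supplied")
        return float(np.mean([
            abs(params[k] - self.optimum[k]) / self.scales[k]
            for k in params
        ]))

    def __call__(self, reads, params: dict[str, float]) -> AnnotationSet:
        d = min(self.distance(params), 1.0)
        txs = sorted(self.truth.transcripts(),
                     key=lambda t: t.transcript_id)
        n_drop = int(d * self.drop_fraction * len(txs))
        rng = np.random.default_rng(self.seed)
        drop_order = rng.permutation(len(txs))
        dropped = set(drop_order[:n_drop])
        trunc = int(math.ceil(d * self.max_truncation)) if d > 0 else 0
        out = []
        for i, t in enumerate(txs):
            if i in dropped:
                continue
            nt = _trim_transcript(t, trunc) if trunc else t
            fpkm, tpm = self.abundances.get(t.transcript_id, (10.0, 10.0))
            out.append(TranscriptModel(
                nt.transcript_id, nt.gene_id, nt.contig, nt.strand, nt.exons,
                attributes={"fpkm": fpkm, "tpm": tpm}))
        if not out:
            raise RuntimeError("all transcripts dropped at this distance")
        n_noise = int(round(d * self.max_noise_genes))
        if n_noise and self.contig_lengths:
            gaps = _intergenic_gaps(self.truth, self.contig_lengths)
            for j in range(n_noise):
                contig, lo, hi = gaps[j % len(gaps)]
                L = min(150, hi - lo - 1)
                s = lo + (j * 37) % max(hi - lo - L, 1)
                gid = f"frag{j + 1:04d}"
                out.append(TranscriptModel(
                    gid + ".t1", gid, contig, "+",
                    (GenomicInterval(contig, s, s + L, "+"),),
                    attributes={"fpkm": 0.5, "tpm": 0.5}))
        by_gene: dict[str, list[TranscriptModel]] = {}
        for t in out:
            by_gene.setdefault(t.gene_id, []).append(t)
        return AnnotationSet(
            GeneModel(gid, tuple(ts)) for gid, ts in by_gene.items()
        )
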