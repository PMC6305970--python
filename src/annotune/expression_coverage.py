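"""Annotation-completeness metrics from mapped reads, and the expression
matrix container.

Two evidence metrics quantify how much transcription an annotation misses:

* the fraction of uniquely-mapped reads that overlap no annotated gene
  region, and
* the fraction of unannotated genomic bases that are covered by at least
  one read block.

By default "annotated region" means the union of transcript spans (introns
included), so pre-mRNA reads over introns do not score as novel
transcription; an exon-only mode is available.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation_core import AnnotationSet, GenomicInterval, _merge_sorted
from .interval_metrics import UndefinedRatioError, _intersect_size

__all__ = [
    "SplicedRead",
    "ReadBlockSet",
    "ExpressionMatrix",
    "TISSUES",
    "SEXED_TISSUES",
    "EXPRESSION_TISSUES",
    "read_bed12",
    "write_bed12",
    "unannotated_read_fraction",
    "unannotated_region_fraction",
    "evaluate_by_sample",
    "median_tissue_expression",
]

#: Adult tissue dissection vocabulary (8 tissue types, dissected per sex).
TISSUES = (
    "head", "thorax", "abdomen", "digestive", "gonad",
    "reproductive_tract", "terminalia", "carcass",
)
#: The 16 sexed tissues: every tissue type in both sexes.
SEXED_TISSUES = tuple(
    f"{sex}_{tissue}" for tissue in TISSUES for sex in ("female", "male")
)
#: The 14 sexed tissues used for expression features: all except terminalia.
EXPRESSION_TISSUES = tuple(
    st for st in SEXED_TISSUES if not st.endswith("terminalia")
)


@dataclass(frozen=True)
class SplicedRead:
    """A uniquely-mapped read as ordered, non-overlapping aligned blocks."""

    read_id: str
    contig: str
    strand: str
    blocks: tuple[GenomicInterval, ...]

    def __post_init__(self):
        blocks = tuple(sorted(self.blocks, key=lambda b: b.start))
        for a, b in zip(blocks, blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"read {self.read_id}: overlapping blocks")
        object.__setattr__(self, "blocks", blocks)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.contig, a.end, b.start, self.strand)
            for a, b in zip(self.blocks, self.blocks[1:])
        )


@dataclass
class ReadBlockSet:
    """A collection of uniquely-mapped spliced reads."""

    reads: list[SplicedRead] = field(default_factory=list)
    uniquely_mapped: bool = True

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


def read_bed12(path) -> ReadBlockSet:
    """Read spliced alignments from BED12 (block-structured intervals)."""
    reads = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 needs 12 fields")
            contig, chrom_start = f[0], int(f[1])
            name, strand = f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            blocks = tuple(
                GenomicInterval(contig, chrom_start + off,
                                chrom_start + off + size, strand)
                for off, size in zip(starts, sizes)
            )
            reads.append(SplicedRead(name, contig, strand, blocks))
    return ReadBlockSet(reads)


def write_bed12(reads: Iterable[SplicedRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            start = r.blocks[0].start
            end = r.blocks[-1].end
            sizes = ",".join(str(b.length) for b in r.blocks)
            offs = ",".join(str(b.start - start) for b in r.blocks)
            fh.write(
                f"{r.contig}\t{start}\t{end}\t{r.read_id}\t0\t{r.strand}\t"
                f"{start}\t{end}\t0,0,0\t{len(r.blocks)}\t{sizes}\t{offs}\n"
            )


def read_bam(path, unique_tag: str = "NH") -> ReadBlockSet:
    """Optional BAM adapter: uniquely-mapped reads (NH==1) as block sets."""
    import pysam  # optional dependency, only needed for BAM input

    reads = []
    with pysam.AlignmentFile(path) as bam:
        for aln in bam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.has_tag(unique_tag) and aln.get_tag(unique_tag) != 1:
                continue
            strand = "-" if aln.is_reverse else "+"
            blocks = tuple(
                GenomicInterval(aln.reference_name, s, e, strand)
                for s, e in aln.get_blocks()
            )
            reads.append(SplicedRead(aln.query_name, aln.reference_name,
                                     strand, blocks))
    return ReadBlockSet(reads)


# ---------------------------------------------------------------------------
# Annotated-region machinery
# ---------------------------------------------------------------------------

def _annotated_intervals(ann: AnnotationSet, region: str) -> dict:
    """Merged annotated intervals per (contig, strand).

    region='span' uses transcript spans (introns included); 'exon' uses
    exonic intervals only.
    """
    raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for g in ann:
        for t in g.transcripts:
            key = (t.contig, t.strand)
            if region == "span":
                s = t.span
                raw.setdefault(key, []).append((s.start, s.end))
            elif region == "exon":
                raw.setdefault(key, []).extend(
                    (e.start, e.end) for e in t.exons)
            else:
                raise ValueError(f"unknown region mode {region!r}")
    return {k: _merge_sorted(sorted(v)) for k, v in raw.items()}


def _unstranded(intervals_by_key: dict) -> dict:
    raw: dict[str, list[tuple[int, int]]] = {}
    for (contig, _), ivs in intervals_by_key.items():
        raw.setdefault(contig, []).extend(ivs)
    return {c: _merge_sorted(sorted(v)) for c, v in raw.items()}


def _block_hits(block: GenomicInterval, ivs: list[tuple[int, int]]) -> bool:
    """Any ≥1 bp overlap between a block and a sorted disjoint interval list."""
    import bisect
    i = bisect.bisect_right([s for s, _ in ivs], block.start)
    # candidate intervals: the one starting at or before block.start, and any
    # starting inside the block
    if i > 0 and ivs[i - 1][1] > block.start:
        return True
    return i < len(ivs) and ivs[i][0] < block.end


def unannotated_read_fraction(reads: ReadBlockSet, ann: AnnotationSet,
                              region: str = "span",
                              stranded: bool = True) -> float:
    """Fraction of reads with no block overlapping any annotated gene region.

    A read counts as annotated if ANY of its blocks overlaps ANY annotated
    region by at least 1 bp.  With ``stranded=True`` a read is first checked
    against its own strand and then, as a fallback, against the opposite
    strand only when its strand is '.'.
    """
    if len(reads) == 0:
        raise UndefinedRatioError("no reads: fraction undefined")
    by_key = _annotated_intervals(ann, region)
    merged_unstranded = _unstranded(by_key)
    novel = 0
    for r in reads:
        if stranded and r.strand in ("+", "-"):
            ivs = by_key.get((r.contig, r.strand), [])
        else:
            ivs = merged_unstranded.get(r.contig, [])
        if not any(_block_hits(b, ivs) for b in r.blocks if ivs):
            novel += 1
    return novel / len(reads)


def unannotated_region_fraction(reads: ReadBlockSet, ann: AnnotationSet,
                                contig_lengths: dict[str, int],
                                region: str = "span") -> float:
    """Fraction of unannotated genomic bases covered by at least one read.

    Unannotated bases = genome minus the (strand-pooled) union of annotated
    gene regions.  Coverage is strand-agnostic: transcription evidence on
    either strand marks a base as expressed.
    """
    ann_by_contig = _unstranded(_annotated_intervals(ann, region))
    total_unannotated = 0
    covered_unannotated = 0
    cov_raw: dict[str, list[tuple[int, int]]] = {}
    for r in reads:
        cov_raw.setdefault(r.contig, []).extend(
            (b.start, b.end) for b in r.blocks)
    cov = {c: _merge_sorted(sorted(v)) for c, v in cov_raw.items()}
    for contig, length in contig_lengths.items():
        ann_ivs = ann_by_contig.get(contig, [])
        ann_bases = sum(e - s for s, e in ann_ivs)
        unann = length - ann_bases
        total_unannotated += unann
        cov_ivs = cov.get(contig, [])
        cov_bases = sum(e - s for s, e in cov_ivs)
        cov_in_ann = _intersect_size(cov_ivs, ann_ivs)
        covered_unannotated += cov_bases - cov_in_ann
    if total_unannotated == 0:
        raise UndefinedRatioError(
            "annotation covers the entire genome: fraction undefined")
    return covered_unannotated / total_unannotated


def evaluate_by_sample(read_sets: dict, ann: AnnotationSet,
                       contig_lengths: dict[str, int],
                       region: str = "span") -> pd.DataFrame:
    """Both metrics per sample group.

    ``read_sets`` maps a group key — e.g. ``(species, sex, tissue)`` — to a
    :class:`ReadBlockSet` (or ``None`` for a missing group, reported NA).
    Returns a tidy DataFrame with one row per group.
    """
    rows = []
    for key, rs in read_sets.items():
        key_t = key if isinstance(key, tuple) else (key,)
        if rs is None or len(rs) == 0:
            rows.append((*key_t, math.nan, math.nan))
            continue
        rows.append((
            *key_t,
            unannotated_read_fraction(rs, ann, region=region),
            unannotated_region_fraction(rs, ann, contig_lengths,
                                        region=region),
        ))
    ncols = max(len(r) - 2 for r in rows) if rows else 1
    key_cols = ["species", "sex", "tissue"][:ncols] or ["group"]
    if ncols > 3:
        key_cols = [f"key{i}" for i in range(ncols)]
    return pd.DataFrame(
        rows, columns=key_cols + ["unannotated_read_fraction",
                                  "unannotated_region_fraction"],
    )


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

class ExpressionMatrix:
    """Normalized gene-by-sample expression with sample metadata.

    ``values`` is a genes × samples DataFrame of normalized counts;
    ``samples`` is a DataFrame indexed by sample id with at least
    ``tissue`` (a sexed-tissue label from :data:`SEXED_TISSUES`) and
    optionally ``species``, ``sex`` and ``replicate`` columns.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        if (values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = set(values.columns) - set(samples.index)
        if missing:
            raise ValueError(f"samples missing metadata: {sorted(missing)[:5]}")
        bad = set(samples["tissue"]) - set(SEXED_TISSUES)
        if bad:
            raise ValueError(f"unknown sexed-tissue labels: {sorted(bad)}")
        self.values = values
        self.samples = samples.loc[list(values.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.values.index

    def to_tsv(self, values_path, samples_path) -> None:
        self.values.to_csv(values_path, sep="\t")
        self.samples.to_csv(samples_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, samples_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(values, samples)


def median_tissue_expression(
    expr: ExpressionMatrix, gene_id: str,
    tissues: Sequence[str] = EXPRESSION_TISSUES,
) -> np.ndarray:
    """Per-sexed-tissue median expression across replicates for one gene.

    Returns the medians in the order of ``tissues`` (default: the 14
    sexed tissues, terminalia excluded).  Tissues without samples give NaN.
    """
    if gene_id not in expr:
        raise KeyError(f"gene {gene_id} not in expression matrix")
    row = expr.values.loc[gene_id]
    tissue_of = expr.samples["tissue"]
    out = np.empty(len(tissues))
    for i, t in enumerate(tissues):
        cols = tissue_of.index[tissue_of == t]
        out[i] = float(np.median(row.loc[cols])) if len(cols) else math.nan
    return out
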