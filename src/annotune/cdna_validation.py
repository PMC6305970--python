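"""Validate an annotation against full-length cDNA alignments.

Full-length cDNAs (e.g. long-read isoform sequencing) arrive as spliced
genome alignments (BED12).  Three views are produced:

* per-cDNA maximum transcript-level Jaccard against the annotation,
* transcript-end categories — is each cDNA contained within its best
  matching transcript's span, extended at the 5' end, the 3' end, both,
  or intergenic, and
* junction categories for intron-containing cDNAs — whether the cDNA's
  intron chain is a contiguous sub-chain of one annotated transcript, all
  junctions known but split across transcripts, partially or fully novel,
  or matching the annotation only on the opposite strand (a hallmark of
  reverse-transcription artifacts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .annotation_core import AnnotationSet, GenomicInterval, TranscriptModel
from .interval_metrics import BaseSet, _intersect_size, transcript_jaccard

__all__ = [
    "CdnaAlignment",
    "EndCategory",
    "JunctionCategory",
    "read_cdna_bed12",
    "cdna_jaccard",
    "best_matching_transcript",
    "classify_ends",
    "classify_junctions",
    "validation_report",
    "ValidationReport",
]


@dataclass(frozen=True)
class CdnaAlignment:
    """A full-length cDNA aligned to the genome as ordered exonic blocks."""

    cdna_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self):
        blocks = tuple(sorted(self.exons, key=lambda b: b.start))
        for a, b in zip(blocks, blocks[1:]):
            if b.start < a.end:
                raise ValueError(f"cDNA {self.cdna_id}: overlapping blocks")
        object.__setattr__(self, "exons", blocks)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.contig, self.exons[0].start,
                               self.exons[-1].end, self.strand)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return tuple(
            GenomicInterval(self.contig, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((i.start, i.end) for i in self.introns)


class EndCategory(str, Enum):
    within = "within"
    ext5_only = "ext5_only"
    ext3_only = "ext3_only"
    ext_both = "ext_both"
    intergenic = "intergenic"


class JunctionCategory(str, Enum):
    all_present = "all_present"
    called_annotated = "called_annotated"
    partially_unannotated = "partially_unannotated"
    all_unannotated = "all_unannotated"
    antisense = "antisense"


def read_cdna_bed12(path) -> list[CdnaAlignment]:
    """Read cDNA alignments from BED12."""
    from .expression_coverage import read_bed12

    return [
        CdnaAlignment(r.read_id, r.contig, r.strand, r.blocks)
        for r in read_bed12(path)
    ]


def _overlapping_transcripts(cdna: CdnaAlignment, ann: AnnotationSet,
                             stranded: bool = True):
    span = cdna.span
    for gene in ann.query(cdna.contig, span.start, span.end,
                          cdna.strand if stranded else None):
        yield from gene.transcripts


def best_matching_transcript(cdna: CdnaAlignment, ann: AnnotationSet
                             ) -> tuple[TranscriptModel | None, float]:
    """The annotated transcript maximizing exonic Jaccard with the cDNA.

    Ties break by transcript id.  Returns ``(None, 0.0)`` when nothing
    overlaps on the cDNA's strand.
    """
    best_t, best_jac, best_id = None, 0.0, None
    for t in _overlapping_transcripts(cdna, ann):
        jac = transcript_jaccard(cdna, t)
        if jac <= 0:
            continue
        if (jac > best_jac
                or (jac == best_jac and (best_id is None
                                         or t.transcript_id < best_id))):
            best_t, best_jac, best_id = t, jac, t.transcript_id
    return best_t, best_jac


def cdna_jaccard(cdna: CdnaAlignment, ann: AnnotationSet) -> float:
    """Maximum transcript-level Jaccard of a cDNA over the annotation."""
    return best_matching_transcript(cdna, ann)[1]


def classify_ends(cdna: CdnaAlignment, ann: AnnotationSet,
                  slack: int = 0) -> EndCategory:
    """Categorize a cDNA by its termini against the best-match transcript.

    Intergenic if no exonic-base overlap with any gene on the cDNA's
    strand.  Otherwise each terminus extending beyond the matched
    transcript's span by more than ``slack`` bp is called unannotated; the
    5'/3' assignment follows the strand.
    """
    t, jac = best_matching_transcript(cdna, ann)
    if t is None or jac == 0.0:
        return EndCategory.intergenic
    span = t.span
    left_ext = cdna.span.start < span.start - slack
    right_ext = cdna.span.end > span.end + slack
    if cdna.strand == "-":
        ext5, ext3 = right_ext, left_ext
    else:
        ext5, ext3 = left_ext, right_ext
    if ext5 and ext3:
        return EndCategory.ext_both
    if ext5:
        return EndCategory.ext5_only
    if ext3:
        return EndCategory.ext3_only
    return EndCategory.within


def _annotation_introns(ann: AnnotationSet, contig: str,
                        strand: str) -> set[tuple[int, int]]:
    # cached per annotation instance: rebuilding the genome-wide intron set
    # for every cDNA would dominate large validation runs
    cache = getattr(ann, "_intron_set_cache", None)
    if cache is None:
        cache = {}
        for g in ann:
            bucket = cache.setdefault((g.contig, g.strand), set())
            for t in g.transcripts:
                bucket.update(t.intron_chain)
        object.__setattr__(ann, "_intron_set_cache", cache)
    return cache.get((contig, strand), set())


def _is_contiguous_subchain(sub: tuple, chain: tuple) -> bool:
    n, m = len(sub), len(chain)
    return any(chain[i:i + n] == sub for i in range(m - n + 1))


def classify_junctions(cdna: CdnaAlignment, ann: AnnotationSet
                       ) -> JunctionCategory:
    """Categorize an intron-containing cDNA by junction agreement.

    Raises ValueError for mono-exonic cDNAs (they have no junctions).
    """
    J = set(cdna.intron_chain)
    if not J:
        raise ValueError(f"cDNA {cdna.cdna_id} is not intron-containing")
    A = _annotation_introns(ann, cdna.contig, cdna.strand)
    opposite = "-" if cdna.strand == "+" else "+"
    A_anti = _annotation_introns(ann, cdna.contig, opposite)
    if not (J & A) and J <= A_anti:
        return JunctionCategory.antisense
    if J <= A:
        chain = cdna.intron_chain
        for gene in ann.query(cdna.contig, cdna.span.start, cdna.span.end,
                              cdna.strand):
            for t in gene.transcripts:
                if _is_contiguous_subchain(chain, t.intron_chain):
                    return JunctionCategory.all_present
        return JunctionCategory.called_annotated
    if not (J & A):
        return JunctionCategory.all_unannotated
    return JunctionCategory.partially_unannotated


@dataclass
class ValidationReport:
    """Per-annotation cDNA validation summary."""

    jaccard: pd.Series                    # per-cDNA max Jaccard
    end_counts: pd.Series                 # per EndCategory
    junction_counts: pd.Series            # per JunctionCategory (spliced only)
    bases_covered_fraction: float         # annotated bases touched by a cDNA
    per_cdna: pd.DataFrame

    @property
    def end_fractions(self) -> pd.Series:
        return self.end_counts / self.end_counts.sum()

    @property
    def junction_fractions(self) -> pd.Series:
        total = self.junction_counts.sum()
        return self.junction_counts / total if total else self.junction_counts

    def to_tsv(self, path) -> None:
        self.per_cdna.to_csv(path, sep="\t", index=False)


def _report_one(cdnas, ann: AnnotationSet, slack: int) -> ValidationReport:
    rows = []
    for c in cdnas:
        jac = cdna_jaccard(c, ann)
        endcat = classify_ends(c, ann, slack=slack)
        juncat = (classify_junctions(c, ann).value
                  if len(c.exons) > 1 else "")
        rows.append((c.cdna_id, jac, endcat.value, juncat))
    per_cdna = pd.DataFrame(
        rows, columns=["cdna_id", "jaccard", "end_category",
                       "junction_category"])
    end_counts = pd.Series(Counter(per_cdna["end_category"]), dtype=int)
    end_counts = end_counts.reindex([c.value for c in EndCategory],
                                    fill_value=0)
    spliced = per_cdna[per_cdna["junction_category"] != ""]
    junction_counts = pd.Series(Counter(spliced["junction_category"]),
                                dtype=int)
    junction_counts = junction_counts.reindex(
        [c.value for c in JunctionCategory], fill_value=0)

    ann_bs = BaseSet.from_exons(ann).unstranded()
    cdna_bs = BaseSet(e for c in cdnas for e in c.exons).unstranded()
    ann_total = ann_bs.total_bases()
    covered = sum(
        _intersect_size(ann_bs.intervals(*k), cdna_bs.intervals(*k))
        for k in set(ann_bs.keys()) & set(cdna_bs.keys())
    )
    return ValidationReport(
        jaccard=per_cdna.set_index("cdna_id")["jaccard"],
        end_counts=end_counts,
        junction_counts=junction_counts,
        bases_covered_fraction=covered / ann_total if ann_total else 0.0,
        per_cdna=per_cdna,
    )


def validation_report(cdnas, ann_old: AnnotationSet,
                      ann_new: AnnotationSet | None = None,
                      slack: int = 0) -> dict[str, ValidationReport]:
    """Validate one or two annotations against a cDNA cohort.

    Returns ``{"old": report}`` or ``{"old": ..., "new": ...}`` for
    side-by-side comparison of a legacy and an updated annotation.
    """
    cdnas = list(cdnas)
    if not cdnas:
        raise ValueError("empty cDNA set")
    out = {"old": _report_one(cdnas, ann_old, slack)}
    if ann_new is not None:
        out["new"] = _report_one(cdnas, ann_new, slack)
    return out
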