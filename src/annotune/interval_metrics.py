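"""Jaccard similarity and junction-sharing statistics over genomic bases.

The central quantity is the base-level Jaccard index |A∩B| / |A∪B|,
computed over sets of genomic bases.  For annotations the base sets are
built from *unique exons* — the deduplicated exon intervals across all
isoforms — so that duplicating a transcript never changes the score.
Stranded comparison is the canonical mode (the RNA-seq libraries this
toolkit targets are stranded); an unstranded mode pools both strands for
cross-checks against tools that ignore strand.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation_core import AnnotationSet, GenomicInterval, TranscriptModel, \
    _merge_sorted

__all__ = [
    "BaseSet",
    "BestMatchRecord",
    "jaccard_bases",
    "exon_jaccard",
    "transcript_jaccard",
    "shared_junctions",
    "best_match_table",
    "best_match_frame",
    "UndefinedRatioError",
]


class UndefinedRatioError(ZeroDivisionError):
    """A ratio whose denominator is empty (e.g. Jaccard of two empty sets)."""


class BaseSet:
    """Disjoint sorted intervals per (contig, strand); a set of genomic bases."""

    def __init__(self, intervals=()):
        raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for iv in intervals:
            raw.setdefault((iv.contig, iv.strand), []).append((iv.start, iv.end))
        self._data = {
            key: _merge_sorted(sorted(pairs)) for key, pairs in raw.items()
        }

    @classmethod
    def from_exons(cls, ann: AnnotationSet) -> "BaseSet":
        """The unique-exon base set of an annotation."""
        return cls(e for g in ann for t in g.transcripts for e in t.exons)

    @classmethod
    def from_transcript(cls, t) -> "BaseSet":
        return cls(t.exons)

    def keys(self):
        return self._data.keys()

    def intervals(self, contig: str, strand: str) -> list[tuple[int, int]]:
        return list(self._data.get((contig, strand), []))

    def total_bases(self) -> int:
        return sum(e - s for ivs in self._data.values() for s, e in ivs)

    def unstranded(self) -> "BaseSet":
        """Collapse both strands onto '.'; used by the unstranded Jaccard mode."""
        out = BaseSet()
        raw: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for (contig, _), ivs in self._data.items():
            raw.setdefault((contig, "."), []).extend(ivs)
        out._data = {k: _merge_sorted(sorted(v)) for k, v in raw.items()}
        return out

    def to_bed6(self, path) -> None:
        with open(path, "w") as fh:
            for (contig, strand), ivs in sorted(self._data.items()):
                for s, e in ivs:
                    fh.write(f"{contig}\t{s}\t{e}\t.\t0\t{strand}\n")


def _intersect_size(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlap between two sorted disjoint interval lists (two-pointer)."""
    i = j = total = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def jaccard_bases(a: BaseSet, b: BaseSet, stranded: bool = True) -> float:
    """Base-level Jaccard index |A∩B| / |A∪B| of two base sets.

    Raises :class:`UndefinedRatioError` when both sets are empty.
    """
    if not stranded:
        a, b = a.unstranded(), b.unstranded()
    na, nb = a.total_bases(), b.total_bases()
    if na == 0 and nb == 0:
        raise UndefinedRatioError("Jaccard of two empty base sets is undefined")
    inter = sum(
        _intersect_size(a.intervals(*key), b.intervals(*key))
        for key in set(a.keys()) & set(b.keys())
    )
    return inter / (na + nb - inter)


def exon_jaccard(ann_a: AnnotationSet, ann_b: AnnotationSet,
                 stranded: bool = True) -> float:
    """Exon-level Jaccard between two annotations of the same genome.

    Computed on the unique-exon base sets: exon intervals are deduplicated
    across isoforms before intersecting, so isoform redundancy does not
    inflate the score.
    """
    return jaccard_bases(BaseSet.from_exons(ann_a), BaseSet.from_exons(ann_b),
                         stranded=stranded)


def transcript_jaccard(t, u, stranded: bool = True) -> float:
    """Base Jaccard of two transcripts' exonic base sets.

    ``t`` may be any object with ``contig`` and ``exons`` (a transcript
    model or a cDNA alignment).  Different contigs score 0 by definition.
    """
    if t.contig != u.contig:
        return 0.0
    return jaccard_bases(BaseSet(t.exons), BaseSet(u.exons), stranded=stranded)


def shared_junctions(t, u) -> int:
    """Number of introns shared by exact coordinates (same contig/strand)."""
    if t.contig != u.contig or t.strand != u.strand:
        return 0
    ti = {(i.start, i.end) for i in t.introns}
    ui = {(i.start, i.end) for i in u.introns}
    return len(ti & ui)


@dataclass(frozen=True)
class BestMatchRecord:
    query_gene_id: str
    subject_gene_id: str
    jaccard: float
    shared_junctions: int


def _gene_base_set(gene) -> BaseSet:
    return BaseSet(gene.unique_exons())


def best_match_table(query: AnnotationSet, subject: AnnotationSet,
                     stranded: bool = True) -> list[BestMatchRecord]:
    """For each query gene, its best-Jaccard subject gene.

    The subject maximizing the gene-level unique-exon base Jaccard is
    reported together with that Jaccard and the maximum shared-junction
    count over transcript pairs.  Ties break by higher shared-junction
    count, then lexicographic subject id.  Query genes overlapping no
    subject gene get jaccard 0 and an empty subject id.
    """
    records = []
    for qgene in query:
        span = qgene.span
        candidates = subject.query(
            qgene.contig, span.start, span.end,
            qgene.strand if stranded else None,
        )
        best = ("", 0.0, 0)
        qbs = _gene_base_set(qgene)
        for sgene in candidates:
            jac = jaccard_bases(qbs, _gene_base_set(sgene), stranded=stranded)
            sj = max(
                (shared_junctions(qt, st)
                 for qt in qgene.transcripts for st in sgene.transcripts),
                default=0,
            )
            key = (jac, sj, sgene.gene_id)
            # maximize jaccard, then shared junctions, then lexicographically
            # smallest id — compare explicitly to keep the id order ascending
            if (jac > best[1]
                    or (jac == best[1] and sj > best[2])
                    or (jac == best[1] and sj == best[2] and best[0]
                        and sgene.gene_id < best[0])):
                best = (sgene.gene_id, jac, sj)
        records.append(BestMatchRecord(qgene.gene_id, best[0], best[1], best[2]))
    return records


def best_match_frame(query: AnnotationSet, subject: AnnotationSet,
                     stranded: bool = True) -> pd.DataFrame:
    """:func:`best_match_table` as a DataFrame (TSV-export friendly)."""
    recs = best_match_table(query, subject, stranded=stranded)
    return pd.DataFrame(
        [(r.query_gene_id, r.subject_gene_id, r.jaccard, r.shared_junctions)
         for r in recs],
        columns=["query_gene_id", "subject_gene_id", "jaccard",
                 "shared_junctions"],
    )
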