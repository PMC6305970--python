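"""Annotation data model and GTF/GFF3 input/output.

All internal coordinates are 0-based half-open; GTF/GFF3 readers and
writers are the only places where the 1-based inclusive convention of
those formats is converted.  An :class:`AnnotationSet` is the central
container: genes hold transcripts, transcripts hold ordered exon
intervals, and an interval index per (contig, strand) supports overlap
queries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "TranscriptModel",
    "GeneModel",
    "AnnotationSet",
    "AnnotationError",
    "ParseError",
    "read_gtf",
    "write_gtf",
    "read_gff3",
    "write_gff3",
    "derive_introns",
    "assign_yo_ids",
    "SPECIES_CODES",
]

#: Two-letter species codes used by the universal gene/transcript ID scheme.
SPECIES_CODES = {
    "Dmel": "ME", "Dyak": "YA", "Dana": "AN", "Dpse": "PS", "Dper": "PE",
    "Dwil": "WI", "Dmoj": "MO", "Dvir": "VI", "Dgri": "GR",
}


class AnnotationError(ValueError):
    """Invalid annotation structure."""


class ParseError(AnnotationError):
    """Malformed annotation file; carries the offending line number."""

    def __init__(self, message: str, path=None, line_number=None):
        loc = f"{path}:{line_number}: " if line_number is not None else ""
        super().__init__(f"{loc}{message}")
        self.path = path
        self.line_number = line_number


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a contig.

    ``strand`` is '+', '-' or '.' (unknown).  ``length`` is ``end - start``.
    """

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise AnnotationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def _merge_sorted(intervals):
    """Merge overlapping-or-touching (start, end) pairs, assumed sorted."""
    merged = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript: an ordered, non-overlapping run of exons on one strand.

    The intron chain — the ordered gaps between consecutive exons — is the
    transcript's structural identity key throughout the toolkit.
    ``attributes`` carries optional per-transcript metadata such as assembler
    abundance estimates (``fpkm``, ``tpm``, ``cov``).
    """

    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    attributes: Mapping[str, object] = field(default_factory=dict, compare=False)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be '+' or '-', "
                f"got {self.strand!r} (unstranded transcripts are rejected)"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id}: no exons")
        exons = tuple(sorted(self.exons, key=lambda e: (e.start, e.end)))
        for e in exons:
            if e.contig != self.contig:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exon on {e.contig}, "
                    f"transcript on {self.contig}"
                )
        merged = _merge_sorted([(e.start, e.end) for e in exons])
        if len(merged) != len(exons):
            warnings.warn(
                f"transcript {self.transcript_id}: overlapping exons merged",
                stacklevel=2,
            )
        object.__setattr__(
            self,
            "exons",
            tuple(
                GenomicInterval(self.contig, s, e, self.strand) for s, e in merged
            ),
        )

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig, self.exons[0].start, self.exons[-1].end, self.strand
        )

    @property
    def exonic_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        return derive_introns(self)

    @property
    def intron_chain(self) -> tuple[tuple[int, int], ...]:
        """Ordered (start, end) pairs of introns; empty for mono-exonic."""
        return tuple((i.start, i.end) for i in self.introns)

    def with_ids(self, transcript_id: str, gene_id: str) -> "TranscriptModel":
        return replace(self, transcript_id=transcript_id, gene_id=gene_id)


@dataclass(frozen=True)
class GeneModel:
    """A gene: one or more transcripts sharing contig and strand."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self):
        if not self.transcripts:
            raise AnnotationError(f"gene {self.gene_id}: no transcripts")
        contigs = {t.contig for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(contigs) > 1 or len(strands) > 1:
            raise AnnotationError(
                f"gene {self.gene_id}: transcripts span multiple "
                f"contigs/strands ({contigs}, {strands})"
            )
        object.__setattr__(
            self,
            "transcripts",
            tuple(sorted(self.transcripts, key=lambda t: (t.span.start, t.span.end,
                                                          t.transcript_id))),
        )

    @property
    def contig(self) -> str:
        return self.transcripts[0].contig

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.contig,
            min(t.span.start for t in self.transcripts),
            max(t.span.end for t in self.transcripts),
            self.strand,
        )

    def unique_exons(self) -> list[GenomicInterval]:
        """Deduplicated exon intervals across all isoforms, sorted."""
        return sorted({e for t in self.transcripts for e in t.exons})

    def unique_introns(self) -> list[GenomicInterval]:
        return sorted({i for t in self.transcripts for i in t.introns})


class AnnotationSet:
    """A collection of gene models with an interval index per (contig, strand)."""

    def __init__(self, genes: Iterable[GeneModel] = ()):
        self._genes: dict[str, GeneModel] = {}
        self._index: dict[tuple[str, str], IntervalTree] = {}
        seen_tx: set[str] = set()
        for g in genes:
            if g.gene_id in self._genes:
                raise AnnotationError(f"duplicate gene_id {g.gene_id}")
            for t in g.transcripts:
                if t.transcript_id in seen_tx:
                    raise AnnotationError(
                        f"duplicate transcript_id {t.transcript_id}"
                    )
                seen_tx.add(t.transcript_id)
            self._genes[g.gene_id] = g
            span = g.span
            self._index.setdefault((g.contig, g.strand), IntervalTree()).addi(
                span.start, span.end, g.gene_id
            )

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(
            sorted(
                self._genes.values(),
                key=lambda g: (g.contig, g.span.start, g.span.end, g.gene_id),
            )
        )

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def genes(self) -> list[GeneModel]:
        return list(self)

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self:
            yield from g.transcripts

    def n_transcripts(self) -> int:
        return sum(len(g.transcripts) for g in self._genes.values())

    def contigs(self) -> list[str]:
        return sorted({g.contig for g in self._genes.values()})

    def query(self, contig: str, start: int, end: int,
              strand: str | None = None) -> list[GeneModel]:
        """Genes whose span overlaps [start, end); all strands if strand None."""
        keys = (
            [(contig, strand)]
            if strand is not None
            else [(contig, "+"), (contig, "-")]
        )
        hits: list[GeneModel] = []
        for key in keys:
            tree = self._index.get(key)
            if tree is not None:
                hits.extend(self._genes[iv.data] for iv in tree.overlap(start, end))
        return sorted(hits, key=lambda g: (g.span.start, g.gene_id))


def derive_introns(transcript: TranscriptModel) -> tuple[GenomicInterval, ...]:
    """Introns as the gaps between consecutive exons (empty if mono-exonic)."""
    exons = transcript.exons
    return tuple(
        GenomicInterval(transcript.contig, a.end, b.start, transcript.strand)
        for a, b in zip(exons, exons[1:])
    )


# ---------------------------------------------------------------------------
# GTF / GFF3 I/O
# ---------------------------------------------------------------------------

def _build_annotation(exon_rows) -> AnnotationSet:
    """Group (tx_id, gene_id, contig, start, end, strand, attrs) rows into genes."""
    tx_exons: dict[str, list] = {}
    tx_meta: dict[str, tuple] = {}
    for tx_id, gene_id, contig, start, end, strand, attrs in exon_rows:
        tx_exons.setdefault(tx_id, []).append(GenomicInterval(contig, start, end,
                                                              strand))
        tx_meta.setdefault(tx_id, (gene_id, contig, strand, attrs))
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx_id, exons in tx_exons.items():
        gene_id, contig, strand, attrs = tx_meta[tx_id]
        t = TranscriptModel(tx_id, gene_id, contig, strand, tuple(exons),
                            attributes=attrs)
        by_gene.setdefault(gene_id, []).append(t)
    return AnnotationSet(
        GeneModel(gid, tuple(txs)) for gid, txs in by_gene.items()
    )


_NUMERIC_TX_ATTRS = ("fpkm", "tpm", "cov")


def _parse_feature_line(line, path, lineno):
    try:
        feat = feature_from_line(line)  # dialect sniffed per line
    except Exception as exc:  # gffutils raises bare exceptions on bad lines
        raise ParseError(f"cannot parse line: {exc}", path, lineno) from exc
    return feat


def _read_features(path, dialect) -> AnnotationSet:
    exon_rows = []
    gff3 = dialect == "gff3"
    # GFF3 needs the Parent hierarchy: map feature ID -> (gene, transcript).
    parent_of: dict[str, str] = {}
    gene_of: dict[str, str] = {}
    pending: list[tuple] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if len(line.split("\t")) != 9:
                raise ParseError("expected 9 tab-separated fields", path, lineno)
            feat = _parse_feature_line(line, path, lineno)
            ftype = feat.featuretype.lower()
            if feat.end < feat.start:
                raise ParseError(
                    f"feature end {feat.end} < start {feat.start}", path, lineno
                )
            if gff3:
                fid = feat.attributes.get("ID", [None])[0]
                parent = feat.attributes.get("Parent", [None])[0]
                if ftype in ("mrna", "transcript", "ncrna", "trna", "rrna",
                             "snorna", "snrna", "pre_mirna", "lnc_rna"):
                    if fid is not None:
                        parent_of[fid] = parent or fid
                elif ftype == "gene":
                    if fid is not None:
                        gene_of[fid] = fid
                elif ftype == "exon":
                    pending.append((feat, parent, lineno))
            else:
                if ftype != "exon":
                    continue
                try:
                    tx_id = feat.attributes["transcript_id"][0]
                    gene_id = feat.attributes["gene_id"][0]
                except KeyError as exc:
                    raise ParseError(
                        f"exon lacks {exc.args[0]} attribute", path, lineno
                    ) from exc
                attrs = {
                    k: float(feat.attributes[k][0])
                    for k in _NUMERIC_TX_ATTRS
                    if k in feat.attributes
                }
                exon_rows.append((tx_id, gene_id, feat.seqid,
                                  feat.start - 1, feat.end, feat.strand, attrs))
    if gff3:
        for feat, parent, lineno in pending:
            if parent is None:
                raise ParseError("exon lacks Parent attribute", path, lineno)
            tx_id = parent
            gene_id = parent_of.get(parent, parent)
            exon_rows.append((tx_id, gene_id, feat.seqid,
                              feat.start - 1, feat.end, feat.strand, {}))
    return _build_annotation(exon_rows)


def read_gtf(path) -> AnnotationSet:
    """Read a GTF2.2 file into an :class:`AnnotationSet`.

    Exon records are grouped by ``transcript_id`` and ``gene_id``; other
    feature types are ignored.  1-based inclusive coordinates become
    0-based half-open.
    """
    return _read_features(path, "gtf")


def read_gff3(path) -> AnnotationSet:
    """Read a GFF3 file (gene -> mRNA -> exon Parent hierarchy)."""
    return _read_features(path, "gff3")


def _format_attrs_gtf(gene_id, tx_id, attributes):
    parts = [f'gene_id "{gene_id}"; transcript_id "{tx_id}";']
    for k in _NUMERIC_TX_ATTRS:
        if k in attributes:
            parts.append(f'{k} "{attributes[k]:g}";')
    return " ".join(parts)


def write_gtf(ann: AnnotationSet, path) -> None:
    """Write exon and transcript records as GTF2.2 (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##format: gtf\n")
        for gene in ann:
            for t in gene.transcripts:
                attrs = _format_attrs_gtf(gene.gene_id, t.transcript_id,
                                          t.attributes)
                span = t.span
                fh.write(
                    f"{t.contig}\tannotune\ttranscript\t{span.start + 1}\t"
                    f"{span.end}\t.\t{t.strand}\t.\t{attrs}\n"
                )
                for e in t.exons:
                    fh.write(
                        f"{t.contig}\tannotune\texon\t{e.start + 1}\t{e.end}\t"
                        f".\t{t.strand}\t.\t{attrs}\n"
                    )


def write_gff3(ann: AnnotationSet, path) -> None:
    """Write a gene/mRNA/exon GFF3 hierarchy (1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in ann:
            gspan = gene.span
            fh.write(
                f"{gene.contig}\tannotune\tgene\t{gspan.start + 1}\t{gspan.end}"
                f"\t.\t{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for t in gene.transcripts:
                span = t.span
                fh.write(
                    f"{t.contig}\tannotune\tmRNA\t{span.start + 1}\t{span.end}"
                    f"\t.\t{t.strand}\t.\tID={t.transcript_id};"
                    f"Parent={gene.gene_id}\n"
                )
                for i, e in enumerate(t.exons, start=1):
                    fh.write(
                        f"{t.contig}\tannotune\texon\t{e.start + 1}\t{e.end}\t"
                        f".\t{t.strand}\t.\tID={t.transcript_id}.exon{i};"
                        f"Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Universal ID assignment
# ---------------------------------------------------------------------------

def assign_yo_ids(ann: AnnotationSet, species_code: str,
                  start_index: int = 1) -> AnnotationSet:
    """Renumber genes and transcripts with universal YO-style identifiers.

    Gene ids are ``YOgn`` + two-letter species code + zero-padded 5-digit
    number (e.g. ``YOgnYA12345``); transcript ids use ``YOtr``.  Numbering
    follows (contig, start) sort order, so it is deterministic for a given
    annotation.  Full species names (e.g. ``"Dyak"``) are accepted and
    mapped through :data:`SPECIES_CODES`.
    """
    code = SPECIES_CODES.get(species_code, species_code)
    if len(code) != 2 or not code.isalpha():
        raise AnnotationError(f"species code must be 2 letters, got {code!r}")
    code = code.upper()
    genes_sorted = list(ann)  # already (contig, start) ordered
    new_genes = []
    gi = start_index
    ti = start_index
    for gene in genes_sorted:
        if gi > 99999:
            raise AnnotationError("gene index overflow beyond 5 digits")
        gene_id = f"YOgn{code}{gi:05d}"
        new_txs = []
        for t in gene.transcripts:
            if ti > 99999:
                raise AnnotationError("transcript index overflow beyond 5 digits")
            new_txs.append(t.with_ids(f"YOtr{code}{ti:05d}", gene_id))
            ti += 1
        new_genes.append(GeneModel(gene_id, tuple(new_txs)))
        gi += 1
    return AnnotationSet(new_genes)
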