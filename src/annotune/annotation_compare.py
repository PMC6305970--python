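"""Multi-level sensitivity/precision between a predicted and a reference
annotation.

Six levels are scored: base, exon, intron, intron chain, transcript and
gene.  At each level sensitivity = TP/(TP+FN) and precision = TP/(TP+FP),
reported as percentages.  Transcript matching is intron-chain identity for
multi-exon transcripts; mono-exonic transcripts match a mono-exonic
reference transcript when their exonic Jaccard reaches a configurable
threshold (default 0.6).  Matching is greedy by descending Jaccard so each
predicted transcript pairs with at most one reference transcript, and
genes pair 1:1 through their matched transcripts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .annotation_core import AnnotationSet
from .interval_metrics import BaseSet, _intersect_size, transcript_jaccard

__all__ = ["LevelCounts", "ComparisonReport", "compare", "LEVELS"]

LEVELS = ("base", "exon", "intron", "intron_chain", "transcript", "gene")


@dataclass(frozen=True)
class LevelCounts:
    level: str
    tp: int
    fn: int
    fp: int

    @property
    def sensitivity(self) -> float:
        """TP/(TP+FN) in percent; NaN when the denominator is zero."""
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else math.nan

    @property
    def precision(self) -> float:
        """TP/(TP+FP) in percent; NaN when the denominator is zero."""
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else math.nan


@dataclass
class ComparisonReport:
    levels: dict[str, LevelCounts] = field(default_factory=dict)
    transcript_matches: list[tuple[str, str]] = field(default_factory=list)

    def __getitem__(self, level: str) -> LevelCounts:
        return self.levels[level]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (lc.level, lc.tp, lc.fn, lc.fp, lc.sensitivity, lc.precision)
            for lc in (self.levels[lv] for lv in LEVELS if lv in self.levels)
        ]
        return pd.DataFrame(
            rows,
            columns=["level", "tp", "fn", "fp", "sensitivity", "precision"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.4f")


def _exon_key_set(ann: AnnotationSet) -> set[tuple]:
    return {
        (t.contig, t.strand, e.start, e.end)
        for t in ann.transcripts()
        for e in t.exons
    }


def _intron_key_set(ann: AnnotationSet) -> set[tuple]:
    return {
        (t.contig, t.strand, i.start, i.end)
        for t in ann.transcripts()
        for i in t.introns
    }


def _chain_key_set(ann: AnnotationSet) -> set[tuple]:
    return {
        (t.contig, t.strand, t.intron_chain)
        for t in ann.transcripts()
        if t.intron_chain
    }


def _set_level(level: str, pred_keys: set, ref_keys: set) -> LevelCounts:
    tp = len(pred_keys & ref_keys)
    return LevelCounts(level, tp, len(ref_keys) - tp, len(pred_keys) - tp)


def _match_transcripts(pred: AnnotationSet, ref: AnnotationSet,
                       mono_jaccard: float) -> list[tuple[str, str]]:
    """Greedy 1:1 transcript pairing: (pred_tx_id, ref_tx_id) matches."""
    # Candidate pairs with a score; exact chain matches score above any
    # Jaccard so they are always preferred.
    ref_by_chain: dict[tuple, list] = {}
    for t in ref.transcripts():
        if t.intron_chain:
            ref_by_chain.setdefault(
                (t.contig, t.strand, t.intron_chain), []
            ).append(t)
    candidates: list[tuple[float, str, str]] = []
    for pt in pred.transcripts():
        if pt.intron_chain:
            for rt in ref_by_chain.get((pt.contig, pt.strand, pt.intron_chain),
                                       ()):
                candidates.append((2.0, pt.transcript_id, rt.transcript_id))
        else:
            span = pt.span
            for rgene in ref.query(pt.contig, span.start, span.end, pt.strand):
                for rt in rgene.transcripts:
                    if rt.intron_chain:
                        continue
                    jac = transcript_jaccard(pt, rt)
                    if jac >= mono_jaccard:
                        candidates.append((jac, pt.transcript_id,
                                           rt.transcript_id))
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    used_pred: set[str] = set()
    used_ref: set[str] = set()
    matches = []
    for _, pid, rid in candidates:
        if pid in used_pred or rid in used_ref:
            continue
        used_pred.add(pid)
        used_ref.add(rid)
        matches.append((pid, rid))
    return matches


def _match_genes(pred: AnnotationSet, ref: AnnotationSet,
                 tx_matches: list[tuple[str, str]]) -> int:
    """Greedy 1:1 gene pairing through matched transcripts; returns TP genes."""
    gene_of_pred_tx = {t.transcript_id: g.gene_id
                       for g in pred for t in g.transcripts}
    gene_of_ref_tx = {t.transcript_id: g.gene_id
                      for g in ref for t in g.transcripts}
    pair_votes: dict[tuple[str, str], int] = {}
    for pid, rid in tx_matches:
        key = (gene_of_pred_tx[pid], gene_of_ref_tx[rid])
        pair_votes[key] = pair_votes.get(key, 0) + 1
    ranked = sorted(pair_votes.items(), key=lambda kv: (-kv[1], kv[0]))
    used_pred: set[str] = set()
    used_ref: set[str] = set()
    tp = 0
    for (pg, rg), _ in ranked:
        if pg in used_pred or rg in used_ref:
            continue
        used_pred.add(pg)
        used_ref.add(rg)
        tp += 1
    return tp


def compare(pred: AnnotationSet, ref: AnnotationSet,
            mono_jaccard: float = 0.6) -> ComparisonReport:
    """Score a predicted annotation against a reference at six levels.

    Base level counts stranded exonic bases; exon, intron and intron-chain
    levels count exact-coordinate unique features; transcript and gene
    levels count greedy 1:1 structural matches (see module docstring).
    Empty inputs yield an all-NA report with a warning.
    """
    report = ComparisonReport()
    if len(pred) == 0 or len(ref) == 0:
        warnings.warn("empty annotation in compare(); report is all-NA",
                      stacklevel=2)
        for lv in LEVELS:
            report.levels[lv] = LevelCounts(lv, 0, 0, 0)
        return report

    pred_bs = BaseSet.from_exons(pred)
    ref_bs = BaseSet.from_exons(ref)
    inter = sum(
        _intersect_size(pred_bs.intervals(*k), ref_bs.intervals(*k))
        for k in set(pred_bs.keys()) & set(ref_bs.keys())
    )
    report.levels["base"] = LevelCounts(
        "base", inter, ref_bs.total_bases() - inter,
        pred_bs.total_bases() - inter,
    )
    report.levels["exon"] = _set_level(
        "exon", _exon_key_set(pred), _exon_key_set(ref))
    report.levels["intron"] = _set_level(
        "intron", _intron_key_set(pred), _intron_key_set(ref))
    report.levels["intron_chain"] = _set_level(
        "intron_chain", _chain_key_set(pred), _chain_key_set(ref))

    tx_matches = _match_transcripts(pred, ref, mono_jaccard)
    n_pred_tx = pred.n_transcripts()
    n_ref_tx = ref.n_transcripts()
    tp_tx = len(tx_matches)
    report.levels["transcript"] = LevelCounts(
        "transcript", tp_tx, n_ref_tx - tp_tx, n_pred_tx - tp_tx)
    report.transcript_matches = tx_matches

    tp_gene = _match_genes(pred, ref, tx_matches)
    report.levels["gene"] = LevelCounts(
        "gene", tp_gene, len(ref) - tp_gene, len(pred) - tp_gene)
    return report
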