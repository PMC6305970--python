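"""Two-stage SVM discovery of novel 1:1 orthologs relative to a reference
species.

Stage 1 scores candidate cross-species gene pairs on three conservation
features — flanking-gene synteny within a ±10-gene window, Spearman
correlation of median expression across 14 sexed tissues, and the ratio of
(unique intron number + 1) — with an RBF SVM (C=1000, gamma=0.001) trained
on known 1:1 orthologs against seeded random-pair nulls.  Stage 2 filters
stage-1 survivors on two sequence-similarity features from a global
alignment of the genes' longest transcripts — alignable/total and
identical/alignable column fractions — with a second RBF SVM (C=1000,
gamma=0.01).  Reference genes retaining several partners after stage 2 are
flagged one-to-many and excluded, so the final table is a partial
bijection.

:class:`OrthologPipeline` is the model object; :meth:`fit` trains both
stages and returns an :class:`OrthologResults` with per-stage AUCs, a
``summary()``, and :meth:`OrthologResults.classify` for candidate tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .annotation_core import AnnotationSet, GeneModel
from .expression_coverage import (EXPRESSION_TISSUES, ExpressionMatrix,
                                  median_tissue_expression)

__all__ = [
    "HomologyTable",
    "GeneOrder",
    "synteny_score",
    "expr_correlation",
    "intron_ratio",
    "sequence_similarity",
    "make_aligner",
    "OrthologPipeline",
    "OrthologResults",
    "STAGE1_FEATURES",
    "STAGE2_FEATURES",
]

STAGE1_FEATURES = ("synteny_score", "expr_spearman", "intron_ratio")
STAGE2_FEATURES = ("alignable_frac", "identity_frac")


class HomologyTable:
    """Cross-species homology pairs with reciprocal-best-hit flags.

    Backed by a DataFrame with columns ``gene_a``, ``gene_b``, ``score``,
    ``rbh`` (bool).  At most one RBH partner per gene.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"gene_a", "gene_b", "score", "rbh"}
        if not required.issubset(frame.columns):
            raise ValueError(f"homology table needs columns {sorted(required)}")
        self.frame = frame.reset_index(drop=True)
        rbh = frame[frame["rbh"].astype(bool)]
        for col in ("gene_a", "gene_b"):
            if rbh[col].duplicated().any():
                raise ValueError("multiple RBH partners for one gene")
        self._rbh_ab = dict(zip(rbh["gene_a"], rbh["gene_b"]))
        self._rbh_ba = dict(zip(rbh["gene_b"], rbh["gene_a"]))

    def rbh_partner(self, gene: str) -> str | None:
        """RBH partner of a gene from either species, or None."""
        return self._rbh_ab.get(gene, self._rbh_ba.get(gene))

    def rbh_pairs(self) -> list[tuple[str, str]]:
        return sorted(self._rbh_ab.items())

    @classmethod
    def from_tsv(cls, path) -> "HomologyTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


class GeneOrder:
    """Per-contig gene order by start coordinate, with rank lookup."""

    def __init__(self, ann: AnnotationSet):
        self.order: dict[str, list[str]] = {}
        self.rank: dict[str, tuple[str, int]] = {}
        for g in ann:  # AnnotationSet iterates (contig, start)-sorted
            self.order.setdefault(g.contig, []).append(g.gene_id)
        for contig, ids in self.order.items():
            for i, gid in enumerate(ids):
                self.rank[gid] = (contig, i)

    def flanking(self, gene_id: str, window: int = 10) -> list[str]:
        """Up to ``window`` gene ids on each side (fewer near contig edges)."""
        contig, i = self.rank[gene_id]
        ids = self.order[contig]
        return ids[max(0, i - window):i] + ids[i + 1:i + 1 + window]


def synteny_score(ref_gene: str, query_gene: str, homology: HomologyTable,
                  ref_order: GeneOrder, query_order: GeneOrder,
                  window: int = 10) -> float:
    """Fraction of the query gene's flanking genes mapping near the ref gene.

    The up-to-``2*window`` genes flanking ``query_gene`` are looked up via
    their RBH partners; the score is the fraction whose partner lies within
    ±``window`` ranks of ``ref_gene`` on its contig.  Flanking genes with
    no RBH partner stay in the denominator; near contig edges the
    denominator shrinks to the genes that exist.
    """
    if ref_gene not in ref_order.rank:
        raise KeyError(f"{ref_gene} not placed in reference gene order")
    if query_gene not in query_order.rank:
        raise KeyError(f"{query_gene} not placed in query gene order")
    ref_contig, ref_rank = ref_order.rank[ref_gene]
    flanks = query_order.flanking(query_gene, window)
    if not flanks:
        return 0.0
    hits = 0
    for f in flanks:
        partner = homology.rbh_partner(f)
        if partner is None or partner not in ref_order.rank:
            continue
        contig, rank = ref_order.rank[partner]
        if contig == ref_contig and abs(rank - ref_rank) <= window:
            hits += 1
    return hits / len(flanks)


def expr_correlation(ref_gene: str, query_gene: str,
                     ref_expr: ExpressionMatrix, query_expr: ExpressionMatrix,
                     tissues=EXPRESSION_TISSUES) -> float:
    """Spearman correlation of the two genes' per-tissue median expression.

    Returns NaN (with scipy's constant-input warning) when either profile
    is constant across tissues.
    """
    a = median_tissue_expression(ref_expr, ref_gene, tissues)
    b = median_tissue_expression(query_expr, query_gene, tissues)
    rho = spearmanr(a, b).statistic
    return float(rho)


def intron_ratio(ref_gene: GeneModel, query_gene: GeneModel) -> float:
    """(unique introns of query + 1) / (unique introns of ref + 1)."""
    return (len(query_gene.unique_introns()) + 1) / \
        (len(ref_gene.unique_introns()) + 1)


def make_aligner() -> Align.PairwiseAligner:
    """Global aligner: match +1, mismatch −1, gap open −2, gap extend −0.5."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def sequence_similarity(seq_a: str, seq_b: str,
                        aligner: Align.PairwiseAligner | None = None
                        ) -> tuple[float, float]:
    """Global-alignment similarity of two sequences.

    Returns ``(alignable_frac, identity_frac)``: alignable columns (a
    residue in both rows) over total alignment columns (gaps included),
    and identical columns over alignable columns.  Input is typically each
    gene's longest transcript sequence.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    if aligner is None:
        aligner = make_aligner()
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a_row, b_row = aln[0], aln[1]
    total = len(a_row)
    alignable = sum(1 for x, y in zip(a_row, b_row) if x != "-" and y != "-")
    identical = sum(1 for x, y in zip(a_row, b_row)
                    if x != "-" and x == y)
    if alignable == 0:
        return 0.0, 0.0
    return alignable / total, identical / alignable


def longest_transcript_seq(gene: GeneModel, genome) -> str:
    """Spliced sequence of the gene's longest (exonic length) transcript."""
    from .model_curation import _fetch, _revcomp

    t = max(gene.transcripts, key=lambda t: (t.exonic_length, t.transcript_id))
    seq = "".join(_fetch(genome, t.contig, e.start, e.end) for e in t.exons)
    return _revcomp(seq) if t.strand == "-" else seq


# ---------------------------------------------------------------------------
# The two-stage pipeline
# ---------------------------------------------------------------------------

def _svm_pipeline(C: float, gamma: float) -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svc", SVC(kernel="rbf", C=C, gamma=gamma)),
    ])


@dataclass
class OrthologPipeline:
    """Two-stage ortholog classifier (model object; call :meth:`fit`).

    Parameters
    ----------
    stage1_table : DataFrame
        Training pairs with columns ``ref_gene``, ``query_gene``, the
        :data:`STAGE1_FEATURES` and a boolean ``label`` (known ortholog vs
        random-pair null).
    stage2_table : DataFrame
        Training pairs with the :data:`STAGE2_FEATURES` and ``label``.
    """

    stage1_table: pd.DataFrame
    stage2_table: pd.DataFrame
    stage1_C: float = 1000.0
    stage1_gamma: float = 0.001
    stage2_C: float = 1000.0
    stage2_gamma: float = 0.01

    def fit(self) -> "OrthologResults":
        models = []
        aucs = []
        for table, feats, C, gamma in (
            (self.stage1_table, STAGE1_FEATURES, self.stage1_C,
             self.stage1_gamma),
            (self.stage2_table, STAGE2_FEATURES, self.stage2_C,
             self.stage2_gamma),
        ):
            y = table["label"].astype(int).values
            if len(np.unique(y)) < 2:
                raise ValueError("training table must contain both classes")
            X = table[list(feats)].values
            pipe = _svm_pipeline(C, gamma)
            pipe.fit(X, y)
            aucs.append(float(roc_auc_score(y, pipe.decision_function(X))))
            models.append(pipe)
        return OrthologResults(self, models[0], models[1], aucs[0], aucs[1])

    @staticmethod
    def build_training_tables(positive_pairs, feature_fn, rng,
                              universe_ref, universe_query,
                              n_null: int | None = None):
        """Assemble stage-1/2 training tables from known orthologs.

        ``feature_fn(ref_gene, query_gene)`` returns a dict with all five
        features.  The null class is ``n_null`` random (ref, query) pairs
        (default: as many as positives) drawn with ``rng`` and excluding
        the known pairs.
        """
        positive_pairs = list(positive_pairs)
        n_null = n_null if n_null is not None else len(positive_pairs)
        known = set(positive_pairs)
        universe_ref = list(universe_ref)
        universe_query = list(universe_query)
        nulls = []
        while len(nulls) < n_null:
            pair = (universe_ref[rng.integers(len(universe_ref))],
                    universe_query[rng.integers(len(universe_query))])
            if pair not in known:
                nulls.append(pair)
        rows = []
        for label, pairs in ((True, positive_pairs), (False, nulls)):
            for ref_g, query_g in pairs:
                row = {"ref_gene": ref_g, "query_gene": query_g,
                       "label": label}
                row.update(feature_fn(ref_g, query_g))
                rows.append(row)
        table = pd.DataFrame(rows)
        return (table[["ref_gene", "query_gene", *STAGE1_FEATURES, "label"]],
                table[["ref_gene", "query_gene", *STAGE2_FEATURES, "label"]])


class OrthologResults:
    """Fitted two-stage ortholog classifier."""

    def __init__(self, model: OrthologPipeline, stage1, stage2,
                 stage1_auc: float, stage2_auc: float):
        self.model = model
        self.stage1_ = stage1
        self.stage2_ = stage2
        self.stage1_auc = stage1_auc
        self.stage2_auc = stage2_auc

    def classify(self, candidates: pd.DataFrame) -> pd.DataFrame:
        """Classify candidate pairs; returns the table with scores + status.

        ``candidates`` needs ``ref_gene``, ``query_gene`` and all five
        feature columns.  Stage-2 scores are computed only for stage-1
        survivors (NaN otherwise).  Reference genes with several stage-2
        survivors are flagged ``one_to_many`` (and their partners too);
        likewise a query gene claimed by several reference genes.  The
        surviving unique pairs are ``one_to_one``.
        """
        out = candidates.copy()
        X1 = out[list(STAGE1_FEATURES)].values
        out["stage1_score"] = self.stage1_.decision_function(X1)
        survivors = out["stage1_score"] > 0
        out["stage2_score"] = math.nan
        out["status"] = "rejected"
        if survivors.any():
            X2 = out.loc[survivors, list(STAGE2_FEATURES)].values
            out.loc[survivors, "stage2_score"] = \
                self.stage2_.decision_function(X2)
        passed = out["stage2_score"] > 0
        out.loc[passed, "status"] = "candidate"
        ref_counts = out.loc[passed, "ref_gene"].value_counts()
        query_counts = out.loc[passed, "query_gene"].value_counts()
        multi = passed & (
            out["ref_gene"].map(ref_counts).gt(1).fillna(False)
            | out["query_gene"].map(query_counts).gt(1).fillna(False)
        )
        out.loc[passed & ~multi, "status"] = "one_to_one"
        out.loc[multi, "status"] = "one_to_many"
        return out

    def one_to_one_table(self, candidates: pd.DataFrame) -> pd.DataFrame:
        """The final 1:1 ortholog table (a partial bijection)."""
        scored = self.classify(candidates)
        return scored[scored["status"] == "one_to_one"].reset_index(drop=True)

    def summary(self) -> str:
        m = self.model
        return "\n".join([
            "Two-stage ortholog classifier (SVM)",
            "=" * 46,
            f"Stage 1 features:  {', '.join(STAGE1_FEATURES)}",
            f"  rbf C={m.stage1_C:g}, gamma={m.stage1_gamma:g}; "
            f"training AUC {self.stage1_auc:.4f} "
            f"(n={len(m.stage1_table)})",
            f"Stage 2 features:  {', '.join(STAGE2_FEATURES)}",
            f"  rbf C={m.stage2_C:g}, gamma={m.stage2_gamma:g}; "
            f"training AUC {self.stage2_auc:.4f} "
            f"(n={len(m.stage2_table)})",
        ])


def candidate_universe(ref_order: GeneOrder, query_order: GeneOrder,
                       homology: HomologyTable, known_pairs,
                       window: int = 10) -> list[tuple[str, str]]:
    """Blocked candidate pairs: RBH-linked, or synteny-anchored.

    The all-vs-all space is blocked down to pairs with an RBH link or with
    at least one flanking RBH anchor placing the query near the ref gene;
    known 1:1 pairs are excluded (they are the training set, not
    candidates).
    """
    known = set(known_pairs)
    cands: set[tuple[str, str]] = set()
    for query_contig, q_ids in query_order.order.items():
        for qi, q in enumerate(q_ids):
            direct = homology.rbh_partner(q)
            anchors: list[tuple[str, int]] = []
            if direct is not None and direct in ref_order.rank:
                anchors.append(ref_order.rank[direct])
            for f in query_order.flanking(q, window):
                p = homology.rbh_partner(f)
                if p is not None and p in ref_order.rank:
                    anchors.append(ref_order.rank[p])
            for contig, rank in anchors:
                ids = ref_order.order[contig]
                for r in ids[max(0, rank - window):rank + window + 1]:
                    if (r, q) not in known:
                        cands.add((r, q))
    return sorted(cands)
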