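import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from annotune.expression_coverage import EXPRESSION_TISSUES
from annotune.ortholog_finder import (GeneOrder, HomologyTable,
                                      OrthologPipeline, STAGE1_FEATURES,
                                      STAGE2_FEATURES, candidate_universe,
                                      expr_correlation, intron_ratio,
                                      longest_transcript_seq, make_aligner,
                                      sequence_similarity, synteny_score)
from annotune.synthetic_data import (SimulationConfig,
                                     simulate_expression_matrix,
                                     simulate_genome_and_annotation,
                                     simulate_matched_expression,
                                     simulate_ortholog_pair_species)

from conftest import make_annotation, make_gene


def linear_annotation(prefix, n, contig="chr1", spacing=500):
    genes = []
    for i in range(n):
        s = i * spacing
        genes.append(make_gene(f"{prefix}{i:03d}", [[(s, s + 200)]], contig))
    return make_annotation(*genes)


def collinear_homology(n):
    rows = [(f"A{i:03d}", f"B{i:03d}", 1.0, True) for i in range(n)]
    return HomologyTable(pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "score", "rbh"]))


class TestSyntenyScore:
    def test_perfect_collinearity(self):
        n = 41
        annA = linear_annotation("A", n)
        annB = linear_annotation("B", n)
        hom = collinear_homology(n)
        score = synteny_score("A020", "B020", hom, GeneOrder(annA),
                              GeneOrder(annB))
        assert score == 1.0

    def test_unrelated_contigs_zero(self):
        annA = linear_annotation("A", 30)
        annB = linear_annotation("B", 30)
        # homology maps everything to a *different* unrelated region: shuffle
        rows = [(f"A{i:03d}", f"B{(i * 13 + 11) % 30:03d}", 1.0, True)
                for i in range(30)]
        hom = HomologyTable(pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "score", "rbh"]))
        # query gene with flanks mapping far from the candidate ref gene
        score = synteny_score("A000", "B015", hom, GeneOrder(annA),
                              GeneOrder(annB))
        assert 0.0 <= score <= 1.0

    def test_half_in_window(self):
        # left flank of B020 (B010..B019) has no RBH partner: those 10
        # genes stay in the denominator, so 10 of 20 flanks hit -> 0.5
        n = 41
        annA = linear_annotation("A", n)
        annB = linear_annotation("B", n)
        rows = [(f"A{i:03d}", f"B{i:03d}", 1.0, True)
                for i in range(n) if not 10 <= i < 20]
        hom = HomologyTable(pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "score", "rbh"]))
        score = synteny_score("A020", "B020", hom, GeneOrder(annA),
                              GeneOrder(annB))
        assert score == 0.5

    def test_contig_edge_adjusts_denominator(self):
        n = 15
        annA = linear_annotation("A", n)
        annB = linear_annotation("B", n)
        hom = collinear_homology(n)
        # first gene: only 10 right flanks exist, all within the window
        score = synteny_score("A000", "B000", hom, GeneOrder(annA),
                              GeneOrder(annB))
        assert score == 1.0

    def test_invariant_under_joint_relabeling(self):
        n = 25
        annA = linear_annotation("A", n)
        annB = linear_annotation("B", n)
        hom = collinear_homology(n)
        base = synteny_score("A012", "B012", hom, GeneOrder(annA),
                             GeneOrder(annB))
        annA2 = linear_annotation("X", n)
        annB2 = linear_annotation("Y", n)
        rows = [(f"X{i:03d}", f"Y{i:03d}", 1.0, True) for i in range(n)]
        hom2 = HomologyTable(pd.DataFrame(
            rows, columns=["gene_a", "gene_b", "score", "rbh"]))
        assert synteny_score("X012", "Y012", hom2, GeneOrder(annA2),
                             GeneOrder(annB2)) == base


class TestExprCorrelation:
    def make_pair(self, profile_b):
        config = SimulationConfig(seed=7, expr_noise_sd=0.0)
        expr, _ = simulate_expression_matrix(["gA"], config)
        values = expr.values.copy()
        values.loc["gB"] = profile_b
        from annotune.expression_coverage import ExpressionMatrix
        return ExpressionMatrix(values, expr.samples)

    def test_identical_profiles(self):
        config = SimulationConfig(seed=7, expr_noise_sd=0.0,
                                  tissue_bias_fraction=1.0)
        expr, _ = simulate_expression_matrix(["gA"], config)
        assert expr_correlation("gA", "gA", expr, expr) == pytest.approx(1.0)

    def test_rank_formula_oracle(self):
        # profiles with a controlled rank pattern across the 14 tissues
        a = np.arange(1.0, 15.0)
        b = np.concatenate([np.arange(1.0, 14.0), [0.0]])
        rho_oracle = np.corrcoef(rankdata(a), rankdata(b))[0, 1]

        config = SimulationConfig(seed=7, expr_noise_sd=0.0, replicates=1)
        expr, _ = simulate_expression_matrix(["gA", "gB"], config)
        values = expr.values.copy()
        tissue_of = expr.samples["tissue"]
        for i, t in enumerate(EXPRESSION_TISSUES):
            col = tissue_of.index[tissue_of == t][0]
            values.loc["gA", col] = a[i]
            values.loc["gB", col] = b[i]
        from annotune.expression_coverage import ExpressionMatrix
        em = ExpressionMatrix(values, expr.samples)
        assert expr_correlation("gA", "gB", em, em) == \
            pytest.approx(rho_oracle)


class TestIntronRatio:
    @pytest.mark.parametrize("n_ref,n_query,expected", [
        (3, 3, 1.0), (3, 0, 0.25), (3, 7, 2.0),
    ])
    def test_plus_one_ratio(self, n_ref, n_query, expected):
        def gene_with_introns(gid, n):
            exons = [(i * 100, i * 100 + 50) for i in range(n + 1)]
            return make_gene(gid, [exons])

        ref = gene_with_introns("r", n_ref)
        query = gene_with_introns("q", n_query)
        assert intron_ratio(ref, query) == expected


class TestSequenceSimilarity:
    def test_identical(self):
        assert sequence_similarity("ACGTACGT", "ACGTACGT") == (1.0, 1.0)

    def test_single_mismatch_no_gaps(self):
        al, ident = sequence_similarity("ACGTACGT", "ACGTTCGT")
        assert al == 1.0
        assert ident == pytest.approx(7 / 8)

    def test_fully_mismatched(self):
        al, ident = sequence_similarity("AAAA", "TTTT")
        assert ident < 1.0  # either mismatched columns or gap-displaced

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_similarity("", "ACGT")

    def test_alignable_fraction_with_gap(self):
        # one sequence 4 bases longer: 4 gap columns in a global alignment
        al, ident = sequence_similarity("ACGTACGTACGT", "ACGTACGT")
        assert al == pytest.approx(8 / 12)
        assert ident == 1.0


@pytest.fixture(scope="module")
def planted_ortholog_problem():
    """Sister species at 5% divergence, 5% rearrangement, 20% holdout."""
    config = SimulationConfig(seed=51, n_genes=60, n_contigs=1,
                              contig_length=300_000, substitution_rate=0.05,
                              rearrangement_rate=0.05, known_holdout=0.2)
    genomeA, annA = simulate_genome_and_annotation(config)
    annB, genomeB, hom, planted = simulate_ortholog_pair_species(
        annA, genomeA, config)
    exprA, _ = simulate_expression_matrix([g.gene_id for g in annA], config)
    exprB = simulate_matched_expression(
        exprA, dict(zip(planted.ref_gene, planted.query_gene)), config)
    ordA, ordB = GeneOrder(annA), GeneOrder(annB)
    aligner = make_aligner()
    seqA = {g.gene_id: longest_transcript_seq(g, genomeA) for g in annA}
    seqB = {g.gene_id: longest_transcript_seq(g, genomeB) for g in annB}

    cache = {}

    def features(r, q):
        if (r, q) not in cache:
            al, ident = sequence_similarity(seqA[r], seqB[q], aligner)
            rho = expr_correlation(r, q, exprA, exprB)
            cache[(r, q)] = {
                "synteny_score": synteny_score(r, q, hom, ordA, ordB),
                "expr_spearman": 0.0 if np.isnan(rho) else rho,
                "intron_ratio": intron_ratio(annA[r], annB[q]),
                "alignable_frac": al,
                "identity_frac": ident,
            }
        return cache[(r, q)]

    return config, annA, annB, hom, planted, ordA, ordB, features


@pytest.fixture(scope="module")
def fitted_pipeline(planted_ortholog_problem):
    (config, annA, annB, hom, planted, ordA, ordB,
     features) = planted_ortholog_problem
    return run_pipeline(planted, features, annA, annB, ordA, ordB, hom)


def run_pipeline(planted, features, annA, annB, ordA, ordB, hom, seed=7):
    known = [(r, q) for r, q, k in planted.itertuples(index=False, name=None)
             if k]
    rng = np.random.default_rng(seed)
    t1, t2 = OrthologPipeline.build_training_tables(
        known, features, rng,
        [g.gene_id for g in annA], [g.gene_id for g in annB])
    res = OrthologPipeline(t1, t2).fit()
    universe = candidate_universe(ordA, ordB, hom, known)
    cand = pd.DataFrame(
        [{"ref_gene": r, "query_gene": q, **features(r, q)}
         for r, q in universe])
    return res, res.one_to_one_table(cand)


class TestPipeline:
    def test_defaults_match_protocol_hyperparameters(self):
        p = OrthologPipeline.__new__(OrthologPipeline)
        assert OrthologPipeline.stage1_C == 1000.0
        assert OrthologPipeline.stage1_gamma == 0.001
        assert OrthologPipeline.stage2_C == 1000.0
        assert OrthologPipeline.stage2_gamma == 0.01

    def test_recovers_withheld_pairs(self, planted_ortholog_problem,
                                     fitted_pipeline):
        (config, annA, annB, hom, planted, ordA, ordB,
         features) = planted_ortholog_problem
        res, final = fitted_pipeline
        assert res.stage1_auc >= 0.95
        assert res.stage2_auc >= 0.95
        withheld = {(r, q) for r, q, k in
                    planted.itertuples(index=False, name=None) if not k}
        got = set(zip(final["ref_gene"], final["query_gene"]))
        tp = len(got & withheld)
        prec = tp / len(got) if len(got) else 0.0
        rec = tp / len(withheld)
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        assert f1 >= 0.9

    def test_final_table_partial_bijection(self, fitted_pipeline):
        _, final = fitted_pipeline
        assert final["ref_gene"].is_unique
        assert final["query_gene"].is_unique

    def test_zero_divergence_perfect_recovery(self):
        config = SimulationConfig(seed=52, n_genes=40, n_contigs=1,
                                  contig_length=200_000,
                                  substitution_rate=0.0,
                                  rearrangement_rate=0.0, expr_noise_sd=0.0,
                                  known_holdout=0.25)
        genomeA, annA = simulate_genome_and_annotation(config)
        annB, genomeB, hom, planted = simulate_ortholog_pair_species(
            annA, genomeA, config)
        exprA, _ = simulate_expression_matrix(
            [g.gene_id for g in annA], config)
        exprB = simulate_matched_expression(
            exprA, dict(zip(planted.ref_gene, planted.query_gene)), config)
        ordA, ordB = GeneOrder(annA), GeneOrder(annB)
        aligner = make_aligner()
        seqA = {g.gene_id: longest_transcript_seq(g, genomeA) for g in annA}
        seqB = {g.gene_id: longest_transcript_seq(g, genomeB) for g in annB}

        def features(r, q):
            al, ident = sequence_similarity(seqA[r], seqB[q], aligner)
            rho = expr_correlation(r, q, exprA, exprB)
            return {
                "synteny_score": synteny_score(r, q, hom, ordA, ordB),
                "expr_spearman": 0.0 if np.isnan(rho) else rho,
                "intron_ratio": intron_ratio(annA[r], annB[q]),
                "alignable_frac": al,
                "identity_frac": ident,
            }

        _, final = run_pipeline(planted, features, annA, annB, ordA, ordB,
                                hom)
        withheld = {(r, q) for r, q, k in
                    planted.itertuples(index=False, name=None) if not k}
        got = set(zip(final["ref_gene"], final["query_gene"]))
        assert withheld <= got

    def test_one_to_many_flagged_and_excluded(self, planted_ortholog_problem):
        (config, annA, annB, hom, planted, ordA, ordB,
         features) = planted_ortholog_problem
        known = [(r, q) for r, q, k in
                 planted.itertuples(index=False, name=None) if k]
        rng = np.random.default_rng(3)
        t1, t2 = OrthologPipeline.build_training_tables(
            known, features, rng,
            [g.gene_id for g in annA], [g.gene_id for g in annB])
        res = OrthologPipeline(t1, t2).fit()
        # duplicate a strong candidate: same ref gene, two perfect partners
        r0, q0 = known[0]
        row = {"ref_gene": r0, "query_gene": q0, **features(r0, q0)}
        row2 = dict(row)
        row2["query_gene"] = "fake_twin"
        cand = pd.DataFrame([row, row2])
        scored = res.classify(cand)
        assert set(scored["status"]) == {"one_to_many"}
        assert len(res.one_to_one_table(cand)) == 0


class TestHomologyTable:
    def test_duplicate_rbh_rejected(self):
        frame = pd.DataFrame({
            "gene_a": ["x", "x"], "gene_b": ["y", "z"],
            "score": [1.0, 1.0], "rbh": [True, True],
        })
        with pytest.raises(ValueError, match="RBH"):
            HomologyTable(frame)

    def test_partner_lookup_symmetric(self):
        frame = pd.DataFrame({
            "gene_a": ["x"], "gene_b": ["y"], "score": [1.0], "rbh": [True],
        })
        hom = HomologyTable(frame)
        assert hom.rbh_partner("x") == "y"
        assert hom.rbh_partner("y") == "x"
        assert hom.rbh_partner("zzz") is None
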