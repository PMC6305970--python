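import itertools
import math

import numpy as np
import pytest

from annotune.interval_metrics import exon_jaccard
from annotune.sweep_optimizer import (ParameterGrid, enumerate_grid,
                                      merge_annotations,
                                      optimize_merge_params, refine_grid,
                                      run_sweep)
from annotune.synthetic_data import (SimulationConfig, SyntheticAssembler,
                                     simulate_genome_and_annotation)

from conftest import make_annotation, make_gene, make_transcript

# The three assembler-tuning rounds of the optimization protocol.
ROUND1_GRID = {
    "c": (1, 3, 5, 7, 9),
    "g": (10, 30, 50, 70, 90),
    "f": (0.01, 0.03, 0.05, 0.07, 0.09),
    "j": (1, 2, 3, 5, 7, 9),
    "a": (5, 10, 15, 20, 25),
    "M": (0.1, 0.3, 0.5, 0.7, 0.9),
}
ROUND2_GRID = {
    "c": (1, 1.5, 2, 2.5, 3, 3.5, 4, 4.5, 5),
    "g": (30, 40, 50, 60, 70),
    "f": (0.005, 0.01, 0.015, 0.02, 0.025, 0.03),
    "j": (1, 2, 3, 4, 5),
    "a": (5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15),
    "M": (0.7, 0.75, 0.8, 0.85, 0.9, 0.95),
}
ROUND3_GRID = {
    "c": (1, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9, 2),
    "g": tuple(range(40, 61)),
    "f": (0.01, 0.011, 0.012, 0.013, 0.014, 0.015, 0.016, 0.017, 0.018,
          0.019, 0.02),
    "j": (1, 2),
    "a": (13, 14, 15),
    "M": (0.9, 0.91, 0.92, 0.93, 0.94, 0.95, 0.96, 0.97, 0.98, 0.99),
}


class TestEnumerateGrid:
    def test_second_round_combination_count(self):
        assert ParameterGrid(ROUND2_GRID).size() == 89_100
        assert len(enumerate_grid(ParameterGrid(ROUND2_GRID))) == 89_100

    def test_third_round_combination_count(self):
        assert ParameterGrid(ROUND3_GRID).size() == 152_460

    def test_single_value_grid(self):
        grid = ParameterGrid({"c": [1.5]})
        assert enumerate_grid(grid) == [{"c": 1.5}]

    def test_product_matches_nested_loop_oracle(self, rng):
        for _ in range(20):
            n_params = int(rng.integers(1, 5))
            values = {
                f"p{i}": sorted(set(
                    float(v) for v in rng.uniform(0, 100,
                                                  int(rng.integers(1, 6)))
                ))
                for i in range(n_params)
            }
            grid = ParameterGrid(values)
            combos = enumerate_grid(grid)
            # oracle: explicit nested loops
            count = 0
            for _combo in itertools.product(*values.values()):
                count += 1
            assert len(combos) == count == grid.size()

    def test_row_major_deterministic_order(self):
        grid = ParameterGrid({"a": [1, 2], "b": [10, 20]})
        assert enumerate_grid(grid) == [
            {"a": 1, "b": 10}, {"a": 1, "b": 20},
            {"a": 2, "b": 10}, {"a": 2, "b": 20},
        ]

    @pytest.mark.parametrize("bad", [
        {}, {"a": []}, {"a": [2, 1]}, {"a": [1, 1]},
    ])
    def test_invalid_grids_rejected(self, bad):
        with pytest.raises(ValueError):
            ParameterGrid(bad)


@pytest.fixture(scope="module")
def planted_setup():
    config = SimulationConfig(seed=31, n_genes=40)
    genome, truth = simulate_genome_and_annotation(config)
    lengths = {c: len(s) for c, s in genome.items()}
    optimum = {"c": 1.5, "g": 51.0, "f": 0.016}
    assembler = SyntheticAssembler(
        truth, optimum, param_scales={"c": 5.0, "g": 50.0, "f": 0.05},
        contig_lengths=lengths, seed=config.seed)
    return truth, assembler, optimum


class TestRunSweep:
    def test_recovers_planted_optimum(self, planted_setup):
        truth, assembler, optimum = planted_setup
        grid = ParameterGrid({
            "c": [0.5, 1.5, 2.5], "g": [31, 51, 71], "f": [0.006, 0.016, 0.026],
        })
        result = run_sweep(assembler, None, grid, truth)
        assert result.best == optimum
        assert result.best_objective == 1.0

    def test_reference_scores_exactly_one_at_optimum(self, planted_setup):
        truth, assembler, optimum = planted_setup
        grid = ParameterGrid({k: [v] for k, v in optimum.items()})
        result = run_sweep(assembler, None, grid, truth)
        assert result.best_objective == 1.0

    def test_objective_decreases_away_from_optimum(self, planted_setup):
        truth, assembler, optimum = planted_setup
        for name, step in (("c", 0.5), ("g", 10.0), ("f", 0.01)):
            objs = []
            for k in range(4):
                params = dict(optimum)
                params[name] = optimum[name] + k * step
                ann = assembler(None, params)
                objs.append(exon_jaccard(ann, truth))
            assert all(a > b for a, b in zip(objs, objs[1:])), (name, objs)

    def test_failures_recorded_as_nan(self, planted_setup):
        truth, assembler, optimum = planted_setup

        def flaky(reads, params):
            if params["c"] > 2:
                raise RuntimeError("boom")
            return assembler(reads, params)

        grid = ParameterGrid({"c": [1.5, 5.0], "g": [51.0], "f": [0.016]})
        result = run_sweep(flaky, None, grid, truth)
        assert result.n_failures == 1
        assert result.table["objective"].isna().sum() == 1
        assert result.best == optimum

    def test_all_failures_error(self, planted_setup):
        truth, _, _ = planted_setup

        def broken(reads, params):
            raise RuntimeError("boom")

        grid = ParameterGrid({"c": [1.0, 2.0]})
        with pytest.raises(RuntimeError, match="no successful"):
            run_sweep(broken, None, grid, truth)


class TestRefineGrid:
    def test_round1_to_round2_c_list(self):
        """Refining c=3 by ±2 at step 0.5 reproduces the second-round list."""
        grid = ParameterGrid({"c": ROUND1_GRID["c"]})
        refined = refine_grid(grid, {"c": 3}, {"c": (2.0, 0.5)})
        assert refined.values("c") == (1, 1.5, 2, 2.5, 3, 3.5, 4, 4.5, 5)

    def test_boundary_optimum_clipped(self):
        grid = ParameterGrid({"c": (1, 3, 5)})
        refined = refine_grid(grid, {"c": 1}, {"c": (2.0, 1.0)},
                              bounds={"c": (1.0, 10.0)})
        assert refined.values("c") == (1, 2, 3)

    def test_incumbent_always_present(self):
        grid = ParameterGrid({"c": (1, 3, 5)})
        refined = refine_grid(grid, {"c": 3}, {"c": (0.8, 0.5)})
        assert 3 in refined.values("c")

    def test_incumbent_not_in_grid_rejected(self):
        grid = ParameterGrid({"c": (1, 3, 5)})
        with pytest.raises(ValueError, match="incumbent"):
            refine_grid(grid, {"c": 2}, {"c": (1.0, 0.5)})

    def test_best_objective_non_decreasing_across_rounds(self, planted_setup):
        truth, assembler, optimum = planted_setup
        grid = ParameterGrid({
            "c": [0.5, 2.5, 4.5], "g": [11, 41, 71], "f": [0.004, 0.024, 0.044],
        })
        best_objs = []
        for round_index in range(3):
            result = run_sweep(assembler, None, grid, truth,
                               round_index=round_index)
            best_objs.append(result.best_objective)
            grid = refine_grid(
                grid, result.best,
                {name: (spacing, spacing / 2) for name, spacing in
                 (("c", 1.0), ("g", 15.0), ("f", 0.01))})
        assert all(b >= a for a, b in zip(best_objs, best_objs[1:]))


class TestMergeAnnotations:
    def make_samples(self):
        tx = [((0, 100), (200, 300)), ((1000, 1200),)]
        s1 = make_annotation(
            make_gene("a1", [list(tx[0])]),
            make_gene("a2", [list(tx[1])]),
        )
        s2 = make_annotation(
            make_gene("b1", [list(tx[0])]),
            make_gene("b2", [list(tx[1])]),
        )
        return s1, s2

    def test_identical_samples_merge_to_same_structure(self):
        s1, s2 = self.make_samples()
        merged = merge_annotations([s1, s2])
        assert exon_jaccard(merged, s1) == 1.0
        assert merged.n_transcripts() == s1.n_transcripts()

    def test_tpm_threshold_filters(self):
        from annotune.annotation_core import AnnotationSet, GeneModel

        t = make_transcript("t1", "g1", [(0, 100)],
                            attributes={"fpkm": 5.0, "tpm": 5.0})
        ann = AnnotationSet([GeneModel("g1", (t,))])
        with pytest.raises(ValueError, match="filtered out"):
            merge_annotations([ann, ann], min_tpm=10.0)

    def test_gap_merges_nearby_mono_exonic(self):
        s = make_annotation(
            make_gene("g1", [[(0, 100)]]),
            make_gene("g2", [[(120, 200)]]),
        )
        merged0 = merge_annotations([s, s], gap=0)
        assert merged0.n_transcripts() == 2
        merged50 = merge_annotations([s, s], gap=50)
        assert merged50.n_transcripts() == 1
        t = next(merged50.transcripts())
        assert (t.exons[0].start, t.exons[0].end) == (0, 200)


class TestOptimizeMergeParams:
    def test_planted_merge_optimum_recovered(self):
        """Noise transcripts sit below TPM 10; truth transcripts above."""
        from annotune.annotation_core import AnnotationSet, GeneModel

        def sample(seed_tag):
            genes = []
            specs = [
                ("real1", [(0, 100), (200, 300)], 50.0),
                ("real2", [(1000, 1300)], 80.0),
                (f"noise{seed_tag}", [(5000 + seed_tag * 40,
                                       5120 + seed_tag * 40)], 2.0),
            ]
            for gid, exons, tpm in specs:
                t = make_transcript(gid + ".t", gid, exons,
                                    attributes={"fpkm": tpm, "tpm": tpm})
                genes.append(GeneModel(gid, (t,)))
            return AnnotationSet(genes)

        reference = make_annotation(
            make_gene("r1", [[(0, 100), (200, 300)]]),
            make_gene("r2", [[(1000, 1300)]]),
        )
        grid = ParameterGrid({"F": [0, 20], "T": [0, 10], "g": [0, 500]})
        result = optimize_merge_params([sample(1), sample(2)], grid, reference)
        assert result.best == {"F": 0, "T": 10, "g": 0}
        assert result.best_objective == 1.0

    def test_threshold_above_everything_is_nan(self):
        s1, s2 = TestMergeAnnotations().make_samples()
        # attach low abundances so T=1000 removes everything
        from annotune.annotation_core import AnnotationSet, GeneModel

        def with_abund(ann):
            genes = []
            for g in ann:
                txs = tuple(
                    make_transcript(t.transcript_id, g.gene_id,
                                    [(e.start, e.end) for e in t.exons],
                                    attributes={"fpkm": 10.0, "tpm": 10.0})
                    for t in g.transcripts)
                genes.append(GeneModel(g.gene_id, txs))
            return AnnotationSet(genes)

        grid = ParameterGrid({"T": [5.0, 1000.0]})
        result = optimize_merge_params(
            [with_abund(s1), with_abund(s2)], grid,
            make_annotation(make_gene("r", [[(0, 100), (200, 300)]])))
        assert result.table["objective"].isna().sum() == 1
        assert result.n_failures == 1
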