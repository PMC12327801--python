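import numpy as np
import pytest

from blastodbn import (
    FixtureDBN,
    class_frequency_stats,
    simulate_cohort,
    simulate_embryo,
    simulate_lineage,
    state_count_distribution,
)


class TestLineage:
    def test_lineage_has_13_cells_and_4_branches(self, f1_results, rng):
        lin = simulate_lineage(f1_results, rng)
        assert lin.n_cells == 13
        stages = [s for s, _ in lin.cells]
        assert [stages.count(i) for i in range(5)] == [1, 2, 2, 4, 4]
        assert set(lin.branches()) == {"aa", "ab", "ba", "bb"}

    def test_embryo_has_32_final_branches(self, f1_results, rng):
        emb = simulate_embryo(f1_results, rng)
        assert len(emb.lineages) == 8
        assert emb.n_final_branches == 32

    def test_deterministic_model_gives_identical_branches(self, f1, rng):
        entries = {k: float(v >= 0.5) for k, v in f1.entries.items()}
        det = FixtureDBN("det", f1.structure, entries).to_results()
        lin = simulate_lineage(det, rng)
        branches = list(lin.branches().values())
        assert all(b == branches[0] for b in branches)

    def test_mixed_daughter_fraction_at_even_odds(self, f1, rng):
        entries = dict(f1.entries)
        entries[("Y1", (1,))] = 0.5
        fx = FixtureDBN("half", f1.structure, entries).to_results()
        mixed = 0
        n = 400
        for _ in range(n):
            lin = simulate_lineage(fx, rng)
            a, b = lin.cells[(1, "a")]["Y1"], lin.cells[(1, "b")]["Y1"]
            mixed += a != b
        # daughters independent given the mother: P(mixed) = 2q(1-q) = 0.5
        assert abs(mixed / n - 0.5) < 3 * np.sqrt(0.25 / n)


class TestCohort:
    def test_same_seed_reproduces_cohort_exactly(self, f1_results):
        a = simulate_cohort(f1_results, 20, seed=5)
        b = simulate_cohort(f1_results, 20, seed=5)
        for node in a.cell_values:
            np.testing.assert_array_equal(a.cell_values[node], b.cell_values[node])

    def test_growing_the_cohort_keeps_earlier_embryos(self, f1_results):
        small = simulate_cohort(f1_results, 5, seed=9)
        large = simulate_cohort(f1_results, 12, seed=9)
        for node in small.cell_values:
            np.testing.assert_array_equal(
                small.cell_values[node], large.cell_values[node][:5]
            )

    def test_cohort_marginals_match_variable_elimination(self, f1_results):
        n = 2000
        cohort = simulate_cohort(f1_results, n, seed=2)
        for node in ("Y2", "S3", "S4"):
            exact = f1_results.posterior((node,)).values[1]
            vals = cohort.cell_values[node]
            est = vals.mean()
            se = np.sqrt(exact * (1 - exact) / vals.size)
            # cells within a lineage are correlated; allow for design effect
            assert abs(est - exact) < 3 * se * np.sqrt(4.0), node

    def test_empirical_trajectory_distribution_converges(self, f1_results):
        """Total-variation gap to the exact joint < 0.02 at N = 3000."""
        cohort = simulate_cohort(f1_results, 3000, seed=13)
        df = cohort.to_frame()
        nodes = list(f1_results.structure.topological_order())
        jd = f1_results.joint_distribution()
        codes = np.zeros(len(df), dtype=np.int64)
        for node in nodes:
            codes = codes * 2 + df[node].to_numpy(dtype=np.int64)
        counts = np.bincount(codes, minlength=len(jd)) / len(df)
        enum_codes = np.zeros(len(jd), dtype=np.int64)
        for j in range(len(nodes)):
            enum_codes = enum_codes * 2 + jd.assignments[:, j]
        exact = np.zeros(len(jd))
        exact[enum_codes] = jd.probs
        tv = 0.5 * np.abs(counts - exact).sum()
        assert tv < 0.02


class TestClassFrequencies:
    def test_fractions_sum_to_one(self, f1_results):
        cohort = simulate_cohort(f1_results, 50, seed=3)
        stats = class_frequency_stats(cohort, "S")
        assert stats["mean"].sum() == pytest.approx(1.0)

    def test_deterministic_induction_has_zero_sd(self, f1):
        entries = {k: float(v >= 0.5) for k, v in f1.entries.items()}
        det = FixtureDBN("det", f1.structure, entries).to_results()
        stats = class_frequency_stats(simulate_cohort(det, 20, seed=1), "S")
        assert (stats["sd"] == 0).all()
        assert stats["mean"].max() == pytest.approx(1.0)

    def test_means_match_exact_class_probabilities(self, f1_results):
        from blastodbn import predict_class_frequencies

        n = 2000
        cohort = simulate_cohort(f1_results, n, seed=4)
        stats = class_frequency_stats(cohort, "S").set_index("class")["mean"]
        exact = predict_class_frequencies(f1_results, "S")
        for label, p in exact.items():
            se = np.sqrt(p * (1 - p) / (n * 32)) * np.sqrt(4.0)
            assert abs(stats[label] - p) < 3 * se, label


class TestStateCounts:
    def test_counts_partition_cells_at_every_stage(self, f3_results):
        cohort = simulate_cohort(f3_results, 30, seed=6)
        counts = state_count_distribution(cohort)
        for stage, expected_total in ((2, 16), (3, 32), (4, 32)):
            assert (counts.per_embryo[stage].sum(axis=1) == expected_total).all()

    def test_pairwise_cohort_is_rejected(self, f1_results):
        cohort = simulate_cohort(f1_results, 5, seed=0)
        with pytest.raises(ValueError, match="fused"):
            state_count_distribution(cohort)

    def test_silent_targets_give_all_double_negative(self, f3):
        entries = dict(f3.entries)
        for (node, cfg) in list(entries):
            if node[0] in ("C", "S"):
                entries[(node, cfg)] = 0.0
        silent = FixtureDBN("silent", f3.structure, entries).to_results()
        counts = state_count_distribution(simulate_cohort(silent, 10, seed=2))
        assert (counts.per_embryo[4][:, 3] == 32).all()

    def test_count_means_match_exact_cell_probabilities(self, f3_results):
        n = 1500
        cohort = simulate_cohort(f3_results, n, seed=8)
        counts = state_count_distribution(cohort)
        post = f3_results.posterior(("C4", "S4"))
        exact = {  # (C, S) -> class column
            (1, 0): 0, (0, 1): 1, (1, 1): 2, (0, 0): 3,
        }
        for (c, s), col in exact.items():
            p = post.values[c, s]
            mean = counts.per_embryo[4][:, col].mean()
            se = 32 * np.sqrt(p * (1 - p) / (n * 32)) * np.sqrt(4.0)
            assert abs(mean - 32 * p) < 3 * se

    def test_shared_ancestry_induces_nonnegative_branch_correlation(self, f1_results):
        cohort = simulate_cohort(f1_results, 1500, seed=10)
        s4 = cohort.branch_values("S4").astype(float)
        sisters = np.corrcoef(s4[:, 0], s4[:, 1])[0, 1]  # share a 16-cell mother
        strangers = np.corrcoef(s4[:, 0], s4[:, 4])[0, 1]  # different lineages
        assert sisters > -0.02
        assert sisters > strangers - 0.05
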