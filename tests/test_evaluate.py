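import numpy as np
import pandas as pd
import pytest

from blastodbn import (
    DiscreteDBN,
    SplitPlan,
    expected_calibration_error,
    predict_class_frequencies,
    report_headline_inference,
    select_model,
    simulate_cohort,
    threshold_sensitivity,
)
from blastodbn.evaluate import calibration_over_splits, class_evidence, one_step_predictions


class TestSplits:
    def test_exhaustive_nine_choose_six(self):
        ids = tuple(f"e{i}" for i in range(9))
        splits = SplitPlan(ids, "exhaustive").splits()
        assert len(splits) == 84
        for train, test in splits:
            assert len(train) == 6 and len(test) == 3
            assert not set(train) & set(test)

    def test_random_splits_are_seeded(self):
        ids = tuple(f"e{i}" for i in range(12))
        a = SplitPlan(ids, "random", n_splits=10, seed=3).splits()
        b = SplitPlan(ids, "random", n_splits=10, seed=3).splits()
        assert a == b
        assert len(a) == 10

    def test_train_size_must_leave_a_test_set(self):
        with pytest.raises(ValueError):
            SplitPlan(("a", "b"), "exhaustive").splits()


class TestSelection:
    def test_single_candidate_returned_trivially(self, small_cohort_df):
        sel = select_model(small_cohort_df, "S", candidates=("M3",))
        assert sel.winner == "M3"

    def test_m3_recovered_from_m3_simulated_data(self, small_cohort_df):
        sel = select_model(small_cohort_df, "S")
        assert sel.winner == "M3"
        assert set(sel.table["model"]) == {"M1", "M2", "M3", "M4"}

    def test_tie_reported_not_broken(self, small_cohort_df):
        sel = select_model(small_cohort_df, "S", candidates=("M3", "M3"))
        assert sel.winner is None
        assert sel.tie == ("M3", "M3")


class TestClassFrequencies:
    def test_probabilities_sum_to_one(self, fitted_m3):
        freqs = predict_class_frequencies(fitted_m3.fill_unobserved(0.5), "S")
        assert freqs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_equal_to_enumeration_masses(self, f1_results):
        freqs = predict_class_frequencies(f1_results, "S")
        jd = f1_results.joint_distribution()
        assert freqs["S2+"] == pytest.approx(jd.prob_of({"S2": 1}), abs=1e-12)
        assert freqs["S3+"] == pytest.approx(
            jd.prob_of({"S2": 0, "S3": 1}), abs=1e-12
        )
        assert freqs["S-"] == pytest.approx(
            jd.prob_of({"S2": 0, "S3": 0, "S4": 0}), abs=1e-12
        )

    def test_deterministic_fixture_concentrates_one_class(self, f1):
        from blastodbn import FixtureDBN

        entries = {k: float(v >= 0.5) for k, v in f1.entries.items()}
        det = FixtureDBN("det", f1.structure, entries).to_results()
        freqs = predict_class_frequencies(det, "S")
        assert freqs.max() == pytest.approx(1.0)


class TestECE:
    def test_constant_one_against_all_negative_labels(self):
        rep = expected_calibration_error(np.ones(50), np.zeros(50))
        assert rep.ece == pytest.approx(1.0)

    def test_bin_rate_predictions_are_perfectly_calibrated(self, rng):
        labels = rng.integers(0, 2, 1000).astype(float)
        preds = np.full(1000, labels.mean())
        rep = expected_calibration_error(preds, labels)
        assert rep.ece == pytest.approx(0.0, abs=1e-12)

    def test_boundary_values_fall_in_lower_bin_except_one(self):
        rep = expected_calibration_error(
            np.array([0.0, 0.3, 1.0]), np.array([0.0, 0.0, 1.0])
        )
        assert rep.bin_counts[0] == 1  # 0.0 -> first bin
        assert rep.bin_counts[2] == 1  # 0.3 -> bin (0.2, 0.3]
        assert rep.bin_counts[9] == 1  # 1.0 -> top bin

    def test_input_validation(self):
        with pytest.raises(ValueError):
            expected_calibration_error(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            expected_calibration_error(np.array([1.2]), np.array([1.0]))
        with pytest.raises(ValueError):
            expected_calibration_error(np.array([0.5]), np.array([2.0]))

    def test_self_simulation_is_well_calibrated(self, f1_results):
        df = simulate_cohort(f1_results, 800, seed=15).to_frame()
        preds, labels = one_step_predictions(f1_results, df)
        rep = expected_calibration_error(preds, labels)
        assert rep.ece < 0.05

    def test_calibration_over_splits_runs(self, small_cohort_df):
        plan = SplitPlan(
            tuple(small_cohort_df["embryo_id"].unique()[:9]), "exhaustive"
        )
        sub = small_cohort_df[
            small_cohort_df["embryo_id"].isin(plan.embryo_ids)
        ]
        table = calibration_over_splits(sub, "S", plan)
        assert len(table) == 84
        assert (table["ece"] >= 0).all() and (table["ece"] <= 1).all()


class TestThresholdSensitivity:
    def test_winner_stable_over_central_thresholds(self, f1_results):
        rng = np.random.default_rng(0)
        df = simulate_cohort(f1_results, 40, seed=19).to_frame()
        # synthetic continuous summaries consistent with the binary truth
        rows = []
        for _, r in df.iterrows():
            for stage in (2, 3, 4):
                value = rng.normal(0.8 if r[f"S{stage}"] else 0.1, 0.05)
                rows.append(
                    {
                        "embryo_id": r["embryo_id"],
                        "lineage_id": r["lineage_id"],
                        "branch_code": r["branch_code"],
                        "variable": "S",
                        "stage": stage,
                        "value": value,
                    }
                )
        summaries = pd.DataFrame(rows)
        y_cols = ["embryo_id", "lineage_id", "branch_code"] + [f"Y{i}" for i in range(5)]
        table = threshold_sensitivity(
            summaries, df[y_cols], "S", thetas=np.linspace(0.3, 0.6, 5)
        )
        assert (~table["degenerate"]).all()
        assert (table["winner"] == "M3").all()

    def test_extreme_thresholds_flagged_degenerate(self, f1_results):
        df = simulate_cohort(f1_results, 10, seed=23).to_frame()
        rows = []
        for _, r in df.iterrows():
            for stage in (2, 3, 4):
                rows.append(
                    {
                        "embryo_id": r["embryo_id"],
                        "lineage_id": r["lineage_id"],
                        "branch_code": r["branch_code"],
                        "variable": "S",
                        "stage": stage,
                        "value": float(r[f"S{stage}"]),
                    }
                )
        summaries = pd.DataFrame(rows)
        y_cols = ["embryo_id", "lineage_id", "branch_code"] + [f"Y{i}" for i in range(5)]
        table = threshold_sensitivity(
            summaries, df[y_cols], "S", thetas=np.array([-1.0, 2.0])
        )
        assert table["degenerate"].all()


class TestHeadlineReport:
    def test_report_quantities_match_enumeration(self, f1_results, f3_results):
        rep = report_headline_inference(
            {"S": f1_results}, f3_results, n_embryos=300, seed=1
        )
        entry = rep["pairwise"]["S"]
        # posterior over Y trajectories sums to 1 for every class
        for label, post in entry["y_posterior_by_class"].items():
            assert "consistently_nuclear_yap" in post
        # exact class probabilities equal the enumeration masses
        jd = f1_results.joint_distribution()
        assert entry["class_probabilities"]["S2+"] == pytest.approx(
            jd.prob_of({"S2": 1}), abs=1e-12
        )
        # simulated frequencies agree with the exact ones within 3 MC SEs
        for label, p in entry["class_probabilities"].items():
            mean = entry["class_frequencies_simulated"][label]["mean"]
            se = np.sqrt(p * (1 - p) / (300 * 32)) * np.sqrt(4.0)
            assert abs(mean - p) < max(3 * se, 0.01), label
        # consistently nuclear YAP is the named trajectory [1,1,1,1,1]
        jd_c = jd.condition(class_evidence("S", "2+"))
        expected = jd_c.marginal(tuple(f"Y{i}" for i in range(5))).values[
            1, 1, 1, 1, 1
        ]
        got = entry["y_posterior_by_class"]["S2+"]["consistently_nuclear_yap"]
        assert got == pytest.approx(expected, abs=1e-12)

    def test_fused_block_reports_state_counts_and_dp_posteriors(
        self, f1_results, f3_results
    ):
        rep = report_headline_inference({"S": f1_results}, f3_results, 200, seed=2)
        assert set(rep["fused"]["state_counts"]) == {2, 3, 4}
        stage4 = rep["fused"]["state_counts"][4]
        total = sum(v["mean"] for v in stage4.values())
        assert total == pytest.approx(32.0, abs=1e-9)
        assert set(rep["fused"]["double_positive_posteriors"]) == {"Y", "C", "S"}
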