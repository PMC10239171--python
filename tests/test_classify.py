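"""Dataset assembly, split integrity, metrics and statistical comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.model_selection import StratifiedGroupKFold

from capnokit.classify import (
    ModellingDataset,
    assemble_dataset,
    audit_split_plan,
    compare_models,
    confusion_metrics,
    feature_importance,
    make_split_plan,
    misclassification_audit,
    paired_ttest,
    per_patient_consistency,
    scale_features,
    train_and_evaluate,
)
from capnokit.errors import ConfigurationError, ParameterError, SplitError
from capnokit.features import ALL_FEATURES


def _fake_cohort(n_copd=80, n_non=215, recs=3, invalid_patients=()):
    """Joined cohort table with stub feature values (selection-rule tests)."""
    rows = []
    pid = 0
    for label, n in (("COPD", n_copd), ("non_COPD", n_non)):
        for _ in range(n):
            pid += 1
            name = f"P{pid:04d}"
            for r in range(recs):
                rows.append({
                    "recording_id": f"{name}_rec{r}", "patient_id": name,
                    "label": label, "order": r, "valid": name not in invalid_patients,
                    "f": float(pid + 0.1 * r),
                })
    return pd.DataFrame(rows)


def _toy_dataset(n_per_class=30, gap=3.0, seed=0, rows_per_patient=1):
    """Single-feature dataset with a controllable class gap."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, n in (("COPD", n_per_class), ("non_COPD", n_per_class)):
        centre = gap if label == "COPD" else 0.0
        for i in range(n):
            pid = f"{label}_{i}"
            for r in range(rows_per_patient):
                rows.append({"recording_id": f"{pid}_r{r}", "patient_id": pid,
                             "label": 1 if label == "COPD" else 0,
                             "f": centre + rng.normal()})
    return ModellingDataset(frame=pd.DataFrame(rows), feature_cols=("f",))


class TestAssemble:
    def test_balancing_rule_row_count(self):
        ds = assemble_dataset(_fake_cohort(), feature_cols=("f",))
        assert len(ds.frame) == 215 + 3 * 80 == 455

    def test_all_invalid_patient_contributes_no_rows(self):
        ds = assemble_dataset(_fake_cohort(n_copd=2, n_non=3, invalid_patients=("P0001",)),
                              feature_cols=("f",))
        assert "P0001" not in set(ds.frame["patient_id"])

    def test_majority_patient_keeps_only_earliest(self):
        cohort = _fake_cohort(n_copd=1, n_non=1, recs=300)
        ds = assemble_dataset(cohort, feature_cols=("f",))
        non = ds.frame[ds.frame["label"] == 0]
        assert len(non) == 1
        assert non.iloc[0]["recording_id"].endswith("_rec0")

    def test_copd_patient_with_fewer_recordings_keeps_what_exists(self):
        cohort = _fake_cohort(n_copd=1, n_non=1, recs=2)
        ds = assemble_dataset(cohort, feature_cols=("f",))
        assert (ds.frame["label"] == 1).sum() == 2


class TestScaling:
    def test_train_columns_standardised(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame({"a": rng.normal(5, 2, 50), "b": rng.normal(-3, 0.5, 50)})
        xt, xa, _ = scale_features(df, df, ("a", "b"))
        assert np.allclose(xt.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(xt.std(axis=0), 1, atol=1e-12)  # population SD

    def test_constant_column_passes_through_as_zeros(self):
        df = pd.DataFrame({"a": [4.0, 4.0, 4.0], "b": [1.0, 2.0, 3.0]})
        xt, _, _ = scale_features(df, df, ("a", "b"))
        assert np.allclose(xt[:, 0], 0.0)

    def test_two_point_column_population_convention(self):
        df = pd.DataFrame({"a": [2.0, 4.0]})
        xt, _, _ = scale_features(df, df, ("a",))
        assert np.allclose(sorted(xt[:, 0]), [-1.0, 1.0])

    def test_apply_rows_use_train_parameters_only(self):
        train = pd.DataFrame({"a": [0.0, 2.0]})
        test = pd.DataFrame({"a": [4.0]})
        _, xa, _ = scale_features(train, test, ("a",))
        assert xa[0, 0] == pytest.approx(3.0)  # (4 - 1) / 1


class TestSplitPlan:
    def test_partition_and_zero_violations(self):
        ds = _toy_dataset(n_per_class=20, rows_per_patient=2)
        plan = make_split_plan(ds, n_iter=10, rng_seed=3)
        assert audit_split_plan(plan, ds) == 0
        dev = set(ds.patients["patient_id"]) - set(plan.holdout_patient_ids)
        for assignment in plan.iterations:
            assert set(assignment) == dev
            assert set(assignment.values()) <= set(range(5))

    def test_too_few_patients_raises(self):
        ds = _toy_dataset(n_per_class=4)
        with pytest.raises(SplitError):
            make_split_plan(ds, k=5, n_iter=1, rng_seed=0)

    def test_fold_sizes_for_289_patient_pool(self):
        # a 289-patient development pool must split 231 train / 58 test
        rows = [{"recording_id": f"P{i}_r0", "patient_id": f"P{i}",
                 "label": i % 4 == 0, "f": 0.0} for i in range(289)]
        ds = ModellingDataset(pd.DataFrame(rows), feature_cols=("f",))
        plan = make_split_plan(ds, holdout_frac=0.0, k=5, n_iter=1, rng_seed=1)
        counts = pd.Series(plan.iterations[0]).value_counts()
        assert sorted(counts) == [57, 58, 58, 58, 58]
        assert 289 - counts.max() == 231

    def test_agrees_with_sklearn_group_stratification_balance(self):
        # cross-check: class balance per fold is as even as sklearn's
        # StratifiedGroupKFold achieves on the same patients
        ds = _toy_dataset(n_per_class=26, rows_per_patient=1)
        plan = make_split_plan(ds, holdout_frac=0.0, k=5, n_iter=1, rng_seed=5)
        pats = ds.patients
        ours = pats.assign(fold=pats["patient_id"].map(plan.iterations[0]))
        our_spread = ours.groupby("fold")["label"].mean().std()
        sgk = StratifiedGroupKFold(n_splits=5, shuffle=True, random_state=5)
        folds = np.zeros(len(pats), dtype=int)
        for f, (_, te) in enumerate(sgk.split(pats, pats["label"], pats["patient_id"])):
            folds[te] = f
        sk_spread = pats.assign(fold=folds).groupby("fold")["label"].mean().std()
        assert our_spread <= sk_spread + 1e-9


class TestMetricsAndModels:
    def test_confusion_metric_definitions(self):
        y = np.array([1] * 10 + [0] * 10)
        prob = np.array([0.9] * 9 + [0.1] + [0.2] * 8 + [0.8] * 2)
        m = confusion_metrics(y, prob)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(9 / 11)
        assert m["npv"] == pytest.approx(8 / 9)
        assert m["tp"] + m["tn"] + m["fp"] + m["fn"] == 20

    def test_separable_classes_give_perfect_auroc_every_fold(self):
        ds = _toy_dataset(n_per_class=30, gap=8.0, seed=2)
        plan = make_split_plan(ds, n_iter=2, rng_seed=2)
        rep = train_and_evaluate(plan, ds, ("logistic_regression",), rng_seed=2)
        assert (rep.cv_metrics["auroc"] == 1.0).all()

    def test_permuted_labels_auroc_near_half(self):
        ds = _toy_dataset(n_per_class=30, gap=4.0, seed=3).permute_labels(9)
        plan = make_split_plan(ds, n_iter=10, rng_seed=3)
        rep = train_and_evaluate(plan, ds, ("logistic_regression",), rng_seed=3)
        per_iter = rep.cv_metrics.groupby("iteration")["auroc"].mean()
        se = per_iter.std() / np.sqrt(len(per_iter))
        assert abs(per_iter.mean() - 0.5) < 3 * max(se, 0.02)

    def test_report_reproducible_for_fixed_seed(self):
        ds = _toy_dataset(n_per_class=12, gap=2.0, seed=4)
        plan = make_split_plan(ds, n_iter=2, rng_seed=4)
        r1 = train_and_evaluate(plan, ds, ("logistic_regression",), rng_seed=4)
        r2 = train_and_evaluate(plan, ds, ("logistic_regression",), rng_seed=4)
        pd.testing.assert_frame_equal(
            r1.cv_metrics.drop(columns="build_time_s"),
            r2.cv_metrics.drop(columns="build_time_s"))


class TestImportance:
    class _Fake:
        def __init__(self, coef):
            self.coef_ = np.asarray(coef).reshape(1, -1)

    def test_zero_coefficient_contributes_zero_everywhere(self):
        cols = ALL_FEATURES[:4]
        rows = np.random.default_rng(0).normal(size=(10, 4))
        coef = [0.0, 1.0, 2.0, 0.0]
        imp, region = feature_importance(self._Fake(coef), rows, cols)
        assert imp.iloc[0] == 0.0 and imp.iloc[3] == 0.0
        assert imp.iloc[2] == 2.0

    def test_unknown_feature_raises_configuration_error(self):
        with pytest.raises(ConfigurationError):
            feature_importance(self._Fake([1.0]), np.ones((2, 1)), ("not_a_feature",))


class TestConsistencyAndBias:
    def test_consistent_patient_has_unit_accuracy_zero_sd(self):
        arch = pd.DataFrame({
            "iteration": [0] * 3, "fold": [0] * 3,
            "patient_id": ["A"] * 3, "recording_id": list("xyz"),
            "y_true": [1] * 3, "prob": [0.9] * 3,
        })
        cond = pd.DataFrame({"patient_id": ["A"], "condition": ["COPD"]})
        out = per_patient_consistency(arch, cond)
        assert out.loc["COPD", "accuracy"] == 1.0
        assert out.loc["COPD", "prob_sd"] == 0.0

    def test_split_probabilities_give_half_accuracy(self):
        arch = pd.DataFrame({
            "iteration": [0, 0], "fold": [0, 0],
            "patient_id": ["A", "A"], "recording_id": ["x", "y"],
            "y_true": [1, 1], "prob": [0.4, 0.6],
        })
        cond = pd.DataFrame({"patient_id": ["A"], "condition": ["COPD"]})
        out = per_patient_consistency(arch, cond)
        assert out.loc["COPD", "accuracy"] == 0.5

    @staticmethod
    def _archive(wrong_iters, n_iter=100):
        rows = []
        for it in range(n_iter):
            prob = 0.1 if it in wrong_iters else 0.9
            rows.append({"iteration": it, "fold": 0, "patient_id": "A",
                         "recording_id": "a0", "y_true": 1, "prob": prob})
        return pd.DataFrame(rows)

    def test_strict_majority_misclassification_rule(self):
        demo = pd.DataFrame({"patient_id": ["A"], "sex": ["F"],
                             "age": [60.0], "bmi": [25.0]})
        out51 = misclassification_audit(self._archive(set(range(51))), demo)
        out50 = misclassification_audit(self._archive(set(range(50))), demo)
        assert bool(out51["per_patient"].loc["A", "misclassified"])
        assert not bool(out50["per_patient"].loc["A", "misclassified"])

    def test_identical_distributions_give_p_one(self):
        res = stats.mannwhitneyu([1, 2, 3], [1, 2, 3], alternative="two-sided")
        assert res.pvalue == pytest.approx(1.0)

    def test_mannwhitney_u_matches_pair_enumeration(self):
        a, b = [1, 2, 3], [4, 5, 6]
        u_brute = sum(1.0 * (x > y) + 0.5 * (x == y) for x in a for y in b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        assert res.statistic == u_brute == 0.0


class TestModelComparison:
    def test_identical_series_give_t0_p1(self):
        out = paired_ttest(np.ones(10), np.ones(10))
        assert out == {"t": 0.0, "p": 1.0, "degenerate": False}

    def test_constant_offset_flagged_degenerate(self):
        a = np.linspace(0, 1, 10)
        out = paired_ttest(a + 0.01, a)
        assert out["degenerate"] and np.isinf(out["t"]) and out["p"] == 0.0

    def test_matches_closed_form_t(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0.8, 0.05, 100)
        b = rng.normal(0.78, 0.05, 100)
        d = a - b
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_oracle = 2 * stats.t.sf(abs(t_oracle), df=len(d) - 1)
        out = paired_ttest(a, b)
        assert out["t"] == pytest.approx(t_oracle, abs=1e-10)
        assert out["p"] == pytest.approx(p_oracle, abs=1e-10)

    def test_length_mismatch_raises(self):
        with pytest.raises(ParameterError):
            paired_ttest(np.ones(5), np.ones(6))

    def test_compare_models_pairs_by_iteration(self):
        ds = _toy_dataset(n_per_class=15, gap=2.0, seed=6)
        plan = make_split_plan(ds, n_iter=3, rng_seed=6)
        rep = train_and_evaluate(plan, ds, ("logistic_regression", "linear_svm"),
                                 rng_seed=6)
        out = compare_models(rep.cv_metrics)
        assert set(out["metric"]) == {"specificity", "sensitivity", "f1", "auroc"}
        assert (out[["t", "p"]].notna()).all().all()
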