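"""Unit and property tests for grouped CV, metrics and feature search."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tremorlab import classify as cls
from tremorlab import features as ft


def toy_cohort(n_per_class=20, seed=0, separation=3.0):
    """Two informative features plus one noise feature, one row per patient."""
    rng = np.random.default_rng(seed)
    rows, labels, groups = [], [], []
    for i in range(2 * n_per_class):
        label = "PD" if i < n_per_class else "ET"
        mu = separation if label == "PD" else 0.0
        rows.append({"f_one": mu + rng.normal(), "f_two": mu + rng.normal(),
                     "noise": rng.normal()})
        labels.append(label)
        groups.append(f"p{i:03d}")
    matrix = ft.FeatureMatrix(pd.DataFrame(rows, index=groups))
    return matrix, np.asarray(labels), np.asarray(groups)


class TestGroupedKfold:
    @given(st.integers(0, 10_000), st.integers(2, 10))
    @settings(max_examples=25, deadline=None)
    def test_patient_atomic_for_any_seed(self, seed, k):
        groups = np.repeat([f"p{i}" for i in range(12)], 4)  # 4 recordings each
        folds = cls.grouped_kfold(groups, k=k, seed=seed)
        for g in np.unique(groups):
            assert np.unique(folds.fold[groups == g]).shape[0] == 1

    def test_stratified_deal_balances_classes(self):
        groups = np.asarray([f"p{i}" for i in range(40)])
        labels = np.asarray(["PD"] * 20 + ["ET"] * 20)
        folds = cls.grouped_kfold(groups, k=10, seed=3, labels=labels)
        for f in range(10):
            in_fold = labels[folds.fold == f]
            assert set(in_fold) == {"PD", "ET"}

    def test_split_patient_rejected_by_invariant(self):
        with pytest.raises(ValueError, match="split across folds"):
            cls.FoldAssignment(fold=np.array([0, 1]), k=2,
                               groups=np.array(["p1", "p1"]))

    def test_more_folds_than_patients_rejected(self):
        with pytest.raises(ValueError):
            cls.grouped_kfold(["a", "b", "c"], k=5)

    def test_deterministic_given_seed(self):
        groups = np.asarray([f"p{i}" for i in range(30)])
        a = cls.grouped_kfold(groups, k=5, seed=9)
        b = cls.grouped_kfold(groups, k=5, seed=9)
        np.testing.assert_array_equal(a.fold, b.fold)


class TestConfusionMetrics:
    def test_textbook_values(self):
        m = cls.confusion_metrics(tp=40, fn=10, tn=30, fp=20)
        assert m["accuracy"] == pytest.approx(70.0)
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(60.0)
        assert m["balanced_accuracy"] == pytest.approx(70.0)
        assert m["ppv"] == pytest.approx(100.0 * 40 / 60)
        assert m["npv"] == pytest.approx(75.0)

    @given(st.integers(0, 200), st.integers(0, 200),
           st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=50, deadline=None)
    def test_identities_hold(self, tp, fn, tn, fp):
        if tp + fn + tn + fp == 0:
            with pytest.raises(ValueError):
                cls.confusion_metrics(tp, fn, tn, fp)
            return
        m = cls.confusion_metrics(tp, fn, tn, fp)
        assert m["accuracy"] == pytest.approx(
            cls.accuracy(tp + tn, tp + fn + tn + fp))
        if np.isfinite(m["balanced_accuracy"]):
            assert m["balanced_accuracy"] == pytest.approx(
                (m["sensitivity"] + m["specificity"]) / 2.0)
        for v in m.values():
            assert np.isnan(v) or 0.0 <= v <= 100.0

    def test_accuracy_empty_rejected(self):
        with pytest.raises(ValueError):
            cls.accuracy(0, 0)


class TestEvaluateClassifier:
    def test_separable_cohort_high_accuracy(self):
        matrix, labels, groups = toy_cohort(separation=5.0)
        folds = cls.grouped_kfold(groups, k=5, seed=0, labels=labels)
        rep = cls.evaluate_classifier(matrix, labels, folds, "svm",
                                      feature_subset=["f_one", "f_two"])
        assert rep.pooled["balanced_accuracy"] > 95.0
        assert rep.confusion["tp"] + rep.confusion["fn"] == 20

    def test_noise_feature_near_chance(self):
        matrix, labels, groups = toy_cohort(seed=5)
        folds = cls.grouped_kfold(groups, k=5, seed=0, labels=labels)
        rep = cls.evaluate_classifier(matrix, labels, folds, "svm",
                                      feature_subset=["noise"])
        assert rep.pooled["balanced_accuracy"] < 75.0

    def test_all_three_models_run(self):
        matrix, labels, groups = toy_cohort()
        folds = cls.grouped_kfold(groups, k=5, seed=0, labels=labels)
        for model in ("svm", "logistic", "rf"):
            rep = cls.evaluate_classifier(matrix, labels, folds, model)
            assert 0.0 <= rep.pooled["accuracy"] <= 100.0

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            cls.make_model("transformer")

    def test_report_markdown_row_order(self):
        matrix, labels, groups = toy_cohort()
        folds = cls.grouped_kfold(groups, k=5, seed=0, labels=labels)
        rep = cls.evaluate_classifier(matrix, labels, folds, "svm")
        md = rep.as_markdown()
        order = [md.index(key) for key in
                 ("Accuracy", "Sensitivity", "Specificity", "PPV", "NPV")]
        assert order == sorted(order)


class TestTrainOnlyNormalization:
    def test_bounds_come_from_train_rows_only(self):
        # an extreme outlier in the test fold must not shift training bounds
        x = np.array([[0.0], [1.0], [2.0], [100.0]])
        lo, hi = cls._train_bounds(x[:3])
        assert hi[0] == 2.0
        scaled = cls._apply_bounds(x[3:], lo, hi)
        assert scaled[0, 0] == pytest.approx(50.0)  # unclipped extrapolation

    def test_degenerate_span_maps_to_zero(self):
        x = np.array([[5.0], [5.0]])
        lo, hi = cls._train_bounds(x)
        out = cls._apply_bounds(x, lo, hi)
        np.testing.assert_allclose(out, 0.0)


class TestScreeningAndSearch:
    def test_screen_keeps_informative_features_only(self):
        matrix, labels, groups = toy_cohort(separation=5.0)
        folds = cls.grouped_kfold(groups, k=5, seed=0, labels=labels)
        screened = cls.screen_features(matrix, labels, folds, threshold=75.0)
        assert "f_one" in screened and "f_two" in screened
        assert "noise" not in screened
        assert all(acc > 75.0 for acc in screened.values())

    def test_combination_search_planted_pair_ranks_first(self):
        matrix, labels, groups = toy_cohort(separation=2.0, seed=3)
        folds = cls.grouped_kfold(groups, k=5, seed=0, labels=labels)
        results = cls.combination_search(matrix, labels, folds,
                                         ["f_one", "f_two", "noise"],
                                         sizes=(2, 3))
        best = results[-1]
        assert set(best.features) == {"f_one", "f_two"}
        # appending the noise feature never helps
        by_set = {r.features: r.accuracy for r in results}
        assert by_set[("f_one", "f_two", "noise")] <= best.accuracy
        assert [r.rank for r in results] == list(range(len(results)))

    def test_search_order_invariant_to_input_order(self):
        matrix, labels, groups = toy_cohort(separation=4.0, seed=2)
        folds = cls.grouped_kfold(groups, k=5, seed=0, labels=labels)
        a = cls.combination_search(matrix, labels, folds,
                                   ["f_one", "f_two", "noise"], sizes=(2,))
        b = cls.combination_search(matrix, labels, folds,
                                   ["noise", "f_two", "f_one"], sizes=(2,))
        assert [r.features for r in a] == [r.features for r in b]

    def test_empty_screen_rejected(self):
        matrix, labels, groups = toy_cohort()
        folds = cls.grouped_kfold(groups, k=5, seed=0, labels=labels)
        with pytest.raises(ValueError):
            cls.combination_search(matrix, labels, folds, [])

    def test_incremental_curve_monotone_feature_count(self):
        matrix, labels, groups = toy_cohort(separation=4.0)
        folds = cls.grouped_kfold(groups, k=5, seed=0, labels=labels)
        curve = cls.incremental_feature_curve(matrix, labels, folds,
                                              ["f_one", "f_two", "noise"])
        assert [n for n, _ in curve] == [1, 2, 3]


class TestExternalValidation:
    def test_fit_on_train_score_on_validation(self):
        train_m, train_y, _ = toy_cohort(separation=5.0, seed=3)
        val_m, val_y, _ = toy_cohort(n_per_class=10, separation=5.0, seed=4)
        rep = cls.validate_external(train_m, train_y, val_m, val_y)
        assert rep.n == 20
        assert rep.pooled["accuracy"] > 80.0

    def test_missing_validation_feature_rejected(self):
        train_m, train_y, _ = toy_cohort(seed=3)
        val_m, val_y, _ = toy_cohort(n_per_class=5, seed=4)
        val_m = ft.FeatureMatrix(val_m.values[["f_one"]])
        with pytest.raises(KeyError):
            cls.validate_external(train_m, train_y, val_m, val_y)

    def test_empty_validation_rejected(self):
        train_m, train_y, _ = toy_cohort(seed=3)
        empty = ft.FeatureMatrix(pd.DataFrame(columns=["f_one", "f_two", "noise"],
                                              dtype=float))
        with pytest.raises(ValueError):
            cls.validate_external(train_m, train_y, empty, np.array([]))
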