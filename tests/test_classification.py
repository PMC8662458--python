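"""Metric suite, ROC/AUC oracle equivalence, classifier contracts, CV protocol."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from collateralis.classification import (
    ModelSpec,
    confusion_metrics,
    crossvalidate,
    holdout_evaluate,
    roc_auc,
    train,
)


def _mann_whitney_auc(scores, labels):
    """Exhaustive pairwise concordance count with half-credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    def test_perfect_classifier(self):
        m = confusion_metrics(50, 50, 0, 0)
        assert all(m[k] == 100.0 for k in ("sensitivity", "specificity", "accuracy", "precision", "f_measure"))

    def test_hand_arithmetic_fixture(self):
        m = confusion_metrics(50, 40, 10, 0)
        assert m["sensitivity"] == pytest.approx(100.0)
        assert m["specificity"] == pytest.approx(80.0)
        assert m["precision"] == pytest.approx(83.3333, abs=1e-3)
        assert m["accuracy"] == pytest.approx(90.0)
        assert m["f_measure"] == pytest.approx(90.9091, abs=1e-3)

    def test_undefined_precision_reported_missing_not_zero(self):
        m = confusion_metrics(0, 10, 0, 5)
        assert math.isnan(m["precision"])
        assert m["specificity"] == 100.0

    def test_recall_is_sensitivity(self):
        m = confusion_metrics(7, 3, 2, 4)
        assert m["recall"] == m["sensitivity"]

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert auc == 1.0

    def test_label_inversion_symmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, size=30)
        if len(set(labels)) < 2:
            labels[0], labels[1] = 0, 1
        _, auc = roc_auc(scores, labels)
        _, auc_inv = roc_auc(scores, 1 - labels)
        assert auc_inv == pytest.approx(1.0 - auc)

    def test_six_point_fixture_equals_eight_ninths(self):
        scores = [0.9, 0.8, 0.7, 0.6, 0.5, 0.4]
        labels = [1, 1, 0, 1, 0, 0]
        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(8 / 9)
        assert auc == pytest.approx(_mann_whitney_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_starts_at_origin_ends_at_one(self, rng):
        points, _ = roc_auc(rng.normal(size=20), [0, 1] * 10)
        assert points[0] == (0.0, 0.0)
        assert points[-1] == (1.0, 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 5), min_size=4, max_size=30))
    def test_threshold_sweep_equals_mann_whitney(self, score_ints):
        labels = [i % 2 for i in range(len(score_ints))]
        _, auc = roc_auc(np.array(score_ints, dtype=float), labels)
        assert auc == pytest.approx(_mann_whitney_auc(score_ints, labels))

    def test_matches_sklearn_cross_check(self, rng):
        scores = rng.normal(size=50)
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        from sklearn.metrics import roc_auc_score

        _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores))


def _toy_table(rng, n=40, separation=5.0):
    X0 = rng.normal(size=(n // 2, 2))
    X1 = rng.normal(size=(n // 2, 2)) + separation
    df = pd.DataFrame(np.vstack([X0, X1]), columns=["f1", "f2"])
    df["label"] = [0] * (n // 2) + [1] * (n // 2)
    return df


class TestTrain:
    @pytest.mark.parametrize("kind", ["svm_poly3", "decision_tree", "random_forest", "knn"])
    def test_separable_data_trains_perfectly(self, rng, kind):
        table = _toy_table(rng)
        model = train(table, ModelSpec(kind=kind, seed=0), feature_columns=["f1", "f2"])
        X = table[["f1", "f2"]].to_numpy()
        assert np.array_equal(model.predict(X), table["label"].to_numpy())

    def test_deterministic_under_seed(self, rng):
        table = _toy_table(rng, separation=1.0)
        X = table[["f1", "f2"]].to_numpy()
        m1 = train(table, ModelSpec(kind="random_forest", seed=7), feature_columns=["f1", "f2"])
        m2 = train(table, ModelSpec(kind="random_forest", seed=7), feature_columns=["f1", "f2"])
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_knn_tie_broken_toward_nearer_neighbor(self):
        # query at x=1: neighbors at x=0 (class 0, d=1) and x=3 (class 1, d=2)
        table = pd.DataFrame(
            {"f1": [0.0, 3.0, 100.0, 103.0], "f2": [0.0, 0.0, 50.0, 50.0], "label": [0, 1, 0, 1]}
        )
        model = train(table, ModelSpec(kind="knn", seed=0), feature_columns=["f1", "f2"])
        assert model.predict([[1.0, 0.0]])[0] == 0
        # symmetric query nearer the class-1 sample
        assert model.predict([[2.5, 0.0]])[0] == 1

    def test_missing_values_rejected_naming_columns(self, rng):
        table = _toy_table(rng)
        table.loc[0, "f2"] = np.nan
        with pytest.raises(ValueError, match="f2"):
            train(table, ModelSpec(kind="knn"), feature_columns=["f1", "f2"])

    def test_single_class_rejected(self, rng):
        table = _toy_table(rng)
        table["label"] = 1
        with pytest.raises(ValueError, match="each class"):
            train(table, ModelSpec(), feature_columns=["f1", "f2"])


class TestCrossvalidate:
    def test_every_sample_predicted_once(self, rng):
        table = _toy_table(rng, n=100)
        report = crossvalidate(table, ModelSpec(kind="decision_tree", seed=0), k=10,
                               feature_columns=["f1", "f2"])
        assert report.tp + report.tn + report.fp + report.fn == 100
        assert len(report.fold_accuracies) == 10

    def test_row_order_invariance(self, rng):
        table = _toy_table(rng, n=60, separation=1.5)
        spec = ModelSpec(kind="svm_poly3", seed=3)
        r1 = crossvalidate(table, spec, k=5, feature_columns=["f1", "f2"])
        shuffled = table.sample(frac=1.0, random_state=9).reset_index(drop=True)
        r2 = crossvalidate(shuffled, spec, k=5, feature_columns=["f1", "f2"])
        assert (r1.tp, r1.tn, r1.fp, r1.fn) == (r2.tp, r2.tn, r2.fp, r2.fn)
        assert r1.auc == r2.auc

    def test_permuted_labels_give_chance_accuracy(self):
        """40 noise features + random labels: pooled accuracy in [35, 65]."""
        for seed in range(5):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(rng.normal(size=(100, 40)), columns=[f"n{i}" for i in range(40)])
            df["label"] = rng.permutation([0] * 50 + [1] * 50)
            report = crossvalidate(df, ModelSpec(kind="svm_poly3", seed=seed), k=10,
                                   feature_columns=[f"n{i}" for i in range(40)])
            assert 35.0 <= report.metrics["accuracy"] <= 65.0

    def test_metric_identities_hold_on_reports(self, rng):
        table = _toy_table(rng, n=60, separation=1.0)
        report = crossvalidate(table, ModelSpec(kind="knn", seed=0), k=5,
                               feature_columns=["f1", "f2"])
        m = report.metrics
        assert m["recall"] == m["sensitivity"]
        fpr = 100.0 * report.fp / (report.fp + report.tn)
        assert fpr == pytest.approx(100.0 - m["specificity"])
        prevalence = (report.tp + report.fn) / 60
        blended = prevalence * m["sensitivity"] + (1 - prevalence) * m["specificity"]
        assert m["accuracy"] == pytest.approx(blended)


class TestHoldout:
    def test_degenerate_test_equals_train_metrics(self, rng):
        table = _toy_table(rng)
        spec = ModelSpec(kind="decision_tree", seed=0)
        report = holdout_evaluate(table, table, spec, feature_columns=["f1", "f2"])
        model = train(table, spec, feature_columns=["f1", "f2"])
        X, y = table[["f1", "f2"]].to_numpy(), table["label"].to_numpy()
        train_acc = 100.0 * np.mean(model.predict(X) == y)
        assert report.metrics["accuracy"] == pytest.approx(train_acc)

    def test_empty_test_table_rejected(self, rng):
        table = _toy_table(rng)
        with pytest.raises(ValueError, match="empty"):
            holdout_evaluate(table, table.iloc[0:0], ModelSpec(), feature_columns=["f1", "f2"])

    def test_schema_mismatch_rejected(self, rng):
        table = _toy_table(rng)
        other = table.rename(columns={"f2": "g2"})
        with pytest.raises(ValueError, match="schema"):
            holdout_evaluate(table, other, ModelSpec())

    def test_holdout_consistent_with_cv_on_phantom_tables(self, pipeline_run):
        """SVM holdout accuracy within 10 points of its 10-fold estimate."""
        import json

        _, _, out_dir = pipeline_run
        results = json.loads((out_dir / "stage7_classify" / "evaluation.json").read_text())
        block = results["glcm_svm_poly3"]
        assert abs(block["cv"]["metrics"]["accuracy"] - block["holdout"]["metrics"]["accuracy"]) <= 10.0
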