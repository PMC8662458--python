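"""Classifier training and evaluation for collateral-vs-normal vessel patches.

Four classifiers are compared: a degree-3 polynomial-kernel SVM, a decision
tree capped at 100 splits, a random forest sampling half the features at
each split, and a k=2 nearest-neighbour model (Euclidean, with 1-1 ties
resolved toward the nearer neighbour).  SVM and KNN operate on z-scored
features (statistics learned from the training folds only).  Evaluation
pools out-of-fold predictions from stratified 10-fold cross-validation
(with per-fold accuracies retained), or fits on a training table and scores
a disjoint holdout.  The metric suite reports sensitivity, specificity,
accuracy, precision, recall and F-measure as percentages, plus an ROC curve
and its trapezoidal AUC; undefined ratios are reported as NaN, never 0.

The positive class throughout is 1 = collateral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES

__all__ = [
    "ModelSpec",
    "EvalReport",
    "FittedModel",
    "confusion_metrics",
    "roc_auc",
    "train",
    "crossvalidate",
    "holdout_evaluate",
    "MODEL_KINDS",
]

MODEL_KINDS = ("svm_poly3", "decision_tree", "random_forest", "knn")


@dataclass
class ModelSpec:
    """Classifier kind and the fixed hyperparameters of the comparison."""

    kind: str = "svm_poly3"
    svm_degree: int = 3
    max_splits: int = 100
    n_trees: int = 100
    knn_k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"kind must be one of {MODEL_KINDS}, got {self.kind!r}")
        if self.svm_degree < 1 or self.knn_k < 1 or self.n_trees < 1 or self.max_splits < 1:
            raise ValueError("hyperparameters must be >= 1")

    @property
    def standardize(self) -> bool:
        return self.kind in ("svm_poly3", "knn")


def _build_estimator(spec: ModelSpec, n_features: int):
    if spec.kind == "svm_poly3":
        core = SVC(kernel="poly", degree=spec.svm_degree, random_state=spec.seed)
    elif spec.kind == "decision_tree":
        # a binary tree with max_leaf_nodes = max_splits + 1 has at most max_splits splits
        core = DecisionTreeClassifier(max_leaf_nodes=spec.max_splits + 1, random_state=spec.seed)
    elif spec.kind == "random_forest":
        core = RandomForestClassifier(
            n_estimators=spec.n_trees,
            max_features=math.ceil(n_features / 2),
            random_state=spec.seed,
        )
    else:  # knn: distance weighting realises the nearer-neighbour tie-break at k=2
        core = KNeighborsClassifier(n_neighbors=spec.knn_k, metric="euclidean", weights="distance")
    if spec.standardize:
        return Pipeline([("scale", StandardScaler()), ("model", core)])
    return core


@dataclass
class FittedModel:
    """A trained estimator plus the feature columns it was fitted on."""

    estimator: object
    spec: ModelSpec
    feature_columns: tuple[str, ...]

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(np.asarray(X, dtype=float)))

    def scores(self, X) -> np.ndarray:
        """Continuous score for ROC: SVM decision value, else positive-class proportion."""
        X = np.asarray(X, dtype=float)
        if self.spec.kind == "svm_poly3":
            return np.asarray(self.estimator.decision_function(X), dtype=float)
        proba = self.estimator.predict_proba(X)
        classes = (
            self.estimator.classes_
            if not isinstance(self.estimator, Pipeline)
            else self.estimator[-1].classes_
        )
        return np.asarray(proba[:, list(classes).index(1)], dtype=float)


@dataclass
class EvalReport:
    """Confusion counts, percentage metrics, ROC points and AUC."""

    tp: int
    tn: int
    fp: int
    fn: int
    metrics: dict[str, float]
    roc_points: list[tuple[float, float]]
    auc: float
    fold_accuracies: list[float] | None = None
    model: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.auc <= 1.0:
            raise ValueError(f"AUC out of range: {self.auc}")
        for name, v in self.metrics.items():
            if not math.isnan(v) and not 0.0 <= v <= 100.0:
                raise ValueError(f"metric {name} out of range: {v}")


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Percentage metrics from confusion counts; undefined ratios become NaN.

    recall is sensitivity by definition; the F-measure is the harmonic mean
    of precision and recall.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("all confusion counts are zero")

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else math.nan

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    prec = ratio(tp, tp + fp)
    acc = ratio(tp + tn, total)
    if math.isnan(prec) or math.isnan(sens) or prec + sens == 0:
        f_measure = math.nan
    else:
        f_measure = 2 * prec * sens / (prec + sens)
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "precision": prec,
        "recall": sens,
        "f_measure": f_measure,
    }


def roc_auc(scores, labels) -> tuple[list[tuple[float, float]], float]:
    """ROC points (FPR, TPR) from a threshold sweep and the trapezoidal AUC.

    Tied scores are grouped at a single threshold; TPR = TP/(TP+FN) and
    FPR = FP/(FP+TN) = 1 - specificity.  Equals the normalized Mann-Whitney
    pair count (ties credited 1/2) exactly.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    p_sorted = pos[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            tp += int(p_sorted[j])
            fp += int(not p_sorted[j])
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    xs, ys = zip(*points)
    auc = float(min(max(np.trapezoid(ys, xs), 0.0), 1.0))  # clamp fp round-off
    return points, auc


def _design(table: pd.DataFrame, feature_columns: Sequence[str] | None):
    if feature_columns is None:
        feature_columns = [c for c in FEATURE_NAMES if c in table.columns]
    missing = [c for c in feature_columns if c not in table.columns]
    if missing:
        raise ValueError(f"feature columns missing from table: {missing}")
    X = table[list(feature_columns)].to_numpy(dtype=float)
    bad = [c for c, has_nan in zip(feature_columns, np.isnan(X).any(axis=0)) if has_nan]
    if bad:
        raise ValueError(f"missing feature values in columns: {bad}")
    y = table["label"].to_numpy(dtype=int)
    return X, y, tuple(feature_columns)


def train(table: pd.DataFrame, spec: ModelSpec,
          feature_columns: Sequence[str] | None = None) -> FittedModel:
    """Fit one classifier on a feature table; deterministic under the model seed."""
    X, y, cols = _design(table, feature_columns)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 samples of each class")
    est = _build_estimator(spec, X.shape[1])
    est.fit(X, y)
    return FittedModel(estimator=est, spec=spec, feature_columns=cols)


def _pooled_report(y, pred, scores, spec, fold_accuracies=None) -> EvalReport:
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    points, auc = roc_auc(scores, y)
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        metrics=confusion_metrics(tp, tn, fp, fn),
        roc_points=points,
        auc=auc,
        fold_accuracies=fold_accuracies,
        model={"kind": spec.kind, "seed": spec.seed},
    )


def crossvalidate(table: pd.DataFrame, spec: ModelSpec, k: int = 10,
                  seed: int | None = None,
                  feature_columns: Sequence[str] | None = None) -> EvalReport:
    """Stratified k-fold CV with metrics pooled over out-of-fold predictions.

    Rows are brought into a canonical order (lexsort over label and
    features) before folding, so the result is invariant to row order.
    """
    from sklearn.model_selection import StratifiedKFold

    X, y, cols = _design(table, feature_columns)
    if len(y) < k:
        raise ValueError(f"need at least {k} samples for {k}-fold CV")
    seed = spec.seed if seed is None else seed
    canon = np.lexsort(tuple(X[:, a] for a in range(X.shape[1] - 1, -1, -1)) + (y,))
    Xc, yc = X[canon], y[canon]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    pred = np.empty(len(yc), dtype=int)
    scores = np.empty(len(yc), dtype=float)
    fold_accuracies = []
    for train_idx, test_idx in skf.split(Xc, yc):
        if len(np.unique(yc[train_idx])) < 2:
            raise ValueError("a class is absent from a training fold")
        est = _build_estimator(spec, Xc.shape[1])
        est.fit(Xc[train_idx], yc[train_idx])
        fm = FittedModel(est, spec, cols)
        pred[test_idx] = fm.predict(Xc[test_idx])
        scores[test_idx] = fm.scores(Xc[test_idx])
        fold_accuracies.append(float(np.mean(pred[test_idx] == yc[test_idx])) * 100.0)
    return _pooled_report(yc, pred, scores, spec, fold_accuracies)


def holdout_evaluate(train_table: pd.DataFrame, test_table: pd.DataFrame, spec: ModelSpec,
                     feature_columns: Sequence[str] | None = None) -> EvalReport:
    """Fit on the training table and evaluate the same metric suite on a holdout."""
    if len(test_table) == 0:
        raise ValueError("empty test table")
    if list(train_table.columns) != list(test_table.columns):
        raise ValueError("train/test schema mismatch")
    model = train(train_table, spec, feature_columns)
    X, y, _ = _design(test_table, model.feature_columns)
    return _pooled_report(y, model.predict(X), model.scores(X), spec)
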