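"""Patient-grouped cross-validated classification and feature-set exploration.

All evaluation is leakage-free: folds are patient-atomic (every recording of a
patient shares a fold), feature min-max normalization bounds are fit on the
training folds only, and validation cohorts never refit anything. PD is the
positive class for sensitivity/PPV (configurable).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .features import FeatureMatrix

__all__ = [
    "FoldAssignment",
    "ClassifierReport",
    "CombinationResult",
    "grouped_kfold",
    "confusion_metrics",
    "accuracy",
    "evaluate_classifier",
    "univariate_feature_accuracy",
    "screen_features",
    "combination_search",
    "incremental_feature_curve",
    "length_ablation",
    "validate_external",
    "make_model",
]


@dataclass
class FoldAssignment:
    """Patient-atomic fold index per recording."""

    fold: np.ndarray           # int fold per recording
    k: int
    groups: np.ndarray         # patient id per recording

    def __post_init__(self) -> None:
        self.fold = np.asarray(self.fold)
        self.groups = np.asarray(self.groups)
        for g in np.unique(self.groups):
            folds = np.unique(self.fold[self.groups == g])
            if folds.shape[0] != 1:
                raise ValueError(f"patient {g!r} split across folds {folds}")


def grouped_kfold(
    groups: Sequence, k: int = 10, seed: int = 0, labels: Sequence | None = None
) -> FoldAssignment:
    """Deterministic patient-atomic k-fold split, stratified by label when given.

    Patients (not recordings) are shuffled with the seed and dealt into folds;
    with labels, the deal happens per class so each fold sees both diagnoses
    whenever patient counts allow.
    """
    groups = np.asarray(groups)
    patients = pd.unique(groups)
    if patients.shape[0] < k:
        raise ValueError(f"fewer patients ({patients.shape[0]}) than folds ({k})")
    rng = np.random.default_rng(seed)

    patient_label: dict = {}
    if labels is not None:
        labels = np.asarray(labels)
        for p in patients:
            patient_label[p] = labels[groups == p][0]
        classes = pd.unique(np.asarray(list(patient_label.values())))
    else:
        classes = np.array([None])

    fold_of: dict = {}
    offset = 0
    for c in classes:
        cls_patients = [p for p in patients if labels is None or patient_label[p] == c]
        order = rng.permutation(len(cls_patients))
        for j, idx in enumerate(order):
            fold_of[cls_patients[idx]] = (j + offset) % k
        offset += len(cls_patients)  # rotate start so fold sizes stay balanced
    fold = np.array([fold_of[g] for g in groups])
    return FoldAssignment(fold=fold, k=k, groups=groups)


def confusion_metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Accuracy, balanced accuracy, sensitivity, specificity, PPV, NPV in percent."""
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion counts")
    def pct(num, den):
        return 100.0 * num / den if den > 0 else float("nan")
    sens = pct(tp, tp + fn)
    spec = pct(tn, tn + fp)
    return {
        "accuracy": pct(tp + tn, total),
        "balanced_accuracy": (sens + spec) / 2.0 if np.isfinite(sens) and np.isfinite(spec)
        else float("nan"),
        "sensitivity": sens,
        "specificity": spec,
        "ppv": pct(tp, tp + fp),
        "npv": pct(tn, tn + fn),
    }


def accuracy(n_correct: int, n_total: int) -> float:
    """Plain classification accuracy in percent: 100 x correct / total."""
    if n_total <= 0:
        raise ValueError("empty classification")
    return 100.0 * n_correct / n_total


@dataclass
class ClassifierReport:
    model: str
    features: tuple[str, ...]
    positive_class: str
    confusion: dict[str, int]           # pooled tp/fn/tn/fp over folds
    pooled: dict[str, float]
    per_fold: list[dict[str, float]]
    seed: int
    n: int
    warnings_: list[str] = field(default_factory=list)

    def as_markdown(self) -> str:
        rows = ["| Parameter | % |", "| --- | --- |"]
        for name in ("accuracy", "sensitivity", "specificity", "ppv", "npv"):
            rows.append(f"| {name.upper() if len(name) <= 3 else name.capitalize()} "
                        f"| {self.pooled[name]:.1f} |")
        return "\n".join(rows)


def make_model(model: str, seed: int = 0):
    """Factory for the three compared classifiers (features pre-scaled to [0,1])."""
    if model in ("svm", "linear-svm"):
        return SVC(kernel="linear", C=1.0)
    if model in ("logistic", "logistic-regression"):
        return LogisticRegression(max_iter=2000)
    if model in ("rf", "random-forest"):
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    raise ValueError(f"unknown model {model!r}")


def _train_bounds(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return x.min(axis=0), x.max(axis=0)


def _apply_bounds(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = np.where(hi > lo, hi - lo, 1.0)
    return (x - lo) / span


def evaluate_classifier(
    matrix: FeatureMatrix,
    labels: Sequence,
    folds: FoldAssignment,
    model: str = "svm",
    *,
    feature_subset: Sequence[str] | None = None,
    positive_class: str = "PD",
    seed: int = 0,
) -> ClassifierReport:
    """Per-fold fit/predict with train-fold-only normalization; pooled metrics.

    ``matrix`` holds raw (un-normalized) feature values; each fold's min-max
    bounds are fit on its training rows only, so no test information leaks into
    scaling. Single-class training folds are skipped with a warning.
    """
    names = list(feature_subset) if feature_subset is not None else matrix.feature_names
    x_all = matrix.values[names].to_numpy(dtype=float)
    valid = matrix.valid[names].all(axis=1).to_numpy()
    labels = np.asarray(labels)
    if not np.all(valid):
        warnings.warn(f"{np.count_nonzero(~valid)} recordings with invalid features excluded",
                      stacklevel=2)
    y_true_all, y_pred_all = [], []
    per_fold = []
    warn_log: list[str] = []
    for f in range(folds.k):
        test = (folds.fold == f) & valid
        train = (folds.fold != f) & valid
        if not np.any(test):
            continue
        y_train = labels[train]
        if np.unique(y_train).shape[0] < 2:
            warn_log.append(f"fold {f}: single-class training data; fold skipped")
            continue
        lo, hi = _train_bounds(x_all[train])
        clf = make_model(model, seed)
        clf.fit(_apply_bounds(x_all[train], lo, hi), y_train)
        pred = clf.predict(_apply_bounds(x_all[test], lo, hi))
        y_true_all.append(labels[test])
        y_pred_all.append(pred)
        tp = int(np.sum((labels[test] == positive_class) & (pred == positive_class)))
        fn = int(np.sum((labels[test] == positive_class) & (pred != positive_class)))
        tn = int(np.sum((labels[test] != positive_class) & (pred != positive_class)))
        fp = int(np.sum((labels[test] != positive_class) & (pred == positive_class)))
        try:
            per_fold.append(confusion_metrics(tp, fn, tn, fp))
        except ValueError:
            pass
    if not y_true_all:
        raise ValueError("no evaluable folds")
    y_true = np.concatenate(y_true_all)
    y_pred = np.concatenate(y_pred_all)
    tp = int(np.sum((y_true == positive_class) & (y_pred == positive_class)))
    fn = int(np.sum((y_true == positive_class) & (y_pred != positive_class)))
    tn = int(np.sum((y_true != positive_class) & (y_pred != positive_class)))
    fp = int(np.sum((y_true != positive_class) & (y_pred == positive_class)))
    return ClassifierReport(
        model=model, features=tuple(names), positive_class=positive_class,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        pooled=confusion_metrics(tp, fn, tn, fp),
        per_fold=per_fold, seed=seed, n=int(y_true.shape[0]), warnings_=warn_log,
    )


def univariate_feature_accuracy(
    matrix: FeatureMatrix, labels: Sequence, folds: FoldAssignment,
    feature: str, model: str = "svm", seed: int = 0,
) -> float:
    """Cross-validated accuracy (percent) of one feature alone."""
    report = evaluate_classifier(matrix, labels, folds, model,
                                 feature_subset=[feature], seed=seed)
    return report.pooled["accuracy"]


def screen_features(
    matrix: FeatureMatrix, labels: Sequence, folds: FoldAssignment,
    threshold: float = 75.0, model: str = "svm", seed: int = 0,
) -> dict[str, float]:
    """Features whose univariate CV accuracy strictly exceeds the threshold (%)."""
    out = {}
    for name in matrix.feature_names:
        try:
            acc = univariate_feature_accuracy(matrix, labels, folds, name, model, seed)
        except ValueError:
            continue
        if acc > threshold:
            out[name] = acc
    return out


@dataclass
class CombinationResult:
    features: tuple[str, ...]
    accuracy: float
    balanced_accuracy: float
    rank: int = -1


def combination_search(
    matrix: FeatureMatrix, labels: Sequence, folds: FoldAssignment,
    screened: Sequence[str], sizes: Iterable[int] = (2, 3, 4),
    model: str = "svm", seed: int = 0,
) -> list[CombinationResult]:
    """Exhaustive CV evaluation of all feature tuples of the given sizes.

    Results are sorted ascending by accuracy (worst to best) and ranked;
    order of the input feature list does not affect the outcome.
    """
    screened = sorted(screened)
    if not screened:
        raise ValueError("screened feature set is empty")
    results = []
    for size in sizes:
        for combo in itertools.combinations(screened, size):
            rep = evaluate_classifier(matrix, labels, folds, model,
                                      feature_subset=list(combo), seed=seed)
            results.append(CombinationResult(
                features=combo, accuracy=rep.pooled["accuracy"],
                balanced_accuracy=rep.pooled["balanced_accuracy"],
            ))
    results.sort(key=lambda r: (r.accuracy, r.features))
    for i, r in enumerate(results):
        r.rank = i
    return results


def incremental_feature_curve(
    matrix: FeatureMatrix, labels: Sequence, folds: FoldAssignment,
    ranked_features: Sequence[str], max_n: int = 10,
    model: str = "svm", seed: int = 0,
) -> list[tuple[int, float]]:
    """CV accuracy of the top-1..top-n feature stacks (n strictly increasing)."""
    curve = []
    for n in range(1, min(max_n, len(ranked_features)) + 1):
        rep = evaluate_classifier(matrix, labels, folds, model,
                                  feature_subset=list(ranked_features[:n]), seed=seed)
        curve.append((n, rep.pooled["accuracy"]))
    return curve


def length_ablation(
    lengths: Sequence[float],
    feature_fn: Callable[[float], tuple[FeatureMatrix, np.ndarray, np.ndarray]],
    *,
    k: int = 10,
    model: str = "svm",
    seed: int = 0,
) -> dict[float, float | None]:
    """Balanced CV accuracy per segment length.

    ``feature_fn(length)`` re-runs the full pipeline on truncations of the same
    series, returning (features, labels, patient groups). Lengths too short for
    model fitting are marked invalid (None) and the run continues.
    """
    out: dict[float, float | None] = {}
    for length in lengths:
        try:
            matrix, labels, groups = feature_fn(length)
            folds = grouped_kfold(groups, k=k, seed=seed, labels=labels)
            rep = evaluate_classifier(matrix, labels, folds, model, seed=seed)
            out[length] = rep.pooled["balanced_accuracy"]
        except (ValueError, RuntimeError):
            out[length] = None
    return out


def validate_external(
    train_matrix: FeatureMatrix, train_labels: Sequence,
    val_matrix: FeatureMatrix, val_labels: Sequence,
    model: str = "svm", positive_class: str = "PD", seed: int = 0,
) -> ClassifierReport:
    """Fit bounds + model on the exploratory cohort only; score a held-out cohort."""
    val_labels = np.asarray(val_labels)
    if val_labels.shape[0] == 0:
        raise ValueError("empty validation set")
    names = train_matrix.feature_names
    missing = [n for n in names if n not in val_matrix.feature_names]
    if missing:
        raise KeyError(f"features missing in validation set: {missing}")
    x_train = train_matrix.values[names].to_numpy(dtype=float)
    x_val = val_matrix.values[names].to_numpy(dtype=float)
    lo, hi = _train_bounds(x_train)
    clf = make_model(model, seed)
    clf.fit(_apply_bounds(x_train, lo, hi), np.asarray(train_labels))
    pred = clf.predict(_apply_bounds(x_val, lo, hi))
    tp = int(np.sum((val_labels == positive_class) & (pred == positive_class)))
    fn = int(np.sum((val_labels == positive_class) & (pred != positive_class)))
    tn = int(np.sum((val_labels != positive_class) & (pred != positive_class)))
    fp = int(np.sum((val_labels != positive_class) & (pred == positive_class)))
    return ClassifierReport(
        model=model, features=tuple(names), positive_class=positive_class,
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        pooled=confusion_metrics(tp, fn, tn, fp),
        per_fold=[], seed=seed, n=int(val_labels.shape[0]),
    )
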