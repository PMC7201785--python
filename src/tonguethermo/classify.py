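"""Classifier training, cross-validation, and screening metrics.

Three classifiers discriminate normal from diabetic subjects: a linear
soft-margin SVM and a Gaussian naive Bayes model on the tabular feature
vector (anthropometrics, blood pressure, mean tongue-ROI temperature and the
ten texture features), and a VGG-style convolutional network fed the
thermogram images directly (see :mod:`tonguethermo.cnn`).  Evaluation is
stratified 10-fold cross-validation with held-out predictions pooled into a
single confusion matrix, from which the screening metrics — sensitivity,
specificity, accuracy, PPV, NPV — are computed exactly, and ROC/AUC by
threshold sweep over the decision scores.

Percentages are reported truncated (not rounded) to two decimals, matching
the convention of the reference study's tables; the rounding mode is
config-exposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "CVConfig",
    "ConfusionMatrix",
    "ClassifierMetrics",
    "fit_svm_linear",
    "fit_nb_gaussian",
    "crossvalidate",
    "metrics_from_confusion",
    "roc_auc",
    "MODEL_FACTORIES",
]

POSITIVE, NEGATIVE = 1, -1  # +1 = diabetic, -1 = normal


@dataclass(frozen=True)
class CVConfig:
    """k-fold cross-validation settings (stratified, seeded shuffle)."""

    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("need at least 2 folds")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; positive class = diabetic."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == POSITIVE) & (y_pred == POSITIVE))),
            fp=int(np.sum((y_true == NEGATIVE) & (y_pred == POSITIVE))),
            tn=int(np.sum((y_true == NEGATIVE) & (y_pred == NEGATIVE))),
            fn=int(np.sum((y_true == POSITIVE) & (y_pred == NEGATIVE))),
        )


@dataclass(frozen=True)
class ClassifierMetrics:
    """Screening metrics in percent (AUC on [0, 1] when available).

    ``undefined`` names metrics whose denominator was zero; they carry NaN.
    """

    sensitivity: float
    specificity: float
    accuracy: float
    ppv: float
    npv: float
    auc: float = float("nan")
    undefined: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "ppv": self.ppv,
            "npv": self.npv,
            "auc": self.auc,
        }


def _percent(num: int, den: int, rounding: str) -> float:
    """Exact ratio to percent with truncation or rounding to 2 decimals."""
    frac = Fraction(num, den) * 10000
    if rounding == "truncate":
        return int(frac) / 100.0
    if rounding == "round":
        return round(float(frac)) / 100.0
    if rounding == "none":
        return float(Fraction(num, den) * 100)
    raise ValueError(f"unknown rounding mode {rounding!r}")


def metrics_from_confusion(cm: ConfusionMatrix, rounding: str = "truncate") -> ClassifierMetrics:
    """The five screening metrics from confusion counts.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/total, PPV = TP/(TP+FP), NPV = TN/(TN+FN),
    each as a percentage.  Zero denominators are flagged, not NaN-propagated
    through arithmetic.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    spec = {
        "sensitivity": (cm.tp, cm.tp + cm.fn),
        "specificity": (cm.tn, cm.tn + cm.fp),
        "accuracy": (cm.tp + cm.tn, cm.total),
        "ppv": (cm.tp, cm.tp + cm.fp),
        "npv": (cm.tn, cm.tn + cm.fn),
    }
    values: dict[str, float] = {}
    undefined: set[str] = set()
    for name, (num, den) in spec.items():
        if den == 0:
            values[name] = float("nan")
            undefined.add(name)
        else:
            values[name] = _percent(num, den, rounding)
    return ClassifierMetrics(**values, undefined=frozenset(undefined))


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")


def fit_svm_linear(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> Pipeline:
    """Soft-margin linear SVM with internal z-score standardization.

    Returns a fitted pipeline exposing ``predict`` (labels in {-1, +1}) and
    ``decision_function`` (signed margin scores).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    model = Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="linear", C=C)),
    ])
    return model.fit(X, y)


class _PriorClassifier:
    """Fallback when every feature is constant: posterior = empirical priors."""

    def fit(self, X, y):
        self.classes_, counts = np.unique(y, return_counts=True)
        self.priors_ = counts / counts.sum()
        return self

    def predict_proba(self, X):
        return np.tile(self.priors_, (len(np.asarray(X)), 1))

    def predict(self, X):
        return np.full(len(np.asarray(X)), self.classes_[self.priors_.argmax()])


def fit_nb_gaussian(X: np.ndarray, y: np.ndarray,
                    var_smoothing: float = 1e-9):
    """Gaussian naive Bayes: class-conditional independent normals + priors.

    Per-class per-feature variances are epsilon-smoothed by
    ``var_smoothing`` times the largest feature variance, so constant
    features degrade to uninformative rather than failing.  A dataset whose
    features are all constant is logged and yields the prior distribution.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    if np.var(X, axis=0).max() == 0.0:
        logging.getLogger("tonguethermo").warning(
            "all features constant; naive Bayes posterior equals the priors")
        return _PriorClassifier().fit(X, y)
    return GaussianNB(var_smoothing=var_smoothing).fit(X, y)


def _decision_scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "decision_function"):
        return np.asarray(model.decision_function(X), dtype=float)
    proba = model.predict_proba(X)
    classes = list(model.classes_)
    return np.asarray(proba[:, classes.index(POSITIVE)], dtype=float)


MODEL_FACTORIES: dict[str, Callable[[np.ndarray, np.ndarray], object]] = {
    "svm": fit_svm_linear,
    "nb": fit_nb_gaussian,
}


@dataclass
class CVResult:
    confusion: ConfusionMatrix
    fold_accuracies: list[float]
    scores: np.ndarray
    y_true: np.ndarray

    @property
    def pooled_accuracy(self) -> float:
        return (self.confusion.tp + self.confusion.tn) / self.confusion.total


def crossvalidate(
    fit: Callable[[np.ndarray, np.ndarray], object] | str,
    X: np.ndarray,
    y: np.ndarray,
    cv: CVConfig = CVConfig(),
) -> CVResult:
    """Stratified k-fold CV with pooled held-out predictions.

    The model (including any internal standardization) is fitted inside each
    training fold only, so no statistics leak from the held-out fold.
    Predictions across all held-out folds are pooled into one confusion
    matrix; per-fold accuracies and pooled decision scores are also returned.
    """
    if isinstance(fit, str):
        fit = MODEL_FACTORIES[fit]
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    minority = min(np.sum(y == POSITIVE), np.sum(y == NEGATIVE))
    if cv.stratified and cv.k > minority:
        raise ValueError(
            f"k={cv.k} exceeds the minority class count ({minority})")
    splitter = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    strata = y if cv.stratified else np.zeros_like(y)
    y_pred = np.empty_like(y)
    scores = np.empty(len(y), dtype=float)
    fold_acc = []
    for train_idx, test_idx in splitter.split(X, strata):
        model = fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        y_pred[test_idx] = pred
        scores[test_idx] = _decision_scores(model, X[test_idx])
        fold_acc.append(float(np.mean(pred == y[test_idx])))
    return CVResult(
        confusion=ConfusionMatrix.from_predictions(y, y_pred),
        fold_accuracies=fold_acc,
        scores=scores,
        y_true=y.copy(),
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep and trapezoidal AUC.

    Thresholds run over the unique scores (ties grouped), producing one
    (FPR, TPR) point per distinct score plus the endpoints.  The trapezoidal
    area equals the normalized Mann-Whitney U statistic with ties counted
    half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == POSITIVE
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_pos = pos[order].astype(float)
    # group tied scores so each threshold is a distinct score value
    boundaries = np.nonzero(np.diff(sorted_scores))[0] + 1
    tp_cum = np.cumsum(sorted_pos)
    fp_cum = np.cumsum(1.0 - sorted_pos)
    idx = np.append(boundaries - 1, len(scores) - 1)
    tpr = np.concatenate([[0.0], tp_cum[idx] / n_pos])
    fpr = np.concatenate([[0.0], fp_cum[idx] / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc
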