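"""Classifier evaluation: accuracy with Wilson CI, sensitivity, specificity,
Cohen's kappa, ROC AUC and the class-imbalance ratio.

The positive class is always label 1 (artifact-distorted, informative, or
the situation being recognized).  The imbalance ratio is the majority-class
share of the data set, so it lives in [0.5, 1] and a kappa of 0 at accuracy
equal to the imbalance ratio marks a chance-level majority predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import cohen_kappa_score, confusion_matrix, roc_auc_score
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ClassifierEvaluation",
    "confusion_metrics",
    "roc_auc",
    "imbalance_ratio",
    "evaluate_classifier",
]


@dataclass(frozen=True)
class ClassifierEvaluation:
    accuracy: float
    ci_low: float
    ci_high: float
    sensitivity: float
    specificity: float
    auc: float
    cohens_kappa: float
    imbalance_ratio: float
    n: int


def _check_binary(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if y.size == 0:
        raise ValueError("empty label array")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary {0, 1}")
    return y


def confusion_metrics(y_true, y_pred) -> dict[str, float]:
    """Accuracy (with 95% Wilson CI), sensitivity, specificity and kappa.

    Sensitivity/specificity are NaN when the corresponding class is absent
    from ``y_true``.
    """
    y_true, y_pred = _check_binary(y_true), _check_binary(y_pred)
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred length mismatch")
    tn, fp, fn, tp = confusion_matrix(y_true, y_pred, labels=[0, 1]).ravel()
    n = y_true.size
    correct = int(tp + tn)
    accuracy = correct / n
    ci_low, ci_high = proportion_confint(correct, n, alpha=0.05, method="wilson")
    sensitivity = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate single-class kappa -> NaN
        kappa = cohen_kappa_score(y_true, y_pred, labels=[0, 1])
    return {
        "accuracy": float(accuracy),
        "ci_low": float(ci_low),
        "ci_high": float(ci_high),
        "sensitivity": float(sensitivity),
        "specificity": float(specificity),
        "cohens_kappa": float(kappa),
        "n": n,
    }


def roc_auc(y_true, decision_values) -> float:
    """Trapezoidal area under the ROC of raw decision values.

    Tied scores are handled by rank averaging, making the result identical
    to the Mann-Whitney U formulation U / (n1 * n0).
    """
    y_true = _check_binary(y_true)
    scores = np.asarray(decision_values, float)
    if np.unique(y_true).size < 2:
        raise ValueError("ROC AUC needs both classes present")
    return float(roc_auc_score(y_true, scores))


def imbalance_ratio(class_counts) -> float:
    """Majority-class count over the total count."""
    counts = np.asarray(class_counts, float)
    if counts.size != 2 or np.any(counts < 0):
        raise ValueError("expected two non-negative class counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("class counts sum to zero")
    return float(counts.max() / total)


def evaluate_classifier(y_true, y_pred, decision_values=None) -> ClassifierEvaluation:
    """One-stop evaluation mirroring the reported model-characteristics table."""
    m = confusion_metrics(y_true, y_pred)
    y = _check_binary(y_true)
    counts = [int(np.sum(y == 0)), int(np.sum(y == 1))]
    auc = float("nan")
    if decision_values is not None and np.unique(y).size == 2:
        auc = roc_auc(y, decision_values)
    return ClassifierEvaluation(
        accuracy=m["accuracy"],
        ci_low=m["ci_low"],
        ci_high=m["ci_high"],
        sensitivity=m["sensitivity"],
        specificity=m["specificity"],
        auc=auc,
        cohens_kappa=m["cohens_kappa"],
        imbalance_ratio=imbalance_ratio(counts),
        n=m["n"],
    )
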