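"""Classification metrics for window-level predictions.

Thin wrappers over scikit-learn: accuracy, macro F1 (unweighted mean of
per-class F1, which amplifies failures on rare classes), weighted F1
(support-weighted mean, which a rare class barely moves), per-class F1 and
the confusion matrix, plus a convenience that bundles them with the
calibration report.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import accuracy_score, confusion_matrix, f1_score

from .calibration import CalibrationReport, reliability_data

__all__ = [
    "accuracy",
    "macro_f1",
    "weighted_f1",
    "per_class_f1",
    "confusion",
    "evaluate_predictions",
]


def accuracy(true_labels, pred_labels) -> float:
    return float(accuracy_score(true_labels, pred_labels))


def macro_f1(true_labels, pred_labels, n_classes: int | None = None) -> float:
    labels = None if n_classes is None else list(range(n_classes))
    return float(
        f1_score(true_labels, pred_labels, labels=labels, average="macro",
                 zero_division=0)
    )


def weighted_f1(true_labels, pred_labels, n_classes: int | None = None) -> float:
    labels = None if n_classes is None else list(range(n_classes))
    return float(
        f1_score(true_labels, pred_labels, labels=labels, average="weighted",
                 zero_division=0)
    )


def per_class_f1(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    return f1_score(
        true_labels, pred_labels, labels=list(range(n_classes)),
        average=None, zero_division=0,
    )


def confusion(true_labels, pred_labels, n_classes: int) -> np.ndarray:
    return confusion_matrix(
        true_labels, pred_labels, labels=list(range(n_classes))
    )


def evaluate_predictions(
    probs: np.ndarray,
    true_labels: np.ndarray,
    n_bins: int = 10,
) -> tuple[dict, CalibrationReport]:
    """All headline metrics for one set of probabilistic predictions.

    Returns a metric dict (accuracy, macro/weighted F1, ECE, N) plus the
    full calibration report behind the ECE value.
    """
    probs = np.asarray(probs, dtype=float)
    true_labels = np.asarray(true_labels, dtype=int)
    pred = np.argmax(probs, axis=1)
    k = probs.shape[1]
    report = reliability_data(probs, true_labels, n_bins=n_bins)
    metrics = {
        "accuracy": accuracy(true_labels, pred),
        "f1_macro": macro_f1(true_labels, pred, k),
        "f1_weighted": weighted_f1(true_labels, pred, k),
        "ece": report.ece,
        "n": int(len(true_labels)),
    }
    return metrics, report
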