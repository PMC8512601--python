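"""Confidence calibration: binned ECE, reliability data, temperature scaling.

A classifier is calibrated when its confidence (the maximum of each
predicted distribution) matches its empirical accuracy: among examples
predicted with confidence ~0.8, about 80% should be correct. The standard
measurement partitions [0, 1] into ``M`` equal-width confidence bins
``B_m = ((m-1)/M, m/M]`` and compares each bin's mean confidence

    conf(B_m) = (1/n_m) * sum_{i in B_m} max_k p(y=k | x_i)

with its accuracy

    acc(B_m) = (1/n_m) * sum_{i in B_m} 1[argmax_k p(y=k | x_i) == y_i].

The expected calibration error is the count-weighted mean absolute gap

    ECE = sum_m (n_m / N) * |acc(B_m) - conf(B_m)|,

with empty bins contributing zero weight. ``M = 10`` bins is the
conventional default. The per-bin gaps themselves (binwise ECE) and the
full per-bin table behind a reliability diagram are also exposed.

Temperature scaling is the standard post-hoc comparison: a single scalar
``T > 0`` fitted on a validation set divides the pre-softmax scores,
``softmax(z / T)``, softening (T > 1) or sharpening (T < 1) every
distribution without ever changing the argmax. For ensemble outputs, which
have no native pre-softmax scores, the log of the combined probabilities
serves as surrogate scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .nn import log_softmax, softmax

__all__ = [
    "BinStats",
    "CalibrationReport",
    "TemperatureModel",
    "bin_index",
    "bin_stats",
    "ece",
    "binwise_ece",
    "reliability_data",
    "apply_temperature",
    "fit_temperature",
    "temperature_for_ensemble",
    "LOG_EPS",
]

#: floor added before taking logs of averaged probabilities
LOG_EPS = 1e-12


def bin_index(confidence: float, n_bins: int) -> int:
    """1-based equal-width bin of a confidence value.

    Bins are right-inclusive, ``B_m = ((m-1)/M, m/M]``, with confidence 0
    assigned to bin 1.
    """
    if not 0.0 <= confidence <= 1.0:
        raise ValueError(f"confidence must be in [0, 1], got {confidence}")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    m = int(np.ceil(confidence * n_bins))
    return min(max(m, 1), n_bins)


def _bin_indices(confidences: np.ndarray, n_bins: int) -> np.ndarray:
    if confidences.size and (
        confidences.min() < 0 or confidences.max() > 1 + 1e-12
    ):
        raise ValueError("confidences must lie in [0, 1]")
    m = np.ceil(confidences * n_bins).astype(int)
    return np.clip(m, 1, n_bins)


def _argmax_smallest(probs: np.ndarray) -> np.ndarray:
    # np.argmax already returns the first (smallest-index) maximum
    return np.argmax(probs, axis=1)


@dataclass
class BinStats:
    """Per-bin confidence/accuracy statistics over ``M`` equal-width bins.

    ``conf_mean`` and ``acc_mean`` are NaN for empty bins — empty is
    reported as empty, not as a zero gap. ``gap`` is ``|acc - conf|``.
    """

    n_bins: int
    counts: np.ndarray
    conf_mean: np.ndarray
    acc_mean: np.ndarray
    n_total: int
    accuracy: float
    mean_confidence: float

    @property
    def gap(self) -> np.ndarray:
        return np.abs(self.acc_mean - self.conf_mean)

    @property
    def nonempty(self) -> np.ndarray:
        return self.counts > 0

    @property
    def edges(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n_bins + 1)


def _validate_inputs(probs, labels) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if probs.ndim != 2:
        raise ValueError("probs must be 2-D (n, K)")
    if len(probs) == 0:
        raise ValueError("empty prediction set")
    if len(labels) != len(probs):
        raise ValueError(
            f"{len(probs)} probability rows but {len(labels)} labels"
        )
    if (probs < -1e-9).any():
        raise ValueError("probabilities must be nonnegative")
    if np.abs(probs.sum(axis=1) - 1.0).max() > 1e-5:
        raise ValueError("probability rows must sum to 1")
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("labels out of range [0, K)")
    return probs, labels


def bin_stats(probs, labels, n_bins: int = 10) -> BinStats:
    """Bin examples by confidence and compute per-bin means.

    Confidence of an example is the maximum of its probability row;
    correctness is whether the argmax (ties to the smallest class index)
    equals its label.
    """
    probs, labels = _validate_inputs(probs, labels)
    conf = probs.max(axis=1)
    correct = (_argmax_smallest(probs) == labels).astype(float)
    bins = _bin_indices(conf, n_bins) - 1  # 0-based for bincount
    counts = np.bincount(bins, minlength=n_bins)
    conf_sum = np.bincount(bins, weights=conf, minlength=n_bins)
    acc_sum = np.bincount(bins, weights=correct, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        conf_mean = np.where(counts > 0, conf_sum / np.maximum(counts, 1), np.nan)
        acc_mean = np.where(counts > 0, acc_sum / np.maximum(counts, 1), np.nan)
    return BinStats(
        n_bins=n_bins,
        counts=counts,
        conf_mean=conf_mean,
        acc_mean=acc_mean,
        n_total=len(probs),
        accuracy=float(correct.mean()),
        mean_confidence=float(conf.mean()),
    )


def ece(probs, labels, n_bins: int = 10) -> float:
    """Expected calibration error over ``n_bins`` equal-width bins."""
    stats = bin_stats(probs, labels, n_bins)
    mask = stats.nonempty
    return float(
        np.sum(stats.counts[mask] / stats.n_total * stats.gap[mask])
    )


def binwise_ece(probs, labels, n_bins: int = 10) -> np.ndarray:
    """Unweighted per-bin |accuracy - confidence| gaps; NaN for empty bins."""
    return bin_stats(probs, labels, n_bins).gap


@dataclass
class CalibrationReport:
    """Everything behind a two-panel reliability diagram.

    Per-bin accuracy/confidence/count plus overall accuracy, overall mean
    confidence (the dotted reference lines in the histogram panel), the
    scalar ECE, and the raw per-example confidence/correctness lists kept
    for plotting.
    """

    bins: BinStats
    ece: float
    binwise: np.ndarray
    confidences: np.ndarray = field(repr=False)
    correct: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        b = self.bins
        return {
            "n_bins": b.n_bins,
            "bin_edges": b.edges.tolist(),
            "counts": b.counts.tolist(),
            "conf_mean": [None if np.isnan(v) else v for v in b.conf_mean],
            "acc_mean": [None if np.isnan(v) else v for v in b.acc_mean],
            "gap": [None if np.isnan(v) else v for v in self.binwise],
            "n_total": b.n_total,
            "accuracy": b.accuracy,
            "mean_confidence": b.mean_confidence,
            "ece": self.ece,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def reliability_data(probs, labels, n_bins: int = 10) -> CalibrationReport:
    """Compute the full calibration report for one prediction set."""
    probs, labels = _validate_inputs(probs, labels)
    stats = bin_stats(probs, labels, n_bins)
    mask = stats.nonempty
    value = float(np.sum(stats.counts[mask] / stats.n_total * stats.gap[mask]))
    return CalibrationReport(
        bins=stats,
        ece=value,
        binwise=stats.gap,
        confidences=probs.max(axis=1),
        correct=(_argmax_smallest(probs) == labels),
    )


# -- temperature scaling ---------------------------------------------------


@dataclass
class TemperatureModel:
    """A fitted temperature plus fit metadata."""

    temperature: float
    t_init: float
    nll: float
    n_val: int

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def apply_temperature(scores: np.ndarray, temperature: float) -> np.ndarray:
    """Softmax of scores divided by ``T``; argmax per row is unchanged.

    Row entropy is non-decreasing in ``T``: large ``T`` flattens toward the
    uniform distribution, ``T = 1`` is the identity.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return softmax(np.asarray(scores, dtype=float) / temperature)


def _nll(scores: np.ndarray, labels: np.ndarray, temperature: float) -> float:
    logp = log_softmax(scores / temperature)
    return -float(logp[np.arange(len(labels)), labels].mean())


def fit_temperature(
    scores_val: np.ndarray,
    labels_val: np.ndarray,
    t_init: float = 1.5,
    bounds: tuple[float, float] = (0.05, 100.0),
) -> TemperatureModel:
    """Fit ``T`` by minimizing validation NLL of ``softmax(scores / T)``.

    Bounded 1-D optimization started from ``t_init`` (1.5 by default, the
    conventional initialization). If the validation labels do not include
    every class a warning is emitted — an incomplete validation set can
    drive the optimum to a sub-optimal ``T < 1``.
    """
    scores = np.asarray(scores_val, dtype=float)
    labels = np.asarray(labels_val, dtype=int)
    if scores.ndim != 2 or len(scores) == 0:
        raise ValueError("validation scores must be a nonempty (n, K) matrix")
    if len(labels) != len(scores):
        raise ValueError("scores and labels length mismatch")
    k = scores.shape[1]
    present = np.unique(labels)
    if len(present) < k:
        missing = sorted(set(range(k)) - set(present.tolist()))
        warnings.warn(
            f"validation set is missing classes {missing}; the fitted "
            "temperature may be sub-optimal (possibly T < 1)",
            UserWarning,
            stacklevel=2,
        )
    result = minimize(
        lambda t: _nll(scores, labels, float(t[0])),
        x0=[t_init],
        bounds=[bounds],
        method="L-BFGS-B",
        options={"ftol": 1e-12, "gtol": 1e-10},
    )
    t_opt = float(result.x[0])
    return TemperatureModel(
        temperature=t_opt,
        t_init=t_init,
        nll=float(result.fun),
        n_val=len(labels),
    )


def temperature_for_ensemble(
    ensemble_probs: np.ndarray,
    labels_val: np.ndarray,
    t_init: float = 1.5,
) -> TemperatureModel:
    """Fit a temperature for combined ensemble output.

    The averaged softmax has no native pre-softmax scores, so
    ``log(p + eps)`` serves as surrogate scores; applying ``T = 1`` to them
    reproduces the input probabilities (up to the epsilon floor).
    """
    probs = np.asarray(ensemble_probs, dtype=float)
    return fit_temperature(np.log(probs + LOG_EPS), labels_val, t_init=t_init)
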