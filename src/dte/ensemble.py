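"""Deep time ensembles: one classifier per window size, averaged at inference.

Training: for each window size ``w_i`` in a descending set ``w1 > w2 > ...
> wN``, extract a temporal matrix and label vector from the raw recordings
and fit one probabilistic classifier on it. Prediction: a test example is a
window framed at the largest size ``w1``; member ``j`` slides its own size
``wj`` inside that outer window, averages its softmax output over the
resulting sub-windows, and the member-level distributions are combined by
an unweighted arithmetic mean:

    p(y | x) = (1/N) * sum_j  mean_over_subwindows softmax_j(.)

Averaging distributions yields a distribution, and the combined maximum
probability can never exceed the largest member maximum — the softening
mechanism that removes single-softmax overconfidence and produces
calibrated output. A same-window "standard ensemble" (members differing
only in initialization seed) is provided as the classical comparison.

The module follows the statsmodels convention: :class:`DeepTimeEnsemble`
and :class:`StandardEnsemble` are model objects built from data whose
``fit()`` returns an :class:`EnsembleResults` carrying the members,
predictions, evaluation diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import learners as learners_mod
from .learners import LearnerConfig, SequenceClassifier
from .series import MultichannelSeries
from .windowing import TemporalMatrix, WindowSizeSet, extract_all

__all__ = [
    "DeepTimeEnsemble",
    "StandardEnsemble",
    "EnsembleResults",
    "PredictionResult",
    "subwindows",
    "train_dte",
    "train_standard_ensemble",
]


def subwindows(
    outer_sequence: np.ndarray, wj_samples: int, inner_stride: int
) -> np.ndarray:
    """Complete sub-windows of length ``wj`` slid inside one outer window.

    Starts at ``0, stride, 2*stride, ...`` (0-based, half-open spans);
    trailing partial sub-windows are dropped, so the count is
    ``floor((w1 - wj) / stride) + 1``.
    """
    outer = np.asarray(outer_sequence, dtype=float)
    if outer.ndim == 1:
        outer = outer[:, None]
    w1 = outer.shape[0]
    if wj_samples > w1:
        raise ValueError(
            f"sub-window of {wj_samples} samples exceeds outer window of {w1}"
        )
    if inner_stride < 1:
        raise ValueError("inner_stride must be >= 1")
    starts = np.arange(0, w1 - wj_samples + 1, inner_stride)
    return np.stack([outer[s : s + wj_samples] for s in starts])


@dataclass
class PredictionResult:
    """Combined ensemble predictions for a batch of outer windows.

    ``probabilities`` rows are the averaged distributions ``p(y|x)``,
    ``predicted_labels`` their argmaxes, and ``per_member_probabilities``
    (``N x n x K``) the pre-combination member outputs kept for
    per-member diagnostics.
    """

    probabilities: np.ndarray
    predicted_labels: np.ndarray
    per_member_probabilities: np.ndarray | None = None

    def to_frame(self, true_labels: np.ndarray | None = None) -> pd.DataFrame:
        """Delimited-table form: ``example_id, true_label, pred_label, p_*``."""
        n, k = self.probabilities.shape
        data = {"example_id": np.arange(n)}
        if true_labels is not None:
            data["true_label"] = np.asarray(true_labels, dtype=int)
        data["pred_label"] = self.predicted_labels
        for c in range(k):
            data[f"p_{c}"] = self.probabilities[:, c]
        return pd.DataFrame(data)


@dataclass
class _Member:
    window_seconds: float
    window_samples: int
    learner: SequenceClassifier


class EnsembleResults:
    """A fitted window-size ensemble and its prediction machinery.

    Members are ordered by strictly decreasing window size; all share the
    class count ``K`` and channel count. ``inner_stride_rule`` governs how
    densely a member slides its window inside the outer ``w1`` window at
    inference (default: non-overlapping, stride equal to the member's own
    window).
    """

    def __init__(
        self,
        members: list[tuple[float, SequenceClassifier]],
        sampling_rate: float,
        inner_stride_rule=None,
        train_counts: dict[float, int] | None = None,
        model: "DeepTimeEnsemble | StandardEnsemble | None" = None,
        distinct_sizes: bool = True,
    ) -> None:
        if not members:
            raise ValueError("ensemble needs at least one member")
        self.members = [
            _Member(float(w), learner.window_samples, learner) for w, learner in members
        ]
        sizes = [m.window_samples for m in self.members]
        if distinct_sizes and any(
            later >= earlier for earlier, later in zip(sizes, sizes[1:])
        ):
            raise ValueError(
                f"member window sizes must be strictly decreasing, got {sizes}"
            )
        ks = {m.learner.n_classes for m in self.members}
        chans = {m.learner.n_channels for m in self.members}
        if len(ks) > 1 or len(chans) > 1:
            raise ValueError("members must share n_classes and n_channels")
        self.n_classes = ks.pop()
        self.n_channels = chans.pop()
        self.sampling_rate = sampling_rate
        self.inner_stride_rule = inner_stride_rule
        self.train_counts = train_counts or {}
        self.model = model

    # -- structure ---------------------------------------------------------

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def window_sizes(self) -> list[float]:
        return [m.window_seconds for m in self.members]

    @property
    def w1_samples(self) -> int:
        return self.members[0].window_samples

    def _inner_stride(self, wj_samples: int) -> int:
        rule = self.inner_stride_rule
        if rule is None:
            return wj_samples  # non-overlapping sub-windows
        if callable(rule):
            return int(rule(wj_samples))
        return int(rule)

    # -- prediction --------------------------------------------------------

    def predict_sequence(self, outer_sequence: np.ndarray) -> np.ndarray:
        """Combined class distribution for one outer window of length w1."""
        result = self.predict_matrix(
            np.asarray(outer_sequence, dtype=float)[None], keep_members=False
        )
        return result.probabilities[0]

    def predict_matrix(
        self, x1: TemporalMatrix | np.ndarray, keep_members: bool = True
    ) -> PredictionResult:
        """Combined predictions for a batch of outer (w1-sized) windows.

        Each member's softmax is averaged over its sub-windows of every
        outer window, then members are averaged uniformly. Ties in the
        final argmax break to the smallest class index.
        """
        if isinstance(x1, TemporalMatrix):
            x1 = x1.values
        x1 = np.asarray(x1, dtype=float)
        if x1.ndim == 2:  # single sequence
            x1 = x1[None]
        m = len(x1)
        if m == 0:
            empty = np.empty((0, self.n_classes))
            return PredictionResult(
                probabilities=empty,
                predicted_labels=np.empty(0, dtype=int),
                per_member_probabilities=np.empty(
                    (self.n_members, 0, self.n_classes)
                ),
            )
        w1 = self.w1_samples
        if x1.shape[1] != w1:
            raise ValueError(
                f"outer windows have {x1.shape[1]} samples, expected w1={w1}"
            )
        member_probs = np.empty((self.n_members, m, self.n_classes))
        for j, member in enumerate(self.members):
            wj = member.window_samples
            if wj == w1:
                member_probs[j] = member.learner.predict_proba(x1)
            else:
                stride = self._inner_stride(wj)
                starts = np.arange(0, w1 - wj + 1, stride)
                # (m * n_sub, wj, C) batch over all outer windows at once
                stacked = np.concatenate(
                    [x1[:, s : s + wj, :] for s in starts], axis=0
                )
                probs = member.learner.predict_proba(stacked)
                probs = probs.reshape(len(starts), m, self.n_classes)
                member_probs[j] = probs.mean(axis=0)
        combined = member_probs.mean(axis=0)
        return PredictionResult(
            probabilities=combined,
            predicted_labels=np.argmax(combined, axis=1),
            per_member_probabilities=member_probs if keep_members else None,
        )

    def predict_series(
        self, series_collection: list[MultichannelSeries], test_step
    ) -> tuple[PredictionResult, np.ndarray]:
        """Frame recordings at w1 and predict; returns (result, true labels).

        Ground truth per example is the outer window's majority label at w1.
        """
        w1_seconds = self.members[0].window_seconds
        table = extract_all(
            series_collection, WindowSizeSet((w1_seconds,)), test_step
        )
        x1 = table[w1_seconds]
        return self.predict_matrix(x1), x1.labels

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Plain-text member table in the spirit of a fit report."""
        lines = [
            "Window-size ensemble",
            "=" * 64,
            f"members: {self.n_members}   classes: {self.n_classes}   "
            f"channels: {self.n_channels}   rate: {self.sampling_rate:g} Hz",
            f"{'member':>6} {'window (s)':>11} {'samples':>8} "
            f"{'train windows':>14} {'architecture':>14}",
        ]
        for j, member in enumerate(self.members):
            count = self.train_counts.get(member.window_seconds, "-")
            lines.append(
                f"{j:>6} {member.window_seconds:>11g} "
                f"{member.window_samples:>8d} {count!s:>14} "
                f"{member.learner.config.architecture:>14}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Write member artifacts plus a JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        entries = []
        for j, member in enumerate(self.members):
            stem = directory / f"member{j}"
            member.learner.save(stem)
            entries.append(
                {
                    "path": f"member{j}.npz",
                    "window_seconds": member.window_seconds,
                    "window_samples": member.window_samples,
                    "seed": member.learner.config.seed,
                }
            )
        manifest = {
            "sampling_rate": self.sampling_rate,
            "n_classes": self.n_classes,
            "n_channels": self.n_channels,
            "inner_stride_rule": (
                None
                if self.inner_stride_rule is None or callable(self.inner_stride_rule)
                else int(self.inner_stride_rule)
            ),
            "members": entries,
        }
        with open(directory / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, directory) -> "EnsembleResults":
        directory = Path(directory)
        with open(directory / "manifest.json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        members = []
        for entry in manifest["members"]:
            stem = directory / Path(entry["path"]).stem
            members.append(
                (entry["window_seconds"], SequenceClassifier.load(stem))
            )
        sizes = [m[1].window_samples for m in members]
        return cls(
            members,
            sampling_rate=manifest["sampling_rate"],
            inner_stride_rule=manifest.get("inner_stride_rule"),
            distinct_sizes=len(set(sizes)) == len(sizes),
        )


class DeepTimeEnsemble:
    """Model object: a window-size ensemble to be fitted on raw recordings.

    Parameters
    ----------
    train_series : list of MultichannelSeries
        Labelled training recordings (windows never cross recordings).
    window_set : WindowSizeSet
        Distinct window sizes, largest first; one member per size.
    learner_config : LearnerConfig
        Shared architecture/training settings; member ``i`` trains with
        seed ``fit(seed) + i``.
    step_rule
        Training slide increment per window size (samples int, ``("seconds",
        s)``, ``("overlap", fraction)`` or callable); shared by all sizes.
    n_classes : int, optional
        Explicit class count when some class may be absent from a split.
    inner_stride_rule : optional
        Inference-time stride for sub-windows inside the outer window;
        default is the member's own window (non-overlapping).
    """

    def __init__(
        self,
        train_series: list[MultichannelSeries],
        window_set: WindowSizeSet,
        learner_config: LearnerConfig,
        step_rule=("overlap", 0.5),
        n_classes: int | None = None,
        inner_stride_rule=None,
    ) -> None:
        self.train_series = list(train_series)
        if not self.train_series:
            raise ValueError("training collection is empty")
        self.window_set = window_set
        self.learner_config = learner_config
        self.step_rule = step_rule
        self.n_classes = n_classes
        self.inner_stride_rule = inner_stride_rule
        self.sampling_rate = self.train_series[0].sampling_rate

    def extract(self) -> dict[float, TemporalMatrix]:
        """Temporal matrices for every window size (exposed for inspection)."""
        return extract_all(self.train_series, self.window_set, self.step_rule)

    def fit(self, seed: int = 0) -> EnsembleResults:
        """Train one learner per window size; member i uses seed ``seed+i``."""
        import dataclasses

        tables = self.extract()
        members = []
        counts = {}
        for i, size in enumerate(self.window_set):
            matrix = tables[size]
            if matrix.n_seq == 0:
                raise ValueError(
                    f"window size {size} s produced zero training windows"
                )
            config = dataclasses.replace(self.learner_config, seed=seed + i)
            learner = learners_mod.fit(config, matrix, n_classes=self.n_classes)
            members.append((size, learner))
            counts[size] = matrix.n_seq
        return EnsembleResults(
            members,
            sampling_rate=self.sampling_rate,
            inner_stride_rule=self.inner_stride_rule,
            train_counts=counts,
            model=self,
        )


class StandardEnsemble:
    """Same-architecture, same-window ensemble (initialization-only diversity).

    All members train on the identical temporal matrix at one fixed window
    size and differ only in their seed; at inference every member sees the
    full outer window (the sub-window step degenerates to identity). The
    classical deep-ensemble comparison for the window-size ensemble.
    """

    def __init__(
        self,
        train_series: list[MultichannelSeries],
        fixed_window_seconds: float,
        n_members: int,
        learner_config: LearnerConfig,
        step_rule=("overlap", 0.5),
        n_classes: int | None = None,
    ) -> None:
        if n_members < 1:
            raise ValueError("n_members must be >= 1")
        self.train_series = list(train_series)
        if not self.train_series:
            raise ValueError("training collection is empty")
        self.fixed_window_seconds = float(fixed_window_seconds)
        self.n_members = n_members
        self.learner_config = learner_config
        self.step_rule = step_rule
        self.n_classes = n_classes
        self.sampling_rate = self.train_series[0].sampling_rate

    def fit(self, seed: int = 0) -> EnsembleResults:
        import dataclasses

        table = extract_all(
            self.train_series,
            WindowSizeSet((self.fixed_window_seconds,)),
            self.step_rule,
        )
        matrix = table[self.fixed_window_seconds]
        if matrix.n_seq == 0:
            raise ValueError(
                f"window size {self.fixed_window_seconds} s produced zero "
                "training windows"
            )
        members = []
        for i in range(self.n_members):
            config = dataclasses.replace(self.learner_config, seed=seed + i)
            learner = learners_mod.fit(config, matrix, n_classes=self.n_classes)
            members.append((self.fixed_window_seconds, learner))
        return EnsembleResults(
            members,
            sampling_rate=self.sampling_rate,
            train_counts={self.fixed_window_seconds: matrix.n_seq},
            model=self,
            distinct_sizes=False,
        )


def train_dte(
    train_series,
    window_set: WindowSizeSet,
    learner_config: LearnerConfig,
    step_rule=("overlap", 0.5),
    seed: int = 0,
    n_classes: int | None = None,
    inner_stride_rule=None,
) -> EnsembleResults:
    """Convenience wrapper: build a :class:`DeepTimeEnsemble` and fit it."""
    return DeepTimeEnsemble(
        train_series,
        window_set,
        learner_config,
        step_rule=step_rule,
        n_classes=n_classes,
        inner_stride_rule=inner_stride_rule,
    ).fit(seed=seed)


def train_standard_ensemble(
    train_series,
    fixed_window_seconds: float,
    n_members: int,
    learner_config: LearnerConfig,
    step_rule=("overlap", 0.5),
    seed: int = 0,
    n_classes: int | None = None,
) -> EnsembleResults:
    """Convenience wrapper for the fixed-window comparison ensemble."""
    return StandardEnsemble(
        train_series,
        fixed_window_seconds,
        n_members,
        learner_config,
        step_rule=step_rule,
        n_classes=n_classes,
    ).fit(seed=seed)
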