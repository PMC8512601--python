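"""Shared fixtures: tiny synthetic datasets, separable windows, stub learners."""

from __future__ import annotations

import numpy as np
import pytest

from dte.nn import softmax
from dte.series import MultichannelSeries
from dte.synthgen import default_activity_specs, generate_dataset


class StubLearner:
    """Table-driven ensemble member: a fixed deterministic map from window
    content to a class distribution, used to test the averaging scheme
    independently of any training."""

    def __init__(self, window_samples: int, n_channels: int = 1,
                 n_classes: int = 3, salt: float = 0.0) -> None:
        self.window_samples = window_samples
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.salt = salt

    def _scores_one(self, window: np.ndarray) -> np.ndarray:
        flat = np.asarray(window, dtype=float).ravel()
        base = np.array(
            [flat.sum(), np.abs(flat).sum() + self.salt, (flat**2).sum()]
        )
        return base[: self.n_classes]

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        return softmax(np.stack([self._scores_one(w) for w in x]))

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        return np.stack([self._scores_one(w) for w in x])


class ConstantLearner:
    """Member that always outputs one fixed distribution."""

    def __init__(self, probs, window_samples: int, n_channels: int = 1):
        self.probs = np.asarray(probs, dtype=float)
        self.window_samples = window_samples
        self.n_channels = n_channels
        self.n_classes = len(self.probs)

    def predict_proba(self, x):
        x = np.asarray(x, dtype=float)
        n = 1 if x.ndim == 2 else len(x)
        return np.tile(self.probs, (n, 1))


@pytest.fixture(scope="session")
def separable_windows():
    """Two perfectly separable classes: constant +1 vs -1 windows plus a
    trace of noise so standardization stays well-conditioned."""
    rng = np.random.default_rng(42)
    n_per, w, c = 24, 30, 2
    x0 = 1.0 + 0.01 * rng.normal(size=(n_per, w, c))
    x1 = -1.0 + 0.01 * rng.normal(size=(n_per, w, c))
    x = np.concatenate([x0, x1])
    y = np.array([0] * n_per + [1] * n_per)
    order = rng.permutation(len(y))
    return x[order], y[order]


@pytest.fixture(scope="session")
def tiny_dataset():
    """Three-subject, two-channel synthetic dataset small enough for
    training tests (about 100 s per subject at 20 Hz)."""
    from dte.synthgen import ProtocolTemplate

    template = ProtocolTemplate(
        n_segments=10, segment_seconds=10.0, sampling_rate=20.0, n_channels=2
    )
    return generate_dataset(
        4, default_activity_specs(), protocol_template=template, seed=11
    )


@pytest.fixture
def uniform_series():
    """A single-activity 400-sample recording."""
    rng = np.random.default_rng(0)
    return MultichannelSeries(
        subject_id="s1",
        sampling_rate=20.0,
        values=rng.normal(size=(400, 2)),
        labels=np.zeros(400, dtype=int),
        activity_names={0: "walk"},
    )
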