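"""Probabilistic sequence classifiers: the contract every ensemble member meets.

A fitted learner maps a batch of fixed-length multichannel windows to one
class-probability distribution per window (rows nonnegative, summing to 1)
and also exposes the pre-softmax scores needed for temperature scaling.
Three small reference architectures are provided — convolutional,
recurrent, and convolutional-recurrent — all trained with multiclass
cross-entropy and Adam. They are deliberately compact (two feature layers,
tens of units) so a full multi-window ensemble trains on one CPU in
minutes; any object satisfying the same ``predict_proba`` /
``predict_scores`` surface can serve as an ensemble member.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from . import nn
from .windowing import TemporalMatrix

__all__ = ["LearnerConfig", "SequenceClassifier", "fit"]

_ARCHITECTURES = ("conv", "recurrent", "conv_recurrent")


@dataclass(frozen=True)
class LearnerConfig:
    """Architecture and training hyperparameters for one learner.

    Parameters
    ----------
    architecture : {"conv", "recurrent", "conv_recurrent"}
        ``conv``: two valid 1-D convolutions + ReLU, global average pooling
        over time, linear output. ``recurrent``: stacked tanh recurrent
        layers, classification from the final hidden state.
        ``conv_recurrent``: one strided convolution feeding one recurrent
        layer.
    n_filters, kernel_size : int
        Convolutional capacity (ignored by ``recurrent``).
    n_units : int
        Hidden width of recurrent layers (ignored by ``conv``).
    n_layers : int
        Number of feature layers (convolutional or recurrent blocks).
    epochs, batch_size, learning_rate
        Plain fixed-epoch Adam training; no early stopping, which keeps the
        reproducibility contract simple.
    seed : int
        Seeds initialization and minibatch shuffling.
    """

    architecture: str = "conv"
    n_filters: int = 12
    kernel_size: int = 7
    n_units: int = 24
    n_layers: int = 2
    epochs: int = 35
    batch_size: int = 32
    learning_rate: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in _ARCHITECTURES:
            raise ValueError(
                f"architecture must be one of {_ARCHITECTURES}, "
                f"got {self.architecture!r}"
            )
        for name in ("n_filters", "kernel_size", "n_units", "n_layers",
                     "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


def _build_network(
    config: LearnerConfig, window_samples: int, n_channels: int, n_classes: int,
    rng: np.random.Generator,
) -> nn.Sequential:
    a = config.architecture
    layers: list[nn.Layer] = []
    if a == "conv":
        width = n_channels
        k = min(config.kernel_size, window_samples)
        for _ in range(config.n_layers):
            layers += [nn.Conv1d(width, config.n_filters, k, rng), nn.ReLU()]
            width = config.n_filters
        layers += [nn.GlobalAvgPool(), nn.Dense(width, n_classes, rng)]
    elif a == "recurrent":
        width = n_channels
        for i in range(config.n_layers):
            last = i == config.n_layers - 1
            layers.append(
                nn.RNN(width, config.n_units, rng, return_sequences=not last)
            )
            width = config.n_units
        layers.append(nn.Dense(width, n_classes, rng))
    else:  # conv_recurrent
        k = min(config.kernel_size, window_samples)
        stride = 2 if window_samples >= 2 * k else 1
        layers += [
            nn.Conv1d(n_channels, config.n_filters, k, rng, stride=stride),
            nn.ReLU(),
            nn.RNN(config.n_filters, config.n_units, rng),
            nn.Dense(config.n_units, n_classes, rng),
        ]
    return nn.Sequential(layers)


class SequenceClassifier:
    """A fitted probabilistic window classifier (ensemble-member contract).

    Carries the window length and channel count it was trained on, the
    number of classes ``K``, per-channel standardization statistics from the
    training set, and the trained network. Inference is deterministic:
    identical input always yields identical output.
    """

    def __init__(
        self,
        config: LearnerConfig,
        window_samples: int,
        n_channels: int,
        n_classes: int,
        network: nn.Sequential,
        channel_mean: np.ndarray,
        channel_sd: np.ndarray,
    ) -> None:
        self.config = config
        self.window_samples = window_samples
        self.n_channels = n_channels
        self.n_classes = n_classes
        self.network = network
        self.channel_mean = channel_mean
        self.channel_sd = channel_sd

    # -- inference ---------------------------------------------------------

    def _validate(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3 or x.shape[1] != self.window_samples or (
            x.shape[2] != self.n_channels
        ):
            raise ValueError(
                f"expected windows of shape (*, {self.window_samples}, "
                f"{self.n_channels}), got {x.shape}"
            )
        return (x - self.channel_mean) / self.channel_sd

    def predict_scores(self, x: np.ndarray) -> np.ndarray:
        """Pre-softmax scores, shape ``(n, K)``.

        ``softmax(predict_scores(x)) == predict_proba(x)`` by construction.
        """
        z = self._validate(x)
        if len(z) == 0:
            return np.empty((0, self.n_classes))
        return self.network.forward(z)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-window class distributions, shape ``(n, K)``."""
        return nn.softmax(self.predict_scores(x))

    def predict(self, x: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(x), axis=1)

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Persist weights (npz) plus a JSON metadata sidecar."""
        path = Path(path)
        arrays = self.network.state_arrays()
        arrays["channel_mean"] = self.channel_mean
        arrays["channel_sd"] = self.channel_sd
        np.savez(path, **arrays)
        meta = {
            "config": asdict(self.config),
            "window_samples": self.window_samples,
            "n_channels": self.n_channels,
            "n_classes": self.n_classes,
        }
        with open(path.with_suffix(".json"), "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)

    @classmethod
    def load(cls, path) -> "SequenceClassifier":
        path = Path(path)
        with open(path.with_suffix(".json"), encoding="utf-8") as fh:
            meta = json.load(fh)
        config = LearnerConfig(**meta["config"])
        rng = np.random.default_rng(0)  # shapes only; weights overwritten
        net = _build_network(
            config, meta["window_samples"], meta["n_channels"],
            meta["n_classes"], rng,
        )
        with np.load(path if path.suffix else path.with_suffix(".npz")) as data:
            arrays = {k: data[k] for k in data.files}
        net.load_state(arrays)
        return cls(
            config=config,
            window_samples=meta["window_samples"],
            n_channels=meta["n_channels"],
            n_classes=meta["n_classes"],
            network=net,
            channel_mean=np.asarray(arrays["channel_mean"]),
            channel_sd=np.asarray(arrays["channel_sd"]),
        )


def fit(
    config: LearnerConfig,
    x: TemporalMatrix | np.ndarray,
    y: np.ndarray | None = None,
    n_classes: int | None = None,
) -> SequenceClassifier:
    """Train a sequence classifier with cross-entropy on labelled windows.

    Parameters
    ----------
    config : LearnerConfig
    x : TemporalMatrix or ndarray (n_seq, window_samples, n_channels)
        Training windows; a :class:`TemporalMatrix` supplies its own labels.
    y : ndarray, optional
        Window labels (required when ``x`` is a bare array).
    n_classes : int, optional
        Explicit ``K``. Without it, the training labels must cover the
        classes ``0..max`` contiguously and include at least two classes;
        a class missing from ``y`` with no override is an error, because
        the learner could never predict it.

    Returns
    -------
    SequenceClassifier
        Deterministic given ``config.seed`` and the data.
    """
    if isinstance(x, TemporalMatrix):
        if y is None:
            y = x.labels
        x = x.values
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError("x must be (n_seq, window_samples, n_channels)")
    if y is None:
        raise ValueError("labels y are required")
    y = np.asarray(y, dtype=int)
    if len(y) != len(x):
        raise ValueError(f"x has {len(x)} windows but y has {len(y)} labels")
    if len(x) == 0:
        raise ValueError("cannot fit on zero windows")

    present = np.unique(y)
    if n_classes is None:
        k = int(present.max()) + 1
        if len(present) < 2 or len(present) != k:
            raise ValueError(
                f"labels present {present.tolist()} do not cover 0..K-1 with "
                "K >= 2; pass n_classes explicitly for absent classes"
            )
    else:
        k = int(n_classes)
        if present.max() >= k:
            raise ValueError("labels exceed n_classes")

    rng = np.random.default_rng(config.seed)
    _, window_samples, n_channels = x.shape
    mean = x.mean(axis=(0, 1))
    sd = x.std(axis=(0, 1))
    sd = np.where(sd < 1e-8, 1.0, sd)
    xs = (x - mean) / sd

    net = _build_network(config, window_samples, n_channels, k, rng)
    opt = nn.Adam(net, lr=config.learning_rate)
    n = len(xs)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = net.forward(xs[idx])
            _, dlogits = nn.cross_entropy_grad(logits, y[idx])
            net.backward(dlogits)
            opt.step()

    return SequenceClassifier(
        config=config,
        window_samples=window_samples,
        n_channels=n_channels,
        n_classes=k,
        network=net,
        channel_mean=mean,
        channel_sd=sd,
    )
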