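"""Temporal sequence extraction: sliding fixed-length windows over recordings.

For each window size ``w`` in a window-size set, every labelled recording is
cut into complete, possibly overlapping windows of ``round(w * rate)``
samples advanced by a step (the slide increment between consecutive window
starts). Each window gets a single label — the most frequent per-sample
label inside it — producing one temporal matrix ``(n_seq, window_samples,
n_channels)`` plus label vector per window size. Windows never cross
subject/session boundaries, and trailing partial windows are dropped.

Coordinates are 0-based and half-open throughout: window ``k`` covers
samples ``[k*step, k*step + window_samples)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import DataError
from .series import MultichannelSeries

__all__ = [
    "WindowSpec",
    "WindowSizeSet",
    "TemporalMatrix",
    "window_count",
    "majority_label",
    "extract_temporal_matrix",
    "extract_all",
    "build_window_set",
    "step_from_overlap",
]


def step_from_overlap(window_samples: int, overlap: float) -> int:
    """Map a fractional overlap ``o`` in [0, 1) to a step in samples.

    ``step = max(1, round(window_samples * (1 - o)))``; ``o = 0`` gives
    non-overlapping windows, larger ``o`` denser sliding.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap fraction must be in [0, 1)")
    return max(1, int(round(window_samples * (1.0 - overlap))))


def resolve_step(step_rule, window_samples: int, sampling_rate: float) -> int:
    """Resolve a step rule to a step in samples for one window size.

    Accepted rules: an ``int`` (step in samples), ``("seconds", s)``,
    ``("overlap", fraction)``, ``("samples", n)``, or a callable
    ``window_samples -> step``.
    """
    if callable(step_rule):
        step = int(step_rule(window_samples))
    elif isinstance(step_rule, tuple):
        kind, value = step_rule
        if kind == "seconds":
            step = int(round(value * sampling_rate))
        elif kind == "overlap":
            step = step_from_overlap(window_samples, value)
        elif kind == "samples":
            step = int(value)
        else:
            raise ValueError(f"unknown step rule kind {kind!r}")
    else:
        step = int(step_rule)
    if step < 1:
        raise ValueError(f"resolved step must be >= 1, got {step}")
    return step


@dataclass(frozen=True)
class WindowSpec:
    """One window size plus slide increment at a given sampling rate."""

    window_seconds: float
    step_samples: int
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.window_seconds <= 0 or self.sampling_rate <= 0:
            raise ValueError("window_seconds and sampling_rate must be positive")
        if self.window_samples < 1:
            raise ValueError("window shorter than one sample")
        if self.step_samples < 1:
            raise ValueError("step_samples must be >= 1")

    @property
    def window_samples(self) -> int:
        return int(round(self.window_seconds * self.sampling_rate))


@dataclass(frozen=True)
class WindowSizeSet:
    """A set of distinct window lengths, stored canonically descending.

    The descending order ``w1 > w2 > ... > wN`` is the inference order: test
    examples are framed at the largest size ``w1`` and the smaller sizes are
    slid inside it.
    """

    sizes_seconds: tuple[float, ...]

    def __post_init__(self) -> None:
        sizes = tuple(float(s) for s in self.sizes_seconds)
        if not sizes:
            raise ValueError("window-size set must be nonempty")
        if any(s <= 0 for s in sizes):
            raise ValueError("all window sizes must be positive")
        if len(set(sizes)) != len(sizes):
            raise ValueError("window sizes must be distinct")
        object.__setattr__(
            self, "sizes_seconds", tuple(sorted(sizes, reverse=True))
        )

    def __len__(self) -> int:
        return len(self.sizes_seconds)

    def __iter__(self):
        return iter(self.sizes_seconds)

    @property
    def largest(self) -> float:
        return self.sizes_seconds[0]


def build_window_set(
    center_seconds: float, n_sizes: int, step_seconds: float = 1.0
) -> WindowSizeSet:
    """Arithmetic window-size set centred on a chosen optimal size.

    An equal number of sizes on both sides of ``center_seconds`` with
    uniform stepping: ``build_window_set(5, 5, 1)`` gives {3, 4, 5, 6, 7} s.
    ``n_sizes`` must be odd so the centre is a member.
    """
    if n_sizes < 1 or n_sizes % 2 == 0:
        raise ValueError("n_sizes must be odd and >= 1")
    if step_seconds <= 0 and n_sizes > 1:
        raise ValueError("step_seconds must be positive")
    half = n_sizes // 2
    sizes = [center_seconds + k * step_seconds for k in range(-half, half + 1)]
    if min(sizes) <= 0:
        raise ValueError(
            f"window-size set {sizes} includes a nonpositive size; "
            "reduce n_sizes or step_seconds"
        )
    return WindowSizeSet(tuple(sizes))


@dataclass
class TemporalMatrix:
    """Stacked fixed-length windows with one label per window."""

    values: np.ndarray  # (n_seq, window_samples, n_channels)
    labels: np.ndarray  # (n_seq,)
    window_samples: int
    source_window_seconds: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 3:
            raise DataError("values must be 3-D (n_seq, window_samples, n_channels)")
        if self.values.shape[0] != len(self.labels):
            raise DataError("labels length must equal n_seq")
        if self.values.shape[1] != self.window_samples:
            raise DataError("values second axis must equal window_samples")

    @property
    def n_seq(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]


def window_count(n_samples: int, window_samples: int, step_samples: int) -> int:
    """Number of complete windows of ``window_samples`` advanced by ``step``.

    ``floor((n - w) / step) + 1``, or 0 when the window does not fit —
    a long window on a short recording is not an error, it simply
    contributes no windows.
    """
    if window_samples < 1:
        raise ValueError("window_samples must be >= 1")
    if step_samples < 1:
        raise ValueError("step_samples must be >= 1")
    if window_samples > n_samples:
        return 0
    return (n_samples - window_samples) // step_samples + 1


def majority_label(window_labels) -> int:
    """Most frequent class index in a window; ties break to the smallest.

    The tie rule makes extraction deterministic and seed-free.
    """
    labels = np.asarray(window_labels, dtype=int)
    if labels.size == 0:
        raise ValueError("majority_label of an empty window is undefined")
    return int(np.bincount(labels).argmax())


def extract_temporal_matrix(
    series: MultichannelSeries, spec: WindowSpec
) -> TemporalMatrix:
    """Cut one recording into complete windows with majority labels.

    Window ``k`` covers samples ``[k*step, k*step + w)``; its label is the
    most frequent per-sample label in that span. Returns an empty matrix
    (``n_seq == 0``) when the window does not fit.
    """
    if abs(spec.sampling_rate - series.sampling_rate) > 1e-9:
        raise DataError(
            f"window spec rate {spec.sampling_rate} != series rate "
            f"{series.sampling_rate}"
        )
    w = spec.window_samples
    step = spec.step_samples
    count = window_count(series.n_samples, w, step)
    if count == 0:
        return TemporalMatrix(
            values=np.empty((0, w, series.n_channels)),
            labels=np.empty(0, dtype=int),
            window_samples=w,
            source_window_seconds=spec.window_seconds,
        )
    starts = np.arange(count) * step
    # windowed views, then select the strided starts (copy to own the data)
    value_view = sliding_window_view(series.values, w, axis=0)  # (n-w+1, C, w)
    values = value_view[starts].transpose(0, 2, 1).copy()
    label_view = sliding_window_view(series.labels, w)  # (n-w+1, w)
    labels = np.array([majority_label(row) for row in label_view[starts]])
    return TemporalMatrix(
        values=values,
        labels=labels,
        window_samples=w,
        source_window_seconds=spec.window_seconds,
    )


def extract_all(
    series_collection,
    window_set: WindowSizeSet,
    step_rule,
) -> dict[float, TemporalMatrix]:
    """Extract one concatenated temporal matrix per window size.

    Windows are extracted per series and concatenated in input order, so no
    window ever straddles two recordings (no subject leakage). All series
    must share sampling rate and channel count.

    Parameters
    ----------
    series_collection : list of MultichannelSeries
    window_set : WindowSizeSet
    step_rule
        Per-size step rule; see :func:`resolve_step`.

    Returns
    -------
    dict mapping window size (seconds, descending insertion order) to
    :class:`TemporalMatrix`.
    """
    series_list = list(series_collection)
    if series_list:
        rates = {s.sampling_rate for s in series_list}
        chans = {s.n_channels for s in series_list}
        if len(rates) > 1:
            raise DataError(f"heterogeneous sampling rates: {rates}")
        if len(chans) > 1:
            raise DataError(f"heterogeneous channel counts: {chans}")
        rate = series_list[0].sampling_rate
        n_channels = series_list[0].n_channels
    else:
        rate = 1.0
        n_channels = 0

    out: dict[float, TemporalMatrix] = {}
    for size in window_set:
        w = int(round(size * rate))
        step = resolve_step(step_rule, w, rate)
        spec = WindowSpec(
            window_seconds=size, step_samples=step, sampling_rate=rate
        )
        parts = [extract_temporal_matrix(s, spec) for s in series_list]
        nonempty = [p for p in parts if p.n_seq > 0]
        if nonempty:
            values = np.concatenate([p.values for p in nonempty])
            labels = np.concatenate([p.labels for p in nonempty])
        else:
            values = np.empty((0, w, n_channels))
            labels = np.empty(0, dtype=int)
        out[size] = TemporalMatrix(
            values=values,
            labels=labels,
            window_samples=w,
            source_window_seconds=size,
        )
    return out
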