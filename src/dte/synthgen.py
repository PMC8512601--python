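"""Synthetic multi-subject wearable-sensor data with controllable periodicity.

Real activity-recognition benchmarks mix activities whose signals differ
qualitatively in their temporal structure: locomotion (walking, running) is
strongly periodic, semi-rhythmic tasks (stair climbing, vacuuming) are only
weakly periodic, and quasi-static tasks (standing, ironing) have essentially
no periodicity. This module generates labelled multichannel recordings that
reproduce those regimes, with multiple subjects, imbalanced class
frequencies and mild between-subject variation, so the full
window-ensemble pipeline can be exercised and tested without any dataset
download.

Signal model
------------
* ``strong`` periodicity: a sum of sinusoidal harmonics of a base period,
  plus white Gaussian noise.
* ``weak`` periodicity: the same harmonic stack, but each cycle's period is
  perturbed by Gaussian jitter, which blurs the spectral peak.
* ``none``: a constant offset plus order-1 autoregressive (low-pass) noise.

Channels share the underlying waveform with an independent random phase
shift and independent noise per channel, which retains multichannel
structure without extra parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .series import MultichannelSeries

__all__ = [
    "ActivitySpec",
    "Protocol",
    "ProtocolTemplate",
    "generate_activity_signal",
    "generate_session",
    "generate_dataset",
    "default_activity_specs",
    "default_class_weights",
]

_PERIODICITIES = ("strong", "weak", "none")

#: autoregressive coefficient for the aperiodic (low-pass noise) regime
_AR_COEFF = 0.9


@dataclass(frozen=True)
class ActivitySpec:
    """Parameters of one synthetic activity class.

    Parameters
    ----------
    name : str
        Human-readable activity label.
    class_index : int
        Integer class index in ``[0, K)``.
    periodicity : {"strong", "weak", "none"}
        Temporal regime of the signal (see module docstring).
    base_period : float
        Fundamental period in seconds; ignored when ``periodicity="none"``.
    amplitude : float
        Peak scale of the harmonic stack, or the constant offset for the
        aperiodic regime (signal units).
    harmonic_weights : tuple of float
        Relative weights of harmonics 1, 2, ... of the base period.
    period_jitter_sd : float
        Per-cycle period jitter (seconds); only used when ``periodicity="weak"``.
    noise_sd : float
        Standard deviation of the additive noise (signal units).
    """

    name: str
    class_index: int
    periodicity: str
    base_period: float = 1.0
    amplitude: float = 1.0
    harmonic_weights: tuple[float, ...] = (1.0,)
    period_jitter_sd: float = 0.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.periodicity not in _PERIODICITIES:
            raise ValueError(
                f"periodicity must be one of {_PERIODICITIES}, got {self.periodicity!r}"
            )
        if self.class_index < 0:
            raise ValueError("class_index must be nonnegative")
        if self.periodicity != "none" and self.base_period <= 0:
            raise ValueError("base_period must be positive for periodic activities")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("amplitude and noise_sd must be nonnegative")
        if any(w < 0 for w in self.harmonic_weights):
            raise ValueError("harmonic_weights must be nonnegative")


@dataclass(frozen=True)
class Protocol:
    """An ordered recording protocol for one subject.

    ``segments`` is a sequence of ``(activity_name, duration_seconds)``
    pairs; each duration is rounded to a whole number of samples.
    """

    segments: tuple[tuple[str, float], ...]
    subject_id: str
    sampling_rate: float
    n_channels: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")


@dataclass(frozen=True)
class ProtocolTemplate:
    """Session layout shared by all generated subjects.

    Each subject performs ``n_segments`` bouts of ``segment_seconds`` each,
    activities drawn per segment according to the dataset-level class
    weights. ``amplitude_subject_sd`` and ``period_subject_sd`` are relative
    standard deviations of per-subject multiplicative factors applied to all
    activity amplitudes and base periods — mild between-subject variation
    that makes subject-held-out evaluation a genuine generalisation test.
    """

    n_segments: int = 24
    segment_seconds: float = 10.0
    sampling_rate: float = 20.0
    n_channels: int = 3
    amplitude_subject_sd: float = 0.25
    period_subject_sd: float = 0.10

    def __post_init__(self) -> None:
        if self.n_segments < 1 or self.segment_seconds <= 0:
            raise ValueError("n_segments >= 1 and segment_seconds > 0 required")
        if self.sampling_rate <= 0 or self.n_channels < 1:
            raise ValueError("sampling_rate > 0 and n_channels >= 1 required")


def _harmonic_wave(phase: np.ndarray, spec: ActivitySpec) -> np.ndarray:
    """Weighted harmonic stack evaluated at a (possibly warped) phase.

    ``phase`` counts fundamental cycles; weights are normalised so the
    stack's RMS is amplitude/sqrt(2), matching a pure sinusoid of the same
    amplitude.
    """
    w = np.asarray(spec.harmonic_weights, dtype=float)
    total = math.sqrt(float(np.sum(w**2)))
    if total == 0:
        return np.zeros_like(phase)
    out = np.zeros_like(phase)
    for h, wh in enumerate(w, start=1):
        out += wh * np.sin(2 * math.pi * h * phase)
    return spec.amplitude * out / total


def generate_activity_signal(
    spec: ActivitySpec,
    duration: float,
    sampling_rate: float,
    n_channels: int = 3,
    seed: int = 0,
) -> MultichannelSeries:
    """Generate one constant-activity recording.

    Parameters
    ----------
    spec : ActivitySpec
        Activity class to synthesize.
    duration : float
        Length in seconds (> 0); rounded to a whole number of samples.
    sampling_rate : float
        Samples per second (> 0).
    n_channels : int
        Number of sensor channels.
    seed : int
        Seed for all randomness; identical arguments and seed give
        sample-identical output.

    Returns
    -------
    MultichannelSeries
        ``round(duration * sampling_rate)`` samples, every sample labelled
        ``spec.class_index``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    n = int(round(duration * sampling_rate))
    rng = np.random.default_rng(seed)
    t = np.arange(n) / sampling_rate
    out = np.empty((n, n_channels), dtype=float)

    if spec.periodicity == "none":
        # constant offset + AR(1) noise with stationary sd == noise_sd
        innov_sd = spec.noise_sd * math.sqrt(1.0 - _AR_COEFF**2)
        from scipy.signal import lfilter

        for c in range(n_channels):
            if spec.noise_sd > 0:
                e = rng.normal(0.0, innov_sd, size=n)
                prev = rng.normal(0.0, spec.noise_sd)
                x, _ = lfilter(
                    [1.0], [1.0, -_AR_COEFF], e, zi=np.array([_AR_COEFF * prev])
                )
            else:
                x = np.zeros(n)
            out[:, c] = spec.amplitude + x
    else:
        if spec.periodicity == "strong" or spec.period_jitter_sd == 0:
            phase = t / spec.base_period
        else:
            # warp phase: cycle k lasts base_period + N(0, jitter_sd)
            n_cycles = int(math.ceil(duration / spec.base_period)) + 3
            periods = spec.base_period + rng.normal(
                0.0, spec.period_jitter_sd, size=n_cycles
            )
            periods = np.maximum(periods, 0.1 * spec.base_period)
            boundaries = np.concatenate([[0.0], np.cumsum(periods)])
            while boundaries[-1] < duration:
                boundaries = np.append(
                    boundaries, boundaries[-1] + spec.base_period
                )
            phase = np.interp(t, boundaries, np.arange(len(boundaries)))
        # shared waveform, random per-channel phase shift, independent noise
        shifts = rng.uniform(0.0, 1.0, size=n_channels)
        for c in range(n_channels):
            sig = _harmonic_wave(phase + shifts[c], spec)
            if spec.noise_sd > 0:
                sig = sig + rng.normal(0.0, spec.noise_sd, size=n)
            out[:, c] = sig

    labels = np.full(n, spec.class_index, dtype=int)
    return MultichannelSeries(
        subject_id="",
        sampling_rate=sampling_rate,
        values=out,
        labels=labels,
        activity_names={spec.class_index: spec.name},
    )


def generate_session(
    protocol: Protocol, specs: dict[str, ActivitySpec]
) -> MultichannelSeries:
    """Concatenate per-segment signals into one subject session.

    The label changes exactly at the first sample of each new segment
    (half-open segments). Unknown activity names raise ``KeyError``.
    """
    seeds = np.random.SeedSequence(protocol.seed).generate_state(
        max(len(protocol.segments), 1)
    )
    parts = []
    names: dict[int, str] = {}
    for k, (activity, dur) in enumerate(protocol.segments):
        if activity not in specs:
            raise KeyError(f"unknown activity name: {activity!r}")
        spec = specs[activity]
        seg = generate_activity_signal(
            spec,
            duration=dur,
            sampling_rate=protocol.sampling_rate,
            n_channels=protocol.n_channels,
            seed=int(seeds[k] % (2**31)),
        )
        parts.append(seg)
        names.update(seg.activity_names)
    if not parts:
        raise ValueError("protocol has no segments")
    return MultichannelSeries(
        subject_id=protocol.subject_id,
        sampling_rate=protocol.sampling_rate,
        values=np.concatenate([p.values for p in parts]),
        labels=np.concatenate([p.labels for p in parts]),
        activity_names=names,
    )


def _subject_specs(
    specs: dict[str, ActivitySpec],
    template: ProtocolTemplate,
    rng: np.random.Generator,
) -> dict[str, ActivitySpec]:
    """Apply per-subject multiplicative amplitude/period factors."""
    amp = float(np.exp(rng.normal(0.0, template.amplitude_subject_sd)))
    per = float(np.exp(rng.normal(0.0, template.period_subject_sd)))
    out = {}
    for name, s in specs.items():
        out[name] = replace(
            s,
            amplitude=s.amplitude * amp,
            base_period=s.base_period * per if s.periodicity != "none" else s.base_period,
        )
    return out


def generate_dataset(
    n_subjects: int,
    specs: dict[str, ActivitySpec],
    protocol_template: ProtocolTemplate | None = None,
    class_weights: np.ndarray | None = None,
    split: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[
    list[MultichannelSeries], list[MultichannelSeries], list[MultichannelSeries]
]:
    """Generate a subject-disjoint train/validation/test dataset.

    Subjects are partitioned disjointly across the three splits (no subject
    leakage); each subject contributes one long session whose segment
    activities are sampled according to ``class_weights``.

    Parameters
    ----------
    n_subjects : int
        Total number of subjects (>= 3 so every split is populated).
    specs : dict
        Activity name -> :class:`ActivitySpec`; class indices must cover
        ``0..K-1``.
    protocol_template : ProtocolTemplate, optional
        Session layout; defaults to :class:`ProtocolTemplate` defaults.
    class_weights : array-like of length K, optional
        Per-class segment sampling weights (need not be normalised);
        defaults to uniform.
    split : (float, float, float)
        Train/validation/test subject fractions; must sum to 1.
    seed : int
        Master seed; identical arguments give identical datasets.

    Returns
    -------
    (train, val, test) : lists of MultichannelSeries
    """
    template = protocol_template or ProtocolTemplate()
    if n_subjects < 3:
        raise ValueError("n_subjects must be >= 3 to populate all three splits")
    if abs(sum(split) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split}")
    if any(f < 0 for f in split):
        raise ValueError("split fractions must be nonnegative")

    by_index = sorted(specs.values(), key=lambda s: s.class_index)
    k = len(by_index)
    if [s.class_index for s in by_index] != list(range(k)):
        raise ValueError("spec class indices must cover 0..K-1 exactly")
    if class_weights is None:
        weights = np.full(k, 1.0 / k)
    else:
        weights = np.asarray(class_weights, dtype=float)
        if len(weights) != k or weights.sum() <= 0 or (weights < 0).any():
            raise ValueError("class_weights must be K nonnegative values, sum > 0")
        weights = weights / weights.sum()

    # largest-remainder apportionment, then force every nonzero split >= 1
    counts = [int(math.floor(f * n_subjects)) for f in split]
    while sum(counts) < n_subjects:
        rem = [f * n_subjects - c for f, c in zip(split, counts)]
        counts[int(np.argmax(rem))] += 1
    for i, f in enumerate(split):
        if f > 0 and counts[i] == 0:
            donor = int(np.argmax(counts))
            if counts[donor] <= 1:
                raise ValueError("n_subjects too small to populate all splits")
            counts[donor] -= 1
            counts[i] += 1

    rng = np.random.default_rng(seed)
    subject_seeds = np.random.SeedSequence(seed).generate_state(n_subjects)
    splits: list[list[MultichannelSeries]] = [[], [], []]
    subject = 0
    for split_idx, count in enumerate(counts):
        for _ in range(count):
            sid = f"subject{subject + 1:02d}"
            srng = np.random.default_rng(int(subject_seeds[subject] % (2**31)))
            local = _subject_specs(specs, template, srng)
            activities = srng.choice(
                [s.name for s in by_index], size=template.n_segments, p=weights
            )
            protocol = Protocol(
                segments=tuple(
                    (str(a), template.segment_seconds) for a in activities
                ),
                subject_id=sid,
                sampling_rate=template.sampling_rate,
                n_channels=template.n_channels,
                seed=int(srng.integers(2**31)),
            )
            splits[split_idx].append(generate_session(protocol, local))
            subject += 1
    del rng
    return splits[0], splits[1], splits[2]


def default_activity_specs() -> dict[str, ActivitySpec]:
    """Six activity classes spanning the three periodicity regimes.

    Two strongly periodic locomotion-like classes, two weakly periodic
    semi-rhythmic classes, and two aperiodic quasi-static classes, with
    distinct periods, amplitudes and noise levels — the heterogeneous
    structure that motivates ensembling over multiple window sizes.
    """
    specs = [
        ActivitySpec("walking", 0, "strong", base_period=0.9, amplitude=1.0,
                     harmonic_weights=(1.0, 0.5, 0.2), noise_sd=0.25),
        ActivitySpec("running", 1, "strong", base_period=0.55, amplitude=1.6,
                     harmonic_weights=(1.0, 0.7, 0.3), noise_sd=0.35),
        ActivitySpec("stairs", 2, "weak", base_period=1.1, amplitude=1.1,
                     harmonic_weights=(1.0, 0.4), period_jitter_sd=0.12,
                     noise_sd=0.3),
        ActivitySpec("vacuuming", 3, "weak", base_period=1.5, amplitude=0.8,
                     harmonic_weights=(1.0, 0.3), period_jitter_sd=0.2,
                     noise_sd=0.3),
        ActivitySpec("standing", 4, "none", amplitude=0.2, noise_sd=0.1),
        ActivitySpec("ironing", 5, "none", amplitude=0.55, noise_sd=0.32),
    ]
    return {s.name: s for s in specs}


def default_class_weights() -> np.ndarray:
    """Imbalanced per-class segment weights mimicking daily-life recordings."""
    return np.array([0.26, 0.20, 0.16, 0.14, 0.13, 0.11])
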