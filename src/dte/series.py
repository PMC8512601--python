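"""Labelled multichannel sensor recordings and their on-disk format.

A :class:`MultichannelSeries` holds one subject's recording: an
``(n_samples, n_channels)`` signal matrix at a fixed sampling rate, a
per-sample integer activity label, and a class-index -> activity-name table.
Collections of series are persisted as plain delimited text with the header
``subject,t,ch1..chD,label`` (one row per sample), the format produced by
the synthetic generator and consumed by the windowing stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

__all__ = ["MultichannelSeries", "write_series_csv", "read_series_csv"]


@dataclass
class MultichannelSeries:
    """One subject's fixed-rate, per-sample-labelled sensor recording.

    Parameters
    ----------
    subject_id : str
        Identifier of the wearer; windows never cross subject boundaries.
    sampling_rate : float
        Samples per second (Hz).
    values : ndarray, shape (n_samples, n_channels)
        Sensor signal in arbitrary (accelerometer-like) units.
    labels : ndarray, shape (n_samples,)
        Integer class index of the activity performed at each sample.
    activity_names : dict[int, str]
        Class-index -> activity-name table.
    """

    subject_id: str
    sampling_rate: float
    values: np.ndarray
    labels: np.ndarray
    activity_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DataError("values must be 2-D (n_samples, n_channels)")
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1 or len(self.labels) != len(self.values):
            raise DataError(
                f"labels length {len(self.labels)} does not match "
                f"n_samples {len(self.values)}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.labels) and self.labels.min() < 0:
            raise DataError("labels must be nonnegative class indices")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def to_frame(self) -> pd.DataFrame:
        """Long-format table with columns ``subject, t, ch1..chD, label``."""
        d = self.n_channels
        data = {"subject": np.repeat(self.subject_id, self.n_samples)}
        data["t"] = np.arange(self.n_samples) / self.sampling_rate
        for c in range(d):
            data[f"ch{c + 1}"] = self.values[:, c]
        data["label"] = self.labels
        return pd.DataFrame(data)


def write_series_csv(
    series: list[MultichannelSeries],
    path,
    delimiter: str = ",",
) -> None:
    """Write a collection of series to one delimited text file.

    A JSON sidecar ``<path>.meta.json`` records the sampling rate and the
    class-index -> name table so the file round-trips losslessly.
    """
    if not series:
        raise ValueError("cannot write an empty series collection")
    rates = {s.sampling_rate for s in series}
    if len(rates) > 1:
        raise DataError(f"series have heterogeneous sampling rates: {rates}")
    chans = {s.n_channels for s in series}
    if len(chans) > 1:
        raise DataError(f"series have heterogeneous channel counts: {chans}")
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    frame.to_csv(path, sep=delimiter, index=False)
    names: dict[int, str] = {}
    for s in series:
        names.update(s.activity_names)
    meta = {
        "sampling_rate": series[0].sampling_rate,
        "n_channels": series[0].n_channels,
        "activity_names": {str(k): v for k, v in sorted(names.items())},
    }
    with open(f"{path}.meta.json", "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2)


def read_series_csv(path, delimiter: str = ",") -> list[MultichannelSeries]:
    """Read a delimited series file written by :func:`write_series_csv`.

    Falls back to a sampling rate inferred from the ``t`` column when the
    sidecar is missing, so externally produced files in the same layout load
    too. Returns one series per subject, in order of first appearance.
    """
    frame = pd.read_csv(path, sep=delimiter)
    required = {"subject", "t", "label"}
    if not required.issubset(frame.columns):
        raise DataError(f"missing required columns {required - set(frame.columns)}")
    channel_cols = [c for c in frame.columns if c.startswith("ch")]
    if not channel_cols:
        raise DataError("no channel columns (ch1..chD) found")
    try:
        with open(f"{path}.meta.json", encoding="utf-8") as fh:
            meta = json.load(fh)
        rate = float(meta["sampling_rate"])
        names = {int(k): v for k, v in meta["activity_names"].items()}
    except FileNotFoundError:
        t = frame["t"].to_numpy()
        dt = np.median(np.diff(t[: min(len(t), 1000)]))
        rate = 1.0 / dt if dt > 0 else 1.0
        names = {}
    out = []
    for subject in frame["subject"].astype(str).unique():
        sub = frame[frame["subject"].astype(str) == subject]
        out.append(
            MultichannelSeries(
                subject_id=subject,
                sampling_rate=rate,
                values=sub[channel_cols].to_numpy(dtype=float),
                labels=sub["label"].to_numpy(dtype=int),
                activity_names=names,
            )
        )
    return out
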