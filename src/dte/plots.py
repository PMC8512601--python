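"""Rendering: reliability diagrams, binwise-ECE curves, method comparisons.

All functions draw to files via the Agg backend and are deterministic for
identical inputs.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .calibration import CalibrationReport

__all__ = ["plot_reliability", "plot_binwise_ece", "plot_method_comparison"]


def plot_reliability(report: CalibrationReport, path, title: str = "") -> None:
    """Two-panel reliability diagram.

    Top: per-bin accuracy vs confidence with gap bars against the identity
    diagonal. Bottom: histogram of examples per bin with dotted lines at
    the overall accuracy and overall mean confidence.
    """
    b = report.bins
    centers = (b.edges[:-1] + b.edges[1:]) / 2
    width = 1.0 / b.n_bins
    fig, (ax_top, ax_bot) = plt.subplots(
        2, 1, figsize=(5, 6), sharex=True,
        gridspec_kw={"height_ratios": [3, 1]},
    )
    mask = b.nonempty
    ax_top.bar(
        centers[mask], b.conf_mean[mask], width=width * 0.92,
        color="#d86a6a", alpha=0.55, label="gap (confidence)", zorder=1,
    )
    ax_top.bar(
        centers[mask], b.acc_mean[mask], width=width * 0.92,
        color="#3c6fb0", alpha=0.9, label="accuracy", zorder=2,
    )
    ax_top.plot([0, 1], [0, 1], "k--", lw=1, label="perfect calibration")
    ax_top.set_ylabel("accuracy")
    ax_top.set_xlim(0, 1)
    ax_top.set_ylim(0, 1)
    ax_top.legend(loc="upper left", fontsize=8)
    label = f"ECE = {report.ece:.4f}"
    ax_top.set_title(f"{title}  ({label})" if title else label, fontsize=10)

    ax_bot.bar(centers, b.counts, width=width * 0.92, color="#777777")
    ax_bot.axvline(b.accuracy, color="#3c6fb0", ls=":", label="accuracy")
    ax_bot.axvline(b.mean_confidence, color="#d86a6a", ls=":",
                   label="mean confidence")
    ax_bot.set_xlabel("confidence")
    ax_bot.set_ylabel("count")
    ax_bot.legend(loc="upper left", fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_binwise_ece(
    gaps_by_method: dict[str, np.ndarray], path, log_scale: bool = True
) -> None:
    """Per-bin calibration gap curves, one line per method.

    NaN entries (empty bins) leave line breaks. The y-axis is logarithmic
    by default so well-calibrated bins remain distinguishable.
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, gaps in gaps_by_method.items():
        gaps = np.asarray(gaps, dtype=float)
        bins = np.arange(1, len(gaps) + 1)
        style = "--" if "dte" in name.lower() else "-"
        ax.plot(bins, np.where(gaps > 0, gaps, np.nan), style, marker="o",
                ms=3, label=name)
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("bin")
    ax.set_ylabel("|accuracy - confidence| per bin")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_method_comparison(
    values_by_method: dict[str, float], path, metric_name: str = "ECE"
) -> None:
    """Bar chart comparing one scalar metric across method variants."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    names = list(values_by_method)
    values = [values_by_method[n] for n in names]
    ax.bar(names, values, color="#3c6fb0")
    ax.set_ylabel(metric_name)
    ax.tick_params(axis="x", labelrotation=20)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
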