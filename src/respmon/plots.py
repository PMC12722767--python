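"""Plotting helpers for evaluation outputs (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .alarms import EventPRCurve
from .modeling import CalibrationReport


def plot_event_pr_curve(curve: EventPRCurve, ax=None, label=None):
    """Event recall vs alarm precision, threshold-ordered."""
    if ax is None:
        _, ax = plt.subplots()
    pts = sorted(
        (p for p in curve.points if p.precision is not None), key=lambda p: p.recall
    )
    ax.plot([p.recall for p in pts], [p.precision for p in pts], marker=".", label=label)
    ax.set_xlabel("event recall")
    ax.set_ylabel("alarm precision")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    if label:
        ax.legend()
    return ax


def plot_earliness(fractions: dict[float, float], ax=None):
    """Fraction of events warned at least h hours ahead, per cutoff."""
    if ax is None:
        _, ax = plt.subplots()
    hs = sorted(fractions)
    ax.bar([str(int(h)) for h in hs], [fractions[h] for h in hs])
    ax.set_xlabel("warning at least h hours early")
    ax.set_ylabel("fraction of events")
    ax.set_ylim(0, 1)
    return ax


def plot_calibration(report: CalibrationReport, ax=None):
    """Observed event fraction per score bin against the diagonal."""
    if ax is None:
        _, ax = plt.subplots()
    ok = ~np.isnan(report.observed)
    ax.plot([0, 1], [0, 1], ls="--", color="grey")
    ax.plot(report.bin_centers[ok], report.observed[ok], marker="o")
    ax.set_xlabel("predicted risk")
    ax.set_ylabel("observed risk")
    return ax
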