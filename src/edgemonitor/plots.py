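"""Matplotlib views of the usage analytics: compliance by month,
completion-time CDF overlays, and the time-of-day usage histogram."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .sessions_io import MonitoringSession
from .usage_analytics import CompletionCdf, ComplianceSeries

__all__ = ["plot_compliance", "plot_completion_cdfs", "plot_time_of_day"]


def plot_compliance(series: ComplianceSeries, path: str) -> None:
    """Mean weekly compliance (days/week) per calendar month, with sd bars;
    excluded months are left blank."""
    included = [m for m in series.monthly if not m.excluded and m.mean is not None]
    labels = [f"{m.year}-{m.month:02d}" for m in included]
    means = [m.mean for m in included]
    sds = [m.sd or 0.0 for m in included]
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.errorbar(range(len(means)), means, yerr=sds, fmt="o-", capsize=3)
    ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
    ax.set_ylim(0, 7.2)
    ax.set_ylabel("days of use per week")
    ax.set_title("Patient compliance by calendar month")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_completion_cdfs(cdfs: Sequence[CompletionCdf], path: str) -> None:
    """One empirical CDF line per month in the study; proficiency shows as
    lines drifting toward the y-axis."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for cdf in cdfs:
        t = np.asarray(cdf.times)
        y = np.arange(1, t.size + 1) / t.size
        ax.step(t, y, where="post", label=f"month {cdf.month_in_study}")
    ax.set_xlabel("diary completion time (s)")
    ax.set_ylabel("cumulative fraction of diaries")
    ax.set_xlim(0, None)
    ax.set_ylim(0, 1.0)
    ax.legend(fontsize=8)
    ax.set_title("Diary completion-time CDF by month in study")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_time_of_day(sessions: Sequence[MonitoringSession], path: str) -> None:
    """Histogram of session clock hours pooled across the cohort."""
    hours = [s.timestamp.hour for s in sessions]
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.hist(hours, bins=np.arange(25) - 0.5, edgecolor="white")
    ax.set_xticks(range(0, 24, 2))
    ax.set_xlabel("hour of day")
    ax.set_ylabel("sessions")
    ax.set_title("Time of use")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
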