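"""Small matplotlib helpers for flows, crash histograms and schedules."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_flow_profile", "plot_crash_histogram", "plot_schedule", "plot_trace"]


def _axes(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_flow_profile(F, ax=None, label=None):
    """Mean flow per interval across links."""
    ax = _axes(ax)
    F = np.asarray(F)
    ax.plot(np.arange(1, F.shape[1] + 1), F.mean(axis=0), label=label)
    ax.set_xlabel("interval")
    ax.set_ylabel("mean vehicles / interval")
    return ax


def plot_crash_histogram(psi, ax=None):
    """Total crashes per hour of day."""
    ax = _axes(ax)
    psi = np.atleast_2d(np.asarray(psi))
    ax.bar(np.arange(24), psi.sum(axis=0))
    ax.set_xlabel("hour of day")
    ax.set_ylabel("crashes")
    return ax


def plot_schedule(schedule, ax=None):
    """Active windows as horizontal bars, one row per site."""
    ax = _axes(ax)
    for w, s in enumerate(schedule.sites):
        ax.barh(w, s.finish - s.start, left=s.start, height=0.8)
    ax.set_xlabel("interval")
    ax.set_ylabel("site")
    ax.set_xlim(0, schedule.t_star)
    return ax


def plot_trace(trace, ax=None):
    """Best-fitness curve over GA generations."""
    ax = _axes(ax)
    ax.plot(trace["generation"], trace["best_fitness"])
    ax.set_xlabel("generation")
    ax.set_ylabel("best fitness")
    return ax
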