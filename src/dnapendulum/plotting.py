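"""Plot helpers for trajectories and viscosity sweeps (matplotlib)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .dynamics import Trajectory
from .experiments import SweepResult
from .observables import ObservableSeries

__all__ = ["plot_angular_deviations", "plot_series", "plot_sweep"]


def plot_angular_deviations(
    traj: Trajectory, strand: int = 1, max_sites: int = 30, ax=None
):
    """Overlay per-site angle traces of one strand against time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    n = traj.n
    step = max(1, n // max_sites)
    for i in range(0, n, step):
        ax.plot(traj.times, traj.phi[:, strand - 1, i], lw=0.5, alpha=0.6)
    ax.set_xlabel("t, s")
    ax.set_ylabel(r"$\varphi$, rad")
    ax.set_title(f"Angular deviations, strand {strand}")
    return ax


def plot_series(series: ObservableSeries, ax=None, **kwargs):
    """Plot one observable series against time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    ax.plot(series.times, series.values, **kwargs)
    ax.set_xlabel("t, s")
    ax.set_ylabel(f"{series.label or 'value'}, rad")
    return ax


def plot_sweep(sweep: SweepResult, vertical_shift: float | None = None, ax=None):
    """Overlay the per-lambda mean-deviation traces with a vertical shift.

    The shift separates the curves visually (as in stacked published
    traces); its magnitude is configurable and defaults to twice the
    largest oscillation amplitude in the sweep.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 6))
    if vertical_shift is None:
        spans = [s.values.max() - s.values.min() for s in sweep.series]
        vertical_shift = 1.0 if not spans else 1.1 * max(spans)
    for rank, (lam, series) in enumerate(zip(sweep.lambdas, sweep.series)):
        ax.plot(
            series.times,
            series.values + rank * vertical_shift,
            lw=0.7,
            label=rf"$\lambda$ = {lam:g}",
        )
    ax.set_xlabel("t, s")
    ax.set_ylabel("mean angular deviation (shifted), rad")
    ax.legend(loc="upper right", fontsize=8)
    return ax
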