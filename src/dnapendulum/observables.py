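"""Stability observables: mean angular deviation, envelopes, damping rates.

The model's primary readout is the strand-averaged base rotation angle

    phibar(t) = (1/n) * sum_i phi_{1i}(t),

whose oscillation amplitude either decays (high solvent viscosity, stable
molecule) or persists/grows (low viscosity).  This module quantifies that
behaviour: it extracts the oscillation envelope around the slowly varying
torque-induced offset and fits an exponential decay rate to the envelope
peaks, plus early/late window amplitudes so runs at different viscosity
scales can be compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks
from scipy.stats import linregress

from .dynamics import Trajectory

__all__ = [
    "ObservableSeries",
    "DampingMetrics",
    "mean_angular_deviation",
    "envelope",
    "damping_metrics",
    "modal_frequencies",
]


@dataclass
class ObservableSeries:
    """A scalar time series (values in rad against times in s)."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""
    window: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.window is None and len(self.times):
            self.window = (float(self.times[0]), float(self.times[-1]))

    def __len__(self) -> int:
        return len(self.times)

    def slice(self, t_start: float, t_end: float) -> "ObservableSeries":
        """Sub-series restricted to ``t_start <= t <= t_end``."""
        m = (self.times >= t_start) & (self.times <= t_end)
        return ObservableSeries(
            self.times[m], self.values[m], self.label, (t_start, t_end)
        )


@dataclass
class DampingMetrics:
    """Summary of how fast an oscillation settles.

    ``decay_rate`` (1/s) is the exponential rate fitted to the envelope
    peaks; ``early_amplitude`` and ``late_amplitude`` (rad) are the largest
    deviations from the steady offset inside the two comparison windows,
    and ``amplitude_ratio`` their late/early quotient (``nan`` and
    ``ratio_defined=False`` when the early amplitude vanishes).
    ``fit_quality`` is the R² of the log-envelope line fit, clipped to
    [0, 1].
    """

    decay_rate: float
    early_amplitude: float
    late_amplitude: float
    amplitude_ratio: float
    fit_quality: float
    ratio_defined: bool = True
    flags: list[str] = field(default_factory=list)


def mean_angular_deviation(traj: Trajectory, strand: int = 1) -> ObservableSeries:
    """Strand-averaged angular deviation phibar(t) = (1/n) sum_i phi_ji(t).

    Defined for the first chain by default; ``strand=2`` averages the
    complementary chain instead.
    """
    if strand not in (1, 2):
        raise ValueError("strand must be 1 or 2")
    values = traj.phi[:, strand - 1, :].mean(axis=1)
    return ObservableSeries(
        times=traj.times,
        values=values,
        label=f"mean_angular_deviation_strand{strand}",
    )


def _steady_offset(series: ObservableSeries) -> float:
    """Steady offset estimate: mean over the final quarter of the window."""
    n = len(series)
    return float(series.values[-max(1, n // 4) :].mean())


def _dominant_period(times: np.ndarray, dev: np.ndarray) -> float:
    """Rough dominant period from zero crossings of the detrended signal."""
    signs = np.sign(dev)
    signs[signs == 0] = 1
    crossings = int(np.count_nonzero(np.diff(signs)))
    span = times[-1] - times[0]
    if crossings < 2:
        return span  # essentially non-oscillatory on this window
    return 2.0 * span / crossings


def envelope(
    series: ObservableSeries, offset: float | None = None
) -> ObservableSeries:
    """Upper envelope of the oscillation around its steady offset.

    Local maxima of ``|values - offset|`` are located with a minimum peak
    separation of half the dominant period (estimated from zero crossings);
    the envelope is the piecewise-linear curve through those peaks.  The
    offset defaults to the mean over the final quarter of the window.

    Raises
    ------
    ValueError
        If fewer than 3 local extrema exist in the window.
    """
    if len(series) < 5:
        raise ValueError("series too short for envelope extraction")
    off = _steady_offset(series) if offset is None else float(offset)
    dev = np.abs(series.values - off)
    period = _dominant_period(series.times, series.values - off)
    dt = float(np.median(np.diff(series.times)))
    distance = max(1, int(round(0.5 * period / dt * 0.5)))
    # half the dominant period, with slack for |.|-rectified signals that
    # peak twice per period
    idx, _ = find_peaks(dev, distance=distance)
    if len(idx) < 3:
        raise ValueError(
            f"only {len(idx)} local extrema in the window; need >= 3 for an envelope"
        )
    return ObservableSeries(
        times=series.times[idx],
        values=dev[idx],
        label=f"envelope({series.label})",
        window=series.window,
    )


def damping_metrics(
    series: ObservableSeries,
    early_window: tuple[float, float] | None = None,
    late_window: tuple[float, float] | None = None,
) -> DampingMetrics:
    """Fit an exponential decay rate to the oscillation envelope.

    The decay rate is minus the slope of a least-squares line through
    ``log(peak amplitude)`` against peak time.  Window amplitudes are the
    maxima of ``|values - offset|`` inside ``early_window`` and
    ``late_window`` (defaults: first and last sixth of the span).

    A series with no usable oscillation (all zero, or fewer than three
    envelope peaks) is flagged and reported with rate 0.
    """
    t0, t1 = series.times[0], series.times[-1]
    span = t1 - t0
    if early_window is None:
        early_window = (t0, t0 + span / 6.0)
    if late_window is None:
        late_window = (t1 - span / 6.0, t1)
    if not (t0 <= early_window[0] < early_window[1] <= t1):
        raise ValueError("early window outside the series span")
    if not (t0 <= late_window[0] < late_window[1] <= t1):
        raise ValueError("late window outside the series span")
    if early_window[1] > late_window[0]:
        raise ValueError("early window must precede the late window")

    off = _steady_offset(series)
    dev = np.abs(series.values - off)
    flags: list[str] = []

    early = series.slice(*early_window)
    late = series.slice(*late_window)
    if len(early) == 0 or len(late) == 0:
        raise ValueError("comparison windows contain no samples")
    early_amp = float(np.abs(early.values - off).max())
    late_amp = float(np.abs(late.values - off).max())

    if dev.max() == 0.0:
        flags.append("all-zero series")
        return DampingMetrics(0.0, 0.0, 0.0, float("nan"), 0.0, False, flags)

    try:
        env = envelope(series, offset=off)
    except ValueError:
        flags.append("too few extrema for envelope fit")
        rate, r2 = 0.0, 0.0
    else:
        # ignore peaks buried in numerical noise relative to the largest one
        keep = env.values > env.values.max() * 1e-9
        t_pk, a_pk = env.times[keep], env.values[keep]
        if len(t_pk) < 3:
            flags.append("too few usable peaks")
            rate, r2 = 0.0, 0.0
        else:
            fit = linregress(t_pk, np.log(a_pk))
            rate = -float(fit.slope)
            r2 = float(np.clip(fit.rvalue**2, 0.0, 1.0))

    if early_amp > 0.0:
        ratio = late_amp / early_amp
        defined = True
    else:
        ratio, defined = float("nan"), False
        flags.append("early amplitude zero; ratio undefined")
    return DampingMetrics(rate, early_amp, late_amp, ratio, r2, defined, flags)


def modal_frequencies(
    values: Sequence[float], dt: float, n_modes: int = 4
) -> np.ndarray:
    """Complex continuous-time mode rates of a uniformly sampled signal.

    Fits the signal as a sum of ``n_modes`` complex exponentials
    ``sum_k c_k exp(mu_k t)`` by linear prediction (Prony-type least
    squares on the autoregressive recurrence, then polynomial roots) and
    returns the ``mu_k = log(z_k)/dt`` sorted by ascending imaginary part.

    Oscillation angular frequencies are ``abs(imag(mu))``; real parts are
    growth (positive) or damping (negative) rates.  This resolves a slow
    oscillation superimposed on an exponential trend far better than an
    FFT on short windows.
    """
    x = np.asarray(values, dtype=float)
    p = int(n_modes)
    if len(x) < 2 * p + 1:
        raise ValueError("signal too short for the requested number of modes")
    # x[k+p] = -a1 x[k+p-1] - ... - ap x[k]  (least squares over all k)
    m = len(x) - p
    A = np.column_stack([x[p - 1 - j : p - 1 - j + m] for j in range(p)])
    b = x[p:]
    coeffs, *_ = np.linalg.lstsq(A, b, rcond=None)
    poly = np.concatenate([[1.0], -coeffs])
    z = np.roots(poly)
    z = z[np.abs(z) > 1e-12]
    mu = np.log(z.astype(complex)) / dt
    return mu[np.argsort(mu.imag)]
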