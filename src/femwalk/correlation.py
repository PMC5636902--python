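"""Time-averaged displacement statistics and their summaries.

For a single trajectory of N samples the package uses time averages
rather than ensemble averages (trials are short and few):

* mean squared displacement
  ``MSD(l) = (1/(N-l)) * sum_i |x[i+l] - x[i]|^2``,
* displacement autocorrelation over a fixed interval of k samples
  ``DACF(l) = (1/(N-l-k)) * sum_i (x[i+l+k]-x[i+l]) . (x[i+k]-x[i]) / k^2``,
  reported normalised to its value at lag 0.

Curves are computed per trial and averaged pointwise across trials
(never pooled over concatenated trials).  The scaling exponent alpha of
``MSD ~ lag^alpha`` is an ordinary least-squares slope in log10-log10
coordinates over a lag window given in milliseconds; the canonical
windows are 2-12 ms (short scale) and 120-1200 ms (long scale) at
500 Hz sampling.

Oscillation metrics locate the first positive local maximum of the DACF
after its initial zero crossing.  For a delayed feedback loop with delay
tau the oscillation period T satisfies ``2 tau < T < 4 tau``, so an
observed period brackets the loop delay as ``T/4 < tau < T/2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import Trajectory

__all__ = [
    "CorrelationCurve",
    "ScalingFit",
    "OscillationMetrics",
    "msd",
    "dacf",
    "average_curves",
    "fit_scaling_exponent",
    "oscillation_metrics",
    "delay_bounds_from_period",
    "SHORT_RANGE_MS",
    "LONG_RANGE_MS",
    "DEFAULT_K",
]

SHORT_RANGE_MS = (2.0, 12.0)
LONG_RANGE_MS = (120.0, 1200.0)
DEFAULT_K = 25  # displacement interval: 50 ms at 500 Hz


@dataclass
class CorrelationCurve:
    """MSD or DACF as a function of integer sample lag."""

    kind: str  # "MSD" | "DACF"
    lags: np.ndarray
    values: np.ndarray
    dt: float
    k: int | None = None  # DACF displacement interval (samples)
    n_trials: int = 1
    sd: np.ndarray | None = None  # per-lag SD across trials, set by average_curves

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must align")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")

    @property
    def lag_ms(self) -> np.ndarray:
        return self.lags * self.dt * 1000.0


@dataclass
class ScalingFit:
    """OLS power-law fit of the MSD over a millisecond lag window."""

    alpha: float
    intercept: float
    range_ms: tuple[float, float]
    stderr: float
    n_points: int
    residual_rms: float


@dataclass
class OscillationMetrics:
    """First-maximum summary of a DACF curve.

    ``detected`` is False when the curve never crosses zero or shows no
    positive local maximum above ``min_peak`` afterwards — a first-class
    outcome, not an error (non-oscillating walks produce it).
    """

    detected: bool
    first_max_lag_ms: float | None = None
    peak_value: float | None = None
    period_ms: float | None = None
    delay_bounds_ms: tuple[float, float] | None = None


def msd(traj: Trajectory, max_lag: int, component: int | None = None) -> CorrelationCurve:
    """Time-averaged mean squared displacement for lags ``1 .. max_lag``.

    2-D input sums the squared displacement over both components;
    ``component`` restricts the estimate to one movement component.
    """
    x = traj.positions if component is None else traj.positions[:, component : component + 1]
    n = x.shape[0]
    if not 1 <= max_lag < n:
        raise ValueError("require 1 <= max_lag < N")
    lags = np.arange(1, max_lag + 1)
    vals = np.empty(max_lag)
    for idx, l in enumerate(lags):
        d = x[l:] - x[:-l]
        vals[idx] = np.einsum("ij,ij->", d, d) / (n - l)
    return CorrelationCurve("MSD", lags, vals, traj.dt)


def dacf(
    traj: Trajectory,
    k: int = DEFAULT_K,
    max_lag: int = 300,
    component: int | None = None,
    normalise: bool = True,
) -> CorrelationCurve:
    """Normalised displacement autocorrelation for lags ``0 .. max_lag``."""
    x = traj.positions if component is None else traj.positions[:, component : component + 1]
    n = x.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if max_lag + k >= n:
        raise ValueError("trajectory too short: need max_lag + k < N")
    d = (x[k:] - x[:-k]) / float(k)  # displacement over k samples, length n-k
    lags = np.arange(0, max_lag + 1)
    vals = np.empty(max_lag + 1)
    for idx, l in enumerate(lags):
        m = n - l - k
        vals[idx] = np.einsum("ij,ij->", d[l : l + m], d[:m]) / m
    if normalise:
        if vals[0] <= 0:
            raise ValueError("DACF(0) <= 0: constant trajectory cannot be normalised")
        vals = vals / vals[0]
    return CorrelationCurve("DACF", lags, vals, traj.dt, k=k)


def average_curves(curves: list[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean across trials, with per-lag SD as error bars."""
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0]
    for c in curves[1:]:
        if c.kind != ref.kind or c.k != ref.k or abs(c.dt - ref.dt) > 1e-12:
            raise ValueError("curves must share kind, k and dt")
        if not np.array_equal(c.lags, ref.lags):
            raise ValueError("mismatched lag grids")
    stack = np.vstack([c.values for c in curves])
    return CorrelationCurve(
        ref.kind,
        ref.lags.copy(),
        stack.mean(axis=0),
        ref.dt,
        k=ref.k,
        n_trials=sum(c.n_trials for c in curves),
        sd=stack.std(axis=0, ddof=0),
    )


def fit_scaling_exponent(
    curve: CorrelationCurve, range_ms: tuple[float, float]
) -> ScalingFit:
    """OLS slope of log10 MSD against log10 lag over an inclusive ms window."""
    lo, hi = range_ms
    lag_ms = curve.lag_ms
    mask = (lag_ms >= lo) & (lag_ms <= hi) & (curve.values > 0) & (curve.lags > 0)
    if mask.sum() < 3:
        raise ValueError(f"fewer than 3 positive lags inside [{lo}, {hi}] ms")
    lx = np.log10(curve.lags[mask] * curve.dt)
    ly = np.log10(curve.values[mask])
    res = stats.linregress(lx, ly)
    resid = ly - (res.intercept + res.slope * lx)
    return ScalingFit(
        alpha=float(res.slope),
        intercept=float(res.intercept),
        range_ms=(lo, hi),
        stderr=float(res.stderr),
        n_points=int(mask.sum()),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def delay_bounds_from_period(period_ms: float) -> tuple[float, float]:
    """Feedback-delay bracket implied by an oscillation period T.

    Delayed physiological control loops oscillate with ``2 tau < T <
    4 tau``; inverting gives ``T/4 < tau < T/2``.
    """
    if not period_ms > 0:
        raise ValueError("period must be positive")
    return (period_ms / 4.0, period_ms / 2.0)


def oscillation_metrics(
    curve: CorrelationCurve,
    min_peak: float = 0.05,
    presmooth: bool = False,
) -> OscillationMetrics:
    """Locate the first positive DACF maximum after the initial decay.

    The curve must span at least 400 ms of lag.  The first maximum is
    the smallest lag after the first zero crossing at which the curve is
    a strict discrete local maximum with value above ``min_peak`` (the
    floor rejects estimator noise around zero on non-oscillating walks).
    The period T is identified with that lag, and the implied feedback
    delay bracket is ``(T/4, T/2)``.
    """
    if curve.kind != "DACF":
        raise ValueError("oscillation metrics are defined on DACF curves")
    if curve.lag_ms[-1] < 400.0:
        raise ValueError("DACF must span at least 400 ms of lag")
    vals = curve.values
    if presmooth:
        kernel = np.ones(3) / 3.0
        inner = np.convolve(vals, kernel, mode="valid")
        vals = np.concatenate([[vals[0]], inner, [vals[-1]]])

    neg = np.nonzero(vals < 0)[0]
    if len(neg) == 0:
        return OscillationMetrics(detected=False)
    start = neg[0]
    for i in range(max(start, 1) + 1, len(vals) - 1):
        if vals[i] > vals[i - 1] and vals[i] > vals[i + 1] and vals[i] > min_peak:
            lag_ms = float(curve.lags[i] * curve.dt * 1000.0)
            return OscillationMetrics(
                detected=True,
                first_max_lag_ms=lag_ms,
                peak_value=float(vals[i]),
                period_ms=lag_ms,
                delay_bounds_ms=delay_bounds_from_period(lag_ms),
            )
    return OscillationMetrics(detected=False)
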