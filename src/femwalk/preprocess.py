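"""Velocity estimation, smoothing, and microsaccade detection/removal.

The pipeline mirrors the classical velocity-based microsaccade detector
for 500 Hz video-oculography:

1. velocities via a weighted moving average over five samples
   (central differences at the two inner endpoints),
2. an elliptical velocity threshold with median-based axes
   ``eta = lambda * sigma``,
3. a minimum episode duration of three velocity samples (6 ms),
4. optional binocular confirmation (temporal overlap of at least one
   velocity sample between the eyes),
5. removal of microsaccades by deleting their velocity samples and
   re-integrating the remainder.

Index convention: positions are 0-based internally; a velocity sample
exists for every interior position index ``i = 1 .. N-2`` and episodes
are reported in that position-index space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Trajectory

__all__ = [
    "VelocitySeries",
    "MsEpisode",
    "DetectionParams",
    "DegenerateThresholdError",
    "estimate_velocity",
    "integrate_velocity",
    "smooth",
    "median_sigma",
    "detect_monocular",
    "pair_binocular",
    "remove_microsaccades",
]


class DegenerateThresholdError(ValueError):
    """Raised when the median-based velocity spread is zero or negative."""


@dataclass
class VelocitySeries:
    """Velocity samples for interior position indices ``1 .. N-2``.

    ``values[m]`` is the velocity at position index ``m + 1``; units are
    position units per second.
    """

    values: np.ndarray  # (N-2, d)
    dt: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if not np.isfinite(v).all():
            raise ValueError("velocity series contains non-finite values")
        self.values = v

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class MsEpisode:
    """A detected microsaccade: inclusive index interval in position-index space."""

    onset: int
    end: int
    eye: str = "left"  # left | right | binocular

    def __post_init__(self) -> None:
        if self.end < self.onset:
            raise ValueError("episode end before onset")

    @property
    def n_samples(self) -> int:
        return self.end - self.onset + 1

    def overlaps(self, other: "MsEpisode") -> bool:
        """Strict-overlap criterion: other.end > self.onset and other.onset < self.end."""
        return other.end > self.onset and other.onset < self.end


@dataclass(frozen=True)
class DetectionParams:
    lambda_thresh: float = 5.0
    min_samples: int = 3
    binocular: bool = False

    def __post_init__(self) -> None:
        if not self.lambda_thresh > 0:
            raise ValueError("lambda_thresh must be positive")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")


def estimate_velocity(traj: Trajectory) -> VelocitySeries:
    """Five-sample weighted moving-average velocity estimate.

    Interior samples use ``(x[i+2] + x[i+1] - x[i-1] - x[i-2]) / (6 dt)``;
    the first and last interior index fall back to the symmetric central
    difference ``(x[i+1] - x[i-1]) / (2 dt)``.
    """
    x = traj.positions
    n = traj.n_samples
    dt = traj.dt
    v = np.empty((n - 2, x.shape[1]))
    v[1:-1] = (x[4:] + x[3:-1] - x[1:-3] - x[:-4]) / (6.0 * dt)
    v[0] = (x[2] - x[0]) / (2.0 * dt)
    v[-1] = (x[-1] - x[-3]) / (2.0 * dt)
    return VelocitySeries(v, dt)


def integrate_velocity(v: VelocitySeries, x1: np.ndarray | float) -> Trajectory:
    """Cumulative summation of velocity samples back to a trajectory.

    ``x[0] = x[1] = x1`` (empty sum) and ``x[i] = x1 + dt * sum(v[:i-1])``
    for ``i >= 2``; the output has ``len(v) + 2`` samples.

    Note the convention implies a one-sample time shift: on a linear
    trajectory the output reproduces ``x[i-1]`` at index ``i``.  A pure
    time shift is irrelevant to the displacement statistics computed
    downstream (MSD, DACF), which are time-averaged.
    """
    vals = v.values
    x1 = np.atleast_1d(np.asarray(x1, dtype=float))
    if x1.shape[0] != vals.shape[1]:
        raise ValueError("x1 dimensionality does not match the velocity series")
    out = np.empty((len(vals) + 2, vals.shape[1]))
    out[0] = x1
    out[1] = x1
    out[2:] = x1 + v.dt * np.cumsum(vals, axis=0)
    return Trajectory(out, dt=v.dt, unit_label="integrated")


def smooth(traj: Trajectory) -> Trajectory:
    """Smoothed trajectory: velocity estimation followed by re-integration."""
    out = integrate_velocity(estimate_velocity(traj), traj.positions[0])
    out.unit_label = traj.unit_label
    return out


def median_sigma(values: np.ndarray) -> np.ndarray:
    """Median-based spread per component: sqrt(median(v^2) - median(v)^2).

    Raises :class:`DegenerateThresholdError` when any component's value
    is not strictly positive (constant velocity, or the pathological
    negative case the median estimator admits).
    """
    var = np.median(values**2, axis=0) - np.median(values, axis=0) ** 2
    if np.any(var <= 0):
        raise DegenerateThresholdError("degenerate threshold: median-based variance <= 0")
    return np.sqrt(var)


def detect_monocular(
    v: VelocitySeries, p: DetectionParams = DetectionParams(), eye: str = "left"
) -> list[MsEpisode]:
    """Elliptical-threshold detection on one eye's velocity series.

    An episode is a maximal run of at least ``min_samples`` consecutive
    velocity samples with ``sum((v_c / eta_c)^2) > 1`` where
    ``eta_c = lambda * sigma_c`` per component.  Episode indices are in
    position-index space (velocity row ``m`` maps to index ``m + 1``).
    """
    vals = v.values
    eta = p.lambda_thresh * median_sigma(vals)
    crit = np.sum((vals / eta) ** 2, axis=1) > 1.0

    episodes: list[MsEpisode] = []
    m = 0
    n = len(crit)
    while m < n:
        if crit[m]:
            start = m
            while m < n and crit[m]:
                m += 1
            if m - start >= p.min_samples:
                episodes.append(MsEpisode(start + 1, m, eye=eye))
        else:
            m += 1
    return episodes


def pair_binocular(left: list[MsEpisode], right: list[MsEpisode]) -> list[MsEpisode]:
    """Binocular confirmation by strict temporal overlap.

    A left/right pair is kept iff ``r.end > l.onset`` and
    ``r.onset < l.end`` (strict inequalities); each surviving pair
    yields one binocular episode spanning the union of the two
    intervals.  Unmatched monocular episodes are dropped.
    """
    out = []
    for l in left:
        for r in right:
            if r.end > l.onset and r.onset < l.end:
                out.append(
                    MsEpisode(min(l.onset, r.onset), max(l.end, r.end), eye="binocular")
                )
    out.sort(key=lambda e: (e.onset, e.end))
    return out


def remove_microsaccades(traj: Trajectory, episodes: list[MsEpisode]) -> Trajectory:
    """Delete microsaccadic velocity samples and re-integrate.

    Episodes refer to position indices of ``traj``; the corresponding
    velocity samples are removed, the remainder concatenated in order,
    and the cumulative summation re-applied from the first position.
    The output is shorter by the total number of removed samples.
    """
    v = estimate_velocity(traj)
    n_v = len(v)
    keep = np.ones(n_v, dtype=bool)
    for ep in episodes:
        lo, hi = ep.onset - 1, ep.end - 1  # position index -> velocity row
        if lo < 0 or hi >= n_v:
            raise IndexError(f"episode [{ep.onset}, {ep.end}] outside velocity range")
        keep[lo : hi + 1] = False
    vv = VelocitySeries(v.values[keep], v.dt)
    out = integrate_velocity(vv, traj.positions[0])
    out.unit_label = traj.unit_label
    return out
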