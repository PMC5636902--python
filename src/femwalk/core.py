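"""Shared data model for eye-trajectory trials.

A :class:`Trajectory` is a uniformly sampled 1-D or 2-D position time
series (degrees for recorded/synthetic data, lattice units for the
self-avoiding-walk family, model units for the delayed-feedback model).
A :class:`TrialSet` bundles the trials of one participant or one
simulated condition, optionally with a paired right-eye trajectory per
trial.

All randomness in the package flows through :func:`trial_rng`: one
independent NumPy generator per (seed, trial index), so any trial can be
re-simulated in isolation and the full set is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MIN_SAMPLES",
    "Trajectory",
    "TrialSet",
    "RngSpec",
    "trial_rng",
]

#: minimum trajectory length: the 5-point velocity estimator needs it
MIN_SAMPLES = 5

DEFAULT_DT = 0.002  # 500 Hz sampling


@dataclass
class Trajectory:
    """Uniformly sampled eye-position time series.

    Parameters
    ----------
    positions
        Array of shape ``(N, d)`` with ``d`` in {1, 2}; column order is
        (horizontal, vertical).  A 1-D array of shape ``(N,)`` is
        accepted and reshaped to ``(N, 1)``.
    dt
        Sample interval in seconds (default 0.002, i.e. 500 Hz).
    unit_label
        Free-text unit tag, e.g. ``"deg"``, ``"lattice"``, ``"model"``.
    """

    positions: np.ndarray
    dt: float = DEFAULT_DT
    unit_label: str = "deg"

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim == 1:
            pos = pos[:, None]
        if pos.ndim != 2 or pos.shape[1] not in (1, 2):
            raise ValueError("positions must have shape (N,), (N, 1) or (N, 2)")
        if pos.shape[0] < MIN_SAMPLES:
            raise ValueError(
                f"trajectory needs at least {MIN_SAMPLES} samples, got {pos.shape[0]}"
            )
        if not np.isfinite(pos).all():
            raise ValueError("trajectory contains missing or non-finite samples")
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        self.positions = pos

    @property
    def n_samples(self) -> int:
        return self.positions.shape[0]

    @property
    def n_dim(self) -> int:
        return self.positions.shape[1]

    @property
    def duration(self) -> float:
        """Trial duration in seconds (N * dt)."""
        return self.n_samples * self.dt

    @property
    def time(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) * self.dt

    def component(self, idx: int) -> "Trajectory":
        """Extract one movement component as a 1-D trajectory."""
        return Trajectory(self.positions[:, idx : idx + 1], self.dt, self.unit_label)

    def __len__(self) -> int:
        return self.n_samples


@dataclass
class TrialSet:
    """A collection of trials sharing dt, optionally binocular.

    ``trials`` holds the (left-eye) trajectories; ``right`` — if given —
    holds the paired right-eye trajectories, index-aligned and with
    matching sample counts.
    """

    trials: list[Trajectory]
    right: list[Trajectory] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.trials:
            dt0 = self.trials[0].dt
            for t in self.trials:
                if abs(t.dt - dt0) > 1e-12 * dt0:
                    raise ValueError("all trials must share dt")
        if self.right is not None:
            if len(self.right) != len(self.trials):
                raise ValueError("left/right trial counts differ")
            for lt, rt in zip(self.trials, self.right):
                if lt.n_samples != rt.n_samples:
                    raise ValueError("paired eyes must share the sample count")

    @property
    def binocular(self) -> bool:
        return self.right is not None

    @property
    def dt(self) -> float:
        if not self.trials:
            raise ValueError("empty TrialSet has no dt")
        return self.trials[0].dt

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)


@dataclass(frozen=True)
class RngSpec:
    """Random-number contract: seed plus a stream-per-trial rule.

    ``for_trial(i)`` returns an independent generator for trial ``i``
    derived via :class:`numpy.random.SeedSequence` spawning, so the same
    (seed, i) always yields the same stream regardless of how many other
    trials are simulated.
    """

    seed: int

    def for_trial(self, trial_index: int) -> np.random.Generator:
        return trial_rng(self.seed, trial_index)


def trial_rng(seed: int, trial_index: int = 0) -> np.random.Generator:
    """Independent per-trial generator derived from (seed, trial_index)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(trial_index))))
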