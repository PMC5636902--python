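"""Non-linear delayed feedback (NDF) model of fixational drift.

A first-order autoregressive map of the pooled activity ``w`` of
excitatory burst neurons, with a tanh-saturated negative feedback acting
after a transmission delay of ``tau`` samples, integrated to eye
position::

    w[i+1] = (1 - gamma) * w[i] + xi[i] - lam * tanh(eps * w[i - tau])
    x[i+1] = x[i] + w[i+1] + eta[i]

``xi`` and ``eta`` are i.i.d. Gaussian (SDs ``sigma`` and ``rho``):
burst-neuron baseline noise and tonic-unit (position) noise.  The leak
``gamma`` models the inertia of the eyeball; the delayed negative
feedback stabilises fixation and, through the delay, produces
antipersistence and oscillatory displacement correlations at long lags.

Horizontal and vertical movement are governed by separate control loops
with different delays (70 ms and 40 ms, i.e. 35 and 20 samples at
500 Hz), so the 2-D simulator runs two independent 1-D instances.
Output positions are in model units; the analyses compare correlation
shapes, not amplitudes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import Trajectory

__all__ = ["NdfParams", "simulate_ndf", "simulate_ndf_2d", "TAU_HOR", "TAU_VER"]

TAU_HOR = 35  # 70 ms at 500 Hz
TAU_VER = 20  # 40 ms


@dataclass(frozen=True)
class NdfParams:
    """Parameters of the delayed-feedback map (defaults: best-match set)."""

    gamma: float = 0.25  # leak (eyeball inertia)
    lam: float = 0.15  # feedback gain
    eps: float = 1.1  # feedback steepness
    sigma: float = 0.075  # SD of burst noise xi
    rho: float = 0.35  # SD of position noise eta
    tau: int = TAU_HOR  # delay in samples
    burn_in: int = 2000  # discarded initial samples (>> tau)

    def __post_init__(self) -> None:
        if self.tau < 0 or int(self.tau) != self.tau:
            raise ValueError("tau must be a non-negative integer")
        if self.sigma < 0 or self.rho < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.gamma <= 1:
            raise ValueError("gamma must lie in [0, 1]")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")


def simulate_ndf(
    p: NdfParams, n_steps: int, rng: np.random.Generator, dt: float = 0.002
) -> Trajectory:
    """Simulate one movement component for ``n_steps`` recorded samples.

    The activity history is initialised at zero (``w[j] = 0`` for
    ``j <= 0``) and the first ``p.burn_in`` samples are discarded so the
    initial transient does not reach the output.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    n_total = p.burn_in + n_steps
    xi = rng.normal(0.0, p.sigma, n_total) if p.sigma > 0 else np.zeros(n_total)
    eta = rng.normal(0.0, p.rho, n_total) if p.rho > 0 else np.zeros(n_total)

    tau = int(p.tau)
    one_m_gamma = 1.0 - p.gamma
    lam, eps = p.lam, p.eps
    tanh = math.tanh

    # w[t] for t = 0 .. n_total; delayed index t - tau reads 0 while t < tau
    w = [0.0] * (n_total + 1)
    x = np.empty(n_total + 1)
    x[0] = 0.0
    xpos = 0.0
    xi_l = xi.tolist()
    eta_l = eta.tolist()
    for i in range(n_total):
        w_del = w[i - tau] if i >= tau else 0.0
        w_new = one_m_gamma * w[i] + xi_l[i] - lam * tanh(eps * w_del)
        w[i + 1] = w_new
        xpos += w_new + eta_l[i]
        x[i + 1] = xpos
    return Trajectory(x[p.burn_in + 1 :], dt=dt, unit_label="model")


def simulate_ndf_2d(
    p_hor: NdfParams | None = None,
    p_ver: NdfParams | None = None,
    n_steps: int = 10_000,
    rng: np.random.Generator | None = None,
    dt: float = 0.002,
) -> Trajectory:
    """Two independent component simulations combined into a 2-D trajectory.

    Defaults use the component delays 35 samples (horizontal) and 20
    samples (vertical); each component consumes an independent child
    stream spawned from ``rng`` so the components are uncorrelated by
    construction.
    """
    if p_hor is None:
        p_hor = NdfParams(tau=TAU_HOR)
    if p_ver is None:
        p_ver = replace(p_hor, tau=TAU_VER)
    if rng is None:
        rng = np.random.default_rng()
    rng_h, rng_v = rng.spawn(2)
    hor = simulate_ndf(p_hor, n_steps, rng_h, dt=dt)
    ver = simulate_ndf(p_ver, n_steps, rng_v, dt=dt)
    pos = np.column_stack([hor.positions[:, 0], ver.positions[:, 0]])
    return Trajectory(pos, dt=dt, unit_label="model")
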