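"""Fading self-avoiding walk (SAW) on a square lattice.

The walker lives on an ``L x L`` lattice that stands for the retinotopic
map of the superior colliculus.  Each iteration (one 2 ms time step):

1. if the activation at the walker's current site exceeds the threshold
   ``h_c``, a microsaccade is triggered: the walker jumps to the global
   minimum of ``h + u + u1``;
2. otherwise the walker steps to the von Neumann neighbour (4
   neighbours) with the lowest ``h + u``, ties broken uniformly;
3. the walker increments the activation at the visited site by one unit
   (self-avoidance memory);
4. the whole field decays geometrically, ``h <- (1 - eps) h``.

``u`` is a quadratic restoring potential centred on the lattice (the
fixation target); its horizontal/vertical slopes ``lam_hor``/``lam_ver``
may differ to model anisotropic fixation control.  ``u1`` is the
microsaccadic potential that biases jump landing sites towards the
horizontal and vertical axes.

The global decay is implemented lazily: the field is stored as
``h = scale * f`` with one scalar ``scale`` shrinking per iteration, so
an iteration costs O(1) instead of O(L^2).  The representation is exact
(same floating-point products), with a periodic renormalisation long
before the scale can underflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Trajectory

__all__ = [
    "SawParams",
    "LatticeState",
    "MsEvent",
    "SawOutput",
    "potential_u",
    "potential_u1",
    "choose_step",
    "saw_iteration",
    "simulate_saw",
]

TIE_TOL = 1e-12
_RENORM_SCALE = 1e-120


@dataclass(frozen=True)
class SawParams:
    """Lattice-walk parameters (defaults: the best-match set)."""

    L: int = 51
    lam: float = 1.0  # potential slope (isotropic)
    lam_hor: float | None = None  # anisotropic override, horizontal
    lam_ver: float | None = None
    chi: float = 2.0  # microsaccadic-potential strength
    eps_relax: float = 1e-3  # global activation decay rate
    h_c: float = 7.9  # microsaccade trigger threshold
    burn_in: int = 10_000

    def __post_init__(self) -> None:
        if self.L < 3 or self.L % 2 == 0:
            raise ValueError("L must be odd and >= 3")
        if not 0 < self.eps_relax < 1:
            raise ValueError("eps_relax must lie in (0, 1)")
        if not self.h_c > 0:
            raise ValueError("h_c must be positive")

    @property
    def slope_hor(self) -> float:
        return self.lam if self.lam_hor is None else self.lam_hor

    @property
    def slope_ver(self) -> float:
        return self.lam if self.lam_ver is None else self.lam_ver


def potential_u(site: tuple[int, int], p: SawParams) -> float:
    """Quadratic restoring potential at a 0-based site ``(i, j)``.

    ``u(i, j) = L * (lam_hor ((i - i0)/d)^2 + lam_ver ((j - j0)/d)^2)``
    with centre ``i0 = j0 = (L - 1)/2`` and ``d = (L + 1)/2``; zero at
    the centre, maximal at the corners.
    """
    i, j = site
    c = (p.L - 1) // 2
    d = (p.L + 1) // 2
    return p.L * (
        p.slope_hor * ((i - c) / d) ** 2 + p.slope_ver * ((j - c) / d) ** 2
    )


def potential_u1(site: tuple[int, int], p: SawParams) -> float:
    """Microsaccadic potential: ``chi * L * ((i-i0)/d)^2 ((j-j0)/d)^2``.

    Vanishes on the horizontal and vertical axes through the centre, so
    jump landings concentrate there.
    """
    i, j = site
    c = (p.L - 1) // 2
    d = (p.L + 1) // 2
    return p.chi * p.L * ((i - c) / d) ** 2 * ((j - c) / d) ** 2


@dataclass(frozen=True)
class MsEvent:
    """A triggered microsaccade: recorded step index, origin and landing site."""

    step: int
    origin: tuple[int, int]
    landing: tuple[int, int]


class LatticeState:
    """Activation field plus walker position, with lazy global decay.

    The physical field is ``h = scale * f``; incrementing h by one unit
    adds ``1/scale`` to ``f`` and the global decay multiplies ``scale``
    alone.  ``h`` materialises the physical field as an ``(L, L)``
    array.
    """

    __slots__ = ("p", "L", "f", "scale", "pos_flat", "_u", "_u_np", "_msu_np", "_nbrs")

    def __init__(self, p: SawParams, h: np.ndarray | None = None,
                 pos: tuple[int, int] | None = None) -> None:
        self.p = p
        L = p.L
        self.L = L
        if h is None:
            h = np.zeros((L, L))
        h = np.asarray(h, dtype=float)
        if h.shape != (L, L) or (h < 0).any():
            raise ValueError("h must be a non-negative (L, L) array")
        self.f = h.ravel().tolist()
        self.scale = 1.0
        c = (L - 1) // 2
        if pos is None:
            pos = (c, c)
        if not (0 <= pos[0] < L and 0 <= pos[1] < L):
            raise ValueError("pos outside lattice")
        self.pos_flat = pos[0] * L + pos[1]

        u = np.empty((L, L))
        u1 = np.empty((L, L))
        for i in range(L):
            for j in range(L):
                u[i, j] = potential_u((i, j), p)
                u1[i, j] = potential_u1((i, j), p)
        self._u_np = u.ravel()
        self._msu_np = (u + u1).ravel()
        self._u = self._u_np.tolist()
        nbrs = []
        for i in range(L):
            for j in range(L):
                nn = []
                if i > 0:
                    nn.append((i - 1) * L + j)
                if i < L - 1:
                    nn.append((i + 1) * L + j)
                if j > 0:
                    nn.append(i * L + j - 1)
                if j < L - 1:
                    nn.append(i * L + j + 1)
                nbrs.append(nn)
        self._nbrs = nbrs

    @classmethod
    def initial(cls, p: SawParams, rng: np.random.Generator) -> "LatticeState":
        """Burn-in initial condition: i.i.d. uniform(0, 1) field, walker centred."""
        return cls(p, h=rng.random((p.L, p.L)))

    @property
    def pos(self) -> tuple[int, int]:
        return divmod(self.pos_flat, self.L)

    @pos.setter
    def pos(self, site: tuple[int, int]) -> None:
        if not (0 <= site[0] < self.L and 0 <= site[1] < self.L):
            raise ValueError("pos outside lattice")
        self.pos_flat = site[0] * self.L + site[1]

    @property
    def h(self) -> np.ndarray:
        return (np.asarray(self.f) * self.scale).reshape(self.L, self.L)

    def set_h(self, site: tuple[int, int], value: float) -> None:
        """Set the physical activation at one site (testing hook)."""
        self.f[site[0] * self.L + site[1]] = value / self.scale

    def _renorm(self) -> None:
        m = self.scale
        self.f = [v * m for v in self.f]
        self.scale = 1.0

    def ms_target_flat(self, field: tuple[list, float] | None = None) -> int:
        """Global argmin of ``h + u + u1``; ``field`` substitutes (f, scale)."""
        f, m = (self.f, self.scale) if field is None else field
        vals = np.asarray(f) * m + self._msu_np
        return int(np.argmin(vals))


def _argmin_step(state: LatticeState, site_flat: int, rng: np.random.Generator,
                 g_f: list | None = None, g_scale: float | None = None) -> int:
    """Argmin of field + u over the available neighbours of ``site_flat``.

    ``g_f``/``g_scale`` substitute a (possibly delayed) field; ties
    within TIE_TOL are broken uniformly at random.  Returns a flat site.
    """
    f = state.f if g_f is None else g_f
    m = state.scale if g_scale is None else g_scale
    u = state._u
    best = None
    best_val = float("inf")
    ties: list[int] = []
    for k in state._nbrs[site_flat]:
        val = m * f[k] + u[k]
        if val < best_val - TIE_TOL:
            best_val = val
            best = k
            ties = [k]
        elif val <= best_val + TIE_TOL:
            ties.append(k)
            if val < best_val:
                best_val = val
                best = k
    if len(ties) > 1:
        return ties[int(rng.integers(len(ties)))]
    return best


def choose_step(state: LatticeState, p: SawParams, rng: np.random.Generator) -> tuple[int, int]:
    """Next site: von Neumann neighbour of the walker minimising ``h + u``."""
    k = _argmin_step(state, state.pos_flat, rng)
    return divmod(k, state.L)


def saw_iteration(
    state: LatticeState,
    p: SawParams,
    rng: np.random.Generator,
    *,
    readout_site: int | None = None,
    readout_field: tuple[list, float] | None = None,
    set_site: int | None = None,
    trigger_field: tuple[list, float] | None = None,
    random_step: bool = False,
    increment: bool = True,
    decay: bool = True,
) -> tuple[tuple[int, int], tuple[int, int]] | None:
    """One lattice iteration; returns (origin, landing) if an MS fired.

    Order: the visit's activation increment is deposited first, then the
    microsaccade trigger tests the activation at the current site
    (always on the current, non-delayed field and position), then the
    step readout, the global decay, and the move.  Counting the visit's
    own deposit in the trigger is what makes the threshold ``h_c = 7.9``
    meaningful: arrival activations excluding the deposit stay below ~7
    at the default parameters and would never fire.

    The keyword hooks implement the delayed variants: a foreign
    ``readout_site`` yields a relative step applied to the walker's true
    position (clamped to the lattice), a foreign ``set_site`` relocates
    the activation increment, ``readout_field`` substitutes a past field
    for the step decision, and ``trigger_field`` substitutes a past
    field for the threshold test and the jump-target readout.
    """
    L = state.L
    f = state.f
    m = state.scale
    cur = state.pos_flat

    if increment:
        ip = cur if set_site is None else set_site
        f[ip] += 1.0 / m

    tf, tm = (f, m) if trigger_field is None else trigger_field
    event = None
    if tm * tf[cur] > p.h_c:
        nxt = state.ms_target_flat(trigger_field)
        event = (divmod(cur, L), divmod(nxt, L))
    elif random_step:
        nn = state._nbrs[cur]
        nxt = nn[int(rng.integers(len(nn)))]
    else:
        site = cur if readout_site is None else readout_site
        if readout_field is None:
            chosen = _argmin_step(state, site, rng)
        else:
            chosen = _argmin_step(state, site, rng, readout_field[0], readout_field[1])
        if site == cur:
            nxt = chosen
        else:  # relative step, applied at the true position
            si, sj = divmod(site, L)
            oi, oj = divmod(chosen, L)
            ci, cj = divmod(cur, L)
            ni = min(max(ci + oi - si, 0), L - 1)
            nj = min(max(cj + oj - sj, 0), L - 1)
            nxt = ni * L + nj

    if decay:
        state.scale = m * (1.0 - p.eps_relax)
        if state.scale < _RENORM_SCALE:
            state._renorm()
    state.pos_flat = nxt
    return event


@dataclass
class SawOutput:
    """Recorded walk: lattice-unit trajectory plus microsaccade events."""

    trajectory: Trajectory
    ms_events: list[MsEvent]
    final_state: LatticeState | None = field(default=None, repr=False)

    @property
    def ms_rate(self) -> float:
        """Microsaccade events per second of recorded trajectory."""
        return len(self.ms_events) / self.trajectory.duration


def simulate_saw(
    p: SawParams, n_steps: int, rng: np.random.Generator, dt: float = 0.002
) -> SawOutput:
    """Simulate the SAW: burn-in from a random field, then record.

    The burn-in runs ``p.burn_in`` iterations from an i.i.d. uniform
    (0, 1) activation field with the walker at the centre; its
    trajectory is discarded and its final state seeds the recorded run.
    One iteration corresponds to one 2 ms sample.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    state = LatticeState.initial(p, rng)
    for _ in range(p.burn_in):
        saw_iteration(state, p, rng)
    traj = np.empty((n_steps, 2))
    events: list[MsEvent] = []
    for t in range(n_steps):
        ev = saw_iteration(state, p, rng)
        if ev is not None:
            events.append(MsEvent(t, ev[0], ev[1]))
        traj[t] = state.pos
    return SawOutput(
        Trajectory(traj, dt=dt, unit_label="lattice"), events, final_state=state
    )
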