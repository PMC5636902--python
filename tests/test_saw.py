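import numpy as np
import pytest
from scipy import stats

from femwalk import (
    LatticeState,
    SawParams,
    Trajectory,
    choose_step,
    fit_scaling_exponent,
    msd,
    average_curves,
    potential_u,
    potential_u1,
    saw_iteration,
    simulate_saw,
    trial_rng,
)


class TestPotentials:
    def test_zero_at_centre(self):
        p = SawParams()
        assert potential_u((25, 25), p) == 0.0

    def test_edge_value_matches_hand_evaluation(self):
        # 0-based (0, 25) is the 1-based lattice edge midpoint (1, 26):
        # u = L * (25/26)^2 = 51 * 625/676
        p = SawParams()
        assert potential_u((0, 25), p) == pytest.approx(51 * 625 / 676)
        assert potential_u((0, 25), p) == pytest.approx(47.152, abs=1e-3)

    def test_mirror_symmetry(self):
        p = SawParams()
        for i, j in [(3, 10), (12, 40), (0, 0)]:
            assert potential_u((i, j), p) == pytest.approx(potential_u((50 - i, j), p))

    def test_anisotropic_slopes(self):
        p = SawParams(lam_hor=0.9, lam_ver=1.1)
        assert potential_u((0, 25), p) == pytest.approx(0.9 * 51 * 625 / 676)
        assert potential_u((25, 0), p) == pytest.approx(1.1 * 51 * 625 / 676)

    def test_ms_potential_zero_on_axes(self):
        p = SawParams()
        for i in range(0, 51, 7):
            assert potential_u1((i, 25), p) == 0.0
            assert potential_u1((25, i), p) == 0.0

    def test_ms_potential_corner_value(self):
        p = SawParams()
        assert potential_u1((0, 0), p) == pytest.approx(2 * 51 * (625 / 676) ** 2)

    def test_ms_potential_nonnegative(self):
        p = SawParams()
        grid = [potential_u1((i, j), p) for i in range(51) for j in range(0, 51, 5)]
        assert min(grid) >= 0.0


class TestChooseStep:
    def test_unique_minimum_is_deterministic(self):
        p = SawParams()
        h = np.zeros((51, 51))
        h[24, 25] = 5.0
        h[26, 25] = 5.0
        h[25, 24] = 5.0  # (25, 26) is the unique minimum
        state = LatticeState(p, h=h)
        for _ in range(5):
            assert choose_step(state, p, trial_rng(0)) == (25, 26)

    def test_zero_field_centre_ties_uniform(self):
        p = SawParams()
        state = LatticeState(p)
        rng = trial_rng(42)
        counts = {}
        for _ in range(10_000):
            s = choose_step(state, p, rng)
            counts[s] = counts.get(s, 0) + 1
        assert set(counts) == {(24, 25), (26, 25), (25, 24), (25, 26)}
        chi2 = stats.chisquare(list(counts.values()))
        assert chi2.pvalue > 0.01

    def test_matches_exhaustive_argmin(self):
        p = SawParams()
        rng = np.random.default_rng(7)
        for _ in range(50):
            h = rng.random((51, 51)) * 10
            i, j = rng.integers(1, 50, 2)
            state = LatticeState(p, h=h, pos=(i, j))
            got = choose_step(state, p, trial_rng(0))
            cands = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
            vals = [h[c] + potential_u(c, p) for c in cands]
            assert got == cands[int(np.argmin(vals))]


class TestSawIteration:
    def test_increment_and_decay_composition(self):
        p = SawParams()
        state = LatticeState(p)  # zero field, walker at centre
        saw_iteration(state, p, trial_rng(0))
        h = state.h
        assert h[25, 25] == pytest.approx(1 - p.eps_relax)
        h[25, 25] = 0.0
        assert np.allclose(h, 0.0)

    def test_forced_trigger_lands_at_global_argmin(self):
        p = SawParams()
        rng = np.random.default_rng(1)
        h = rng.random((51, 51))
        state = LatticeState(p, h=h, pos=(10, 40))
        state.set_h((10, 40), p.h_c + 1.0)
        ev = saw_iteration(state, p, trial_rng(0))
        assert ev is not None
        origin, landing = ev
        assert origin == (10, 40)
        # oracle: full-lattice scan of h + u + u1 (h as seen by the trigger,
        # i.e. including the visit's own deposit)
        field = state.h / (1 - p.eps_relax)  # undo this iteration's decay
        total = np.array(
            [
                [field[i, j] + potential_u((i, j), p) + potential_u1((i, j), p) for j in range(51)]
                for i in range(51)
            ]
        )
        assert landing == tuple(int(v) for v in np.unravel_index(np.argmin(total), (51, 51)))
        assert state.pos == landing

    def test_infinite_threshold_never_fires(self):
        p = SawParams(h_c=float("inf"), burn_in=200)
        out = simulate_saw(p, 2000, trial_rng(0))
        assert out.ms_events == []


class TestSimulateSaw:
    def test_same_seed_identical_output(self):
        p = SawParams(burn_in=500)
        a = simulate_saw(p, 1000, trial_rng(8, 1))
        b = simulate_saw(p, 1000, trial_rng(8, 1))
        assert np.array_equal(a.trajectory.positions, b.trajectory.positions)
        assert [(e.step, e.origin, e.landing) for e in a.ms_events] == [
            (e.step, e.origin, e.landing) for e in b.ms_events
        ]

    def test_walker_confined_and_field_bounded(self):
        p = SawParams(burn_in=2000)
        out = simulate_saw(p, 5000, trial_rng(3))
        pos = out.trajectory.positions
        assert pos.min() >= 0 and pos.max() <= 50
        h = out.final_state.h
        assert h.min() >= 0
        assert h.max() <= 1.0 / p.eps_relax  # geometric-series bound

    def test_memoryless_flat_limit_is_diffusive(self):
        # near-instant fading and no potential: long-range exponent ~ 1
        p = SawParams(L=201, lam=0.0, eps_relax=0.99, h_c=float("inf"), burn_in=100)
        curves = [
            msd(simulate_saw(p, 2500, trial_rng(21, s)).trajectory, 650) for s in range(8)
        ]
        fit = fit_scaling_exponent(average_curves(curves), (120, 1200))
        assert 0.8 <= fit.alpha <= 1.2

    def test_ms_origins_at_activation_core_landings_outside(self):
        # activation accumulates fastest at the potential minimum, so
        # threshold crossings happen at the lattice core while the jump
        # target (global minimum of h + u + u1) avoids the activation hump
        p = SawParams(burn_in=5000)
        dists_o, dists_l = [], []
        for s in range(12):
            out = simulate_saw(p, 10_000, trial_rng(17, s))
            for e in out.ms_events:
                dists_o.append(np.hypot(e.origin[0] - 25, e.origin[1] - 25))
                dists_l.append(np.hypot(e.landing[0] - 25, e.landing[1] - 25))
        assert len(dists_o) >= 10
        assert np.median(dists_o) <= 2.0
        assert np.median(dists_l) > np.median(dists_o)
        assert np.max(dists_l) < 15.0  # jumps stay well inside the lattice

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SawParams(L=50)
        with pytest.raises(ValueError):
            SawParams(eps_relax=0.0)
        with pytest.raises(ValueError):
            SawParams(h_c=0.0)
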