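import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from femwalk import (
    DegenerateThresholdError,
    DetectionParams,
    MsEpisode,
    Trajectory,
    VelocitySeries,
    detect_monocular,
    estimate_velocity,
    integrate_velocity,
    pair_binocular,
    remove_microsaccades,
    smooth,
)

DT = 0.002


class TestEstimateVelocity:
    def test_linear_gives_exact_slope_everywhere(self, linear_trajectory):
        v = estimate_velocity(linear_trajectory)
        # 1 unit per sample = 500 units/s; both the 5-point form and the
        # endpoint central differences reduce to the exact slope
        assert np.allclose(v.values, 500.0)
        assert len(v) == linear_trajectory.n_samples - 2

    def test_quadratic_matches_symbolic_expansion(self):
        # x_j = j^2 (0-based): the 5-point sum expands to 12j/(6 dt) = 2j/dt
        j = np.arange(20, dtype=float)
        v = estimate_velocity(Trajectory(j**2, dt=DT))
        interior = np.arange(2, 18)
        assert np.allclose(v.values[1:-1, 0], 2 * interior / DT)

    def test_endpoints_use_central_difference(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(10, 1))
        v = estimate_velocity(Trajectory(x, dt=DT))
        assert v.values[0, 0] == pytest.approx((x[2, 0] - x[0, 0]) / (2 * DT))
        assert v.values[-1, 0] == pytest.approx((x[9, 0] - x[7, 0]) / (2 * DT))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=(2, 12, 2))
        vx = estimate_velocity(Trajectory(x, dt=DT)).values
        vy = estimate_velocity(Trajectory(y, dt=DT)).values
        vmix = estimate_velocity(Trajectory(a * x + b * y, dt=DT)).values
        assert np.allclose(vmix, a * vx + b * vy, atol=1e-8)


class TestIntegrateVelocity:
    def test_constant_velocity_gives_linear_output(self):
        v = VelocitySeries(np.full((8, 1), 3.0), dt=DT)
        out = integrate_velocity(v, np.array([1.0]))
        x = out.positions[:, 0]
        assert x[0] == x[1] == 1.0
        assert np.allclose(np.diff(x[1:]), 3.0 * DT)
        assert out.n_samples == 10

    def test_matches_naive_loop_summation(self, rng):
        vals = rng.normal(size=(40, 2))
        v = VelocitySeries(vals, dt=DT)
        out = integrate_velocity(v, np.array([0.5, -0.5]))
        # brute-force cumulative summation oracle
        expect = np.zeros((42, 2))
        expect[0] = expect[1] = [0.5, -0.5]
        for i in range(2, 42):
            expect[i] = expect[0] + DT * vals[: i - 1].sum(axis=0)
        assert np.allclose(out.positions, expect, atol=1e-12)

    def test_round_trip_on_linear_data_is_one_sample_shift(self, linear_trajectory):
        # the cumulative-summation convention reproduces x[i-1] at index i
        out = smooth(linear_trajectory)
        x = linear_trajectory.positions
        assert np.allclose(out.positions[2:], x[1:-1])
        assert np.allclose(out.positions[:2], x[0])


class TestSmooth:
    def test_white_noise_short_msd_slope_increases(self, rng):
        from femwalk import fit_scaling_exponent, msd

        t = Trajectory(rng.normal(0, 1, (5000, 2)), dt=DT)
        raw = fit_scaling_exponent(msd(t, 20), (2, 12)).alpha
        sm = fit_scaling_exponent(msd(smooth(t), 20), (2, 12)).alpha
        assert sm > raw


class TestDetectMonocular:
    def _series(self, vals):
        return VelocitySeries(np.asarray(vals, dtype=float), dt=DT)

    def test_constant_velocity_is_degenerate(self):
        with pytest.raises(DegenerateThresholdError):
            detect_monocular(self._series(np.ones((30, 2))))

    def test_minimum_run_length(self, rng):
        base = rng.normal(0, 1, (60, 2))
        p = DetectionParams(lambda_thresh=5, min_samples=3)
        for run, expected in [(3, 1), (2, 0)]:
            v = base.copy()
            v[20 : 20 + run] = 40.0  # far outside the 5-sigma ellipse
            eps = detect_monocular(self._series(v), p)
            assert len(eps) == expected
            if expected:
                assert eps[0].onset == 21 and eps[0].end == 20 + run

    def test_matches_bruteforce_run_scan(self, rng):
        from femwalk.preprocess import median_sigma

        vals = rng.standard_t(3, size=(200, 2))
        p = DetectionParams(min_samples=3)
        eps = detect_monocular(VelocitySeries(vals, DT), p)
        # oracle: exhaustive scan over all index windows
        eta = p.lambda_thresh * median_sigma(vals)
        crit = ((vals / eta) ** 2).sum(axis=1) > 1
        expected = []
        i = 0
        while i < len(crit):
            j = i
            while j < len(crit) and crit[j]:
                j += 1
            if j - i >= 3:
                expected.append((i + 1, j))
            i = max(j, i + 1)
        assert [(e.onset, e.end) for e in eps] == expected

    def test_invariant_under_position_offset(self, rng):
        x = np.cumsum(rng.normal(0, 1, (500, 2)), axis=0)
        x[100:110] += np.linspace(0, 50, 10)[:, None]  # a fast event
        a = detect_monocular(estimate_velocity(Trajectory(x, dt=DT)))
        b = detect_monocular(estimate_velocity(Trajectory(x + 17.3, dt=DT)))
        assert [(e.onset, e.end) for e in a] == [(e.onset, e.end) for e in b]


class TestPairBinocular:
    def test_touching_intervals_rejected(self):
        # r_onset < l_end fails: 15 < 15 is false under the strict criterion
        out = pair_binocular([MsEpisode(10, 15)], [MsEpisode(15, 20, "right")])
        assert out == []

    def test_overlap_gives_union_episode(self):
        out = pair_binocular([MsEpisode(10, 15)], [MsEpisode(14, 20, "right")])
        assert len(out) == 1
        assert (out[0].onset, out[0].end, out[0].eye) == (10, 20, "binocular")

    def test_disjoint_rejected(self):
        assert pair_binocular([MsEpisode(10, 15)], [MsEpisode(30, 35, "right")]) == []

    def test_symmetric_in_eyes(self, rng):
        def randeps(r):
            eps, t = [], 0
            for _ in range(8):
                t += int(r.integers(1, 20))
                end = t + int(r.integers(2, 10))
                eps.append(MsEpisode(t, end))
                t = end + 1
            return eps

        left, right = randeps(np.random.default_rng(3)), randeps(np.random.default_rng(4))
        ab = {(e.onset, e.end) for e in pair_binocular(left, right)}
        ba = {(e.onset, e.end) for e in pair_binocular(right, left)}
        assert ab == ba


class TestRemoveMicrosaccades:
    def test_empty_episode_list_equals_smoothing(self, random_walk_2d):
        out = remove_microsaccades(random_walk_2d, [])
        assert np.allclose(out.positions, smooth(random_walk_2d).positions)

    def test_length_shrinks_by_episode_size(self, random_walk_2d):
        out = remove_microsaccades(random_walk_2d, [MsEpisode(50, 57)])
        assert out.n_samples == random_walk_2d.n_samples - 8

    def test_out_of_range_episode_raises(self, random_walk_2d):
        with pytest.raises(IndexError):
            remove_microsaccades(random_walk_2d, [MsEpisode(398, 399)])
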