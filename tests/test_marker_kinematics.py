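import numpy as np
import pytest

from gaitlen import (
    GaitScenario,
    MarkerTrajectory,
    StanceConfig,
    finite_difference,
    generate_markers,
    kinematics,
    reference_strides,
)


class TestFiniteDifference:
    def test_exact_for_linear(self):
        t = np.sort(np.random.default_rng(0).uniform(0, 5, 50))
        np.testing.assert_allclose(finite_difference(2 * t, t), 2.0)

    def test_central_difference_exact_for_quadratic_interior(self):
        t = np.arange(0, 2, 0.1)
        d = finite_difference(t**2, t)
        np.testing.assert_allclose(d[1:-1], 2 * t[1:-1], atol=1e-12)

    def test_interior_error_bounded_for_sine(self):
        h = 0.01
        t = np.arange(0, 2 * np.pi, h)
        err = np.abs(finite_difference(np.sin(t), t)[1:-1] - np.cos(t)[1:-1])
        assert err.max() <= h**2 / 6 + 1e-12

    def test_linearity(self, rng):
        t = np.arange(0, 1, 0.01)
        f, g = rng.standard_normal(t.size), rng.standard_normal(t.size)
        lhs = finite_difference(3 * f - 2 * g, t)
        rhs = 3 * finite_difference(f, t) - 2 * finite_difference(g, t)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_short_series_and_duplicate_times_rejected(self):
        with pytest.raises(ValueError):
            finite_difference(np.array([1.0, 2.0]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="duplicate"):
            finite_difference(np.zeros(3), np.array([0.0, 0.0, 1.0]))


class TestKinematics:
    def test_stationary_marker_is_all_zero(self):
        t = np.arange(0, 2, 0.01)
        traj = MarkerTrajectory("M1", t, np.ones_like(t), np.zeros_like(t), np.zeros_like(t))
        kin = kinematics(traj)
        np.testing.assert_allclose(kin.velocity, 0.0, atol=1e-12)
        np.testing.assert_allclose(kin.acceleration, 0.0, atol=1e-12)

    def test_uniform_motion(self):
        t = np.arange(0, 2, 0.01)
        traj = MarkerTrajectory("M1", t, t, np.zeros_like(t), np.zeros_like(t))
        kin = kinematics(traj)
        np.testing.assert_allclose(kin.velocity[:, 0], 1.0, atol=1e-9)
        np.testing.assert_allclose(kin.acceleration[5:-5], 0.0, atol=1e-9)

    def test_sinusoid_velocity_amplitude(self):
        t = np.arange(0, 5, 0.01)
        A, w = 0.05, 2 * np.pi * 1.0
        traj = MarkerTrajectory("M1", t, A * np.sin(w * t), np.zeros_like(t), np.zeros_like(t))
        kin = kinematics(traj)
        assert np.max(np.abs(kin.velocity[:, 0])) == pytest.approx(A * w, rel=0.03)


def _overground_heel(stride_lengths, seed=7, noise=0.0):
    scenario = GaitScenario(seed=seed, n_strides=len(stride_lengths), route="overground")
    return generate_markers(scenario, stride_lengths=list(stride_lengths),
                            marker_noise_sd=noise)["M7"]


class TestReferenceStrides:
    def test_constructed_stance_geometry(self):
        # stance plateaus centred at x = 0, 1.2, 2.4 m
        fs, stance, swing = 100, 0.5, 0.5
        xs, ts = [], []
        t0 = 0.0
        for cx in (0.0, 1.2, 2.4):
            n_st = int(stance * fs)
            n_sw = int(swing * fs)
            xs += [cx] * n_st
            xs += list(cx + 1.2 * 0.5 * (1 - np.cos(np.pi * np.arange(n_sw) / n_sw)))
        xs = np.array(xs[: len(xs) - n_sw])  # end in last stance
        t = np.arange(len(xs)) / fs
        heel = MarkerTrajectory("M7", t, xs, np.zeros_like(xs), np.zeros_like(xs))
        refs = reference_strides(heel)
        assert len(refs) == 2
        assert [d for _, d in refs] == pytest.approx([1.2, 1.2], abs=0.02)

    def test_treadmill_belt_identity(self):
        # stationary stance points; stride = belt_speed * inter-stance interval
        fs = 100
        x = np.concatenate([np.zeros(60), 0.1 * np.sin(np.pi * np.arange(50) / 50),
                            np.zeros(60)])
        t = np.arange(x.size) / fs
        heel = MarkerTrajectory("M7", t, x, np.zeros_like(x), np.zeros_like(x))
        refs = reference_strides(heel, StanceConfig(belt_speed=1.0))
        assert len(refs) == 1
        (t0, t1), d = refs[0]
        # identity up to stance-edge detection granularity (sub-millimetre)
        assert d == pytest.approx(t1 - t0, abs=2e-3)

    def test_round_trip_recovers_configured_length(self):
        heel = _overground_heel([1.30] * 30)
        refs = reference_strides(heel)
        assert len(refs) == 29
        assert np.mean([d for _, d in refs]) == pytest.approx(1.30, abs=0.02)

    def test_jittered_stance_positions_recovered(self):
        heel = _overground_heel([1.30] * 30, noise=0.005)
        lengths = np.array([d for _, d in reference_strides(heel)])
        assert np.max(np.abs(lengths - 1.30)) < 0.02

    def test_invariant_to_in_plane_rotation(self):
        heel = _overground_heel([1.25] * 20)
        th = 0.7
        rx = heel.x * np.cos(th) - heel.y * np.sin(th)
        ry = heel.x * np.sin(th) + heel.y * np.cos(th)
        rot = MarkerTrajectory("M7", heel.t, rx, ry, heel.z)
        d0 = [d for _, d in reference_strides(heel)]
        d1 = [d for _, d in reference_strides(rot)]
        np.testing.assert_allclose(d0, d1, atol=1e-9)

    def test_too_few_stances_gives_empty(self):
        t = np.arange(0, 1, 0.01)
        heel = MarkerTrajectory("M7", t, t * 2.0, np.zeros_like(t), np.zeros_like(t))
        assert reference_strides(heel) == []
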