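import dataclasses

import numpy as np
import pytest
from scipy.signal import find_peaks

import surromod.motion_model as mm
import surromod.synthetic as syn
from surromod.surrogates import SurrogateTrace, interpolate_height

from conftest import noiseless_scenario


def regular_params(**kw):
    defaults = dict(nominal_period=4.0, period_sd=0.0, nominal_amplitude=10.0,
                    amplitude_sd=0.0, drift_rate=0.0, noise_sd=0.0,
                    duration=120.0, sample_rate=3.0)
    defaults.update(kw)
    return syn.BreathingParams(**defaults)


class TestBreathingSignal:
    def test_degenerate_variability_is_periodic(self):
        sig = syn.simulate_breathing_signal(regular_params(), seed=0)
        shift = 12  # one 4 s period at 3 Hz
        np.testing.assert_allclose(sig.values[shift:], sig.values[:-shift], atol=1e-9)

    def test_same_seed_identical(self):
        p = syn.BreathingParams(duration=60.0)
        a = syn.simulate_breathing_signal(p, seed=42)
        b = syn.simulate_breathing_signal(p, seed=42)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.clean, b.clean)

    def test_different_seed_differs(self):
        p = syn.BreathingParams(duration=60.0)
        a = syn.simulate_breathing_signal(p, seed=1)
        b = syn.simulate_breathing_signal(p, seed=2)
        assert not np.array_equal(a.values, b.values)

    def test_mean_cycle_length_matches_nominal(self):
        # oracle: independent minima detection on the generated signal
        period_sd = 0.4
        p = regular_params(period_sd=period_sd, duration=420.0)  # ~100 cycles
        sig = syn.simulate_breathing_signal(p, seed=3)
        idx, _ = find_peaks(sig.clean, distance=6)  # inhalation peaks, >2 s apart
        cycles = np.diff(sig.times[idx])
        n = cycles.size
        assert n > 80
        se = period_sd / np.sqrt(n)
        assert abs(np.mean(cycles) - p.nominal_period) < 2 * se + 2 / 3.0 / n

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            syn.simulate_breathing_signal(regular_params(duration=-1.0), seed=0)
        with pytest.raises(ValueError):
            syn.simulate_breathing_signal(regular_params(sample_rate=0.0), seed=0)

    def test_drift_rate_applied(self):
        p = regular_params(drift_rate=6.0, duration=60.0)  # 6 mm/min = 0.1 mm/s
        sig = syn.simulate_breathing_signal(p, seed=0)
        drift = sig.values - sig.clean
        np.testing.assert_allclose(drift, 0.1 * sig.times, atol=1e-12)


class TestSurfaceSequence:
    def test_zero_signal_static_frames(self):
        n = 30
        sig = syn.LatentSignal(np.arange(n) / 3.0, np.zeros(n), np.zeros(n), 3.0)
        torso = syn.default_torso(point_noise_sd=0.0, dropout_rate_edges=0.0)
        frames = syn.simulate_surface_sequence(sig, torso, seed=0)
        ref = frames[0]
        for frame in frames[1:]:
            for lid in ref.lines:
                np.testing.assert_array_equal(frame.lines[lid], ref.lines[lid])

    def test_frame_count(self):
        p = regular_params(duration=480.0)
        sig = syn.simulate_breathing_signal(p, seed=0)
        torso = syn.default_torso(points_per_line=10)
        frames = syn.simulate_surface_sequence(sig, torso, seed=0)
        assert len(frames) == 1440

    def test_ap_height_round_trip(self):
        # oracle: the generator's own height model z0 + w_ab * v at the AP
        p = regular_params(period_sd=0.3, amplitude_sd=0.8, duration=60.0)
        sig = syn.simulate_breathing_signal(p, seed=5)
        noise_sd = 0.2
        torso = syn.default_torso(point_noise_sd=noise_sd, dropout_rate_edges=0.0,
                                  points_per_line=40)
        frames = syn.simulate_surface_sequence(sig, torso, seed=6)
        ap = (0.0, -150.0)
        z0 = float(torso.base_height_map(np.array(ap[0]), np.array(ap[1])))
        got = np.array([interpolate_height(f, ap) for f in frames])
        expected = z0 + sig.values  # w_ab = 1 at the AP
        err = np.abs(got - expected)
        assert np.percentile(err, 99) < 3 * noise_sd

    def test_point_budget_and_edge_only_dropout(self):
        p = regular_params(duration=20.0)
        sig = syn.simulate_breathing_signal(p, seed=0)
        torso = syn.default_torso(points_per_line=20, dropout_rate_edges=0.5,
                                  point_noise_sd=0.0)
        frames = syn.simulate_surface_sequence(sig, torso, seed=1)
        cut = torso.edge_fraction * torso.lateral_extent
        full_x = np.linspace(-torso.lateral_extent, torso.lateral_extent, 20)
        interior = set(np.round(full_x[np.abs(full_x) <= cut], 6))
        for frame in frames:
            assert frame.n_points <= 20 * 11
            for pts in frame.lines.values():
                assert interior <= set(np.round(pts[:, 0], 6))

    def test_empty_signal_raises(self):
        with pytest.raises(ValueError):
            syn.LatentSignal(np.array([]), np.array([]), np.array([]), 3.0)


class TestTumorTrajectory:
    def _sine_signal(self, amplitude=5.0, period=4.0, rate=30.0, duration=40.0):
        t = np.arange(int(duration * rate)) / rate
        v = amplitude * np.sin(2 * np.pi * t / period)
        return syn.LatentSignal(t, v, v, rate)

    def test_zero_hysteresis_collinear(self):
        sig = self._sine_signal()
        gt = syn.GroundTruthModel(xAprime_true=np.zeros(3), obs_noise_sd=0.0)
        traj = syn.simulate_tumor_trajectory(sig, gt)
        # closed shoelace area of the (v, component) loop is 0 per component
        for c in range(3):
            x = sig.clean - sig.clean.mean()
            y = traj.positions[:, c] - traj.positions[:, c].mean()
            area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
            assert area < 1e-9 * max(1.0, np.max(np.abs(y))) * np.max(np.abs(x))

    def test_noiseless_refit_recovers_ground_truth(self):
        sig = self._sine_signal(rate=3.0)
        gt = syn.GroundTruthModel(obs_noise_sd=0.0)
        traj = syn.simulate_tumor_trajectory(sig, gt)
        vp = mm.estimate_derivative(SurrogateTrace(sig.times, sig.clean, "l")).values
        params = mm.fit_low_model(mm.TrainingSet(sig.clean, vp, traj.positions))
        np.testing.assert_allclose(params.x0, gt.x0_true, atol=1e-9)
        np.testing.assert_allclose(params.xA, gt.xA_true, atol=1e-9)
        np.testing.assert_allclose(params.xAprime, gt.xAprime_true, atol=1e-9)

    def test_sinusoid_loop_area_matches_ellipse(self):
        # oracle: for v = A0 sin(wt), the (v, x_c) loop is an ellipse of
        # area pi * A0^2 * w * |xAprime_c|
        A0, period = 5.0, 4.0
        w = 2 * np.pi / period
        sig = self._sine_signal(amplitude=A0, period=period, rate=30.0,
                                duration=period)
        gt = syn.GroundTruthModel(obs_noise_sd=0.0)
        traj = syn.simulate_tumor_trajectory(sig, gt)
        c = 1  # component with the largest hysteresis coefficient
        x, y = sig.clean, traj.positions[:, c]
        area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
        expected = np.pi * A0**2 * w * abs(gt.xAprime_true[c])
        assert area == pytest.approx(expected, rel=1e-2)


class TestCineSampling:
    def _linear_traj(self, slope=np.array([1.0, -2.0, 0.5]), duration=200.0):
        t = np.arange(int(duration * 3)) / 3.0
        pos = t[:, None] * slope[None, :]
        return syn.Trajectory(t, pos), slope

    def test_observation_count(self):
        traj, _ = self._linear_traj(duration=600.0)
        obs = syn.sample_cine_sessions(traj, syn.CineSchedule(n_acquisitions=100),
                                       seed=0)
        assert len(obs) == 100

    def test_constant_trajectory_no_jitter(self):
        t = np.arange(300) / 3.0
        c = np.array([1.0, 2.0, 3.0])
        traj = syn.Trajectory(t, np.tile(c, (t.size, 1)))
        sched = syn.CineSchedule(n_acquisitions=10, mean_interval=5.0,
                                 interval_jitter=0.0)
        obs = syn.sample_cine_sessions(traj, sched, seed=0, noise_sd=0.0)
        for o in obs:
            np.testing.assert_allclose(o.position, c, atol=1e-12)

    def test_linear_trajectory_equals_midpoint(self):
        traj, slope = self._linear_traj()
        sched = syn.CineSchedule(n_acquisitions=20, mean_interval=5.0,
                                 interval_jitter=1.0)
        obs = syn.sample_cine_sessions(traj, sched, seed=3, noise_sd=0.0)
        for o in obs:
            np.testing.assert_allclose(o.position, o.time * slope, atol=1e-10)

    def test_schedule_exceeding_span_raises(self):
        traj, _ = self._linear_traj(duration=30.0)
        with pytest.raises(ValueError, match="span"):
            syn.sample_cine_sessions(traj, syn.CineSchedule(n_acquisitions=100),
                                     seed=0)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            syn.CineSchedule(n_acquisitions=0).validate()
        with pytest.raises(ValueError):
            syn.CineSchedule(mean_interval=0.2, exposure=0.3).validate()


class TestDeterminism:
    def test_full_stage_determinism(self):
        p = syn.BreathingParams(duration=40.0)
        torso = syn.default_torso(points_per_line=10)
        gt = syn.GroundTruthModel()
        out = []
        for _ in range(2):
            sig = syn.simulate_breathing_signal(p, seed=11)
            frames = syn.simulate_surface_sequence(sig, torso, seed=12)
            traj = syn.simulate_tumor_trajectory(sig, gt)
            obs = syn.sample_cine_sessions(
                traj, syn.CineSchedule(n_acquisitions=5), seed=13,
                noise_sd=gt.obs_noise_sd)
            out.append((sig, frames, traj, obs))
        (s1, f1, t1, o1), (s2, f2, t2, o2) = out
        np.testing.assert_array_equal(s1.values, s2.values)
        np.testing.assert_array_equal(t1.positions, t2.positions)
        for a, b in zip(f1, f2):
            for lid in a.lines:
                np.testing.assert_array_equal(a.lines[lid], b.lines[lid])
        for a, b in zip(o1, o2):
            assert a.time == b.time
            np.testing.assert_array_equal(a.position, b.position)


def test_noiseless_pipeline_round_trip_invariant():
    """Surface -> AP -> baseline -> derivative -> fit recovers the generator."""
    import surromod.experiments as ex

    scen = noiseless_scenario(duration=100.0, n_acquisitions=20,
                              points_per_line=25)
    scen.center_observations = False
    ds = ex.simulate_study(scen, seed=21)
    params = mm.fit_low_model(ds.training_session.training_set("AP", centered=False))
    gt = scen.ground_truth
    assert np.max(np.abs(params.x0 - gt.x0_true)) <= 1e-6
    assert np.max(np.abs(params.xA - gt.xA_true)) <= 1e-6
    assert np.max(np.abs(params.xAprime - gt.xAprime_true)) <= 1e-6
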