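"""Movement-unit segmentation, distance and velocity, and their invariances."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

from oracles import oracle_movement_units
from steptime.kinematics import (
    SpeedSeries,
    average_velocity,
    count_movement_units,
    cumulative_distance,
    summarize_leg,
    tangential_speed,
)
from steptime.mocap_io import Config, MarkerTrajectory, MuConfig
from steptime.preprocess import filter_trial
from steptime.scoring import detect_taps
from steptime.simulate import TrajectoryParams, generate_trial, minimum_jerk_position


def _speed_series(values, fs=120.0):
    v = np.asarray(values, dtype=float)
    a = np.gradient(v, 1.0 / fs) if len(v) >= 2 else np.zeros_like(v)
    return SpeedSeries(v, a, fs)


def _bell(peak, n=60):
    tau = np.linspace(0, 1, n)
    return peak * 16 * tau**2 * (1 - tau) ** 2


class TestTangentialSpeed:
    def test_uniform_motion_recovers_speed(self):
        fs = 120.0
        t = np.arange(240) / fs
        pos = np.stack([60.0 * t, 80.0 * t, np.zeros_like(t)], axis=1)  # |v| = 100
        s = tangential_speed(MarkerTrajectory("m", pos, fs))
        np.testing.assert_allclose(s.speed[1:-1], 100.0, atol=1e-9)

    def test_stationary_marker_zero(self):
        s = tangential_speed(MarkerTrajectory("m", np.full((100, 3), 7.0), 120.0))
        assert np.all(s.speed == 0) and np.all(s.accel == 0)

    def test_minimum_jerk_peak_speed_closed_form(self):
        # peak speed of a minimum-jerk move of amplitude A over T is 1.875 A/T
        fs, A, T = 120.0, 500.0, 0.8
        t = np.arange(int(T * fs) + 1) / fs
        pos = np.zeros((len(t), 3))
        pos[:, 0] = A * minimum_jerk_position(t / T)
        s = tangential_speed(MarkerTrajectory("m", pos, fs))
        assert s.speed.max() == pytest.approx(1.875 * A / T, rel=1e-3)


class TestCountMovementUnits:
    def test_constant_speed_no_units(self, cfg):
        n, units = count_movement_units(_speed_series(np.full(100, 300.0)), cfg)
        assert n == 0 and units == []

    def test_single_bell_is_one_unit(self, cfg):
        n, units = count_movement_units(_speed_series(_bell(400.0)), cfg)
        assert n == 1
        u = units[0]
        assert u.velocity_rise_mm_s == pytest.approx(400.0, rel=0.01)
        assert u.start_frame <= u.peak_frame <= u.end_frame

    @pytest.mark.parametrize("dip,expected", [(10.0, 1), (50.0, 2)])
    def test_dip_depth_decides_merging(self, cfg, dip, expected):
        # rise to a peak, fall by `dip`, rise back, fall to zero
        peak = 400.0
        up = np.linspace(0, peak, 30)
        down = np.linspace(peak, peak - dip, 8)
        up2 = np.linspace(peak - dip, peak, 8)
        end = np.linspace(peak, 0, 30)
        series = np.concatenate([up, down, up2, end])
        n, _ = count_movement_units(_speed_series(series), cfg)
        assert n == expected

    def test_empty_window_zero_units(self, cfg):
        n, units = count_movement_units(_speed_series([]), cfg)
        assert n == 0 and units == []

    def test_acceleration_gate_discards_slow_ramps(self):
        # raise the gate far above what a gentle bell can reach
        cfg = Config(mu=MuConfig(dv_min_mm_s=20.0, da_min_mm_s2=1e7))
        n, _ = count_movement_units(_speed_series(_bell(400.0)), cfg)
        assert n == 0


class TestMuOracleEquivalence:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(hst.data())
    def test_matches_brute_force_on_random_series(self, cfg, data):
        n = data.draw(hst.integers(3, 300))
        kind = data.draw(hst.sampled_from(["smooth", "walk", "steps"]))
        seed = data.draw(hst.integers(0, 2**31 - 1))
        rng = np.random.default_rng(seed)
        if kind == "smooth":
            raw = rng.normal(0, 60, n + 40)
            k = np.hanning(21)
            v = np.abs(np.convolve(raw, k / k.sum(), mode="same"))[:n] * 4
        elif kind == "walk":
            v = np.abs(np.cumsum(rng.normal(0, 15, n)))
        else:  # integer plateaus exercise tie handling
            v = rng.integers(0, 8, n).astype(float) * 10.0
        s = _speed_series(v)
        mine, _ = count_movement_units(s, cfg)
        ref = oracle_movement_units(s.speed, s.accel, cfg.mu.dv_min_mm_s, cfg.mu.da_min_mm_s2)
        assert mine == ref

    def test_noise_far_below_threshold_does_not_change_count(self, cfg, rng):
        base = np.concatenate([_bell(400.0), np.zeros(10), _bell(250.0)])
        n0, _ = count_movement_units(_speed_series(base), cfg)
        for _ in range(20):
            jitter = rng.normal(0, 1.0, base.shape)  # 1 mm/s jitter on the speed
            n1, _ = count_movement_units(_speed_series(np.abs(base + jitter)), cfg)
            assert n1 == n0 == 2

    def test_time_reversal_invariance(self, cfg, rng):
        for _ in range(20):
            v = np.abs(np.cumsum(rng.normal(0, 15, 200)))
            n_fwd, _ = count_movement_units(_speed_series(v), cfg)
            n_rev, _ = count_movement_units(_speed_series(v[::-1]), cfg)
            assert n_fwd == n_rev


class TestDistanceAndVelocity:
    def test_stationary_zero_distance(self):
        traj = MarkerTrajectory("m", np.full((100, 3), 5.0), 120.0)
        assert cumulative_distance(traj) == 0.0

    def test_straight_line_distance_and_velocity(self):
        fs = 120.0
        t = np.arange(int(2 * fs)) / fs
        pos = np.stack([100.0 * t, np.zeros_like(t), np.zeros_like(t)], axis=1)
        traj = MarkerTrajectory("m", pos, fs)
        assert cumulative_distance(traj) == pytest.approx(200.0, abs=100.0 / fs + 1e-9)
        assert average_velocity(traj) == pytest.approx(100.0, rel=0.01)

    def test_distance_bounds_displacement(self, rng):
        for _ in range(20):
            pos = np.cumsum(rng.normal(0, 3, (150, 3)), axis=0)
            traj = MarkerTrajectory("m", pos, 120.0)
            chord = np.linalg.norm(pos[-1] - pos[0])
            assert cumulative_distance(traj) >= chord - 1e-9

    def test_linear_scaling(self, rng):
        pos = np.cumsum(rng.normal(0, 3, (150, 3)), axis=0)
        t1 = MarkerTrajectory("m", pos, 120.0)
        t3 = MarkerTrajectory("m", 3.0 * pos, 120.0)
        assert cumulative_distance(t3) == pytest.approx(3 * cumulative_distance(t1), rel=1e-12)
        assert average_velocity(t3) == pytest.approx(3 * average_velocity(t1), rel=1e-12)

    def test_velocity_matches_mean_tangential_speed_on_smooth_moves(self):
        fs, A, T = 120.0, 400.0, 1.0
        t = np.arange(int(T * fs) + 1) / fs
        pos = np.zeros((len(t), 3))
        pos[:, 0] = A * minimum_jerk_position(t / T)
        traj = MarkerTrajectory("m", pos, fs)
        v_avg = average_velocity(traj)
        v_mean = tangential_speed(traj).speed.mean()
        assert v_avg == pytest.approx(v_mean, rel=0.01)

    def test_zero_length_window_rejected(self):
        traj = MarkerTrajectory("m", np.zeros((100, 3)), 120.0)
        with pytest.raises(ValueError, match="window"):
            average_velocity(traj, (0.1, 0.1))


class TestSummarizeLeg:
    def test_noiseless_trial_counts_three_units_per_leg(self, cfg, clean_trial):
        trial, truth = clean_trial
        smooth = filter_trial(trial, cfg)
        taps = detect_taps(trial, cfg)
        summ = summarize_leg(smooth, taps, cfg)
        for side in "LR":
            assert summ[side].mu_count == pytest.approx(3.0)
            assert not summ[side].incomplete
            assert summ[side].window_s[1] == pytest.approx(truth.true_tap_times_s[5], abs=0.02)

    def test_composite_is_mean_of_markers(self, cfg, clean_trial):
        trial, _ = clean_trial
        smooth = filter_trial(trial, cfg)
        taps = detect_taps(trial, cfg)
        summ = summarize_leg(smooth, taps, cfg)
        s = summ["L"]
        assert s.distance_mm == pytest.approx(
            np.mean([m["distance_mm"] for m in s.per_marker.values()])
        )

    def test_fewer_than_six_taps_flagged_incomplete(self, cfg):
        params = TrajectoryParams(seed=2, noise_sd_mm=0.0, trial_length_s=4.0)  # 4 taps fit
        trial, _ = generate_trial([1, 6, 5, 2, 3, 4], params)
        smooth = filter_trial(trial, cfg)
        taps = detect_taps(trial, cfg)
        assert len(taps) < 6
        summ = summarize_leg(smooth, taps, cfg)
        assert summ["L"].incomplete and summ["R"].incomplete
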