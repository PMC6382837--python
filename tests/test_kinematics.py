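"""Filtered speed, lag kinematics, activity coefficient, acclimatization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cionetho import (
    acclimatization_profile,
    activity_coefficient,
    filtered_speed,
    lag_kinematics,
    local_complexity,
    equal_area_zones,
    summarize,
    thigmo_metrics,
    wrap_angle,
)

from conftest import make_traj, straight_line


def undulating_line(drift_um_s=300.0, amp_um=50.0, freq_hz=5.0, n=3000, fps=30.0):
    """Constant drift with a perpendicular sinusoid (head undulation)."""
    t = np.arange(n) / fps
    x = drift_um_s * 1e-3 * t
    y = amp_um * 1e-3 * np.sin(2 * np.pi * freq_hz * t)
    return make_traj(x, y, fps=fps)


class TestFilteredSpeed:
    def test_dc_passthrough(self):
        traj = straight_line(300.0, n=3000)
        v = filtered_speed(traj)
        core = v[np.isfinite(v)]
        assert len(core) > 2000
        assert np.abs(core - 300.0).max() < 1.0  # um/s

    def test_undulation_attenuated(self):
        # a 5 Hz, 50 um perpendicular tone inflates the raw speed hugely;
        # the 1 Hz low-pass restores the drift speed to within 5%
        traj = undulating_line()
        raw = np.hypot(np.diff(traj.x), np.diff(traj.y)) * traj.fps * 1e3
        assert raw.mean() > 1.3 * 300.0
        v = filtered_speed(traj)
        core = v[np.isfinite(v)]
        np.testing.assert_allclose(core, 300.0, rtol=0.05)

    def test_attenuation_matches_filter_frequency_response(self):
        # independent oracle: the perpendicular velocity tone has amplitude
        # A*2*pi*f; after a forward-backward pass its residual is bounded by
        # the squared Butterworth gain at 5 Hz (plus a numerical floor)
        from scipy.signal import butter, sosfreqz

        sos = butter(4, 1.0, btype="low", fs=30.0, output="sos")
        _, h = sosfreqz(sos, worN=[5.0], fs=30.0)
        gain2 = np.abs(h[0]) ** 2  # filtfilt applies the magnitude twice
        tone_amp = 50.0 * 2 * np.pi * 5.0  # um/s
        traj = undulating_line()
        v = filtered_speed(traj)[120:-120]  # steady state, past edge transients
        ripple_out = np.abs(v[np.isfinite(v)] - 300.0).max()
        assert ripple_out <= gain2 * tone_amp * 10 + 1.0

    def test_stationary_point_zero(self):
        traj = make_traj(np.zeros(2000), np.zeros(2000))
        v = filtered_speed(traj)
        assert np.nanmax(np.abs(v)) < 1e-9

    def test_low_fps_rejected(self):
        with pytest.raises(ValueError):
            filtered_speed(straight_line(300.0, fps=2.0, n=100))

    def test_gap_frames_stay_invalid(self):
        traj = straight_line(300.0, n=3000)
        traj.x[1500] = np.nan
        traj.gap_mask[1500] = True
        v = filtered_speed(traj)
        assert np.isnan(v[1500])


class TestLagKinematics:
    def test_straight_line_zero_turn(self):
        kin = lag_kinematics(straight_line(600.0, n=600))
        assert np.abs(kin.turn[kin.valid_mask]).max() == 0.0
        np.testing.assert_allclose(kin.rho[kin.valid_mask], 600.0, rtol=1e-9)

    def test_circular_motion_constant_turn(self):
        # uniform circular motion at angular rate w: turn = w * lag / fps
        fps, w, R, n, lag = 30.0, 1.2, 2.0, 900, 5
        t = np.arange(n) / fps
        traj = make_traj(R * np.cos(w * t), R * np.sin(w * t), fps=fps)
        kin = lag_kinematics(traj, lag=lag)
        expect = w * lag / fps
        np.testing.assert_allclose(kin.turn[kin.valid_mask], expect, rtol=1e-9)

    def test_reversal_turn_is_pi(self):
        # out and back along a line: the turn at the reversal is exactly pi
        fwd = np.arange(100) * 0.01
        x = np.concatenate([fwd, fwd[::-1]])
        kin = lag_kinematics(make_traj(x, np.zeros_like(x)))
        turns = kin.turn[kin.valid_mask]
        assert np.isclose(np.abs(turns).max(), np.pi)
        assert turns.max() == pytest.approx(np.pi)  # (-pi, pi] convention

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            lag_kinematics(straight_line(300.0, n=10), lag=5)

    @given(st.floats(-20, 20))
    @settings(deadline=None, max_examples=50)
    def test_wrap_angle_range_and_identity(self, a):
        w = float(wrap_angle(a))
        assert -np.pi < w <= np.pi
        assert np.isclose(np.sin(w), np.sin(a), atol=1e-9)
        assert np.isclose(np.cos(w), np.cos(a), atol=1e-9)

    def test_isotropic_walk_turn_symmetry(self, rng):
        # turns of an isotropic random walk are symmetric about zero
        steps = rng.normal(0, 0.01, size=(5000, 2))
        p = np.cumsum(steps, axis=0)
        kin = lag_kinematics(make_traj(p[:, 0], p[:, 1]))
        turns = kin.turn[kin.valid_mask]
        from scipy.stats import binomtest

        n_pos = int((turns > 0).sum())
        n = int((turns != 0).sum())
        assert binomtest(n_pos, n, 0.5).pvalue > 0.01


class TestActivityCoefficient:
    @pytest.mark.parametrize(
        "speeds,expected",
        [
            (np.full(100, 300.0), 1.0),
            (np.full(100, 100.0), 0.0),
            (np.r_[np.full(50, 300.0), np.full(50, 100.0)], 0.5),
        ],
    )
    def test_threshold_fraction(self, speeds, expected):
        assert activity_coefficient(speeds) == expected

    def test_all_invalid_rejected(self):
        with pytest.raises(ValueError):
            activity_coefficient(np.full(10, np.nan))

    def test_rigid_motion_invariance(self, rng):
        steps = rng.normal(0, 0.02, size=(3000, 2))
        p = np.cumsum(steps, axis=0)
        a = 0.7
        Rm = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        q = p @ Rm.T + np.array([1.5, -2.0])
        ac1 = activity_coefficient(filtered_speed(make_traj(p[:, 0], p[:, 1])))
        ac2 = activity_coefficient(filtered_speed(make_traj(q[:, 0], q[:, 1])))
        assert ac1 == pytest.approx(ac2, abs=1e-12)


class TestSummarize:
    def test_constant_speed_median_equals_max(self):
        traj = straight_line(400.0, n=3000)
        kin = lag_kinematics(traj)
        comp = local_complexity(traj)
        th = thigmo_metrics(traj, equal_area_zones(5.0))
        s = summarize(traj, kin, comp, th)
        assert s.median_speed == pytest.approx(s.max_speed, rel=1e-6)
        assert s.AC == 1.0

    def test_max_at_least_median(self, rng):
        steps = rng.normal(0, 0.02, size=(3000, 2))
        p = np.cumsum(steps, axis=0)
        p -= p.mean(axis=0)
        p = np.clip(p, -3.5, 3.5)
        traj = make_traj(p[:, 0], p[:, 1])
        s = summarize(
            traj,
            lag_kinematics(traj),
            local_complexity(traj),
            thigmo_metrics(traj, equal_area_zones(5.0)),
        )
        assert s.max_speed >= s.median_speed >= 0


class TestAcclimatization:
    def test_constant_cohort_stabilizes_immediately(self):
        cohort = [straight_line(300.0, n=30 * 400) for _ in range(3)]
        prof = acclimatization_profile(cohort, window=300.0, step=10.0)
        assert np.nanmax(np.abs(prof.slopes)) < 0.05
        assert prof.stabilization_time == 0.0

    def test_exponential_decay_detected_in_2_to_5_tau(self):
        # speed = 300 + 200 exp(-t/tau): the 5-min-window OLS slope falls
        # below 0.05 um/s^2 somewhere in [2 tau, 5 tau]
        tau, fps, T = 120.0, 10.0, 900.0
        t = np.arange(int(T * fps)) / fps
        speed = 300.0 + 200.0 * np.exp(-t / tau)  # um/s
        step = speed / fps * 1e-3
        x = np.cumsum(step)
        cohort = [make_traj(x, np.zeros_like(x), fps=fps)]
        prof = acclimatization_profile(cohort, window=300.0, step=10.0)
        assert prof.stabilization_time is not None
        assert 2 * tau <= prof.stabilization_time <= 5 * tau

    def test_monotone_increase_never_stabilizes(self):
        fps = 10.0
        t = np.arange(int(600 * fps)) / fps
        speed = 100.0 + 2.0 * t  # um/s, slope 2 um/s^2 always
        x = np.cumsum(speed / fps * 1e-3)
        prof = acclimatization_profile(
            [make_traj(x, np.zeros_like(x), fps=fps)], window=300.0
        )
        assert prof.stabilization_time is None

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            acclimatization_profile([straight_line(300.0, n=100)], window=300.0)
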