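"""Kinematic primitives: filtering, event detection, sway metrics, geometry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial import ConvexHull as ScipyHull

from posturometry.kinematics import (
    CoPTrace,
    FilterSpec,
    InsufficientDataError,
    InvalidConfigError,
    MarkerTrajectorySet,
    MissingMarkerError,
    StanceWindow,
    WindowTooShortError,
    balance_variables,
    cop_velocity,
    detect_single_leg_window,
    extract_panel,
    lowpass_filter,
    max_sway_velocity,
    pct_left_leg,
    posture_variables,
    side_bend_variables,
    sway_area,
)
from posturometry.synthetic import simulate_trial

from oracles import hull_area_bruteforce


def make_trace(ap, ml, rate=30.0):
    return CoPTrace(np.asarray(ap, float), np.asarray(ml, float), rate)


# ---------------------------------------------------------------------------
# low-pass filter


class TestLowpassFilter:
    def test_constant_series_passes_unchanged(self):
        s = np.full(200, 3.7)
        out = lowpass_filter(s, FilterSpec(), 30.0)
        assert out.shape == s.shape
        np.testing.assert_allclose(out, s, atol=1e-10)

    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 20, 1 / 30)
        s = np.sin(2 * np.pi * 0.1 * t)
        out = lowpass_filter(s, FilterSpec(), 30.0)
        assert abs(np.abs(out[150:-150]).max() - 1.0) < 0.01

    def test_single_pass_gain_at_cutoff_is_half_power(self):
        # order-4 Butterworth magnitude at the cut-off is exactly 1/sqrt(2)
        rate, f_c = 100.0, 7.0
        t = np.arange(0, 60, 1 / rate)
        s = np.sin(2 * np.pi * f_c * t)
        out = lowpass_filter(s, FilterSpec(cutoff=f_c, zero_phase=False), rate)
        gain = np.abs(out[2000:]).max()
        assert gain == pytest.approx(1 / math.sqrt(2), rel=0.02)

    def test_zero_phase_gain_at_cutoff_is_squared(self):
        rate, f_c = 100.0, 7.0
        t = np.arange(0, 60, 1 / rate)
        s = np.sin(2 * np.pi * f_c * t)
        out = lowpass_filter(s, FilterSpec(cutoff=f_c, zero_phase=True), rate)
        assert np.abs(out[2000:-2000]).max() == pytest.approx(0.5, rel=0.02)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(InvalidConfigError):
            lowpass_filter(np.zeros(100), FilterSpec(cutoff=16.0), 30.0)

    def test_short_series_rejected(self):
        with pytest.raises(InsufficientDataError):
            lowpass_filter(np.zeros(10), FilterSpec(order=4), 30.0)


# ---------------------------------------------------------------------------
# single-leg window


class TestSingleLegWindow:
    def test_ramp_then_plateau_starts_at_peak(self):
        x = np.concatenate([np.linspace(0, 1, 41), np.full(200, 0.98)])
        w = detect_single_leg_window(x, 30.0, hold=5.0)
        assert w.start == 40

    @pytest.mark.parametrize("hold,frames", [(3.0, 90), (5.0, 150)])
    def test_window_length_at_30hz(self, hold, frames):
        x = np.concatenate([np.linspace(0, 1, 31), np.full(300, 0.9)])
        w = detect_single_leg_window(x, 30.0, hold=hold)
        assert w.n_frames == frames
        assert w.duration == pytest.approx(hold)

    def test_tied_maxima_take_earliest(self):
        x = np.zeros(300)
        peaks = [50, 90, 130]
        x[peaks] = 1.0
        w = detect_single_leg_window(x, 30.0, hold=3.0)
        # exhaustive scan oracle for the earliest global maximum
        assert w.start == min(i for i in range(300) if x[i] == x.max()) == 50

    def test_too_little_data_after_peak_is_a_missing_trial(self):
        x = np.concatenate([np.linspace(0, 1, 100), np.full(30, 0.9)])
        with pytest.raises(WindowTooShortError):
            detect_single_leg_window(x, 30.0, hold=5.0)

    def test_hold_outside_protocol_range_rejected(self):
        with pytest.raises(InvalidConfigError):
            detect_single_leg_window(np.arange(300.0), 30.0, hold=6.0)


# ---------------------------------------------------------------------------
# CoP velocity and percentile


class TestCopVelocity:
    def test_linear_drift_gives_constant_speed(self):
        tr = make_trace(np.arange(100) * 0.1, np.zeros(100), rate=30.0)
        v = cop_velocity(tr, "ap")
        assert v.shape == (99,)
        np.testing.assert_allclose(v, 3.0)

    def test_constant_trace_gives_zero(self):
        tr = make_trace(np.full(50, 1.2), np.full(50, -0.4))
        assert np.all(cop_velocity(tr, "ap") == 0)
        assert np.all(cop_velocity(tr, "ml") == 0)

    def test_matches_finite_difference_oracle(self, rng):
        s = rng.normal(size=200)
        tr = make_trace(s, rng.normal(size=200), rate=100.0)
        v = cop_velocity(tr, "ap")
        expected = np.array([abs(s[i + 1] - s[i]) * 100.0 for i in range(199)])
        np.testing.assert_allclose(v, expected)

    def test_single_frame_rejected(self):
        with pytest.raises(InsufficientDataError):
            cop_velocity(make_trace([1.0], [1.0]), "ap")


class TestMaxSwayVelocity:
    def test_constant_series(self):
        assert max_sway_velocity(np.full(40, 2.5)) == 2.5

    def test_percentile_100_is_maximum(self):
        v = np.arange(1.0, 101.0)
        assert max_sway_velocity(v, percentile=100) == 100.0

    def test_95th_matches_sort_and_interpolate_oracle(self):
        v = np.arange(1.0, 101.0)
        # linear interpolation between order statistics at q = 0.95
        pos = 0.95 * (v.size - 1)
        lo, frac = int(pos), pos - int(pos)
        expected = np.sort(v)[lo] * (1 - frac) + np.sort(v)[lo + 1] * frac
        assert max_sway_velocity(v) == pytest.approx(expected)

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            max_sway_velocity(np.array([]))


# ---------------------------------------------------------------------------
# sway area


class TestSwayArea:
    def test_unit_square(self):
        assert sway_area(np.array([[0, 0], [1, 0], [1, 1], [0, 1]])) == 1.0

    def test_collinear_is_zero(self, rng):
        t = rng.normal(size=30)
        pts = np.column_stack([2 * t + 1, -3 * t + 0.5])
        assert sway_area(pts) == 0.0

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            sway_area(np.array([[0, 0], [1, 1]]))

    def test_matches_bruteforce_and_qhull_oracles(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 51))
            pts = rng.normal(size=(n, 2))
            ours = sway_area(pts)
            brute = hull_area_bruteforce(pts)
            assert ours == pytest.approx(brute, rel=1e-9, abs=1e-12)
            if n >= 3:
                assert ours == pytest.approx(ScipyHull(pts).volume, rel=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_scale_and_translation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(25, 2))
        area = sway_area(pts)
        c = 2.5
        assert sway_area(pts * c) == pytest.approx(area * c * c, rel=1e-12)
        assert sway_area(pts + [17.0, -4.0]) == pytest.approx(area, rel=1e-9, abs=1e-9)


# ---------------------------------------------------------------------------
# balance block


class TestBalanceVariables:
    def test_constant_trace_is_perfect_stillness(self):
        tr = make_trace(np.full(300, 0.7), np.full(300, -0.2))
        out = balance_variables(tr)
        assert out == {"SA": 0.0, "SVAP": 0.0, "SVML": 0.0}

    def test_velocity_scales_with_trace(self, rng):
        s = rng.normal(size=300)
        m = rng.normal(size=300)
        one = balance_variables(make_trace(s, m))
        three = balance_variables(make_trace(3 * s, 3 * m))
        assert three["SA"] == pytest.approx(9 * one["SA"], rel=1e-9)
        assert three["SVAP"] == pytest.approx(3 * one["SVAP"], rel=1e-9)
        assert three["SVML"] == pytest.approx(3 * one["SVML"], rel=1e-9)

    def test_larger_sway_sd_gives_larger_area_on_average(self):
        from posturometry.synthetic import SimulationConfig, _ou

        wins = 0
        for seed in range(50):
            rng1 = np.random.default_rng(seed)
            rng2 = np.random.default_rng(seed)
            small = _ou(rng1, 240, 0.3, 1.0, 1 / 30)
            big = _ou(rng2, 240, 0.9, 1.0, 1 / 30)
            a_small = balance_variables(make_trace(small, np.zeros(240) + small[::-1]))
            a_big = balance_variables(make_trace(big, np.zeros(240) + big[::-1]))
            wins += a_big["SA"] > a_small["SA"]
        assert wins >= 45

    def test_window_cropping_applied(self):
        ap = np.concatenate([np.zeros(60), np.linspace(0, 5, 90), np.zeros(60)])
        tr = make_trace(ap, ap[::-1].copy(), rate=30.0)
        whole = balance_variables(tr)
        still = balance_variables(tr, StanceWindow(0, 50, 30.0))
        assert still["SA"] < whole["SA"]

    def test_resampling_consistency_for_bandlimited_motion(self):
        # a smooth (<= 1 Hz) trajectory measured at 100 Hz and 30 Hz must
        # give near-identical endpoints: the cross-device construct
        t100 = np.arange(0, 10, 1 / 100)
        t30 = np.arange(0, 10, 1 / 30)

        def traj(t):
            return (0.8 * np.sin(2 * np.pi * 0.4 * t)
                    + 0.3 * np.sin(2 * np.pi * 1.0 * t + 1.0))

        hi = balance_variables(make_trace(traj(t100), traj(t100 + 0.3), rate=100.0))
        lo = balance_variables(make_trace(traj(t30), traj(t30 + 0.3), rate=30.0))
        for key in ("SA", "SVAP", "SVML"):
            assert hi[key] == pytest.approx(lo[key], rel=0.05)


# ---------------------------------------------------------------------------
# posture and side-bend geometry


def stance_markers(profile, traits=None):
    from posturometry.synthetic import _static_pose

    traits = traits if traits is not None else profile.trait_vector
    pose = _static_pose(profile, traits)
    data = {k: np.tile(v, (60, 1)) for k, v in pose.items()}
    return MarkerTrajectorySet(data, 30.0)


class TestPostureVariables:
    def test_symmetric_pose_is_all_zero(self, quiet_profile):
        traits = dict(quiet_profile.trait_vector)
        for k in ("P-HL", "P-HF", "P-NA", "P-PP", "P-HS"):
            traits[k] = 0.0
        markers = stance_markers(quiet_profile, traits)
        cop = make_trace(np.zeros(60), np.zeros(60))
        out = posture_variables(markers, cop, quiet_profile.height)
        for k in ("P-HL", "P-HF", "P-NA", "P-PP", "P-HS"):
            assert out[k] == pytest.approx(0.0, abs=1e-9)
        assert out["P-WB"] == pytest.approx(50.0, abs=1e-9)

    def test_planted_offsets_recovered_exactly(self, quiet_profile):
        markers = stance_markers(quiet_profile)
        cop = make_trace(np.zeros(60), np.zeros(60))
        out = posture_variables(markers, cop, quiet_profile.height)
        t = quiet_profile.trait_vector
        assert out["P-HL"] == pytest.approx(t["P-HL"], abs=1e-9)
        assert out["P-HF"] == pytest.approx(t["P-HF"], abs=1e-9)
        assert out["P-NA"] == pytest.approx(t["P-NA"], abs=1e-6)
        assert out["P-PP"] == pytest.approx(t["P-PP"], abs=1e-9)
        assert out["P-HS"] == pytest.approx(t["P-HS"], abs=1e-9)

    def test_cop_at_left_ankle_maps_to_100pct(self, quiet_profile):
        markers = stance_markers(quiet_profile)
        z_left = markers["malleolus_l"][0, 2]
        cop = make_trace(np.zeros(60), np.full(60, z_left))
        out = posture_variables(markers, cop, quiet_profile.height)
        assert out["P-WB"] == pytest.approx(100.0, abs=1e-9)

    def test_missing_marker_is_named(self, quiet_profile):
        markers = stance_markers(quiet_profile)
        del markers.data["head_top"]
        with pytest.raises(MissingMarkerError, match="head_top"):
            posture_variables(markers, None, quiet_profile.height)


class TestSideBendVariables:
    def test_planted_minimum_recovered(self, quiet_profile):
        markers = stance_markers(quiet_profile)
        h = quiet_profile.height
        n = 240
        data = {k: np.tile(v[0], (n, 1)) for k, v in markers.data.items()}
        # slow cosine dip to 23 %height at mid-trial (well inside the passband)
        t = np.arange(n) / 30.0
        y0, ymin = 0.47 * h, 0.23 * h
        data["fingertip_l"] = data["fingertip_l"].copy()
        data["fingertip_l"][:, 1] = y0 - (y0 - ymin) * np.sin(np.pi * t / t[-1])**2
        out = side_bend_variables(MarkerTrajectorySet(data, 30.0), None, h, "left")
        assert out["SB-LF"] == pytest.approx(23.0, abs=0.05)

    def test_no_bend_reads_standing_fingertip_height(self, quiet_profile):
        markers = stance_markers(quiet_profile)
        h = quiet_profile.height
        markers.data["fingertip_r"][:, 1] = 0.29 * h
        out = side_bend_variables(markers, None, h, "right")
        assert out["SB-RF"] == pytest.approx(29.0, abs=1e-9)

    def test_cop_never_left_of_midpoint_caps_weight_shift(self, quiet_profile, rng):
        markers = stance_markers(quiet_profile)
        ml = -np.abs(rng.normal(0.0, 1.0, size=120))  # never leftward
        cop = make_trace(np.zeros(120), ml)
        out = side_bend_variables(markers, cop, quiet_profile.height, "left")
        assert out["SB-%BW"] <= 50.0


class TestPctLeftLeg:
    def test_linear_map_endpoints(self):
        assert pct_left_leg(0.0, 0.0, 8.0) == 50.0
        assert pct_left_leg(8.0, 0.0, 8.0) == 100.0
        assert pct_left_leg(-8.0, 0.0, 8.0) == 0.0

    def test_values_beyond_span_are_preserved_not_clamped(self):
        assert pct_left_leg(12.0, 0.0, 8.0) == 125.0


# ---------------------------------------------------------------------------
# panel assembly / trial-selection rule


class TestExtractPanel:
    def _session(self, profile, cfg, bad_trials=()):
        trials = []
        for trial in (1, 2, 3):
            t = simulate_trial(profile, "side_bend", 1, "kinect_like", cfg, trial)
            if trial in bad_trials:
                t.valid = False
            trials.append(t)
        return trials

    def test_third_trial_preferred(self, quiet_profile, noise_free_config):
        trials = self._session(quiet_profile, noise_free_config)
        panel = extract_panel(trials, quiet_profile.height)
        assert panel.source_trial["SB-LF"] == 3

    def test_fallback_to_second_then_first(self, quiet_profile, noise_free_config):
        trials = self._session(quiet_profile, noise_free_config, bad_trials=(3,))
        panel = extract_panel(trials, quiet_profile.height)
        assert panel.source_trial["SB-LF"] == 2
        trials = self._session(quiet_profile, noise_free_config, bad_trials=(2, 3))
        panel = extract_panel(trials, quiet_profile.height)
        assert panel.source_trial["SB-LF"] == 1

    def test_all_trials_invalid_marks_endpoints_missing(self, quiet_profile,
                                                        noise_free_config):
        trials = self._session(quiet_profile, noise_free_config,
                               bad_trials=(1, 2, 3))
        panel = extract_panel(trials, quiet_profile.height)
        for name in ("SB-LF", "SB-RF", "SB-%BW"):
            assert math.isnan(panel[name])
            assert name in panel.missing
        # unrecorded tasks are missing too, explicitly
        assert "DS-SA" in panel.missing

    def test_empty_session_rejected(self, quiet_profile):
        with pytest.raises(InvalidConfigError):
            extract_panel([], quiet_profile.height)
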