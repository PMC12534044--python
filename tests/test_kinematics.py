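import numpy as np
import pytest

from pawkit.kinematics import (
    FeatureConfig,
    detect_guarding,
    detect_shakes,
    extract_features,
    find_t_star,
    paw_velocity,
    reflexive_features,
    withdrawal_latency,
)
from pawkit.preprocess import preprocess
from pawkit.stimulus import mesh_crossing_time
from pawkit.synth import WithdrawalParams, synth_withdrawal_track
from pawkit.track_io import compute_calibration

from conftest import make_simple_track


def _mm_track(y, fps=2000.0, x=None, t0=0.0):
    t = make_simple_track(y, fps=fps, x=x, t0=t0)
    t.meta["stages"] = ["baseline"]  # already height-referenced
    return t


class TestVelocity:
    def test_linear_motion_constant_speed(self):
        y = np.arange(10, dtype=float)  # 1 mm per frame at 2000 fps
        v = paw_velocity(_mm_track(y))
        np.testing.assert_allclose(v[:, 1], 2000.0)

    def test_stationary_zero(self):
        v = paw_velocity(_mm_track(np.full(20, 3.0)))
        np.testing.assert_allclose(v, 0.0)

    def test_sine_peak_speed_matches_analytic(self):
        t = np.arange(0, 0.5, 1 / 2000.0)
        y = np.sin(2 * np.pi * 10 * t)
        v = paw_velocity(_mm_track(y))
        assert np.abs(v[:, 1]).max() == pytest.approx(2 * np.pi * 10, rel=0.01)

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            paw_velocity(_mm_track(np.zeros(2)))


class TestTStar:
    def test_first_local_max(self):
        assert find_t_star([0, 0.6, 1.2, 0.9, 1.5, 0.2]).index == 2

    def test_plateau_resolves_to_last_index(self):
        assert find_t_star([0, 1, 1, 0.5]).index == 2

    def test_monotone_flagged_no_descent(self):
        ts = find_t_star([0, 0.6, 1.0, 1.5, 2.0])
        assert ts.index == 4
        assert ts.no_descent

    def test_subthreshold_series_rejected(self):
        with pytest.raises(ValueError, match="never exceeds"):
            find_t_star([0.0, 0.2, 0.3, 0.1])

    def test_programmed_peak_recovered(self, clean_trial, pinprick, calibrated):
        params, track, truth = clean_trial
        cal = compute_calibration(track, params.known_mm)
        feats = extract_features(track, pinprick, calibration=cal)
        assert feats.t_star_s == pytest.approx(truth["t_star_s"], abs=1.5 / 2000.0)


class TestLatency:
    def test_lift_after_retraction(self, pinprick):
        tc = mesh_crossing_time(pinprick)
        fps = 2000.0
        n = int(1.2 * fps)
        t = -0.1 + np.arange(n) / fps
        y = np.zeros(n)
        lift = t >= tc + 0.08  # after the stimulus is back under the mesh? no:
        # 80 ms after crossing the stimulus is still above mesh (apex at 92 ms)
        y[lift] = 3.0
        track = _mm_track(y, t0=-0.1)
        latency, pre = withdrawal_latency(track, pinprick)
        assert latency == pytest.approx(0.080, abs=1.5 / fps)
        assert not pre

    def test_pre_lifted_paw_flagged_zero_latency(self, pinprick):
        fps = 2000.0
        n = int(1.0 * fps)
        y = np.full(n, 3.0)  # above apex-above-mesh (2 mm) throughout
        track = _mm_track(y, t0=-0.1)
        latency, pre = withdrawal_latency(track, pinprick)
        assert latency == pytest.approx(0.0, abs=1.0 / fps)
        assert pre

    def test_non_responder_none(self, pinprick):
        track = _mm_track(np.zeros(2400), t0=-0.1)
        latency, pre = withdrawal_latency(track, pinprick)
        assert latency is None

    def test_lift_only_after_stimulus_down(self, pinprick):
        tc = mesh_crossing_time(pinprick)
        fps = 2000.0
        n = int(1.5 * fps)
        t = -0.1 + np.arange(n) / fps
        y = np.zeros(n)
        t_lift = 0.6  # stimulus back below mesh after ~0.49 s
        y[t >= t_lift] = 2.0
        latency, _ = withdrawal_latency(_mm_track(y, t0=-0.1), pinprick)
        assert latency == pytest.approx(t_lift - tc, abs=1.5 / fps)

    def test_track_ending_before_crossing_is_alignment_error(self, pinprick):
        from pawkit.kinematics import AlignmentError

        with pytest.raises(AlignmentError):
            withdrawal_latency(_mm_track(np.zeros(100)), pinprick)


class TestReflexive:
    def test_straight_rise_path_equals_displacement(self):
        y = np.concatenate([np.zeros(10), np.linspace(0, 5, 50), np.full(10, 5.0)])
        track = _mm_track(y)
        ts = find_t_star(y)
        feats = reflexive_features(track, ts.index)
        assert feats["distance_reflexive_mm"] == pytest.approx(5.0, abs=1e-9)
        assert feats["max_height_mm"] == pytest.approx(5.0)

    def test_stationary_segment_zero_distance(self):
        y = np.concatenate([np.zeros(5), [0.6, 1.2], np.zeros(5)])
        track = _mm_track(y)
        feats = reflexive_features(track, 6)
        assert feats["distance_reflexive_mm"] == pytest.approx(1.2)

    def test_noisy_peak_within_three_sigma(self, noisy_trial, pinprick):
        params, track, truth = noisy_trial
        cal = compute_calibration(track, params.known_mm)
        feats = extract_features(track, pinprick, calibration=cal)
        assert feats.max_height_mm == pytest.approx(
            truth["peak_height_mm"], abs=3 * params.noise_sd_mm)


class TestShakes:
    def _oscillation_track(self, freq=20.0, amp=1.5, level=2.0, n_half=8):
        fps = 2000.0
        dur = (n_half + 0.5) / (2 * freq)
        pre = np.zeros(100)
        rise = np.linspace(0, 5.0, 60)
        down = np.linspace(5.0, level + amp, 40)
        t = np.arange(int(dur * fps)) / fps
        bout = level + amp * np.cos(2 * np.pi * freq * t)
        tail = np.full(200, level)
        ret = np.linspace(level, 0, 300)
        y = np.concatenate([pre, rise, down, bout, tail, ret])
        return _mm_track(y), len(pre) + len(rise) - 1

    def test_analytic_oscillation_count(self):
        # 20 Hz cosine bout spanning 8 half-periods -> 8 velocity sign changes
        track, t_star = self._oscillation_track(n_half=8)
        shakes, dur = detect_shakes(track, t_star)
        assert len(shakes) == 8

    def test_still_paw_no_shakes(self):
        y = np.concatenate([np.zeros(50), np.linspace(0, 3, 50), np.full(400, 3.0),
                            np.linspace(3, 0, 200)])
        track = _mm_track(y)
        shakes, dur = detect_shakes(track, find_t_star(y).index)
        assert len(shakes) == 0
        assert dur == 0.0

    def test_low_oscillation_gated_by_height(self):
        # oscillation entirely below the 0.35 mm shaking height threshold
        track, t_star = self._oscillation_track(amp=0.1, level=0.2)
        shakes, _ = detect_shakes(track, t_star)
        assert len(shakes) == 0

    def test_slow_oscillation_gated_by_speed(self):
        track, t_star = self._oscillation_track(freq=2.0, amp=1.0, n_half=4)
        # peak speed 2*pi*2*1 = 12.6 mm/s < 50 mm/s
        shakes, _ = detect_shakes(track, t_star)
        assert len(shakes) == 0

    def test_generator_shake_count_exact(self, pinprick):
        for seed in range(5):
            p = WithdrawalParams(seed=seed, n_shakes=3 + seed, noise_sd_mm=0.03)
            track, truth = synth_withdrawal_track(p, pinprick)
            cal = compute_calibration(track, p.known_mm)
            feats = extract_features(track, pinprick, calibration=cal)
            assert feats.n_shakes == truth["n_shakes"]


class TestGuarding:
    def test_plateau_duration(self):
        fps = 2000.0
        y = np.concatenate([np.zeros(100), np.linspace(0, 3, 60),
                            np.full(int(1.0 * fps), 2.0), np.linspace(2, 0, 100)])
        track = _mm_track(y)
        ts = find_t_star(y)
        _, dur = detect_guarding(track, ts.index)
        assert dur == pytest.approx(1.0, abs=0.05)

    def test_immediate_return_no_guarding(self):
        y = np.concatenate([np.zeros(50), np.linspace(0, 3, 30),
                            np.linspace(3, 0, 30), np.zeros(200)])
        track = _mm_track(y)
        _, dur = detect_guarding(track, find_t_star(y).index)
        assert dur == pytest.approx(0.0, abs=0.04)

    def test_shaking_bout_subtracted(self, pinprick):
        p = WithdrawalParams(seed=2, noise_sd_mm=0.0, dropout_prob=0.0)
        track, truth = synth_withdrawal_track(p, pinprick)
        cal = compute_calibration(track, p.known_mm)
        feats = extract_features(track, pinprick, calibration=cal)
        assert feats.guarding_duration_s == pytest.approx(
            truth["guard_duration_s"], abs=0.02)


class TestExtractFeatures:
    def test_full_recovery_on_programmed_trial(self, pinprick):
        p = WithdrawalParams(seed=21, latency_s=0.06, peak_height_mm=4.0,
                             n_shakes=6, guard_duration_s=0.8, noise_sd_mm=0.02)
        track, truth = synth_withdrawal_track(p, pinprick)
        cal = compute_calibration(track, p.known_mm)
        feats = extract_features(track, pinprick, calibration=cal)
        assert feats.latency_s == pytest.approx(truth["latency_s"],
                                                abs=1 / 2000.0)
        assert feats.max_height_mm == pytest.approx(truth["peak_height_mm"],
                                                    abs=3 * p.noise_sd_mm)
        assert feats.n_shakes == truth["n_shakes"]
        assert feats.guarding_duration_s == pytest.approx(
            truth["guard_duration_s"], abs=0.02)

    def test_non_response_trial_zeroes(self, pinprick):
        p = WithdrawalParams(seed=3, latency_s=None, noise_sd_mm=0.01,
                             dropout_prob=0.0)
        track, _ = synth_withdrawal_track(p, pinprick)
        cal = compute_calibration(track, p.known_mm)
        feats = extract_features(track, pinprick, calibration=cal)
        assert feats.latency_s is None
        assert not feats.responded
        assert feats.n_shakes == 0
        assert feats.guarding_duration_s == 0.0
        assert feats.distance_affective_mm == 0.0

    def test_deterministic(self, noisy_trial, pinprick):
        params, track, _ = noisy_trial
        cal = compute_calibration(track, params.known_mm)
        a = extract_features(track, pinprick, calibration=cal)
        b = extract_features(track, pinprick, calibration=cal)
        assert a == b


class TestInvariances:
    def test_horizontal_translation_invariance(self, noisy_trial, pinprick):
        params, track, _ = noisy_trial
        cal = compute_calibration(track, params.known_mm)
        moved = track.copy()
        moved.coords = moved.coords + np.array([37.0, 0.0])
        a = extract_features(track, pinprick, calibration=cal)
        b = extract_features(moved, pinprick, calibration=cal)
        assert a.max_height_mm == pytest.approx(b.max_height_mm, abs=1e-9)
        assert a.latency_s == pytest.approx(b.latency_s, abs=1e-9)
        assert a.n_shakes == b.n_shakes

    def test_x_reflection_preserves_height_and_vy(self, noisy_trial, pinprick):
        params, track, _ = noisy_trial
        cal = compute_calibration(track, params.known_mm)
        flipped = track.copy()
        flipped.coords[:, :, 0] = 100.0 - flipped.coords[:, :, 0]
        a = extract_features(track, pinprick, calibration=cal)
        b = extract_features(flipped, pinprick, calibration=cal)
        assert a.max_height_mm == pytest.approx(b.max_height_mm, abs=1e-9)
        assert a.max_y_velocity_mm_s == pytest.approx(b.max_y_velocity_mm_s,
                                                      abs=1e-9)

    def test_path_length_at_least_displacement(self, pinprick):
        rng = np.random.default_rng(8)
        for seed in range(5):
            p = WithdrawalParams(seed=seed + 100,
                                 peak_height_mm=float(rng.uniform(3.6, 7)),
                                 noise_sd_mm=0.03)
            track, _ = synth_withdrawal_track(p, pinprick)
            cal = compute_calibration(track, p.known_mm)
            mm = preprocess(
                __import__("pawkit.track_io", fromlist=["x"]).apply_calibration(
                    track, cal))
            xy = mm.node_xy("center")
            from pawkit.kinematics import _path_length

            for lo, hi in ((0, len(xy) // 2), (len(xy) // 3, len(xy) - 1)):
                seg = xy[lo:hi]
                assert (_path_length(seg, True)
                        >= np.linalg.norm(seg[-1] - seg[0]) - 1e-9)

    def test_monotone_peak_height(self, pinprick):
        heights = []
        for peak in (4.0, 5.0, 6.0, 7.0):
            p = WithdrawalParams(seed=55, peak_height_mm=peak, noise_sd_mm=0.02)
            track, _ = synth_withdrawal_track(p, pinprick)
            cal = compute_calibration(track, p.known_mm)
            heights.append(extract_features(track, pinprick,
                                            calibration=cal).max_height_mm)
        assert all(b > a for a, b in zip(heights, heights[1:]))
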