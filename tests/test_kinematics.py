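"""Detection, onset refinement, per-event measures and metric normalization."""

import numpy as np
import pandas as pd
import pytest

from binoc.kinematics import (
    DetectionConfig,
    EyeTrace,
    METRIC_NAMES,
    SaccadeEvent,
    EyeMeasures,
    compute_measures,
    detect_coarse,
    detect_saccades,
    nine_metrics,
    normalize_metrics,
    pair_and_refractory,
    refine_onset,
)


def _step_trace(step_t=5.0, amp=10.0, duration=10.0, rate=300.0, noise=0.0, seed=0):
    t = np.arange(0.0, duration, 1.0 / rate)
    x = np.where(t >= step_t, amp, 0.0)
    if noise > 0:
        x = x + np.random.default_rng(seed).normal(0, noise, len(t))
    return EyeTrace(t=t, left=x.copy(), right=x.copy())


class TestCoarseDetection:
    def test_constant_trace_yields_no_events(self):
        t = np.arange(0, 10, 0.01)
        trace = EyeTrace(t=t, left=np.full_like(t, 3.0), right=np.full_like(t, 3.0))
        events = detect_coarse(trace)
        assert len(events["left"]) == 0 and len(events["right"]) == 0

    def test_single_step_detected_near_step_time(self):
        events = detect_coarse(_step_trace())
        assert len(events["left"]) == 1
        assert abs(events["left"][0] - 5.0) <= 0.030

    def test_temporal_resolution_of_close_steps(self):
        # The 1 Hz low-pass smears position steps over ~0.4 s, so two 8 deg
        # steps 150 ms apart merge into a single coarse peak; well-separated
        # steps are resolved individually.
        t = np.arange(0, 10, 1 / 300.0)

        def steps(dt):
            x = np.where(t >= 5.0, 8.0, 0.0) + np.where(t >= 5.0 + dt, 8.0, 0.0)
            return EyeTrace(t=t, left=x, right=x)

        assert len(detect_coarse(steps(0.15))["left"]) == 1
        assert len(detect_coarse(steps(1.5))["left"]) == 2

    def test_too_short_trace_rejected(self):
        t = np.arange(0, 0.5, 0.01)
        with pytest.raises(ValueError):
            detect_coarse(EyeTrace(t=t, left=np.zeros_like(t), right=np.zeros_like(t)))


class TestPairing:
    def test_events_within_100ms_pair_binocularly(self):
        retained = pair_and_refractory([1.00], [1.05])
        assert len(retained) == 1 and retained[0].binocular

    def test_unpaired_event_within_refractory_is_discarded(self):
        retained = pair_and_refractory([1.00], [1.20])
        assert len(retained) == 1
        assert retained[0].t_left == 1.00 and retained[0].t_right is None

    def test_single_eye_event_retained_monocular(self):
        retained = pair_and_refractory([2.0], [])
        assert len(retained) == 1 and not retained[0].binocular

    def test_refractory_drops_trailing_binocular_event(self):
        retained = pair_and_refractory([1.00, 1.25], [1.02, 1.27])
        assert len(retained) == 1

    def test_empty_inputs(self):
        assert pair_and_refractory([], []) == []


class TestOnsetRefinement:
    def test_step_onset_recovered_near_step_time(self):
        # the wide (100 ms) kernel sees an ideal step slightly ahead, so the
        # product threshold crosses up to ~20 ms before the step itself
        onset = refine_onset(_step_trace(step_t=2.0, amp=12.0), 2.0, "left")
        assert onset is not None and -0.020 <= onset - 2.0 <= 0.005

    def test_pure_noise_window_rejected(self):
        trace = _step_trace(step_t=50.0, amp=0.0, duration=10.0, noise=0.1)
        assert refine_onset(trace, 5.0, "left") is None

    def test_onset_stable_under_small_noise(self):
        clean = refine_onset(_step_trace(step_t=3.0, amp=12.0), 3.0, "left")
        for seed in range(5):
            noisy = refine_onset(
                _step_trace(step_t=3.0, amp=12.0, noise=0.1, seed=seed), 3.0, "left"
            )
            assert noisy is not None and abs(noisy - clean) <= 0.010

    def test_window_outside_trace_raises(self):
        with pytest.raises(ValueError):
            refine_onset(_step_trace(), 0.05, "left")


class TestMeasures:
    def test_step_amplitude_is_med_post_minus_pre(self):
        m = compute_measures(_step_trace(step_t=5.0, amp=10.0), 5.0, "left")
        assert m.amplitude == pytest.approx(10.0, abs=0.05)

    def test_ramp_velocity(self):
        t = np.arange(0, 10, 1 / 500.0)
        x = 10.0 * t  # 10 deg/s linear ramp, no saccade
        trace = EyeTrace(t=t, left=x, right=x)
        m = compute_measures(trace, 5.0, "left")
        assert m.vel_cw == pytest.approx(10.0, abs=0.5)
        assert m.vel_ccw >= 0.0 - 0.5

    def test_overshoot_max_vs_median(self):
        t = np.arange(0, 10, 1 / 500.0)
        x = np.zeros_like(t)
        x[(t > 5.0) & (t < 5.1)] = 12.0  # overshoot just after onset, then settle
        x[t >= 5.1] = 10.0
        trace = EyeTrace(t=t, left=x, right=x)
        m = compute_measures(trace, 5.0, "left")
        assert m.max_post_pos == pytest.approx(12.0, abs=0.2)
        assert m.med_post_pos == pytest.approx(10.0, abs=0.2)
        assert m.maxmed == pytest.approx(2.0, abs=0.4)

    def test_cw_velocity_never_below_ccw(self):
        for seed in range(5):
            trace = _step_trace(amp=8.0, noise=0.2, seed=seed)
            m = compute_measures(trace, 5.0, "left")
            assert m.vel_cw >= m.vel_ccw


class TestNineMetrics:
    @staticmethod
    def _event(left: EyeMeasures | None, right: EyeMeasures | None):
        return SaccadeEvent(coarse_peak_s=1.0, onset_left_s=1.0, onset_right_s=1.0, left=left, right=right)

    def test_vector_length_and_order(self):
        m = EyeMeasures(0.0, 10.0, 10.0, 500.0, -20.0)
        v = nine_metrics(self._event(m, m))
        assert v.shape == (9,) and len(METRIC_NAMES) == 9
        assert np.isfinite(v).all()

    def test_symmetric_conjugate_has_zero_vergence(self):
        m = EyeMeasures(0.0, 10.0, 10.0, 500.0, -20.0)
        assert nine_metrics(self._event(m, m))[8] == 0.0

    def test_symmetric_convergence_vergence_is_sum_of_nasal_amplitudes(self):
        left = EyeMeasures(0.0, 8.0, 8.0, 400.0, -10.0)  # +8 = nasal for left eye
        right = EyeMeasures(0.0, -8.0, -8.0, 10.0, -400.0)  # -8 = nasal for right eye
        assert nine_metrics(self._event(left, right))[8] == pytest.approx(16.0)

    def test_monocular_event_has_nan_for_missing_eye(self):
        m = EyeMeasures(0.0, 10.0, 10.0, 500.0, -20.0)
        v = nine_metrics(self._event(m, None))
        assert np.isnan(v[[1, 3, 6, 7, 8]]).all() and np.isfinite(v[[0, 2, 4, 5]]).all()


class TestNormalizeMetrics:
    def test_constant_column_zeroed_and_flagged(self):
        M = np.column_stack([np.full(20, 7.0), np.random.default_rng(0).normal(size=20)])
        out, flags = normalize_metrics(M)
        assert np.all(out[:, 0] == 0.0)
        assert any(f[1] == 0 for f in flags)

    def test_standard_normal_column_approximately_preserved(self):
        x = np.random.default_rng(1).normal(size=(10_000, 1))
        out, _ = normalize_metrics(x)
        assert abs(out.mean()) < 0.05
        assert 0.95 <= out.std() <= 1.05

    def test_extreme_outlier_is_winsorized(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=1000)
        x[0] = 100 * x.std()
        out, _ = normalize_metrics(x[:, None])
        # after clipping to P99.5 the outlier cannot dominate the z-range
        assert out[0, 0] < 4.0

    def test_requires_two_events(self):
        with pytest.raises(ValueError):
            normalize_metrics(np.ones((1, 9)))


def test_detection_is_deterministic():
    trace = _step_trace(amp=9.0, noise=0.15, seed=3)
    a = detect_saccades(trace)
    b = detect_saccades(trace)
    pd.testing.assert_frame_equal(a, b)


def test_amplitude_sign_matches_displacement():
    up = compute_measures(_step_trace(amp=10.0), 5.0, "left")
    down = compute_measures(_step_trace(amp=-10.0), 5.0, "left")
    assert up.amplitude > 0 > down.amplitude
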