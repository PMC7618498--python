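"""Saccade-triggered fluorescence metrics: STF, rectilinear fits, saccade-type
index, OKR power, PC1 and directionality."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sig

from binoc.encoding import CIRF
from binoc.tuning import (
    directionality_preference,
    normalized_stf,
    okr_power,
    pc1_score,
    rectilinear_fit,
    saccade_type_index,
)


class TestNormalizedSTF:
    def test_flat_trace_gives_zero_everywhere(self):
        vals, flag = normalized_stf(np.full(500, 2.0), np.array([50, 150, 250, 350, 450]), 4.8)
        assert np.all(vals[np.isfinite(vals)] == 0.0)

    def test_identical_responses_normalize_to_one(self):
        fs = 4.8
        z = np.zeros(1000)
        onsets = np.array([100, 250, 400, 550, 700])
        kernel = CIRF(0.2, 3.0).kernel(fs)
        for o in onsets:
            z[o : o + len(kernel)] += kernel[: len(z) - o]
        vals, flag = normalized_stf(z, onsets, fs)
        assert not flag
        assert np.allclose(vals, 1.0)

    def test_value_equals_direct_kernel_window_sum(self):
        # one doubled response among unit responses: ratios follow the
        # independent 2 s kernel sum computed directly
        fs = 4.8
        kernel = CIRF(0.2, 3.0).kernel(fs)
        n_post = int(round(2.0 * fs))
        S = kernel[:n_post].sum()  # direct kernel evaluation oracle
        z = np.zeros(1000)
        onsets = np.array([100, 250, 400, 550, 700])
        for i, o in enumerate(onsets):
            amp = 2.0 if i == 4 else 1.0
            z[o : o + len(kernel)] += amp * kernel[: len(z) - o]
        vals, _ = normalized_stf(z, onsets, fs)
        p95 = np.percentile([S, S, S, S, 2 * S], 95)
        assert vals[0] == pytest.approx(S / p95, rel=1e-6)
        assert vals[4] == pytest.approx(2 * S / p95, rel=1e-6)

    def test_needs_five_saccades(self):
        with pytest.raises(ValueError):
            normalized_stf(np.zeros(100), np.array([50]), 4.8)


class TestRectilinearFit:
    def test_flat_data_baseline_only(self, rng):
        x = rng.uniform(0, 1, 50)
        y = np.full(50, 0.3)
        fit = rectilinear_fit(x, y)
        assert not fit.ramp_accepted and fit.slope is None
        assert fit.baseline == pytest.approx(0.3)

    def test_noiseless_hinge_recovery(self):
        x = np.linspace(0.0, 1.0, 200)
        y = np.where(x <= 0.5, 0.0, 2.0 * (x - 0.5))
        fit = rectilinear_fit(x, y)
        assert fit.ramp_accepted
        grid_step = 1.0 / 40
        assert abs(fit.breakpoint - 0.5) <= grid_step + 1e-9
        assert fit.slope == pytest.approx(2.0, rel=0.05)

    def test_noisy_hinge_accepted_and_beats_baseline(self, rng):
        x = rng.uniform(0, 1, 200)
        y = np.where(x <= 0.5, 0.0, 2.0 * (x - 0.5)) + rng.normal(0, 0.1, 200)
        fit = rectilinear_fit(x, y)
        base_mse = np.mean((y - np.median(y)) ** 2)
        assert fit.ramp_accepted
        assert fit.mse <= base_mse + 1e-12

    def test_selected_mse_never_exceeds_baseline_only(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            x = r.uniform(0, 1, 60)
            y = r.normal(size=60)
            fit = rectilinear_fit(x, y)
            assert fit.mse <= np.mean((y - np.median(y)) ** 2) + 1e-12

    def test_degenerate_positions_flagged(self):
        fit = rectilinear_fit(np.full(20, 0.5), np.arange(20.0))
        assert fit.flag == "degenerate_positions" and not fit.ramp_accepted


class TestSaccadeTypeIndex:
    @staticmethod
    def _frames(n, rng, stf_fn, jitter=0.0):
        pos = rng.uniform(0.2, 1.0, n)
        vel = rng.uniform(0.2, 1.0, n)
        stf = stf_fn(pos, vel) + (rng.normal(0, jitter, n) if jitter else 0.0)
        return pd.DataFrame({"pos_norm": pos, "vel_norm": vel, "stf": stf})

    def test_kinematics_only_response_gives_near_zero_index(self):
        rng = np.random.default_rng(0)
        f = lambda p, v: 0.5 * p + 0.3 * v
        conj = self._frames(100, rng, f)
        conv = conj.copy()
        conv[["pos_norm", "vel_norm"]] += rng.normal(0, 0.01, (100, 2))
        conv["stf"] = f(conv["pos_norm"], conv["vel_norm"])
        idx, n = saccade_type_index(conj, conv)
        assert n >= 90 and abs(idx) < 0.05

    def test_constant_shift_recovered_exactly(self, rng):
        conj = self._frames(50, rng, lambda p, v: 0.4 * p)
        conv = conj.copy()
        conv["stf"] = conj["stf"] + 0.3
        idx, n = saccade_type_index(conj, conv)
        assert idx == pytest.approx(0.3)

    def test_no_match_within_radius_gives_missing(self, rng):
        conj = pd.DataFrame({"pos_norm": [0.1], "vel_norm": [0.1], "stf": [0.0]})
        conv = pd.DataFrame({"pos_norm": [0.9], "vel_norm": [0.9], "stf": [1.0]})
        idx, n = saccade_type_index(conj, conv)
        assert np.isnan(idx) and n == 0


def _grating_epochs(n_cycles=6, t_epoch=4.0, t0=10.0):
    rows = []
    t = t0
    for k in range(2 * n_cycles):
        rows.append({"kind": "grating", "start_s": t, "stop_s": t + t_epoch, "direction": -1 if k % 2 == 0 else 1})
        t += t_epoch
    return pd.DataFrame(rows)


class TestOkrPower:
    def test_direction_symmetric_response_has_zero_power(self):
        fs = 4.8
        frame_t = (np.arange(1000) + 0.5) / fs
        epochs = _grating_epochs()
        z = np.zeros(1000)
        for _, row in epochs.iterrows():
            sel = (frame_t >= row.start_s) & (frame_t < row.stop_s)
            z[sel] = 1.0  # same response to both directions
        assert okr_power(z, epochs, frame_t) == pytest.approx(0.0, abs=1e-20)

    def test_power_scales_with_amplitude_squared_and_matches_periodogram(self):
        fs = 4.8
        frame_t = (np.arange(1000) + 0.5) / fs
        epochs = _grating_epochs()
        powers = []
        for a in (1.0, 2.0, 3.0):
            z = np.zeros(1000)
            for _, row in epochs.iterrows():
                sel = (frame_t >= row.start_s) & (frame_t < row.stop_s)
                z[sel] = a * row.direction  # direction-selective square wave
            powers.append(okr_power(z, epochs, frame_t))
        assert powers[1] / powers[0] == pytest.approx(4.0, rel=1e-6)
        assert powers[2] / powers[0] == pytest.approx(9.0, rel=1e-6)
        # independent oracle: periodogram of one alternation cycle
        n_ep = int(round(4.0 * fs))
        cycle = np.concatenate([np.full(n_ep, -1.0), np.full(n_ep, 1.0)])
        f, pxx = sig.periodogram(cycle, fs=fs)
        assert powers[0] == pytest.approx(pxx[1], rel=1e-9)

    def test_dc_offset_invariance(self):
        fs = 4.8
        frame_t = (np.arange(1000) + 0.5) / fs
        epochs = _grating_epochs()
        rng = np.random.default_rng(0)
        z = rng.normal(size=1000)
        assert okr_power(z + 5.0, epochs, frame_t) == pytest.approx(
            okr_power(z, epochs, frame_t), rel=1e-9
        )

    def test_no_gratings_rejected(self):
        with pytest.raises(ValueError, match="grating"):
            okr_power(np.zeros(500), pd.DataFrame({"kind": [], "start_s": [], "stop_s": [], "direction": []}), np.arange(500) / 4.8)


class TestPC1:
    def test_anticorrelated_metrics_closed_form(self, rng):
        z1 = rng.normal(size=50)
        sti = z1
        okr = -2.0 * z1  # perfectly anticorrelated
        scores, loadings, evr = pc1_score(sti, okr)
        assert evr == pytest.approx(1.0)
        z1s = (sti - sti.mean()) / sti.std()
        z2s = (okr - okr.mean()) / okr.std()
        assert np.allclose(scores, (z1s - z2s) / np.sqrt(2))

    def test_loadings_magnitude_and_sign_orientation(self, rng):
        sti = rng.normal(size=200)
        okr = rng.normal(size=200)
        _, loadings, _ = pc1_score(sti, okr)
        assert np.allclose(np.abs(loadings), 1 / np.sqrt(2), atol=1e-9)
        assert loadings[0] > 0

    def test_duplication_invariance_and_zero_mean(self, rng):
        sti = rng.normal(size=40)
        okr = 0.5 * sti + rng.normal(size=40)
        s1, _, _ = pc1_score(sti, okr)
        s2, _, _ = pc1_score(np.tile(sti, 2), np.tile(okr, 2))
        assert np.allclose(s1, s2[:40])
        assert abs(np.nanmean(s1)) < 1e-9

    def test_too_few_rois_rejected(self):
        with pytest.raises(ValueError):
            pc1_score(np.ones(5), np.ones(5))


class TestDirectionality:
    def test_more_negative_left_sum_wins(self):
        d = {
            "sacc_ConjL": -0.1,
            "sacc_ConvL": -0.05,
            "pos_nasal_right": -0.02,
            "sacc_ConjR": 0.0,
            "sacc_ConvR": 0.0,
            "pos_nasal_left": 0.0,
        }
        pref, tie = directionality_preference(d)
        assert pref == "left" and not tie

    def test_exact_tie_defaults_left_with_flag(self):
        d = {k: 0.0 for k in (
            "sacc_ConjL", "sacc_ConvL", "pos_nasal_right",
            "sacc_ConjR", "sacc_ConvR", "pos_nasal_left")}
        pref, tie = directionality_preference(d)
        assert pref == "left" and tie
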