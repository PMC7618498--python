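"""zF standardization, d' statistics, design matrix, ridge and delta cvR^2."""

import numpy as np
import pandas as pd
import pytest

from binoc.encoding import (
    CIRF,
    classify_tuned,
    compute_zF,
    delta_cvR2,
    dprime_null_test,
    ols_hyperparam_search,
    ridge_cv_fit,
    saccade_dprime,
    build_design,
    OCULOMOTOR_COLUMNS,
)
from binoc.kinematics import EyeTrace


class TestCIRF:
    def test_kernel_rises_then_decays_with_unit_max(self):
        k = CIRF(0.2, 4.0).kernel(10.0)
        assert k.max() == pytest.approx(1.0)
        assert k[0] == pytest.approx(0.0)
        peak = np.argmax(k)
        assert 0 < peak < len(k) - 1
        assert np.all(np.diff(k[peak:]) <= 1e-12)

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            CIRF(0.2, 0.1)
        with pytest.raises(ValueError):
            CIRF(-1.0, 4.0)


class TestComputeZF:
    def test_gaussian_trace_baseline_and_noise(self):
        rng = np.random.default_rng(0)
        F = rng.normal(10.0, 2.0, (1, 10_000))
        zF, info = compute_zF(F)
        assert info["baseline"][0] == pytest.approx(10.0, abs=0.1)
        assert info["noise"][0] == pytest.approx(2.0, rel=0.10)

    def test_constant_trace_flagged_zero_noise(self):
        zF, info = compute_zF(np.full((1, 200), 7.0))
        assert info["zero_noise"][0]
        assert np.all(zF == 0.0)

    def test_high_motion_frame_interpolated(self):
        F = np.full((1, 200), 3.0)
        F[0, 100] = 50.0
        motion = np.zeros(200)
        motion[100] = 6.0
        zF, info = compute_zF(F, motion)
        assert info["interpolated_frames"][100]
        # the excursion frame is replaced by its (constant) neighbours
        assert zF[0, 100] == pytest.approx(zF[0, 99])

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        F = rng.normal(50.0, 5.0, (2, 2000)) + np.sin(np.linspace(0, 20, 2000))
        z1, _ = compute_zF(F)
        z2, _ = compute_zF(3.0 * F + 17.0)
        assert np.allclose(z1, z2, atol=1e-8)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            compute_zF(np.zeros((1, 50)))

    def test_all_frames_bad_rejected(self):
        with pytest.raises(ValueError):
            compute_zF(np.zeros((1, 200)), np.full(200, 10.0))


class TestDPrime:
    def test_analytic_value_on_constructed_arrays(self):
        # pre alternates +-1 (mean 0, var 1); post = pre + 2 -> d' = 2
        fs = 1.0
        pre = np.tile([1.0, -1.0], 10)
        z = np.zeros(400)
        onsets = np.arange(5, 395, 20)[:10]
        for o in onsets:
            z[o - 2 : o] = [1.0, -1.0]
            z[o : o + 4] = [3.0, 1.0, 3.0, 1.0]
        d = saccade_dprime(z, onsets, frame_rate_hz=2.0, pre_s=1.0, post_s=2.0)
        assert d == pytest.approx(2.0)

    def test_identical_pre_post_gives_zero(self):
        z = np.ones(500)
        d = saccade_dprime(z, np.array([100, 200, 300]), frame_rate_hz=4.8)
        assert d == 0.0

    def test_sign_antisymmetry_under_time_reversal(self):
        # with equal windows, reversing time swaps pre and post exactly
        rng = np.random.default_rng(2)
        z = rng.normal(size=600)
        onsets = np.array([100, 250, 400])
        d_fwd = saccade_dprime(z, onsets, 4.8, pre_s=1.0, post_s=1.0)
        d_rev = saccade_dprime(z[::-1], len(z) - onsets, 4.8, pre_s=1.0, post_s=1.0)
        assert d_rev == pytest.approx(-d_fwd)

    def test_convergence_to_population_dprime(self):
        rng = np.random.default_rng(3)
        n_ev, w = 200, 5
        z = rng.normal(0.0, 1.0, n_ev * 20)
        onsets = np.arange(8, n_ev * 20 - 12, 20)[:n_ev]
        for o in onsets:
            z[o : o + 2 * w] += 1.0
        d = saccade_dprime(z, onsets, frame_rate_hz=w, pre_s=1.0, post_s=2.0)
        assert d == pytest.approx(1.0, abs=0.1)

    def test_needs_two_events(self):
        with pytest.raises(ValueError):
            saccade_dprime(np.zeros(100), np.array([50]), 4.8)


class TestDPrimeNull:
    def test_zero_variance_roi_never_flagged(self, rng):
        z = np.ones(1000)
        res = dprime_null_test(z, {"Conv": np.array([100, 300, 500])}, 4.8, rng)
        assert not res["Conv"].active

    def test_responsive_roi_flagged(self, rng):
        z = rng.normal(0, 1, 2000)
        onsets = np.arange(100, 1900, 100)
        for o in onsets:
            z[o : o + 10] += 2.0
        res = dprime_null_test(z, {"Conv": onsets}, 4.8, rng, n_shuffle=500)
        assert res["Conv"].active and res["Conv"].dprime > res["Conv"].null_p95


@pytest.fixture(scope="module")
def session_design(small_session):
    return small_session.design


class TestDesignMatrix:
    def test_group_structure(self, session_design):
        g = session_design.groups
        assert session_design.X.shape[1] == 33
        assert (g == "oculomotor").sum() == 6
        assert (g == "locomotor").sum() == 8
        assert (g == "stimulus").sum() == 18
        assert (g == "motion").sum() == 1
        assert set(OCULOMOTOR_COLUMNS) <= set(session_design.names)

    def test_no_swims_keeps_zero_locomotor_columns(self, small_session):
        d = build_design(
            events=small_session.events,
            trace=small_session.trace,
            swims=small_session.swims.iloc[:0],
            stimuli=small_session.stimuli,
            motion_error_um=small_session.motion_error_um,
            frame_t=small_session.frame_t,
        )
        loco = d.X[:, d.groups == "locomotor"]
        assert loco.shape[1] == 8 and np.all(loco == 0.0)

    def test_missing_log_raises_named_error(self, small_session):
        with pytest.raises(ValueError, match="swims"):
            build_design(
                events=small_session.events,
                trace=small_session.trace,
                swims=None,
                stimuli=small_session.stimuli,
                motion_error_um=small_session.motion_error_um,
                frame_t=small_session.frame_t,
            )

    def test_single_onset_column_is_the_shifted_kernel(self, small_session):
        events = pd.DataFrame({"onset_s": [100.0], "label": ["ConjR"]})
        cirf = CIRF(0.2, 3.0)
        offset = 2
        d = build_design(
            events=events,
            trace=small_session.trace,
            swims=small_session.swims.iloc[:0],
            stimuli=small_session.stimuli.iloc[:0],
            motion_error_um=small_session.motion_error_um,
            frame_t=small_session.frame_t,
            cirf=cirf,
            offset_frames=offset,
        )
        col = d.column("sacc_ConjR")
        rate = 1.0 / np.median(np.diff(small_session.frame_t))
        kernel = cirf.kernel(rate)
        onset_frame = int(np.argmax(col > 0)) if col.any() else -1
        expected = np.zeros_like(col)
        f0 = np.argmin(np.abs(small_session.frame_t - 100.0)) + offset
        expected[f0 : f0 + len(kernel)] = kernel[: len(expected) - f0]
        assert np.allclose(col, expected)

    def test_motion_column_unconvolved(self, small_session, session_design):
        assert np.allclose(session_design.column("motion_error"), small_session.motion_error_um)


class TestOLSSearch:
    def test_noiseless_roi_recovers_hyperparameters(self, small_session):
        from binoc.encoding import build_design_grid

        grid = build_design_grid(
            events=small_session.events,
            trace=small_session.trace,
            swims=small_session.swims,
            stimuli=small_session.stimuli,
            motion_error_um=small_session.motion_error_um,
            frame_t=small_session.frame_t,
        )
        X = grid[(4.0, 2)].X
        y = 2.0 * X[:, 3] + 0.5 * X[:, 4]
        res = ols_hyperparam_search(y, grid)
        assert res.loc[0, "ols_r2"] >= 0.999
        assert res.loc[0, "best_tau_off"] == 4.0 and res.loc[0, "best_offset"] == 2
        assert res.loc[0, "gate"]

    def test_white_noise_fails_gate(self, small_session, rng):
        from binoc.encoding import build_design_grid

        grid = build_design_grid(
            events=small_session.events,
            trace=small_session.trace,
            swims=small_session.swims,
            stimuli=small_session.stimuli,
            motion_error_um=small_session.motion_error_um,
            frame_t=small_session.frame_t,
        )
        y = rng.normal(size=next(iter(grid.values())).X.shape[0])
        res = ols_hyperparam_search(y, grid)
        assert not res.loc[0, "gate"]


class TestRidge:
    @staticmethod
    def _toy(n=400, p=6, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        beta = np.array([2.0, -1.5, 1.0, 0.0, 0.0, 0.0])
        y = X @ beta + rng.normal(0, 0.5, n)
        return X, y, beta

    def test_small_lambda_limit_matches_ols(self):
        X, y, _ = self._toy()
        fit = ridge_cv_fit(y, X, lambdas=np.array([1e-8]))
        Xs = (X - X.mean(0)) / X.std(0)
        beta_ols = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)[0]
        assert np.allclose(fit.coef, beta_ols, atol=1e-6)

    def test_large_lambda_shrinks_norm_monotonically(self):
        X, y, _ = self._toy()
        norms = []
        for lam in (1e-2, 1.0, 1e2, 1e4):
            fit = ridge_cv_fit(y, X, lambdas=np.array([lam]))
            norms.append(np.linalg.norm(fit.coef))
        assert all(a >= b for a, b in zip(norms, norms[1:]))

    def test_true_support_recovered(self):
        X, y, beta = self._toy(seed=1)
        fit = ridge_cv_fit(y, X)
        top = np.argsort(-np.abs(fit.coef))[:3]
        assert set(top) == {0, 1, 2}
        assert np.sign(fit.coef[0]) > 0 > np.sign(fit.coef[1])
        assert fit.cvR2 > 0.8


class TestDeltaCvR2:
    def test_sole_driver_collapse_and_null_regressor(self, rng):
        n = 600
        X = rng.normal(size=(n, 5))
        y = 3.0 * X[:, 0]  # noiseless single driver
        fit = ridge_cv_fit(y, X, lambdas=np.array([1e-6]))
        deltas, shifts = delta_cvR2(y, X, fit, rng)
        assert deltas[0] == pytest.approx(-fit.cvR2, abs=0.05)
        assert np.all(np.abs(deltas[1:]) < 0.02)
        assert np.all((shifts >= 10) & (shifts <= n - 10))

    def test_collinear_pair_masks_unique_contribution(self, rng):
        n = 600
        x = rng.normal(size=n)
        X = np.column_stack([x, x, rng.normal(size=n)])
        y = x + rng.normal(0, 0.1, n)
        fit = ridge_cv_fit(y, X)
        deltas, _ = delta_cvR2(y, X, fit, rng)
        # each duplicate can be absorbed by the other: no unique variance
        assert abs(deltas[0]) < 0.05 and abs(deltas[1]) < 0.05


class TestClassifyTuned:
    @staticmethod
    def _groups():
        return np.array(["oculomotor"] * 6 + ["locomotor"] * 8 + ["stimulus"] * 18 + ["motion"])

    def _deltas(self, n_rois=60, seed=0):
        rng = np.random.default_rng(seed)
        return rng.uniform(-0.004, 0.004, size=(n_rois, 33))

    def test_rule_application_both_label(self):
        deltas = self._deltas()
        deltas[0, 0] = -0.5  # strong oculomotor unique contribution
        active = {
            "Conv": np.array([True] + [False] * 59),
            "LConj": np.array([True] + [False] * 59),
            "RConj": np.zeros(60, bool),
        }
        out = classify_tuned(deltas, self._groups(), active)
        assert out.loc[0, "tuned"] and out.loc[0, "label"] == "Both"

    def test_motion_dominated_roi_excluded(self):
        deltas = self._deltas(seed=1)
        deltas[0, 32] = -0.5  # motion regressor dominates
        deltas[0, 0] = -0.1
        active = {"Conv": np.array([True] + [False] * 59)}
        out = classify_tuned(deltas, self._groups(), active)
        assert not out.loc[0, "tuned"]
        assert not out.loc[0, "crit_most_negative_oculomotor"]
        assert not out.loc[0, "crit_motion_not_significant"]

    def test_locomotor_dominated_roi_excluded(self):
        deltas = self._deltas(seed=2)
        deltas[0, 7] = -0.5  # a swim regressor
        active = {"Conv": np.array([True] + [False] * 59)}
        out = classify_tuned(deltas, self._groups(), active)
        assert not out.loc[0, "tuned"]

    def test_small_null_pool_rejected(self):
        deltas = -np.abs(self._deltas(n_rois=1))
        with pytest.raises(ValueError, match="null pool"):
            classify_tuned(deltas, self._groups(), {"Conv": np.array([True])})
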