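"""Calcium-imaging encoding analysis.

Stage one identifies *saccade-active* ROIs: a saccade-triggered
sensitivity index d' = (mu_post - mu_pre) / sqrt((var_post + var_pre)/2)
is computed per saccade type (Conv, LConj, RConj) and compared against a
permutation null of 1000 d' values obtained by randomising saccade onset
times.

Stage two models each active ROI's standardized fluorescence (zF) with a
33-regressor linear model: 6 oculomotor + 8 locomotor + 18 stimulus
predictors convolved with a calcium impulse response function (CIRF), plus
one unconvolved motion-error regressor. Hyperparameters (CIRF decay
constant and a frame offset) are chosen by exhaustive OLS search; gated
ROIs are then fit with ridge regression (lambda by 10-fold cross-validation
on contiguous time blocks) and each regressor's unique contribution is
measured as the drop in cross-validated R^2 when that regressor is
circularly permuted (delta cvR^2). ROIs are labelled oculomotor-tuned when
the most negative delta cvR^2 belongs to an oculomotor regressor, at least
one oculomotor delta is beyond the null's 95th percentile, and the motion
regressor is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "CIRF",
    "DesignMatrix",
    "DPrimeResult",
    "RidgeFit",
    "RoiEncodingResult",
    "compute_zF",
    "saccade_dprime",
    "dprime_null_test",
    "dprime_null_test_batch",
    "build_design",
    "build_design_grid",
    "ols_hyperparam_search",
    "ridge_cv_fit",
    "cv_r2",
    "delta_cvR2",
    "classify_tuned",
    "SACCADE_COLUMNS",
    "OCULOMOTOR_COLUMNS",
]

SACCADE_COLUMNS = ("sacc_ConvL", "sacc_ConvR", "sacc_ConjL", "sacc_ConjR")
OCULOMOTOR_COLUMNS = SACCADE_COLUMNS + ("pos_nasal_left", "pos_nasal_right")

DPRIME_TYPES = ("Conv", "LConj", "RConj")
_DPRIME_LABELS = {"Conv": ("ConvL", "ConvR"), "LConj": ("ConjL",), "RConj": ("ConjR",)}


# ---------------------------------------------------------------------------
# CIRF


@dataclass(frozen=True)
class CIRF:
    """Calcium impulse response: exponential rise and decay.

    h(t) = (1 - exp(-t/tau_on)) * exp(-t/tau_off) on t in [0, 5 tau_off],
    normalized to unit maximum. tau_on defaults to 0.2 s; tau_off is the
    hyperparameter searched over {3, 4, 5} s.
    """

    tau_on: float = 0.2
    tau_off: float = 4.0

    def __post_init__(self) -> None:
        if self.tau_on <= 0 or self.tau_off <= 0:
            raise ValueError("CIRF time constants must be positive")
        if self.tau_off <= self.tau_on:
            raise ValueError("tau_off must exceed tau_on")

    def kernel(self, rate_hz: float) -> np.ndarray:
        t = np.arange(0.0, 5.0 * self.tau_off, 1.0 / rate_hz)
        h = (1.0 - np.exp(-t / self.tau_on)) * np.exp(-t / self.tau_off)
        m = h.max()
        return h / m if m > 0 else h


# ---------------------------------------------------------------------------
# zF


def _baseline_noise_psd(x: np.ndarray) -> float:
    """High-frequency PSD estimate of the additive noise SD.

    Mean one-sided Welch power over the upper quarter of the spectrum;
    unbiased for white noise and insensitive to slow calcium transients.
    """
    n = x.shape[-1]
    nperseg = min(256, n)
    f, pxx = _sig.welch(x, fs=1.0, nperseg=nperseg)
    band = f >= 0.25
    return float(np.sqrt(np.mean(pxx[..., band]) / 2.0))


def compute_zF(
    F: np.ndarray,
    motion_error_um: np.ndarray | None = None,
    motion_threshold_um: float = 5.0,
) -> tuple[np.ndarray, dict]:
    """Standardize raw fluorescence into zF.

    Frames whose motion error exceeds the threshold are replaced by linear
    interpolation from neighbouring good frames; baseline is the per-ROI
    median (50th percentile); noise is a robust high-frequency estimate of
    the baseline noise SD. zF = (F - baseline) / noise. Affine rescaling
    of F (positive gain, any offset) leaves zF unchanged.

    Returns (zF, info) where info holds 'baseline', 'noise',
    'zero_noise' flags and the interpolated frame mask.
    """
    F = np.atleast_2d(np.asarray(F, dtype=float)).copy()
    n_rois, n_frames = F.shape
    if n_frames < 100:
        raise ValueError("need at least 100 frames to estimate baseline and noise")
    interpolated = np.zeros(n_frames, dtype=bool)
    if motion_error_um is not None:
        motion_error_um = np.asarray(motion_error_um, dtype=float)
        if motion_error_um.shape != (n_frames,):
            raise ValueError("motion_error_um must have one value per frame")
        bad = motion_error_um > motion_threshold_um
        if bad.all():
            raise ValueError("all frames exceed the motion-error threshold")
        if bad.any():
            idx = np.arange(n_frames)
            for r in range(n_rois):
                F[r, bad] = np.interp(idx[bad], idx[~bad], F[r, ~bad])
            interpolated = bad
    baseline = np.median(F, axis=1)
    resid = F - baseline[:, None]
    noise = np.array([_baseline_noise_psd(resid[r]) for r in range(n_rois)])
    zero_noise = noise <= 0
    scale = np.abs(resid).max(axis=1)
    floor = np.where(scale > 0, scale, 1.0) * np.finfo(float).eps
    noise_safe = np.where(zero_noise, floor, noise)
    zF = resid / noise_safe[:, None]
    info = {
        "baseline": baseline,
        "noise": noise,
        "zero_noise": zero_noise,
        "interpolated_frames": interpolated,
    }
    return zF, info


# ---------------------------------------------------------------------------
# d' and permutation null


def _window_counts(frame_rate_hz: float, pre_s: float, post_s: float) -> tuple[int, int]:
    return max(1, int(round(pre_s * frame_rate_hz))), max(1, int(round(post_s * frame_rate_hz)))


def _pooled_dprime_from_sums(
    s1_pre: np.ndarray,
    s2_pre: np.ndarray,
    n_pre: int,
    s1_post: np.ndarray,
    s2_post: np.ndarray,
    n_post: int,
) -> np.ndarray:
    mu_pre = s1_pre / n_pre
    mu_post = s1_post / n_post
    var_pre = np.maximum(s2_pre / n_pre - mu_pre**2, 0.0)
    var_post = np.maximum(s2_post / n_post - mu_post**2, 0.0)
    denom = np.sqrt((var_post + var_pre) / 2.0)
    diff = mu_post - mu_pre
    with np.errstate(divide="ignore", invalid="ignore"):
        d = diff / denom
    both_zero = denom == 0
    d = np.where(both_zero & (diff == 0), 0.0, d)
    d = np.where(both_zero & (diff != 0), np.sign(diff) * 100.0, d)
    return np.clip(d, -100.0, 100.0)


def _dprime_for_onsets(
    cz: np.ndarray, cz2: np.ndarray, onsets: np.ndarray, n_pre: int, n_post: int
) -> np.ndarray:
    """Pooled d' for each row of an onset matrix, for each ROI.

    cz/cz2: (R, T+1) prefix sums of zF and zF^2. onsets: (..., E) frame
    indices. Returns array of shape (R, ...).
    """
    o = np.asarray(onsets)
    s1_post = (cz[:, o + n_post] - cz[:, o]).sum(axis=-1)
    s2_post = (cz2[:, o + n_post] - cz2[:, o]).sum(axis=-1)
    s1_pre = (cz[:, o] - cz[:, o - n_pre]).sum(axis=-1)
    s2_pre = (cz2[:, o] - cz2[:, o - n_pre]).sum(axis=-1)
    n_events = o.shape[-1]
    return _pooled_dprime_from_sums(
        s1_pre, s2_pre, n_pre * n_events, s1_post, s2_post, n_post * n_events
    )


def _prefix_sums(Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    cz = np.concatenate([np.zeros((Z.shape[0], 1)), np.cumsum(Z, axis=1)], axis=1)
    cz2 = np.concatenate([np.zeros((Z.shape[0], 1)), np.cumsum(Z**2, axis=1)], axis=1)
    return cz, cz2


def saccade_dprime(
    zF_roi: np.ndarray,
    onset_frames: np.ndarray,
    frame_rate_hz: float,
    pre_s: float = 1.0,
    post_s: float = 2.0,
) -> float:
    """Pooled saccade-triggered d' for one ROI and one set of onsets.

    Means and variances pool every (event, frame-in-window) sample: a 1 s
    pre window immediately before onset and a 2 s post window starting at
    onset. Requires >= 2 events with windows inside the recording.
    """
    z = np.asarray(zF_roi, dtype=float)[None, :]
    n_pre, n_post = _window_counts(frame_rate_hz, pre_s, post_s)
    o = np.asarray(onset_frames, dtype=int)
    valid = (o - n_pre >= 0) & (o + n_post <= z.shape[1])
    o = o[valid]
    if len(o) < 2:
        raise ValueError("need at least 2 events with full windows inside the recording")
    cz, cz2 = _prefix_sums(z)
    return float(_dprime_for_onsets(cz, cz2, o[None, :], n_pre, n_post)[0, 0])


@dataclass
class DPrimeResult:
    dprime: float
    null_p95: float
    active: bool


def dprime_null_test_batch(
    Z: np.ndarray,
    onsets_by_type: dict[str, np.ndarray],
    frame_rate_hz: float,
    rng: np.random.Generator,
    n_shuffle: int = 1000,
    pre_s: float = 1.0,
    post_s: float = 2.0,
    percentile: float = 95.0,
) -> dict[str, dict[str, np.ndarray]]:
    """Observed d', null 95th percentile and active flag for many ROIs.

    The null randomises onset times uniformly over frames where both
    windows fit, preserving the event count; one shared shuffle set per
    saccade type is drawn per call (the ROI dimension is fully
    vectorized). Zero-variance ROIs have d' = 0 and are never flagged.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n_rois, n_frames = Z.shape
    n_pre, n_post = _window_counts(frame_rate_hz, pre_s, post_s)
    cz, cz2 = _prefix_sums(Z)
    out: dict[str, dict[str, np.ndarray]] = {}
    for typ, onsets in onsets_by_type.items():
        o = np.asarray(onsets, dtype=int)
        o = o[(o - n_pre >= 0) & (o + n_post <= n_frames)]
        if len(o) < 2:
            out[typ] = {
                "dprime": np.zeros(n_rois),
                "null_p95": np.full(n_rois, np.inf),
                "active": np.zeros(n_rois, dtype=bool),
            }
            continue
        observed = _dprime_for_onsets(cz, cz2, o[None, :], n_pre, n_post)[:, 0]
        lo, hi = n_pre, n_frames - n_post
        if hi <= lo:
            raise ValueError("recording too short for shuffled windows")
        shuffles = rng.integers(lo, hi, size=(n_shuffle, len(o)))
        null = _dprime_for_onsets(cz, cz2, shuffles, n_pre, n_post)  # (R, S)
        p95 = np.percentile(null, percentile, axis=1)
        out[typ] = {"dprime": observed, "null_p95": p95, "active": observed > p95}
    return out


def dprime_null_test(
    zF_roi: np.ndarray,
    onsets_by_type: dict[str, np.ndarray],
    frame_rate_hz: float,
    rng: np.random.Generator,
    n_shuffle: int = 1000,
    **kw,
) -> dict[str, DPrimeResult]:
    """Single-ROI convenience wrapper around :func:`dprime_null_test_batch`."""
    res = dprime_null_test_batch(
        np.asarray(zF_roi)[None, :], onsets_by_type, frame_rate_hz, rng, n_shuffle, **kw
    )
    return {
        typ: DPrimeResult(float(d["dprime"][0]), float(d["null_p95"][0]), bool(d["active"][0]))
        for typ, d in res.items()
    }


# ---------------------------------------------------------------------------
# design matrix


@dataclass
class DesignMatrix:
    """Frame-aligned regressor matrix with named, group-tagged columns."""

    X: np.ndarray
    names: list
    groups: np.ndarray  # 'oculomotor' | 'locomotor' | 'stimulus' | 'motion'
    cirf: CIRF
    offset_frames: int

    def __post_init__(self) -> None:
        counts = {g: int((self.groups == g).sum()) for g in np.unique(self.groups)}
        expected = {"oculomotor": 6, "locomotor": 8, "stimulus": 18, "motion": 1}
        if counts != expected or self.X.shape[1] != 33:
            raise ValueError(f"design must have 33 columns grouped 6/8/18/1, got {counts}")

    def column(self, name: str) -> np.ndarray:
        return self.X[:, self.names.index(name)]


SPOT_AZ_EDGES = np.array([-60.0, -30.0, 0.0, 30.0, 60.0])


def _nearest_frames(times_s: np.ndarray, frame_t: np.ndarray) -> np.ndarray:
    idx = np.searchsorted(frame_t, times_s)
    idx = np.clip(idx, 1, len(frame_t) - 1)
    left_closer = np.abs(times_s - frame_t[idx - 1]) <= np.abs(frame_t[idx] - times_s)
    return np.where(left_closer, idx - 1, idx)


def build_design(
    events: pd.DataFrame,
    trace,
    swims: pd.DataFrame,
    stimuli: pd.DataFrame,
    motion_error_um: np.ndarray,
    frame_t: np.ndarray,
    cirf: CIRF | None = None,
    offset_frames: int = 0,
) -> DesignMatrix:
    """Build the 33-column design matrix on the imaging time base.

    Oculomotor (6): one-hot saccade onsets for ConvL/ConvR/ConjL/ConjR and
    two rectified nasal eye-position traces (nasal-positive position minus
    its experiment-wide median, temporal side zeroed). Locomotor (8): swim
    onsets one-hot by direction x per-session vigour quartile. Stimulus
    (18): two grating-direction indicators and 16 moving-spot predictors
    (4 azimuth bins spanning -60..+60 deg x 2 directions x 2 contrast
    polarities). All 32 are convolved with the CIRF and shifted by
    ``offset_frames``; the motion-error regressor is appended unconvolved.
    """
    for name, log in (("events", events), ("swims", swims), ("stimuli", stimuli)):
        if log is None:
            raise ValueError(f"missing predictor log: {name}")
    if motion_error_um is None:
        raise ValueError("missing predictor log: motion_error")
    cirf = cirf or CIRF()
    frame_t = np.asarray(frame_t, dtype=float)
    n = len(frame_t)
    rate = 1.0 / float(np.median(np.diff(frame_t)))
    cols: list[np.ndarray] = []
    names: list[str] = []
    groups: list[str] = []

    # --- oculomotor: 4 saccade one-hots
    labels = events["label"].to_numpy() if len(events) else np.array([])
    onset_t = events["onset_s"].to_numpy() if len(events) else np.array([])
    for typ in ("ConvL", "ConvR", "ConjL", "ConjR"):
        col = np.zeros(n)
        sel = labels == typ
        if sel.any():
            col[_nearest_frames(onset_t[sel], frame_t)] = 1.0
        cols.append(col)
        names.append(f"sacc_{typ}")
        groups.append("oculomotor")

    # --- oculomotor: rectified nasal eye positions
    for eye, sign in (("left", 1.0), ("right", -1.0)):
        p = sign * np.interp(frame_t, trace.t, trace.eye(eye))
        med = np.median(p)
        cols.append(np.where(p > med, p - med, 0.0))
        names.append(f"pos_nasal_{eye}")
        groups.append("oculomotor")

    # --- locomotor: direction x vigour quartile
    if len(swims):
        vig = swims["vigour"].to_numpy(dtype=float)
        q = np.nanpercentile(vig, [25, 50, 75])
        quartile = np.searchsorted(q, vig, side="right")  # 0..3
        swim_frames = _nearest_frames(swims["time_s"].to_numpy(dtype=float), frame_t)
        directions = swims["direction"].to_numpy()
    for d in ("left", "right"):
        for k in range(4):
            col = np.zeros(n)
            if len(swims):
                sel = (directions == d) & (quartile == k)
                col[swim_frames[sel]] = 1.0
            cols.append(col)
            names.append(f"swim_{d}_q{k + 1}")
            groups.append("locomotor")

    # --- stimulus: gratings
    gr = stimuli[stimuli["kind"] == "grating"] if len(stimuli) else stimuli
    for d, sign in (("left", -1), ("right", 1)):
        col = np.zeros(n)
        if len(gr):
            for _, row in gr[gr["direction"] == sign].iterrows():
                col[(frame_t >= row["start_s"]) & (frame_t < row["stop_s"])] = 1.0
        cols.append(col)
        names.append(f"grating_{d}")
        groups.append("stimulus")

    # --- stimulus: moving spots, 4 az bins x 2 directions x 2 contrasts
    sp = stimuli[stimuli["kind"] == "spot"] if len(stimuli) else stimuli
    spot_cols = {}
    for b in range(4):
        for d, dsign in (("L", -1), ("R", 1)):
            for cname, csign in (("cpos", 1), ("cneg", -1)):
                key = (b, dsign, csign)
                spot_cols[key] = np.zeros(n)
                names.append(f"spot_az{b}_dir{d}_{cname}")
                groups.append("stimulus")
    if len(sp):
        for _, row in sp.iterrows():
            sel = (frame_t >= row["start_s"]) & (frame_t < row["stop_s"])
            az = row["az_start_deg"] + row["az_speed_deg_s"] * (frame_t[sel] - row["start_s"])
            bins = np.clip(np.searchsorted(SPOT_AZ_EDGES, az, side="right") - 1, 0, 3)
            idx = np.flatnonzero(sel)
            for b in range(4):
                key = (b, int(row["direction"]), int(row["contrast"]))
                if key in spot_cols:
                    spot_cols[key][idx[bins == b]] = 1.0
    cols.extend(spot_cols.values())

    # --- convolve with CIRF, apply temporal offset
    kernel = cirf.kernel(rate)
    X = np.empty((n, 33))
    for j, col in enumerate(cols):
        conv = np.convolve(col, kernel)[:n]
        if offset_frames > 0:
            shifted = np.zeros(n)
            shifted[offset_frames:] = conv[: n - offset_frames]
            conv = shifted
        X[:, j] = conv

    # --- motion error, unconvolved
    motion = np.asarray(motion_error_um, dtype=float)
    if motion.shape != (n,):
        raise ValueError("motion_error_um must have one value per frame")
    X[:, 32] = motion
    names.append("motion_error")
    groups.append("motion")
    return DesignMatrix(
        X=X, names=names, groups=np.array(groups), cirf=cirf, offset_frames=offset_frames
    )


def build_design_grid(
    tau_offs=(3.0, 4.0, 5.0), offsets=(0, 1, 2, 3), tau_on: float = 0.2, **design_kw
) -> dict[tuple[float, int], DesignMatrix]:
    """All 12 hyperparameter combinations of the design matrix."""
    return {
        (tau, off): build_design(cirf=CIRF(tau_on, tau), offset_frames=off, **design_kw)
        for tau in tau_offs
        for off in offsets
    }


# ---------------------------------------------------------------------------
# OLS hyperparameter search


def _ols_r2(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """OLS R^2 with intercept for each row of Y (rank-deficiency tolerated)."""
    Xa = np.column_stack([np.ones(X.shape[0]), X])
    beta, *_ = np.linalg.lstsq(Xa, Y.T, rcond=None)
    resid = Y.T - Xa @ beta
    rss = (resid**2).sum(axis=0)
    tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - rss / tss
    return np.where(tss > 0, r2, 0.0)


def ols_hyperparam_search(
    zF: np.ndarray,
    designs: dict[tuple[float, int], DesignMatrix],
    r2_gate: float = 0.05,
) -> pd.DataFrame:
    """Exhaustive OLS search over (tau_off, offset) for one or many ROIs.

    Returns one row per ROI with the argmax-R^2 combination and the gate
    flag (best R^2 > ``r2_gate``).
    """
    Z = np.atleast_2d(np.asarray(zF, dtype=float))
    keys = list(designs.keys())
    r2 = np.column_stack([_ols_r2(Z, designs[k].X) for k in keys])  # (R, 12)
    best = np.argmax(r2, axis=1)
    rows = []
    for i, b in enumerate(best):
        tau, off = keys[b]
        rows.append(
            {
                "best_tau_off": tau,
                "best_offset": int(off),
                "ols_r2": float(r2[i, b]),
                "gate": bool(r2[i, b] > r2_gate),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# ridge regression with contiguous-block cross-validation


def _contiguous_folds(n: int, n_folds: int) -> list[np.ndarray]:
    return [np.asarray(f) for f in np.array_split(np.arange(n), n_folds)]


class _CVRidgeEngine:
    """Cached Gram matrices for repeated ridge CV on one (X, y) pair.

    Standardizes X globally and centres y; per-fold training Grams are
    obtained by subtracting the held-out block's contribution. Column
    replacement (for circular-permutation tests) is a rank-style update,
    so a full refit costs one tall matvec rather than a new Gram.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, folds: list[np.ndarray]):
        X = np.asarray(X, dtype=float)
        self.X_mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self.X_sd = np.where(sd > 0, sd, 1.0)
        self.Xs = (X - self.X_mean) / self.X_sd
        self.y_mean = float(np.mean(y))
        self.yc = np.asarray(y, dtype=float) - self.y_mean
        self.folds = folds
        self.G = self.Xs.T @ self.Xs
        self.b = self.Xs.T @ self.yc
        self.fold_G = [self.Xs[f].T @ self.Xs[f] for f in folds]
        self.fold_b = [self.Xs[f].T @ self.yc[f] for f in folds]
        self.ss_tot = float(self.yc @ self.yc)

    def _cv_r2_core(self, G, b, fold_G, fold_b, fold_X, lam: float) -> float:
        p = self.Xs.shape[1]
        eye = lam * np.eye(p)
        ss_res = 0.0
        for k, f in enumerate(self.folds):
            beta = np.linalg.solve(G - fold_G[k] + eye, b - fold_b[k])
            pred = fold_X[k] @ beta
            ss_res += float(((self.yc[f] - pred) ** 2).sum())
        return 1.0 - ss_res / self.ss_tot if self.ss_tot > 0 else 0.0

    def cv_r2(self, lam: float) -> float:
        return self._cv_r2_core(
            self.G, self.b, self.fold_G, self.fold_b, [self.Xs[f] for f in self.folds], lam
        )

    def cv_r2_perm(self, j: int, shifted_col_std: np.ndarray, lam: float) -> float:
        """cvR^2 with standardized column j replaced by a circular shift."""
        xp = shifted_col_std
        G = self.G.copy()
        v = self.Xs.T @ xp
        v[j] = xp @ xp
        G[j, :] = v
        G[:, j] = v
        b = self.b.copy()
        b[j] = xp @ self.yc
        fold_G, fold_b, fold_X = [], [], []
        for k, f in enumerate(self.folds):
            Xf = self.Xs[f].copy()
            Xf[:, j] = xp[f]
            vf = Xf.T @ xp[f]
            Gf = self.fold_G[k].copy()
            Gf[j, :] = vf
            Gf[:, j] = vf
            bf = self.fold_b[k].copy()
            bf[j] = xp[f] @ self.yc[f]
            fold_G.append(Gf)
            fold_b.append(bf)
            fold_X.append(Xf)
        return self._cv_r2_core(G, b, fold_G, fold_b, fold_X, lam)

    def fit(self, lam: float) -> np.ndarray:
        p = self.Xs.shape[1]
        return np.linalg.solve(self.G + lam * np.eye(p), self.b)


DEFAULT_LAMBDAS = np.logspace(-3, 3, 13)


@dataclass
class RidgeFit:
    """Ridge fit with CV-selected penalty (coefficients in standardized X space)."""

    lambda_: float
    cvR2: float
    coef: np.ndarray
    cv_curve: pd.DataFrame
    folds: list = field(repr=False, default_factory=list)
    X_mean: np.ndarray | None = field(repr=False, default=None)
    X_sd: np.ndarray | None = field(repr=False, default=None)
    y_mean: float = 0.0


def ridge_cv_fit(
    zF_roi: np.ndarray,
    X: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_folds: int = 10,
) -> RidgeFit:
    """Ridge regression with lambda chosen by 10-fold cross-validation.

    Folds are contiguous time blocks (to limit leakage through
    autocorrelation); lambda comes from a 13-point log grid on
    standardized regressors; cvR^2 is the pooled out-of-fold R^2 at the
    chosen lambda. Deterministic: the fold layout depends only on the
    number of frames.
    """
    lambdas = DEFAULT_LAMBDAS if lambdas is None else np.asarray(lambdas, dtype=float)
    y = np.asarray(zF_roi, dtype=float)
    folds = _contiguous_folds(len(y), n_folds)
    eng = _CVRidgeEngine(X, y, folds)
    scores = np.array([eng.cv_r2(lam) for lam in lambdas])
    best = int(np.argmax(scores))
    coef = eng.fit(float(lambdas[best]))
    return RidgeFit(
        lambda_=float(lambdas[best]),
        cvR2=float(scores[best]),
        coef=coef,
        cv_curve=pd.DataFrame({"lambda": lambdas, "cvR2": scores}),
        folds=folds,
        X_mean=eng.X_mean,
        X_sd=eng.X_sd,
        y_mean=eng.y_mean,
    )


def cv_r2(zF_roi: np.ndarray, X: np.ndarray, lam: float, folds: list[np.ndarray]) -> float:
    """Out-of-fold R^2 of a ridge model at a fixed lambda and fold layout."""
    eng = _CVRidgeEngine(X, np.asarray(zF_roi, dtype=float), folds)
    return eng.cv_r2(lam)


def delta_cvR2(
    zF_roi: np.ndarray,
    X: np.ndarray,
    fit: RidgeFit,
    rng: np.random.Generator,
    min_shift: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Unique-variance attribution by circular permutation.

    For each regressor: circularly shift it by a random offset at least
    ``min_shift`` frames away from zero (mod the recording length), refit
    with the *same* lambda and folds, and report delta cvR^2 = permuted
    cvR^2 - original cvR^2. Negative values mean the regressor carried
    variance no other regressor could absorb. Returns (deltas, shifts).
    """
    y = np.asarray(zF_roi, dtype=float)
    n, p = X.shape
    eng = _CVRidgeEngine(X, y, fit.folds)
    base = eng.cv_r2(fit.lambda_)
    deltas = np.empty(p)
    shifts = np.empty(p, dtype=int)
    for j in range(p):
        shift = int(rng.integers(min_shift, n - min_shift))
        shifts[j] = shift
        xp = np.roll(eng.Xs[:, j], shift)
        deltas[j] = eng.cv_r2_perm(j, xp, fit.lambda_) - base
    return deltas, shifts


# ---------------------------------------------------------------------------
# oculomotor-tuned classification


@dataclass
class RoiEncodingResult:
    """Full per-ROI encoding summary (d' triplet through tuned label)."""

    dprime: dict
    best_tau_off: float | None = None
    best_offset: int | None = None
    ols_r2: float | None = None
    ridge: RidgeFit | None = None
    delta_cvR2: np.ndarray | None = None
    perm_shifts: np.ndarray | None = None
    label: str = "none"


def classify_tuned(
    deltas: np.ndarray,
    groups: np.ndarray,
    active: dict[str, np.ndarray],
    dprime: dict[str, np.ndarray] | None = None,
    min_null: int = 50,
    percentile: float = 95.0,
    side: str = "signed",
) -> pd.DataFrame:
    """Label oculomotor-tuned ROIs from delta cvR^2 and d' flags.

    Null distribution: positive delta cvR^2 values pooled across all ROIs
    and regressors (random fit improvements), mirrored about zero so the
    95th percentile of the positives bounds chance-level |delta|. An ROI
    is oculomotor-tuned iff (i) its most negative delta belongs to an
    oculomotor regressor, (ii) at least one oculomotor delta is more
    negative than -P95, and (iii) the motion-error delta is less negative
    than -P95. Tuned ROIs are labelled Conv / LConj / RConj from their d'
    flags, or Both when convergent and either conjugate type are active.

    ``deltas`` is (n_rois, 33); rows of non-gated ROIs may be NaN and are
    labelled 'none'.
    """
    deltas = np.atleast_2d(np.asarray(deltas, dtype=float))
    groups = np.asarray(groups)
    gated = ~np.isnan(deltas).any(axis=1)
    pool = deltas[gated]
    pool = pool[pool > 0]
    if pool.size < min_null:
        raise ValueError(
            f"null pool has {pool.size} positive delta cvR^2 values; need >= {min_null}"
        )
    thr = float(np.percentile(pool, percentile))
    ocu = groups == "oculomotor"
    motion = groups == "motion"
    n = deltas.shape[0]
    crit1 = np.zeros(n, dtype=bool)
    crit2 = np.zeros(n, dtype=bool)
    crit3 = np.zeros(n, dtype=bool)
    use = np.where(np.isnan(deltas), np.inf, deltas)
    if side == "abs":
        mag = np.abs(np.where(np.isnan(deltas), 0, deltas))
        crit2[gated] = ((mag[:, ocu] > thr) & (np.where(np.isnan(deltas), 1, deltas)[:, ocu] < 0)).any(axis=1)[gated]
        crit3[gated] = ~((mag[gated][:, motion] > thr) & (deltas[gated][:, motion] < 0)).any(axis=1)
    else:
        crit2[gated] = (use[gated][:, ocu] < -thr).any(axis=1)
        crit3[gated] = ~(use[gated][:, motion] < -thr).any(axis=1)
    crit1[gated] = ocu[np.argmin(use[gated], axis=1)]
    tuned = crit1 & crit2 & crit3
    labels = np.full(n, "none", dtype=object)
    conv = np.asarray(active.get("Conv", np.zeros(n, bool)))
    lconj = np.asarray(active.get("LConj", np.zeros(n, bool)))
    rconj = np.asarray(active.get("RConj", np.zeros(n, bool)))
    for i in np.flatnonzero(tuned):
        if conv[i] and (lconj[i] or rconj[i]):
            labels[i] = "Both"
        elif conv[i]:
            labels[i] = "Conv"
        elif lconj[i] and rconj[i]:
            if dprime is not None:
                labels[i] = "LConj" if dprime["LConj"][i] >= dprime["RConj"][i] else "RConj"
            else:
                labels[i] = "LConj"
        elif lconj[i]:
            labels[i] = "LConj"
        elif rconj[i]:
            labels[i] = "RConj"
    return pd.DataFrame(
        {
            "tuned": tuned & (labels != "none"),
            "label": labels,
            "crit_most_negative_oculomotor": crit1,
            "crit_oculomotor_significant": crit2,
            "crit_motion_not_significant": crit3,
            "null_p95": thr,
        }
    )
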