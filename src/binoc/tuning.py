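"""Per-ROI functional tuning metrics.

Built on the normalized saccade-triggered fluorescence (STF): the change
in zF around each saccade (2 s post-onset sum, baselined by the mean over
the 1 s pre window), normalized per ROI by the 95th percentile across
saccades. From the STF come rectilinear eye-position tuning fits, the
saccade-type index (median STF difference between kinematically matched
convergent/conjugate saccade pairs), OKR power (spectral power of the
direction-differential median response at the grating alternation
frequency), the PC1 score summarizing (saccade-type index, OKR power),
and the directionality preference that routes each ROI's analyses to the
appropriate eye.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "normalized_stf",
    "RectilinearFit",
    "rectilinear_fit",
    "saccade_type_index",
    "okr_power",
    "pc1_score",
    "directionality_preference",
]


def normalized_stf(
    zF_roi: np.ndarray,
    onset_frames: np.ndarray,
    frame_rate_hz: float,
    pre_s: float = 1.0,
    post_s: float = 2.0,
) -> tuple[np.ndarray, bool]:
    """Per-saccade normalized saccade-triggered fluorescence.

    For each saccade: subtract the mean zF over the 1 s pre-onset window,
    sum zF over the 2 s window from onset, then divide the resulting
    values by their 95th percentile across all saccades of this ROI.
    Returns (values, flag); the flag marks ROIs whose 95th percentile was
    non-positive (normalized by its absolute value instead, so the soft
    upper bound of ~1 no longer holds).
    """
    z = np.asarray(zF_roi, dtype=float)
    o = np.asarray(onset_frames, dtype=int)
    n_pre = max(1, int(round(pre_s * frame_rate_hz)))
    n_post = max(1, int(round(post_s * frame_rate_hz)))
    if len(o) < 5:
        raise ValueError("need at least 5 saccades for normalized STF")
    vals = np.full(len(o), np.nan)
    for i, f in enumerate(o):
        if f - n_pre < 0 or f + n_post > len(z):
            continue
        base = z[f - n_pre : f].mean()
        vals[i] = (z[f : f + n_post] - base).sum()
    p95 = np.nanpercentile(vals, 95)
    flag = False
    if p95 <= 0:
        flag = True
        p95 = abs(p95) if p95 != 0 else 1.0
    return vals / p95, flag


@dataclass
class RectilinearFit:
    """Baseline-plus-ramp tuning fit over normalized eye position."""

    baseline: float
    breakpoint: float | None
    slope: float | None
    mse: float
    r2: float
    ramp_accepted: bool
    flag: str = ""


def rectilinear_fit(
    positions_norm: np.ndarray,
    stf_values: np.ndarray,
    n_grid: int = 41,
    accept_factor: float = 2.0,
) -> RectilinearFit:
    """Fit a horizontal baseline plus optional linear ramp.

    Candidate breakpoints are 41 evenly spaced positions across the
    observed range. For each candidate the baseline is the median of the
    values at or below it and the ramp is the least-squares slope of the
    remainder (anchored at the baseline level). The minimum-MSE candidate
    is selected, and the ramp is accepted only when its fitted excursion
    exceeds ``accept_factor`` times the RMSE of the baseline-only fit;
    otherwise only a baseline is returned. The selected model's MSE never
    exceeds the baseline-only MSE.
    """
    x = np.asarray(positions_norm, dtype=float)
    y = np.asarray(stf_values, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 10:
        raise ValueError("need at least 10 (position, value) pairs")
    b0 = float(np.median(y))
    mse0 = float(np.mean((y - b0) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    if np.ptp(x) == 0:
        return RectilinearFit(b0, None, None, mse0, 0.0, False, flag="degenerate_positions")
    grid = np.linspace(x.min(), x.max(), n_grid)
    best = (mse0, None, None)  # (mse, breakpoint, slope)
    for c in grid:
        base_sel = x <= c
        ramp_sel = ~base_sel
        if base_sel.sum() < 2 or ramp_sel.sum() < 2:
            continue
        b = float(np.median(y[base_sel]))
        dx = x[ramp_sel] - c
        s = float(np.sum((y[ramp_sel] - b) * dx) / np.sum(dx * dx))
        resid = np.where(base_sel, y - b, y - (b + s * (x - c)))
        mse = float(np.mean(resid**2))
        if mse < best[0]:
            best = (mse, float(c), s, b)
    if best[1] is None:
        r2 = 1.0 - mse0 * len(y) / tss if tss > 0 else 0.0
        return RectilinearFit(b0, None, None, mse0, r2, False)
    mse, c, s, b = best
    excursion = abs(s * (x.max() - c))
    rmse0 = np.sqrt(mse0)
    if excursion > accept_factor * rmse0:
        r2 = 1.0 - mse * len(y) / tss if tss > 0 else 0.0
        return RectilinearFit(b, c, s, mse, r2, True)
    r2 = 1.0 - mse0 * len(y) / tss if tss > 0 else 0.0
    return RectilinearFit(b0, None, None, mse0, r2, False)


def saccade_type_index(
    conj: pd.DataFrame,
    conv: pd.DataFrame,
    radius: float = 0.1,
    with_replacement: bool = True,
) -> tuple[float, int]:
    """Median STF difference between kinematically matched saccade pairs.

    Both frames need columns ``pos_norm``, ``vel_norm`` and ``stf``
    (normalized post-saccadic position, normalized peak velocity,
    normalized saccade-triggered fluorescence). For each conjugate
    adducting saccade, the nearest convergent saccade within Euclidean
    ``radius`` in (pos_norm, vel_norm) space is its match; by default a
    convergent saccade may serve several conjugates. The index is the
    median of (convergent - conjugate) STF over matched pairs — positive
    means a larger calcium response for convergent saccades. Returns
    (index, n_pairs); the index is NaN when no pair matches.
    """
    if not len(conj) or not len(conv):
        return np.nan, 0
    cj = conj[["pos_norm", "vel_norm"]].to_numpy(dtype=float)
    cv = conv[["pos_norm", "vel_norm"]].to_numpy(dtype=float)
    stf_cj = conj["stf"].to_numpy(dtype=float)
    stf_cv = conv["stf"].to_numpy(dtype=float)
    available = np.ones(len(cv), dtype=bool)
    diffs = []
    for i in range(len(cj)):
        d = np.sqrt(((cv - cj[i]) ** 2).sum(axis=1))
        if not with_replacement:
            d = np.where(available, d, np.inf)
        j = int(np.argmin(d))
        if d[j] < radius:
            diffs.append(stf_cv[j] - stf_cj[i])
            if not with_replacement:
                available[j] = False
    if not diffs:
        return np.nan, 0
    return float(np.median(diffs)), len(diffs)


def okr_power(
    zF_roi: np.ndarray,
    grating_epochs: pd.DataFrame,
    frame_t: np.ndarray,
    min_presentations: int = 3,
) -> float:
    """Spectral power of the direction-differential OKR response.

    The median zF response across presentations of each grating direction
    is computed on a common per-epoch frame grid; their difference
    isolates direction-selective modulation. One full alternation cycle
    (leftward median followed by rightward median) is Fourier transformed
    and the one-sided power spectral density is read at the bin of the
    alternation frequency 1 / (2 T_epoch). Invariant to any DC offset of
    zF. Requires the epoch durations to define the alternation frequency.
    """
    z = np.asarray(zF_roi, dtype=float)
    gr = grating_epochs[grating_epochs["kind"] == "grating"] if "kind" in grating_epochs else grating_epochs
    if not len(gr):
        raise ValueError("no grating epochs: alternation frequency unknown")
    durations = (gr["stop_s"] - gr["start_s"]).to_numpy(dtype=float)
    t_epoch = float(np.median(durations))
    if t_epoch <= 0:
        raise ValueError("grating epochs have non-positive duration")
    frame_rate = 1.0 / float(np.median(np.diff(frame_t)))
    n_ep = int(round(t_epoch * frame_rate))
    med = {}
    for direction in (-1, 1):
        segs = []
        for _, row in gr[gr["direction"] == direction].iterrows():
            i0 = int(np.searchsorted(frame_t, row["start_s"]))
            if i0 + n_ep <= len(z):
                segs.append(z[i0 : i0 + n_ep])
        if len(segs) < min_presentations:
            raise ValueError(
                f"need >= {min_presentations} presentations per direction, got {len(segs)}"
            )
        med[direction] = np.median(np.vstack(segs), axis=0)
    cycle = np.concatenate([med[-1], med[1]])  # one full alternation period
    n = len(cycle)
    spec = np.fft.rfft(cycle)
    # one-sided PSD at the alternation frequency (bin 1 of the 2T window)
    psd = (2.0 / (frame_rate * n)) * np.abs(spec) ** 2
    return float(psd[1])


def pc1_score(
    sti: np.ndarray, okr: np.ndarray, min_rois: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """First-principal-component summary of (saccade-type index, OKR power).

    Both metrics are standardized across ROIs; the score is the projection
    onto the first principal component with its sign oriented so the
    saccade-type index loads positively. ROIs missing either metric get
    NaN scores. Returns (scores, loadings, explained_variance_ratio).
    Scores have zero mean across the used ROIs by construction.
    """
    sti = np.asarray(sti, dtype=float)
    okr = np.asarray(okr, dtype=float)
    ok = np.isfinite(sti) & np.isfinite(okr)
    if ok.sum() < min_rois:
        raise ValueError(f"need >= {min_rois} ROIs with both metrics, got {int(ok.sum())}")
    Z = np.column_stack([sti[ok], okr[ok]])
    Z = (Z - Z.mean(axis=0)) / np.where(Z.std(axis=0) > 0, Z.std(axis=0), 1.0)
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt[0]
    if loadings[0] < 0:
        loadings = -loadings
    scores = np.full(len(sti), np.nan)
    scores[ok] = Z @ loadings
    evr = float(s[0] ** 2 / (s**2).sum())
    return scores, loadings, evr


def directionality_preference(delta_by_name: dict) -> tuple[str, bool]:
    """Left/right eye-movement preference from delta cvR^2 sums.

    Leftward components: LConj and ConvL saccade onsets and right-eye
    nasal position; rightward: RConj, ConvR and left-eye nasal position.
    The more negative sum wins. For leftward-preferring ROIs the
    saccade-type index and nasal ramp fits are computed on the right eye
    (temporal fits on the left eye); reversed for rightward. Exact ties
    default to leftward with a flag. Returns (preference, tie_flag).
    """
    left_sum = (
        delta_by_name["sacc_ConjL"]
        + delta_by_name["sacc_ConvL"]
        + delta_by_name["pos_nasal_right"]
    )
    right_sum = (
        delta_by_name["sacc_ConjR"]
        + delta_by_name["sacc_ConvR"]
        + delta_by_name["pos_nasal_left"]
    )
    if left_sum == right_sum:
        return "left", True
    return ("left", False) if left_sum < right_sum else ("right", False)
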