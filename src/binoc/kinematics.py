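"""Saccade detection and per-event kinematics from binocular eye traces.

The detection stage works on a 100 Hz resampled, 1 Hz low-pass filtered
position trace: rapid eye movements appear as peaks in the convolution of
position with an antisymmetric step kernel (width 160 ms), which
approximates the local displacement. Candidate events of the two eyes are
paired within 100 ms and a 300 ms refractory rule discards events that
follow too closely after a retained one.

Onset refinement and all position/velocity measures use a 500 Hz resampled
trace smoothed with a guarded LOWESS: samples where the displacement
convolution exceeds a guard threshold (putative saccades) are left
unsmoothed so that saccadic steps are not flattened.

Sign convention
---------------
Positive position means rightward rotation for *both* eyes in a shared
head-fixed frame. Nasal (adducting) rotation is therefore positive for the
left eye and negative for the right eye. Vergence is reported as
``left - right`` of the median post-saccadic positions, which is positive
for convergent events and zero for symmetric conjugate events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "EyeTrace",
    "EyeMeasures",
    "SaccadeEvent",
    "DetectionConfig",
    "detect_coarse",
    "pair_and_refractory",
    "refine_onset",
    "compute_measures",
    "nine_metrics",
    "METRIC_NAMES",
    "normalize_metrics",
    "detect_saccades",
]

#: Column order of the nine-metric descriptor of a binocular event.
METRIC_NAMES = (
    "amp_left",
    "amp_right",
    "maxmed_left",
    "maxmed_right",
    "vel_cw_left",
    "vel_ccw_left",
    "vel_cw_right",
    "vel_ccw_right",
    "vergence",
)


@dataclass
class EyeTrace:
    """Timestamped binocular horizontal eye positions (degrees).

    ``t`` must be strictly increasing. NaN samples are linearly
    interpolated at construction time so downstream filters never see
    missing data.
    """

    t: np.ndarray
    left: np.ndarray
    right: np.ndarray
    convention: str = "right-positive"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.t.ndim != 1 or len(self.t) != len(self.left) or len(self.t) != len(self.right):
            raise ValueError("t, left and right must be 1-D arrays of equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("time base must be strictly increasing")
        for name in ("left", "right"):
            x = getattr(self, name)
            if np.any(~np.isfinite(x)):
                good = np.isfinite(x)
                if not good.any():
                    raise ValueError(f"{name} eye trace contains no finite samples")
                setattr(self, name, np.interp(self.t, self.t[good], x[good]))

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def eye(self, which: str) -> np.ndarray:
        if which not in ("left", "right"):
            raise ValueError("eye must be 'left' or 'right'")
        return getattr(self, which)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "left_deg": self.left, "right_deg": self.right})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, convention: str = "right-positive") -> "EyeTrace":
        return cls(
            t=df["t_s"].to_numpy(),
            left=df["left_deg"].to_numpy(),
            right=df["right_deg"].to_numpy(),
            convention=convention,
        )


@dataclass
class DetectionConfig:
    """Tunable parameters of the detection/refinement stage.

    All widths and windows are seconds; thresholds are degrees.
    """

    coarse_rate_hz: float = 100.0
    lowpass_hz: float = 1.0
    coarse_kernel_s: float = 0.160
    min_displacement_deg: float = 1.5  # coarse threshold, displacement-equivalent
    pair_window_s: float = 0.100
    refractory_s: float = 0.300
    fine_rate_hz: float = 500.0
    lowess_span_s: float = 0.080
    guard_threshold_deg: float = 3.0
    guard_kernel_s: float = 0.160
    onset_kernel_wide_s: float = 0.100
    onset_kernel_narrow_s: float = 0.040
    onset_window_s: float = 0.400
    onset_rel_threshold: float = 0.10  # fraction of window max of the conv product
    onset_floor_deg2: float = 0.25  # absolute floor on the conv product (deg^2)
    pre_window_s: float = 0.200
    post_window_s: float = 0.200
    vel_window_s: float = 0.150
    all_peaks: bool = False  # keep every local max of |conv| regardless of height


# ---------------------------------------------------------------------------
# coarse detection


def _displacement_kernel(width_s: float, rate_hz: float) -> np.ndarray:
    """Antisymmetric difference-of-means step kernel.

    Convolving position with this kernel yields ``mean(next half) -
    mean(previous half)``, i.e. a local displacement estimate whose response
    to an ideal step of amplitude A is exactly A.
    """
    half = max(1, int(round(width_s * rate_hz / 2)))
    k = np.concatenate([np.full(half, 1.0 / half), np.full(half, -1.0 / half)])
    return k


def _resample(trace: EyeTrace, rate_hz: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    tq = np.arange(trace.t[0], trace.t[-1], 1.0 / rate_hz)
    return tq, np.interp(tq, trace.t, trace.left), np.interp(tq, trace.t, trace.right)


def _lowpass(x: np.ndarray, rate_hz: float, cutoff_hz: float) -> np.ndarray:
    sos = signal.butter(2, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, x)


def _step_response_gain(cfg: DetectionConfig) -> float:
    """Peak response of lowpass+kernel chain to a unit position step.

    Used to express the coarse threshold in displacement-equivalent degrees
    regardless of how much the 1 Hz low-pass smears the step.
    """
    rate = cfg.coarse_rate_hz
    n = int(rate * 6)
    x = np.zeros(n)
    x[n // 2 :] = 1.0
    xf = _lowpass(x, rate, cfg.lowpass_hz)
    conv = np.convolve(xf, _displacement_kernel(cfg.coarse_kernel_s, rate), mode="same")
    # ignore the boundary region where the kernel hangs off the array
    margin = len(_displacement_kernel(cfg.coarse_kernel_s, rate))
    return float(np.max(np.abs(conv[margin:-margin])))


def detect_coarse(trace: EyeTrace, cfg: DetectionConfig | None = None) -> dict[str, np.ndarray]:
    """Detect per-eye candidate rapid-eye-movement events.

    Returns a dict mapping eye name to an array of coarse peak times
    (seconds). Peaks are maxima of the absolute displacement convolution of
    the 100 Hz, 1 Hz low-passed trace.
    """
    cfg = cfg or DetectionConfig()
    if trace.duration < 1.0:
        raise ValueError("trace must span at least 1 s")
    tq, left, right = _resample(trace, cfg.coarse_rate_hz)
    kernel = _displacement_kernel(cfg.coarse_kernel_s, cfg.coarse_rate_hz)
    height = None if cfg.all_peaks else cfg.min_displacement_deg * _step_response_gain(cfg)
    min_dist = max(1, int(round(0.1 * cfg.coarse_rate_hz)))
    out: dict[str, np.ndarray] = {}
    margin = len(kernel)
    for name, x in (("left", left), ("right", right)):
        xf = _lowpass(x, cfg.coarse_rate_hz, cfg.lowpass_hz)
        conv = np.abs(np.convolve(xf, kernel, mode="same"))
        conv[:margin] = 0.0  # boundary artifacts of the 'same' convolution
        conv[-margin:] = 0.0
        peaks, _ = signal.find_peaks(conv, height=height, distance=min_dist)
        out[name] = tq[peaks]
    return out


# ---------------------------------------------------------------------------
# pairing and refractory rule


@dataclass
class _Candidate:
    """A coarse binocular (or monocular) candidate prior to refinement."""

    t_left: float | None
    t_right: float | None

    @property
    def time(self) -> float:
        times = [t for t in (self.t_left, self.t_right) if t is not None]
        return min(times)

    @property
    def binocular(self) -> bool:
        return self.t_left is not None and self.t_right is not None


def pair_and_refractory(
    events_left: Sequence[float],
    events_right: Sequence[float],
    pair_window_s: float = 0.100,
    refractory_s: float = 0.300,
) -> list[_Candidate]:
    """Pair per-eye events within 100 ms, then apply the 300 ms refractory rule.

    Pairing is greedy in chronological order with the nearest-in-time
    partner winning; after pairing, any event starting within the
    refractory interval of the previously retained event is discarded
    (earliest event wins the conflict).
    """
    left = sorted(float(t) for t in events_left)
    right = sorted(float(t) for t in events_right)
    used_r = np.zeros(len(right), dtype=bool)
    candidates: list[_Candidate] = []
    for tl in left:
        best_j, best_d = -1, pair_window_s
        for j, tr in enumerate(right):
            if used_r[j]:
                continue
            d = abs(tr - tl)
            if d <= best_d:
                best_j, best_d = j, d
        if best_j >= 0:
            used_r[best_j] = True
            candidates.append(_Candidate(t_left=tl, t_right=right[best_j]))
        else:
            candidates.append(_Candidate(t_left=tl, t_right=None))
    for j, tr in enumerate(right):
        if not used_r[j]:
            candidates.append(_Candidate(t_left=None, t_right=tr))
    candidates.sort(key=lambda c: c.time)
    retained: list[_Candidate] = []
    for c in candidates:
        if retained and (c.time - retained[-1].time) < refractory_s:
            continue
        retained.append(c)
    return retained


# ---------------------------------------------------------------------------
# guarded LOWESS smoothing and onset refinement


def _guarded_lowess(tq: np.ndarray, x: np.ndarray, cfg: DetectionConfig) -> np.ndarray:
    """LOWESS smoothing everywhere except inside putative saccades.

    Samples where the displacement convolution of the raw trace exceeds the
    guard threshold are returned unsmoothed, so rapid position steps keep
    their true slope.
    """
    span = max(tq[-1] - tq[0], 1e-9)
    frac = min(1.0, cfg.lowess_span_s / span)
    sm = _sm_lowess(x, tq, frac=frac, it=0, delta=0.5 / cfg.fine_rate_hz, return_sorted=False)
    conv = np.convolve(x, _displacement_kernel(cfg.guard_kernel_s, cfg.fine_rate_hz), mode="same")
    guard = np.abs(conv) > cfg.guard_threshold_deg
    out = np.where(guard, x, sm)
    return out


def _fine_segment(
    trace: EyeTrace, center_s: float, half_width_s: float, cfg: DetectionConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """500 Hz resampled, guard-smoothed segment around ``center_s``."""
    t0 = max(trace.t[0], center_s - half_width_s)
    t1 = min(trace.t[-1], center_s + half_width_s)
    tq = np.arange(t0, t1, 1.0 / cfg.fine_rate_hz)
    if len(tq) < 10:
        raise ValueError("segment too short for refinement")
    left = _guarded_lowess(tq, np.interp(tq, trace.t, trace.left), cfg)
    right = _guarded_lowess(tq, np.interp(tq, trace.t, trace.right), cfg)
    return tq, left, right


def _refine_onset_on_segment(
    tq: np.ndarray, x: np.ndarray, coarse_peak_s: float, cfg: DetectionConfig
) -> float | None:
    wide = np.convolve(x, _displacement_kernel(cfg.onset_kernel_wide_s, cfg.fine_rate_hz), mode="same")
    narrow = np.convolve(
        x, _displacement_kernel(cfg.onset_kernel_narrow_s, cfg.fine_rate_hz), mode="same"
    )
    prod = wide * narrow
    half = cfg.onset_window_s / 2
    sel = (tq >= coarse_peak_s - half) & (tq <= coarse_peak_s + half)
    if not sel.any():
        return None
    pw = prod[sel]
    thr = max(cfg.onset_rel_threshold * float(pw.max(initial=0.0)), cfg.onset_floor_deg2)
    above = pw >= thr
    if not above.any():
        return None
    return float(tq[sel][np.argmax(above)])


def refine_onset(
    trace: EyeTrace, coarse_peak_s: float, eye: str, cfg: DetectionConfig | None = None
) -> float | None:
    """Refined saccade onset for one eye, or None if no threshold crossing.

    The onset is the first time inside a 400 ms window centred on the
    coarse peak where the product of the 100 ms and 40 ms displacement
    convolutions of the smoothed 500 Hz trace crosses threshold (10% of the
    window maximum, with an absolute floor so pure-noise windows reject).
    """
    cfg = cfg or DetectionConfig()
    margin = cfg.onset_window_s / 2 + cfg.onset_kernel_wide_s
    if coarse_peak_s - margin < trace.t[0] or coarse_peak_s + margin > trace.t[-1]:
        raise ValueError("refinement window exceeds trace bounds")
    tq, left, right = _fine_segment(trace, coarse_peak_s, 1.0, cfg)
    x = left if eye == "left" else right
    return _refine_onset_on_segment(tq, x, coarse_peak_s, cfg)


# ---------------------------------------------------------------------------
# per-event measures


@dataclass
class EyeMeasures:
    """Per-eye position and velocity measures of one rapid eye movement."""

    pre_pos: float
    max_post_pos: float
    med_post_pos: float
    vel_cw: float
    vel_ccw: float

    @property
    def amplitude(self) -> float:
        return self.med_post_pos - self.pre_pos

    @property
    def maxmed(self) -> float:
        return self.max_post_pos - self.med_post_pos


def _measures_on_segment(
    tq: np.ndarray, x: np.ndarray, onset_s: float, cfg: DetectionConfig
) -> EyeMeasures:
    dt = 1.0 / cfg.fine_rate_hz
    i0 = int(round((onset_s - tq[0]) * cfg.fine_rate_hz))  # robust to float grid jitter
    i0 = max(0, min(i0, len(tq) - 1))
    n_pre = int(round(cfg.pre_window_s * cfg.fine_rate_hz))
    n_post = int(round(cfg.post_window_s * cfg.fine_rate_hz))
    n_vel = int(round(cfg.vel_window_s * cfg.fine_rate_hz / 2))
    if i0 - n_pre < 0 or i0 + 2 * n_post > len(tq) or i0 - n_vel < 0:
        raise ValueError("measure window truncated at trace edge")
    pre = float(np.median(x[i0 - n_pre : i0]))
    post = x[i0 : i0 + n_post]
    onset_pos = x[i0]
    i_max = int(np.argmax(np.abs(post - onset_pos)))
    max_post = float(post[i_max])
    med_post = float(np.median(x[i0 + i_max : i0 + i_max + n_post]))
    vel = np.gradient(x, dt)
    vwin = vel[i0 - n_vel : i0 + n_vel + 1]
    return EyeMeasures(
        pre_pos=pre,
        max_post_pos=max_post,
        med_post_pos=med_post,
        vel_cw=float(vwin.max()),
        vel_ccw=float(vwin.min()),
    )


def compute_measures(
    trace: EyeTrace, onset_s: float, eye: str, cfg: DetectionConfig | None = None
) -> EyeMeasures:
    """Position/velocity measures around a refined onset for one eye.

    pre-saccadic position: median over 200 ms before onset. Max
    post-saccadic position: sample within 200 ms after onset deviating most
    from the onset position. Median post-saccadic position: median over
    200 ms starting at that sample. cw/ccw velocity: max/min of the central
    time-derivative of the smoothed 500 Hz trace over 150 ms centred on
    onset.
    """
    cfg = cfg or DetectionConfig()
    tq, left, right = _fine_segment(trace, onset_s, 1.0, cfg)
    x = left if eye == "left" else right
    return _measures_on_segment(tq, x, onset_s, cfg)


@dataclass
class SaccadeEvent:
    """One (possibly binocular) rapid eye movement with refined measures."""

    coarse_peak_s: float
    onset_left_s: float | None = None
    onset_right_s: float | None = None
    left: EyeMeasures | None = None
    right: EyeMeasures | None = None
    label: str = "unclassified"
    flags: list[str] = field(default_factory=list)

    @property
    def binocular(self) -> bool:
        return self.left is not None and self.right is not None

    @property
    def onset_s(self) -> float:
        times = [t for t in (self.onset_left_s, self.onset_right_s) if t is not None]
        return min(times)


def nine_metrics(event: SaccadeEvent) -> np.ndarray:
    """Nine-metric descriptor of a binocular event (see ``METRIC_NAMES``).

    Vergence = left minus right median post-saccadic position in the shared
    rightward-positive frame (equivalently the sum of the two per-eye nasal
    positions): +16 deg for a symmetric 8-deg-per-eye convergence, 0 for a
    symmetric conjugate saccade. Monocular events return NaN in the slots
    of the absent eye.
    """
    out = np.full(9, np.nan)
    if event.left is not None:
        out[0] = event.left.amplitude
        out[2] = event.left.maxmed
        out[4] = event.left.vel_cw
        out[5] = event.left.vel_ccw
    if event.right is not None:
        out[1] = event.right.amplitude
        out[3] = event.right.maxmed
        out[6] = event.right.vel_cw
        out[7] = event.right.vel_ccw
    if event.binocular:
        out[8] = event.left.med_post_pos - event.right.med_post_pos
    return out


def normalize_metrics(
    metrics: np.ndarray,
    animal_ids: Sequence | None = None,
    lower_pct: float = 0.5,
    upper_pct: float = 99.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Winsorize each metric to [P0.5, P99.5] per animal, then z-score.

    Returns ``(normalized, zero_variance_flags)`` where the flags mark
    (animal, metric) groups whose winsorized values had zero variance and
    were set to all zeros.
    """
    M = np.asarray(metrics, dtype=float)
    if M.ndim != 2:
        raise ValueError("metrics must be 2-D (events x metrics)")
    if animal_ids is None:
        animal_ids = np.zeros(len(M), dtype=int)
    animal_ids = np.asarray(animal_ids)
    out = np.empty_like(M)
    flags = []
    for animal in np.unique(animal_ids):
        sel = animal_ids == animal
        if sel.sum() < 2:
            raise ValueError("need at least 2 events per animal to normalize")
        block = M[sel]
        for j in range(block.shape[1]):
            col = block[:, j]
            finite = np.isfinite(col)
            if finite.sum() < 2:
                out[sel, j] = 0.0
                flags.append((animal, j))
                continue
            lo, hi = np.nanpercentile(col, [lower_pct, upper_pct])
            w = np.clip(col, lo, hi)
            sd = np.nanstd(w)
            if sd == 0 or not np.isfinite(sd):
                out[sel, j] = 0.0
                flags.append((animal, j))
            else:
                out[sel, j] = (w - np.nanmean(w)) / sd
    return out, np.array(flags, dtype=object)


# ---------------------------------------------------------------------------
# full detection pipeline


def detect_saccades(trace: EyeTrace, cfg: DetectionConfig | None = None) -> pd.DataFrame:
    """Run coarse detection, pairing, refinement and measures end to end.

    Returns one row per retained event with per-eye onsets, all measures,
    the nine metrics and a ``binocular`` flag. Events whose onset could not
    be refined on any eye, or whose measure windows fall off the trace, are
    dropped.
    """
    cfg = cfg or DetectionConfig()
    coarse = detect_coarse(trace, cfg)
    candidates = pair_and_refractory(
        coarse["left"], coarse["right"], cfg.pair_window_s, cfg.refractory_s
    )
    rows = []
    for cand in candidates:
        event = SaccadeEvent(coarse_peak_s=cand.time)
        try:
            tq, left, right = _fine_segment(trace, cand.time, 1.2, cfg)
        except ValueError:
            continue
        for eye, t_coarse in (("left", cand.t_left), ("right", cand.t_right)):
            if t_coarse is None:
                continue
            x = left if eye == "left" else right
            half = cfg.onset_window_s / 2 + cfg.onset_kernel_wide_s
            if t_coarse - half < tq[0] or t_coarse + half > tq[-1]:
                continue
            onset = _refine_onset_on_segment(tq, x, t_coarse, cfg)
            if onset is None:
                continue
            try:
                m = _measures_on_segment(tq, x, onset, cfg)
            except ValueError:
                event.flags.append(f"{eye}_window_truncated")
                continue
            if eye == "left":
                event.onset_left_s, event.left = onset, m
            else:
                event.onset_right_s, event.right = onset, m
        if event.left is None and event.right is None:
            continue
        m9 = nine_metrics(event)
        row = {
            "coarse_peak_s": event.coarse_peak_s,
            "onset_s": event.onset_s,
            "onset_left_s": event.onset_left_s,
            "onset_right_s": event.onset_right_s,
            "binocular": event.binocular,
            "label": event.label,
        }
        for eye in ("left", "right"):
            m = getattr(event, eye)
            if m is None:
                row.update(
                    {
                        f"pre_pos_{eye}": np.nan,
                        f"max_post_pos_{eye}": np.nan,
                        f"med_post_pos_{eye}": np.nan,
                        f"vel_cw_{eye}": np.nan,
                        f"vel_ccw_{eye}": np.nan,
                    }
                )
            else:
                row.update(
                    {
                        f"pre_pos_{eye}": m.pre_pos,
                        f"max_post_pos_{eye}": m.max_post_pos,
                        f"med_post_pos_{eye}": m.med_post_pos,
                        f"vel_cw_{eye}": m.vel_cw,
                        f"vel_ccw_{eye}": m.vel_ccw,
                    }
                )
        row.update(dict(zip(METRIC_NAMES, m9)))
        rows.append(row)
    return pd.DataFrame(rows)
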