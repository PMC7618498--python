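"""Synthetic session generator with recorded ground truth.

Generates everything the analysis pipeline consumes: binocular eye traces
containing conjugate and convergent saccades (obeying type-specific
exponential velocity main sequences), optokinetic slow phases with reset
saccades, swim-bout and visual-stimulus logs, and per-ROI fluorescence
matrices built by inverting the encoding model (ground-truth-weighted sums
of CIRF-convolved regressors plus noise and motion artifacts).

Saccade waveform: a minimum-jerk position step ``A * (10 s^3 - 15 s^4 +
6 s^5)`` whose duration is set so the analytic peak velocity ``1.875 A / T``
equals the main-sequence value ``Vmax (1 - exp(-A / A0))`` for the event's
type. Convergent events optionally relax back toward rest with a slow
exponential (vergence is transient in freely behaving animals); the
relaxation velocity is far below detection threshold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .encoding import CIRF, build_design, DesignMatrix
from .kinematics import EyeTrace, METRIC_NAMES, normalize_metrics

__all__ = [
    "SessionConfig",
    "SaccadePlan",
    "OkrEpoch",
    "SpotEpoch",
    "SwimBout",
    "Schedule",
    "GroundTruth",
    "SyntheticSession",
    "generate_eye_traces",
    "generate_motion_error",
    "generate_calcium",
    "sample_metrics9",
    "generate_reference_set",
    "make_saccade_schedule",
    "make_session_schedule",
    "simulate_session",
    "ROI_CLASSES",
    "DEFAULT_MAIN_SEQUENCE",
    "DEFAULT_CLASS_WEIGHTS",
]

SACCADE_TYPES = ("ConvL", "ConvR", "ConjL", "ConjR")

#: (Vmax deg/s, A0 deg) per type. Conjugate saccades saturate near 700 deg/s;
#: convergent saccades saturate weakly so velocity keeps scaling with
#: amplitude over the behavioural range. Config, not a claim about any fish.
DEFAULT_MAIN_SEQUENCE = {
    "ConjL": (700.0, 6.0),
    "ConjR": (700.0, 6.0),
    "ConvL": (1600.0, 25.0),
    "ConvR": (1600.0, 25.0),
}

ROI_CLASSES = (
    "mrmn_both",
    "mrmn_conv",
    "inn_like",
    "lrmn_like",
    "locomotor",
    "motion_artifact",
    "silent",
)

#: Per-class true effect sizes, expressed per unit SD of the (convolved)
#: design column and in units of the calcium noise SD. Converted to raw
#: column weights at generation time.
DEFAULT_CLASS_WEIGHTS: dict[str, dict[str, float]] = {
    "mrmn_both": {"sacc_ConvL": 2.0, "sacc_ConvR": 2.0, "sacc_ConjR": 2.5, "pos_nasal_left": 1.0},
    "mrmn_conv": {"sacc_ConvL": 2.5, "sacc_ConvR": 2.5, "pos_nasal_left": 0.5},
    "inn_like": {"sacc_ConjR": 3.0, "pos_nasal_left": 1.0},
    "lrmn_like": {"sacc_ConjL": 3.0, "pos_nasal_right": 1.0},
    "locomotor": {"swim_right_q4": 3.0, "swim_right_q3": 2.0},
    "motion_artifact": {"motion_error": 3.0},
    "silent": {},
}

ORBITAL_RANGE_DEG = 35.0


@dataclass
class SessionConfig:
    """Study conditions for one synthetic session."""

    duration_s: float = 600.0
    eye_rate_hz: float = 60.0
    imaging_rate_hz: float = 4.8
    rng_seed: int = 0
    eye_noise_sd_deg: float = 0.1
    calcium_noise_sd: float = 1.0
    n_rois_per_class: int = 8
    main_sequence: dict = field(default_factory=lambda: dict(DEFAULT_MAIN_SEQUENCE))
    convergence_return_tau_s: float | None = 4.0
    convergence_return_hold_s: float = 0.8
    okr_slow_velocity: float = 2.5  # deg/s
    okr_alternation_s: float = 4.0
    spot_response_lag_s: float = 1.5  # configurable; no fidelity claim
    spot_response_prob: float = 0.6
    swim_rate_hz: float = 0.1
    true_tau_off: float = 4.0
    true_offset_frames: int = 2
    calcium_gain: float = 10.0  # raw fluorescence units per zF unit

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.eye_rate_hz <= 0 or self.imaging_rate_hz <= 0:
            raise ValueError("rates must be positive")
        if self.eye_noise_sd_deg < 0 or self.calcium_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass
class SaccadePlan:
    time_s: float
    label: str  # ConvL / ConvR / ConjL / ConjR
    amp_left: float  # signed, shared rightward-positive frame
    amp_right: float


@dataclass
class OkrEpoch:
    start_s: float
    stop_s: float
    direction: int  # +1 rightward grating motion, -1 leftward
    slow_velocity: float  # deg/s, signed by direction at build time


@dataclass
class SpotEpoch:
    start_s: float
    stop_s: float
    direction: int  # +1 left-to-right sweep
    contrast: int  # +1 bright, -1 dark
    az_start_deg: float
    az_speed_deg_s: float


@dataclass
class SwimBout:
    time_s: float
    direction: str  # 'left' / 'right'
    vigour: float  # positive scalar; quartiles computed per session


@dataclass
class Schedule:
    saccades: list = field(default_factory=list)
    okr_epochs: list = field(default_factory=list)
    spots: list = field(default_factory=list)
    swims: list = field(default_factory=list)

    def saccade_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset_s": [s.time_s for s in self.saccades],
                "label": [s.label for s in self.saccades],
                "amp_left": [s.amp_left for s in self.saccades],
                "amp_right": [s.amp_right for s in self.saccades],
            }
        )

    def stimulus_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.okr_epochs:
            rows.append(
                {
                    "kind": "grating",
                    "start_s": e.start_s,
                    "stop_s": e.stop_s,
                    "direction": e.direction,
                    "contrast": np.nan,
                    "az_start_deg": np.nan,
                    "az_speed_deg_s": np.nan,
                }
            )
        for e in self.spots:
            rows.append(
                {
                    "kind": "spot",
                    "start_s": e.start_s,
                    "stop_s": e.stop_s,
                    "direction": e.direction,
                    "contrast": e.contrast,
                    "az_start_deg": e.az_start_deg,
                    "az_speed_deg_s": e.az_speed_deg_s,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "kind",
                "start_s",
                "stop_s",
                "direction",
                "contrast",
                "az_start_deg",
                "az_speed_deg_s",
            ],
        )

    def swim_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [s.time_s for s in self.swims],
                "direction": [s.direction for s in self.swims],
                "vigour": [s.vigour for s in self.swims],
            },
            columns=["time_s", "direction", "vigour"],
        )


@dataclass
class GroundTruth:
    """Everything the generator knows and the pipeline must recover."""

    saccade_times_s: np.ndarray
    saccade_types: np.ndarray
    saccade_amp_left: np.ndarray
    saccade_amp_right: np.ndarray
    main_sequence_params: dict
    roi_class: np.ndarray | None = None
    roi_weights: np.ndarray | None = None


# ---------------------------------------------------------------------------
# eye traces


def _minjerk_step(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 0.0, 1.0)
    return 10 * s**3 - 15 * s**4 + 6 * s**5


_MINJERK_PEAK_VEL = 1.875  # peak of d/ds (10 s^3 - 15 s^4 + 6 s^5)


def main_sequence_velocity(amp_deg: float, vmax: float, a0: float) -> float:
    """Exponential main sequence: V = Vmax (1 - exp(-A / A0))."""
    return vmax * (1.0 - np.exp(-abs(amp_deg) / a0))


def _saccade_duration(amp_deg: float, vmax: float, a0: float) -> float:
    vpk = main_sequence_velocity(amp_deg, vmax, a0)
    return _MINJERK_PEAK_VEL * abs(amp_deg) / vpk


def generate_eye_traces(
    cfg: SessionConfig, schedule: Schedule, rng: np.random.Generator | None = None
) -> tuple[EyeTrace, GroundTruth]:
    """Synthesize the binocular position trace implied by a schedule.

    Saccades are superposed minimum-jerk steps; OKR epochs add a
    constant-velocity conjugate slow phase; convergent events relax back
    toward rest when ``convergence_return_tau_s`` is set. Rejects schedules
    whose noiseless trace would leave the +/-35 deg orbital range.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    n = int(round(cfg.duration_s * cfg.eye_rate_hz))
    t = np.arange(n) / cfg.eye_rate_hz
    left = np.zeros(n)
    right = np.zeros(n)
    for sac in schedule.saccades:
        if sac.label not in SACCADE_TYPES:
            raise ValueError(f"unknown saccade type {sac.label!r}")
        vmax, a0 = cfg.main_sequence[sac.label]
        for eye, amp in (("left", sac.amp_left), ("right", sac.amp_right)):
            if amp == 0:
                continue
            T = _saccade_duration(amp, vmax, a0)
            contrib = amp * _minjerk_step((t - sac.time_s) / T)
            if sac.label.startswith("Conv") and cfg.convergence_return_tau_s:
                u = t - (sac.time_s + T + cfg.convergence_return_hold_s)
                contrib = contrib - amp * np.where(
                    u > 0, 1.0 - np.exp(-np.maximum(u, 0) / cfg.convergence_return_tau_s), 0.0
                )
            if eye == "left":
                left += contrib
            else:
                right += contrib
    for ep in schedule.okr_epochs:
        vel = ep.slow_velocity * ep.direction
        drift = vel * np.clip(t - ep.start_s, 0.0, ep.stop_s - ep.start_s)
        left += drift
        right += drift
    peak = max(np.abs(left).max(initial=0.0), np.abs(right).max(initial=0.0))
    if peak > ORBITAL_RANGE_DEG:
        raise ValueError(
            f"schedule drives the eye to {peak:.1f} deg, beyond the "
            f"+/-{ORBITAL_RANGE_DEG:.0f} deg orbital range"
        )
    if cfg.eye_noise_sd_deg > 0:
        left = left + rng.normal(0.0, cfg.eye_noise_sd_deg, n)
        right = right + rng.normal(0.0, cfg.eye_noise_sd_deg, n)
    truth = GroundTruth(
        saccade_times_s=np.array([s.time_s for s in schedule.saccades]),
        saccade_types=np.array([s.label for s in schedule.saccades]),
        saccade_amp_left=np.array([s.amp_left for s in schedule.saccades]),
        saccade_amp_right=np.array([s.amp_right for s in schedule.saccades]),
        main_sequence_params=dict(cfg.main_sequence),
    )
    return EyeTrace(t=t, left=left, right=right), truth


# ---------------------------------------------------------------------------
# motion error and calcium


def generate_motion_error(
    n_frames: int,
    rng: np.random.Generator,
    baseline_um: float = 1.0,
    excursion_rate_per_frame: float = 0.01,
    excursion_um: tuple[float, float] = (6.0, 10.0),
) -> np.ndarray:
    """Per-frame motion-error trace (micrometres).

    Baseline jitter in 0-2 um with Poisson-timed excursions to 6-10 um,
    large enough to trigger the >5 um interpolation rule downstream.
    """
    err = np.abs(rng.normal(baseline_um, 0.5, n_frames))
    err = np.clip(err, 0.0, 2.0)
    bad = rng.random(n_frames) < excursion_rate_per_frame
    err[bad] = rng.uniform(*excursion_um, bad.sum())
    return err


def generate_calcium(
    cfg: SessionConfig,
    design: DesignMatrix,
    weights: np.ndarray,
    baselines: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Raw fluorescence as baseline + weights @ regressors + Gaussian noise.

    ``weights`` is (n_rois, n_regressors) applied to the raw design
    columns; the noise SD defaults to ``calcium_gain * calcium_noise_sd``
    so that, after zF standardization, effect sizes come out in units of
    the configured calcium noise.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    if weights.shape[1] != design.X.shape[1]:
        raise ValueError(
            f"weights have {weights.shape[1]} columns but the design has {design.X.shape[1]}"
        )
    n_rois = weights.shape[0]
    if baselines is None:
        baselines = np.full(n_rois, 100.0)
    F = baselines[:, None] + weights @ design.X.T
    sd = noise_sd if noise_sd is not None else cfg.calcium_gain * cfg.calcium_noise_sd
    if sd > 0:
        F = F + rng.normal(0.0, sd, F.shape)
    return F


# ---------------------------------------------------------------------------
# reference nine-metric set (for the classification embedding)


def sample_metrics9(label: str, rng: np.random.Generator, cfg: SessionConfig | None = None) -> np.ndarray:
    """Draw one nine-metric vector from the type's kinematic model.

    Amplitudes and peak velocities follow the configured main sequences
    with multiplicative jitter; signs and the vergence entry follow the
    shared rightward-positive convention used by the detection stage.
    """
    cfg = cfg or SessionConfig()
    vmax, a0 = cfg.main_sequence[label]
    a_primary = rng.uniform(4.0, 16.0)
    if label in ("ConjL", "ConjR"):
        sign = 1.0 if label == "ConjR" else -1.0
        amp_l = sign * a_primary
        amp_r = sign * a_primary * rng.uniform(0.8, 1.2)
    else:
        a_small = rng.uniform(2.0, 5.0)
        if label == "ConvR":  # rightward version: left eye makes the large nasal movement
            amp_l, amp_r = a_primary, -a_small
        else:
            amp_l, amp_r = a_small, -a_primary
    pre_l, pre_r = rng.normal(0.0, 3.0, 2)
    post_l, post_r = pre_l + amp_l, pre_r + amp_r
    m = np.empty(9)
    for k, amp in ((0, amp_l), (1, amp_r)):
        m[k] = amp
    # minimum-jerk steps are monotonic (no overshoot), so max-median
    # amplitude is a noise-dominated metric, independent of saccade type
    m[2] = rng.normal(0.0, 0.3)
    m[3] = rng.normal(0.0, 0.3)
    for slot_cw, slot_ccw, amp in ((4, 5, amp_l), (6, 7, amp_r)):
        vpk = main_sequence_velocity(amp, vmax, a0) * rng.normal(1.0, 0.05)
        if amp >= 0:
            m[slot_cw], m[slot_ccw] = vpk, -abs(rng.normal(0.0, 20.0))
        else:
            m[slot_cw], m[slot_ccw] = abs(rng.normal(0.0, 20.0)), -vpk
    m[8] = post_l - post_r
    return m


def generate_reference_set(
    n_per_type: int,
    rng_seed: int,
    types: tuple[str, ...] = SACCADE_TYPES,
    cfg: SessionConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled, normalized nine-metric matrix for fitting the embedding.

    Refuses ``n_per_type < 100`` (the modal 100-NN vote would be
    undefined) and single-type inputs (a supervised embedding of one class
    is degenerate).
    """
    if n_per_type < 100:
        raise ValueError("n_per_type must be >= 100 (the 100-NN vote requires it)")
    if len(set(types)) < 2:
        raise ValueError("need at least two saccade types for a reference set")
    rng = np.random.default_rng(rng_seed)
    X = np.vstack([sample_metrics9(lbl, rng, cfg) for lbl in types for _ in range(n_per_type)])
    y = np.repeat(list(types), n_per_type)
    Xn, _ = normalize_metrics(X)
    return Xn, y


# ---------------------------------------------------------------------------
# schedules


def analytic_eye_position(sched: Schedule, cfg: SessionConfig, t0: float) -> tuple[float, float]:
    """Noiseless (left, right) eye position implied by the schedule at t0.

    Conjugate steps persist, convergent steps relax with the configured
    time constant, and OKR slow phases contribute their accumulated
    drift. Saccades still in flight are treated as completed.
    """
    pl = pr = 0.0
    for s in sched.saccades:
        if s.time_s >= t0:
            continue
        if s.label.startswith("Conv") and cfg.convergence_return_tau_s:
            decay = np.exp(
                -max(t0 - s.time_s - cfg.convergence_return_hold_s, 0.0)
                / cfg.convergence_return_tau_s
            )
        else:
            decay = 1.0
        pl += s.amp_left * decay
        pr += s.amp_right * decay
    for ep in sched.okr_epochs:
        if ep.start_s >= t0:
            continue
        drift = ep.slow_velocity * ep.direction * min(t0 - ep.start_s, ep.stop_s - ep.start_s)
        pl += drift
        pr += drift
    return pl, pr


def _conv_label_from_version(pl: float, pr: float, amp_l: float, amp_r: float) -> str:
    """Ground-truth convergent laterality: the sign of post-saccadic version."""
    version = ((pl + amp_l) + (pr + amp_r)) / 2.0
    return "ConvR" if version >= 0 else "ConvL"


def make_saccade_schedule(
    n_saccades: int,
    rng: np.random.Generator,
    spacing_s: float = 2.5,
    start_s: float = 3.0,
    types: tuple[str, ...] = SACCADE_TYPES,
    cfg: SessionConfig | None = None,
) -> Schedule:
    """A saccade-only schedule cycling through types, bounded in position.

    Tracks the analytic noiseless eye position implied by the events
    placed so far and steers conjugate saccades toward centre, so
    arbitrarily long schedules stay inside the orbital range. Convergent
    labels follow the operational definition (sign of the noiseless
    post-saccadic version).
    """
    cfg = cfg or SessionConfig()
    sched = Schedule()
    for i in range(n_saccades):
        t0 = start_s + i * spacing_s
        label = types[i % len(types)]
        pl, pr = analytic_eye_position(sched, cfg, t0)
        if label in ("ConjL", "ConjR"):
            sign = -1 if (pl + pr) > 0 else 1  # recentre
            label = "ConjR" if sign > 0 else "ConjL"
            a = rng.uniform(5.0, 14.0)
            amp_l = sign * a
            amp_r = sign * a * rng.uniform(0.85, 1.15)
        else:
            amp_l, amp_r = _conv_amps(label, rng)
        # hard guard against orbital overflow
        amp_l = float(np.clip(amp_l, -28.0 - pl, 28.0 - pl))
        amp_r = float(np.clip(amp_r, -28.0 - pr, 28.0 - pr))
        if label.startswith("Conv"):
            label = _conv_label_from_version(pl, pr, amp_l, amp_r)
        sched.saccades.append(SaccadePlan(t0, label, amp_l, amp_r))
    return sched


def _conv_amps(label: str, rng: np.random.Generator) -> tuple[float, float]:
    big, small = rng.uniform(7.0, 13.0), rng.uniform(2.0, 5.0)
    return (big, -small) if label == "ConvR" else (small, -big)


def make_session_schedule(cfg: SessionConfig, rng: np.random.Generator) -> Schedule:
    """Realistic session plan: OKR blocks, moving spots, spontaneous
    saccades and swim bouts, repeating on a 60 s cycle.

    Each OKR block is six alternation epochs (direction flipping every
    ``okr_alternation_s``); the slow phase runs for the first 3.5 s of each
    epoch and a conjugate reset saccade at 3.5 s exactly cancels the
    accumulated drift, so positions stay bounded. Spots sweep the frontal
    field and evoke a lateralized convergent saccade after the configured
    lag.
    """
    sched = Schedule()
    cycle = 60.0
    n_cycles = int(cfg.duration_s // cycle)
    for c in range(n_cycles):
        base = c * cycle
        # --- OKR block: 6 alternating epochs; the reset saccade at each
        # epoch end exactly cancels the slow-phase drift of that epoch
        for k in range(6):
            e0 = base + 2.0 + k * cfg.okr_alternation_s
            direction = -1 if k % 2 == 0 else 1
            sched.okr_epochs.append(
                OkrEpoch(e0, e0 + cfg.okr_alternation_s, direction, cfg.okr_slow_velocity)
            )
            drift = cfg.okr_slow_velocity * cfg.okr_alternation_s * direction
            reset_label = "ConjR" if drift < 0 else "ConjL"
            sched.saccades.append(
                SaccadePlan(
                    e0 + cfg.okr_alternation_s,
                    reset_label,
                    -drift,
                    -drift * rng.uniform(0.9, 1.1),
                )
            )
        # --- spontaneous conjugate saccade
        t_sp = base + 28.0
        sign = 1 if c % 2 == 0 else -1
        a = rng.uniform(6.0, 12.0)
        sched.saccades.append(
            SaccadePlan(t_sp, "ConjR" if sign > 0 else "ConjL", sign * a, sign * a * rng.uniform(0.85, 1.15))
        )
        sched.saccades.append(
            SaccadePlan(t_sp + 3.0, "ConjL" if sign > 0 else "ConjR", -sign * a, -sign * a * rng.uniform(0.85, 1.15))
        )
        # --- moving spots; hunting responses are probabilistic with
        # jittered latency, so spot and saccade regressors decorrelate
        for t_spot, direction, label in ((base + 34.0, 1, "ConvR"), (base + 46.0, -1, "ConvL")):
            contrast = 1 if rng.random() < 0.5 else -1
            sched.spots.append(
                SpotEpoch(t_spot, t_spot + 4.0, direction, contrast, -60.0 * direction, 30.0 * direction)
            )
            if rng.random() < cfg.spot_response_prob:
                lag = cfg.spot_response_lag_s + rng.uniform(-0.5, 1.0)
                t_resp = t_spot + lag
                amp_l, amp_r = _conv_amps(label, rng)
                pl, pr = analytic_eye_position(sched, cfg, t_resp)
                sched.saccades.append(
                    SaccadePlan(
                        t_resp, _conv_label_from_version(pl, pr, amp_l, amp_r), amp_l, amp_r
                    )
                )
        # --- spontaneous convergent saccade (hunting without a spot)
        label = "ConvR" if rng.random() < 0.5 else "ConvL"
        t_conv = base + 54.0 + rng.uniform(0.0, 2.0)
        amp_l, amp_r = _conv_amps(label, rng)
        pl, pr = analytic_eye_position(sched, cfg, t_conv)
        sched.saccades.append(
            SaccadePlan(t_conv, _conv_label_from_version(pl, pr, amp_l, amp_r), amp_l, amp_r)
        )
    n_swims = rng.poisson(cfg.swim_rate_hz * cfg.duration_s)
    for t_swim in np.sort(rng.uniform(1.0, cfg.duration_s - 1.0, n_swims)):
        sched.swims.append(
            SwimBout(float(t_swim), "left" if rng.random() < 0.5 else "right", float(rng.lognormal(0.0, 0.5)))
        )
    sched.saccades.sort(key=lambda s: s.time_s)
    return sched


# ---------------------------------------------------------------------------
# full session


@dataclass
class SyntheticSession:
    """One complete generated session plus its ground truth."""

    config: SessionConfig
    trace: EyeTrace
    truth: GroundTruth
    events: pd.DataFrame  # ground-truth events (onset_s, label, amplitudes)
    stimuli: pd.DataFrame
    swims: pd.DataFrame
    frame_t: np.ndarray
    motion_error_um: np.ndarray
    fluorescence: np.ndarray  # (n_rois, n_frames) raw units
    design: DesignMatrix  # the generating design (true tau_off / offset)


def _assign_roi_weights(
    cfg: SessionConfig,
    design: DesignMatrix,
    rng: np.random.Generator,
    class_weights: dict[str, dict[str, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    class_weights = class_weights or DEFAULT_CLASS_WEIGHTS
    col_sd = design.X.std(axis=0)
    name_to_idx = {n: i for i, n in enumerate(design.names)}
    classes, weights = [], []
    for cls in ROI_CLASSES:
        spec_w = class_weights.get(cls, {})
        for _ in range(cfg.n_rois_per_class):
            w = np.zeros(design.X.shape[1])
            for name, eff in spec_w.items():
                j = name_to_idx[name]
                if col_sd[j] > 0:
                    jitter = rng.uniform(0.85, 1.15)
                    w[j] = eff * jitter * cfg.calcium_gain * cfg.calcium_noise_sd / col_sd[j]
            classes.append(cls)
            weights.append(w)
    return np.array(classes), np.vstack(weights)


def simulate_session(cfg: SessionConfig | None = None) -> SyntheticSession:
    """Generate a full session: behaviour, stimuli, and fluorescence.

    Deterministic given ``cfg`` (all randomness flows from
    ``cfg.rng_seed``).
    """
    cfg = cfg or SessionConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    schedule = make_session_schedule(cfg, rng)
    trace, truth = generate_eye_traces(cfg, schedule, rng)
    n_frames = int(round(cfg.duration_s * cfg.imaging_rate_hz))
    frame_t = (np.arange(n_frames) + 0.5) / cfg.imaging_rate_hz
    motion = generate_motion_error(n_frames, rng)
    events = schedule.saccade_frame()
    design = build_design(
        events=events,
        trace=trace,
        swims=schedule.swim_frame(),
        stimuli=schedule.stimulus_frame(),
        motion_error_um=motion,
        frame_t=frame_t,
        cirf=CIRF(tau_on=0.2, tau_off=cfg.true_tau_off),
        offset_frames=cfg.true_offset_frames,
    )
    roi_class, roi_weights = _assign_roi_weights(cfg, design, rng)
    baselines = rng.uniform(50.0, 150.0, len(roi_class))
    F = generate_calcium(cfg, design, roi_weights, baselines, rng)
    truth.roi_class = roi_class
    truth.roi_weights = roi_weights
    return SyntheticSession(
        config=cfg,
        trace=trace,
        truth=truth,
        events=events,
        stimuli=schedule.stimulus_frame(),
        swims=schedule.swim_frame(),
        frame_t=frame_t,
        motion_error_um=motion,
        fluorescence=F,
        design=design,
    )
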