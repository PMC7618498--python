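"""End-to-end pipeline driver: detect -> classify -> encode -> metrics.

Everything is deterministic given the session data and one integer seed;
all stage RNGs are spawned from it and every output table carries the
config hash and seed in a leading comment line.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as _classify
from . import encoding as enc
from . import tuning as _tuning
from .kinematics import DetectionConfig, METRIC_NAMES, detect_saccades, normalize_metrics
from .synth import generate_reference_set

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All pipeline parameters with the documented defaults."""

    detection: DetectionConfig = field(default_factory=DetectionConfig)
    use_umap: bool = False  # 9-D kNN reference space by default; UMAP optional
    ref_n_per_type: int = 300
    knn_vote: int = 100
    tau_offs: tuple = (3.0, 4.0, 5.0)
    offsets: tuple = (0, 1, 2, 3)
    r2_gate: float = 0.05
    n_shuffle: int = 1000
    n_folds: int = 10
    match_radius: float = 0.1
    min_null_pool: int = 50

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    events: pd.DataFrame
    roi_results: pd.DataFrame
    deltas: pd.DataFrame  # per-ROI delta cvR^2 (33 columns), NaN when not gated
    summary: dict


def _onsets_by_type(events: pd.DataFrame, frame_t: np.ndarray) -> dict[str, np.ndarray]:
    frames = enc._nearest_frames(events["onset_s"].to_numpy(dtype=float), frame_t)
    labels = events["label"].to_numpy()
    return {
        "Conv": frames[np.isin(labels, ["ConvL", "ConvR"])],
        "LConj": frames[labels == "ConjL"],
        "RConj": frames[labels == "ConjR"],
    }


def _nasal_columns(events: pd.DataFrame, eye: str) -> pd.DataFrame:
    """Adducting saccades of one eye with nasal-normalized kinematics."""
    sign = 1.0 if eye == "left" else -1.0
    amp = sign * (
        events[f"med_post_pos_{eye}"].to_numpy() - events[f"pre_pos_{eye}"].to_numpy()
    )
    pos = sign * events[f"med_post_pos_{eye}"].to_numpy()
    vel = events[f"vel_cw_{eye}"].to_numpy() if eye == "left" else -events[
        f"vel_ccw_{eye}"
    ].to_numpy()
    df = pd.DataFrame(
        {
            "idx": np.arange(len(events)),
            "label": events["label"].to_numpy(),
            "nasal_amp": amp,
            "nasal_pos": pos,
            "nasal_vel": vel,
        }
    )
    return df[df["nasal_amp"] > 0].reset_index(drop=True)


def run_pipeline(session, config: PipelineConfig | None = None, seed: int = 0, out_dir=None):
    """Run the full analysis on a session bundle.

    ``session`` needs attributes trace, stimuli, swims, frame_t,
    motion_error_um and fluorescence (a SyntheticSession or loaded
    bundle). Returns a :class:`PipelineResult`; when ``out_dir`` is given,
    events and per-ROI tables are also written as CSV with the config
    hash and seed in a comment header.
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    seeds = np.random.SeedSequence(seed).spawn(4)

    # --- stage 1: behaviour
    events = detect_saccades(session.trace, config.detection)
    if not len(events):
        raise RuntimeError("detect: no saccades found")
    bino = events[events["binocular"]].copy()
    metrics = bino[list(METRIC_NAMES)].to_numpy()
    metrics_norm, _ = normalize_metrics(metrics)
    ref_X, ref_y = generate_reference_set(config.ref_n_per_type, rng_seed=int(seeds[0].generate_state(1)[0] % 2**31))
    ref = _classify.fit_reference_embedding(
        ref_X, ref_y, use_umap=config.use_umap, rng_seed=int(seeds[0].generate_state(1)[0] % 2**31)
    )
    labels = _classify.classify_saccades(metrics_norm, ref, k=config.knn_vote)
    bino["label"] = labels
    bino, _ = _classify.lateralize_convergent(bino)
    events = bino.reset_index(drop=True)

    # --- stage 2: encoding
    F = session.fluorescence
    frame_t = np.asarray(session.frame_t)
    zF, zf_info = enc.compute_zF(F, session.motion_error_um)
    frame_rate = 1.0 / float(np.median(np.diff(frame_t)))
    onsets = _onsets_by_type(events, frame_t)
    dp_rng = np.random.default_rng(seeds[1].generate_state(1)[0] % 2**31)
    dp = enc.dprime_null_test_batch(
        zF, onsets, frame_rate, dp_rng, n_shuffle=config.n_shuffle
    )
    active_any = np.zeros(zF.shape[0], dtype=bool)
    for typ in dp:
        active_any |= dp[typ]["active"]

    designs = enc.build_design_grid(
        tau_offs=config.tau_offs,
        offsets=config.offsets,
        events=events,
        trace=session.trace,
        swims=session.swims,
        stimuli=session.stimuli,
        motion_error_um=session.motion_error_um,
        frame_t=frame_t,
    )
    search = enc.ols_hyperparam_search(zF, designs, r2_gate=config.r2_gate)
    gated = active_any & search["gate"].to_numpy()

    n_rois = zF.shape[0]
    n_reg = 33
    deltas = np.full((n_rois, n_reg), np.nan)
    shifts = np.full((n_rois, n_reg), -1, dtype=int)
    ridge_lambda = np.full(n_rois, np.nan)
    cvr2 = np.full(n_rois, np.nan)
    delta_rng = np.random.default_rng(seeds[2].generate_state(1)[0] % 2**31)
    any_design = next(iter(designs.values()))
    names, groups = any_design.names, any_design.groups
    for r in np.flatnonzero(gated):
        key = (search.loc[r, "best_tau_off"], int(search.loc[r, "best_offset"]))
        X = designs[key].X
        fit = enc.ridge_cv_fit(zF[r], X, n_folds=config.n_folds)
        ridge_lambda[r] = fit.lambda_
        cvr2[r] = fit.cvR2
        deltas[r], shifts[r] = enc.delta_cvR2(zF[r], X, fit, delta_rng)

    active = {typ: dp[typ]["active"] for typ in dp}
    dprime = {typ: dp[typ]["dprime"] for typ in dp}
    if gated.any():
        tuned_df = enc.classify_tuned(
            deltas, groups, active, dprime, min_null=config.min_null_pool
        )
    else:
        tuned_df = pd.DataFrame(
            {"tuned": np.zeros(n_rois, bool), "label": np.full(n_rois, "none", object)}
        )

    # --- stage 3: tuning metrics
    all_frames = enc._nearest_frames(events["onset_s"].to_numpy(dtype=float), frame_t)
    sti = np.full(n_rois, np.nan)
    n_pairs = np.zeros(n_rois, dtype=int)
    okr = np.full(n_rois, np.nan)
    pref = np.full(n_rois, "", dtype=object)
    adducting = {eye: _nasal_columns(events, eye) for eye in ("left", "right")}
    has_grating = len(session.stimuli) and (session.stimuli["kind"] == "grating").any()
    for r in range(n_rois):
        try:
            stf, _ = _tuning.normalized_stf(zF[r], all_frames, frame_rate)
        except ValueError:
            continue
        if has_grating:
            try:
                okr[r] = _tuning.okr_power(zF[r], session.stimuli, frame_t)
            except ValueError:
                pass
        if not gated[r] or np.isnan(deltas[r]).any():
            continue
        delta_by_name = dict(zip(names, deltas[r]))
        pref[r], _ = _tuning.directionality_preference(delta_by_name)
        eye = "right" if pref[r] == "left" else "left"
        add = adducting[eye]
        if not len(add):
            continue
        pos_scale = add["nasal_pos"].max()
        vel_scale = np.percentile(add["nasal_vel"], 95)
        if pos_scale <= 0 or vel_scale <= 0:
            continue
        sub = add.assign(
            pos_norm=add["nasal_pos"] / pos_scale,
            vel_norm=add["nasal_vel"] / vel_scale,
            stf=stf[add["idx"].to_numpy()],
        )
        conj = sub[sub["label"].str.startswith("Conj")]
        conv = sub[sub["label"].str.startswith("Conv")]
        sti[r], n_pairs[r] = _tuning.saccade_type_index(
            conj, conv, radius=config.match_radius
        )
    try:
        pc1, _, _ = _tuning.pc1_score(sti, okr)
    except ValueError:
        pc1 = np.full(n_rois, np.nan)

    roi_results = pd.DataFrame(
        {
            "dprime_Conv": dprime["Conv"],
            "dprime_LConj": dprime["LConj"],
            "dprime_RConj": dprime["RConj"],
            "active_Conv": active["Conv"],
            "active_LConj": active["LConj"],
            "active_RConj": active["RConj"],
            "best_tau_off": search["best_tau_off"],
            "best_offset": search["best_offset"],
            "ols_r2": search["ols_r2"],
            "gate": gated,
            "ridge_lambda": ridge_lambda,
            "cvR2": cvr2,
            "tuned": tuned_df["tuned"],
            "label": tuned_df["label"],
            "saccade_type_index": sti,
            "sti_n_pairs": n_pairs,
            "okr_power": okr,
            "pc1_score": pc1,
            "directionality": pref,
            "zf_noise": zf_info["noise"],
        }
    )
    deltas_df = pd.DataFrame(deltas, columns=names)
    summary = {
        "n_events": int(len(events)),
        "n_rois": int(n_rois),
        "n_saccade_active": int(active_any.sum()),
        "n_gated": int(gated.sum()),
        "n_tuned": int(tuned_df["tuned"].sum()),
        "seed": int(seed),
        "config_hash": config.hash,
    }
    result = PipelineResult(events=events, roi_results=roi_results, deltas=deltas_df, summary=summary)
    if out_dir is not None:
        _write_outputs(result, config, seed, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, seed: int, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    header = f"# binoc config_hash={config.hash} seed={seed}\n"
    for name, df in (
        ("events.csv", result.events),
        ("roi_results.csv", result.roi_results),
        ("delta_cvr2.csv", result.deltas),
    ):
        with open(out / name, "w") as f:
            f.write(header)
            df.to_csv(f, index=False)
    (out / "summary.json").write_text(json.dumps(result.summary, indent=1, sort_keys=True))
    (out / "config_snapshot.json").write_text(config.to_json())
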