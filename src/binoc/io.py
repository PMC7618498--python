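"""Session-bundle readers and writers.

A session bundle is a directory with CSV tables for the behavioural logs
(eye trace, events, stimuli, swims), an HDF5 container for arrays
(fluorescence, frame times, motion error) and JSON for config and ground
truth. CSV/HDF5/JSON were chosen as standard, language-neutral formats.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .kinematics import EyeTrace
from .synth import GroundTruth, SessionConfig, SyntheticSession

__all__ = ["save_session", "load_session"]


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"cannot serialize {type(o)}")


def save_session(session: SyntheticSession, out_dir: str | Path) -> Path:
    """Write a session bundle; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.trace.to_frame().to_csv(out / "trace.csv", index=False)
    session.events.to_csv(out / "events_truth.csv", index=False)
    session.stimuli.to_csv(out / "stimuli.csv", index=False)
    session.swims.to_csv(out / "swims.csv", index=False)
    with h5py.File(out / "session.h5", "w") as f:
        f.create_dataset("fluorescence", data=session.fluorescence)
        f.create_dataset("frame_t", data=session.frame_t)
        f.create_dataset("motion_error_um", data=session.motion_error_um)
    truth = session.truth
    truth_dict = {
        "saccade_times_s": truth.saccade_times_s,
        "saccade_types": truth.saccade_types,
        "saccade_amp_left": truth.saccade_amp_left,
        "saccade_amp_right": truth.saccade_amp_right,
        "main_sequence_params": truth.main_sequence_params,
        "roi_class": truth.roi_class,
        "roi_weights": truth.roi_weights,
    }
    (out / "ground_truth.json").write_text(
        json.dumps(truth_dict, default=_json_default, indent=1)
    )
    (out / "config.json").write_text(
        json.dumps(dataclasses.asdict(session.config), default=_json_default, indent=1)
    )
    return out


def load_session(in_dir: str | Path) -> SyntheticSession:
    """Read a session bundle written by :func:`save_session`."""
    d = Path(in_dir)
    cfg_dict = json.loads((d / "config.json").read_text())
    cfg_dict["main_sequence"] = {k: tuple(v) for k, v in cfg_dict["main_sequence"].items()}
    cfg = SessionConfig(**cfg_dict)
    trace = EyeTrace.from_frame(pd.read_csv(d / "trace.csv"))
    with h5py.File(d / "session.h5", "r") as f:
        F = f["fluorescence"][...]
        frame_t = f["frame_t"][...]
        motion = f["motion_error_um"][...]
    td = json.loads((d / "ground_truth.json").read_text())
    truth = GroundTruth(
        saccade_times_s=np.asarray(td["saccade_times_s"], dtype=float),
        saccade_types=np.asarray(td["saccade_types"]),
        saccade_amp_left=np.asarray(td["saccade_amp_left"], dtype=float),
        saccade_amp_right=np.asarray(td["saccade_amp_right"], dtype=float),
        main_sequence_params={k: tuple(v) for k, v in td["main_sequence_params"].items()},
        roi_class=None if td["roi_class"] is None else np.asarray(td["roi_class"]),
        roi_weights=None if td["roi_weights"] is None else np.asarray(td["roi_weights"]),
    )
    return SyntheticSession(
        config=cfg,
        trace=trace,
        truth=truth,
        events=pd.read_csv(d / "events_truth.csv"),
        stimuli=pd.read_csv(d / "stimuli.csv"),
        swims=pd.read_csv(d / "swims.csv"),
        frame_t=frame_t,
        motion_error_um=motion,
        fluorescence=F,
        design=None,
    )
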