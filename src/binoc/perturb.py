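"""Pre/post-manipulation behavioural change quantification.

Ablation deficits are differences of per-animal medians (post-saccadic
eye position and peak saccade speed) between a pre- and a post-epoch,
computed per eye and saccade type; the Conv-Conj residual (convergent
minus conjugate deficit) can be regressed on the median saccade-type
index of the manipulated cells. Optogenetic position changes compare
median eye position in 250 ms windows ending at stimulus onset and
offset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ablation_deficit",
    "conv_conj_residual_regression",
    "opto_position_change",
]

_MEASURES = ("med_post_pos", "peak_speed")


def _event_measures(events: pd.DataFrame, eye: str) -> pd.DataFrame:
    out = pd.DataFrame(
        {
            "med_post_pos": events[f"med_post_pos_{eye}"],
            "peak_speed": np.maximum(
                events[f"vel_cw_{eye}"], -events[f"vel_ccw_{eye}"]
            ),
            "label": events["label"],
        }
    )
    return out.dropna(subset=["med_post_pos"])


def _pool_label(label: str) -> str:
    return "Conv" if str(label).startswith("Conv") else "Conj"


def ablation_deficit(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    min_events: int = 5,
    animal: str | int = 0,
) -> pd.DataFrame:
    """Per (eye, saccade type, measure) medians pre and post, and deficits.

    ``deficit = post-epoch median - pre-epoch median``; a cell is reported
    only when both epochs contain at least ``min_events`` saccades of the
    type. Rows are produced both for lateralized types (ConvL, ConjR, ...)
    and for the pooled Conv/Conj grouping. Swapping the epochs flips the
    sign of every deficit.
    """
    rows = []
    for eye in ("left", "right"):
        pre_m = _event_measures(pre, eye)
        post_m = _event_measures(post, eye)
        type_sets = [("split", pre_m["label"], post_m["label"])]
        type_sets.append(
            ("pooled", pre_m["label"].map(_pool_label), post_m["label"].map(_pool_label))
        )
        for grouping, pre_lab, post_lab in type_sets:
            for typ in sorted(set(pre_lab) | set(post_lab)):
                a = pre_m[pre_lab == typ]
                b = post_m[post_lab == typ]
                if len(a) < min_events or len(b) < min_events:
                    continue
                for measure in _MEASURES:
                    pre_med = float(a[measure].median())
                    post_med = float(b[measure].median())
                    rows.append(
                        {
                            "animal": animal,
                            "eye": eye,
                            "grouping": grouping,
                            "saccade_type": typ,
                            "measure": measure,
                            "pre_median": pre_med,
                            "post_median": post_med,
                            "deficit": post_med - pre_med,
                            "n_pre": len(a),
                            "n_post": len(b),
                        }
                    )
    return pd.DataFrame(rows)


def deficit_tests(deficits: pd.DataFrame) -> pd.DataFrame:
    """Across-animal paired tests of pre vs post medians.

    Reports both the signed-rank (Wilcoxon) and paired t statistics per
    (eye, grouping, saccade type, measure) cell.
    """
    rows = []
    keys = ["eye", "grouping", "saccade_type", "measure"]
    for key, g in deficits.groupby(keys):
        if len(g) < 2:
            continue
        d = g["deficit"].to_numpy()
        rec = dict(zip(keys, key))
        rec["n_animals"] = len(g)
        rec["median_deficit"] = float(np.median(d))
        if np.any(d != 0):
            rec["signed_rank_p"] = float(stats.wilcoxon(d).pvalue)
        else:
            rec["signed_rank_p"] = 1.0
        rec["t_p"] = float(stats.ttest_rel(g["post_median"], g["pre_median"]).pvalue)
        rows.append(rec)
    return pd.DataFrame(rows)


def conv_conj_residual_regression(
    residuals: np.ndarray, median_indices: np.ndarray
) -> dict:
    """OLS line of Conv-Conj residual against median saccade-type index.

    One point per animal: the difference between the convergent and
    conjugate deficits versus the median saccade-type index of the
    manipulated neurons. Requires >= 4 animals. Returns slope, intercept,
    R^2 and the two-sided slope p value.
    """
    x = np.asarray(median_indices, dtype=float)
    y = np.asarray(residuals, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise ValueError("need at least 4 animals for the residual regression")
    res = stats.linregress(x[ok], y[ok])
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r2": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": int(ok.sum()),
    }


def opto_position_change(
    trace, epochs: pd.DataFrame, window_s: float = 0.250
) -> pd.DataFrame:
    """Optogenetically evoked eye-position change per stimulation epoch.

    change = median position over the 250 ms window ending at stimulus
    offset minus the median over the 250 ms window ending at onset,
    per eye. Adding a constant to the trace leaves the change unchanged.
    Epochs shorter than twice the window would overlap and are rejected.
    """
    rows = []
    for _, row in epochs.iterrows():
        on, off = float(row["start_s"]), float(row["stop_s"])
        if off - on < 2 * window_s:
            raise ValueError("epoch shorter than 2x the analysis window")
        if on - window_s < trace.t[0] or off > trace.t[-1]:
            raise ValueError("analysis windows fall outside the trace")
        rec = {"start_s": on, "stop_s": off}
        for eye in ("left", "right"):
            x = trace.eye(eye)
            pre = x[(trace.t >= on - window_s) & (trace.t < on)]
            post = x[(trace.t >= off - window_s) & (trace.t < off)]
            rec[f"change_{eye}"] = float(np.median(post) - np.median(pre))
        rows.append(rec)
    return pd.DataFrame(rows)
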