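"""Quantify behavioural deficits after a simulated manipulation.

Simulates an adduction-gain loss (post-epoch convergent/conjugate
saccades are slower and hypometric for one eye) and measures the deficit
as the difference of per-epoch medians, plus an optogenetic eye-position
change readout.
"""

import numpy as np
import pandas as pd

from binoc import ablation_deficit, detect_saccades, opto_position_change
from binoc.kinematics import EyeTrace
from binoc.synth import SessionConfig, generate_eye_traces, make_saccade_schedule

cfg = SessionConfig(duration_s=160.0, eye_noise_sd_deg=0.2, rng_seed=0)
sched = make_saccade_schedule(60, np.random.default_rng(0), cfg=cfg)
pre_trace, _ = generate_eye_traces(cfg, sched, np.random.default_rng(1))

# post-ablation: same behaviour, but 40% loss of left-eye plant gain
# (positions and velocities of that eye scale down together)
post_trace, _ = generate_eye_traces(cfg, sched, np.random.default_rng(2))
post_trace.left = 0.6 * post_trace.left

pre = detect_saccades(pre_trace)
post = detect_saccades(post_trace)
pre = pre[pre["amp_left"] > 0].copy()  # left-eye adducting saccades
post = post[post["amp_left"] > 0].copy()
pre["label"] = "ConjR"
post["label"] = "ConjR"
deficits = ablation_deficit(pre, post)
left_pos = deficits.query("eye == 'left' and measure == 'med_post_pos' and grouping == 'pooled'")
print("left-eye post-saccadic position deficit (deg):", left_pos["deficit"].round(2).tolist())
# A negative deficit means the eye reaches less nasal positions after the
# simulated gain loss.

# optogenetic stimulation: eye ramps to +6 deg during a 4 s epoch
t = np.arange(0.0, 20.0, 1 / 300.0)
x = np.clip((t - 8.0) * 3.0, 0.0, 6.0) + np.random.default_rng(2).normal(0, 0.2, len(t))
trace = EyeTrace(t=t, left=x, right=x.copy())
epochs = pd.DataFrame({"start_s": [8.0], "stop_s": [12.0]})
change = opto_position_change(trace, epochs)
print(f"evoked position change: {change['change_left'].iloc[0]:+.2f} deg (true +6.00)")
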