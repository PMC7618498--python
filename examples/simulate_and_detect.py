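"""Generate a synthetic behaving session and detect its saccades.

Builds a 5-minute session with known ground truth (conjugate and
convergent saccades, OKR slow phases, swims, moving spots), runs the
detection stage and compares detected onsets against the schedule.
"""

import numpy as np

from binoc import detect_saccades
from binoc.synth import SessionConfig, simulate_session

session = simulate_session(SessionConfig(duration_s=300.0, rng_seed=0, n_rois_per_class=2))
events = detect_saccades(session.trace)

truth_t = session.truth.saccade_times_s
det_t = events["onset_s"].to_numpy()
errors = []
for t0 in truth_t:
    d = np.abs(det_t - t0)
    if d.min() < 0.15:
        errors.append(d.min())

print(f"scheduled saccades : {len(truth_t)}")
print(f"detected events    : {len(events)} ({int(events['binocular'].sum())} binocular)")
print(f"recall             : {len(errors) / len(truth_t):.3f}")
print(f"median onset error : {1000 * np.median(errors):.1f} ms")
# A recall of 1.0 with single-digit-millisecond onset error means every
# scheduled rapid eye movement was recovered at its true time.
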