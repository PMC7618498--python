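# Methods

This note documents the models, parameter choices and numerical decisions
behind `binoc`, and what the synthetic-data validation does and does not
establish.

## Sign conventions

All eye positions live in a shared head-fixed frame in which positive
means rightward rotation for both eyes. Nasal (adducting) rotation is
therefore positive for the left eye and negative for the right; per-eye
nasal coordinates are obtained by flipping the right eye's sign.
Vergence is reported as `left − right` of the median post-saccadic
positions, which equals the sum of the two per-eye nasal positions:
positive for convergence, zero for a symmetric conjugate movement.
Post-saccadic *version* (the mean of the two positions) lateralizes
convergent saccades: positive version → rightward (ConvR).

## Saccade detection

Raw traces are interpolated to 100 Hz and low-pass filtered with a
zero-phase 2nd-order Butterworth at 1 Hz (zero phase preserves onset
timing; only the cutoff frequency is prescribed, the realization is a
package choice). Convolution with
a mean-zero antisymmetric step kernel of width 160 ms estimates local
displacement; peaks of its absolute value above a displacement-equivalent
threshold (default 1.5°, converted to convolution units via the measured
step response of the filter+kernel chain, so the threshold's meaning is
rate-independent) are coarse event times. Per-eye events within 100 ms
are paired greedily in time order (nearest partner wins); events within
300 ms of a retained predecessor are discarded (earliest wins).

A 1 Hz low-pass smears steps over roughly 0.4 s, so events closer than a
few hundred milliseconds merge at the coarse stage; all schedules the
generator produces space events ≥ 2 s apart, and the refractory rule
makes closer events unusable anyway.

Onset refinement interpolates a ±1 s segment to 500 Hz and smooths it
with LOWESS (span 80 ms), except where the 160 ms displacement
convolution exceeds 3° — putative saccades are left unsmoothed so their
slope survives. The product of 100 ms and 40 ms displacement convolutions
is thresholded inside a 400 ms window centred on the coarse peak; onset
is the first crossing of max(10% of the window maximum, 0.25 deg²). The
absolute floor rejects pure-noise windows, where a purely relative
threshold would always cross. For an ideal instantaneous step the wide
kernel anticipates the edge and the crossing occurs up to ~16 ms early;
for realistic minimum-jerk saccades the median onset error is ~8 ms.

Measures follow fixed windows: pre-saccadic position = median over 200 ms
before onset; max post-saccadic position = the sample within 200 ms after
onset deviating most from the onset position; median post-saccadic
position = median over 200 ms from that sample; cw/ccw velocity = max/min
of the central-difference derivative over 150 ms centred on onset. The
nine-metric descriptor is (amplitude L/R, max−median amplitude L/R,
cw/ccw velocity × L/R, vergence), winsorized to [P0.5, P99.5] and
z-scored per animal; zero-variance metrics are zeroed and flagged.

## Classification and the main sequence

Saccade types are the modal label of an event's 100 nearest reference
neighbours; ties break by summed inverse distance (deterministic). The
reference space is either a supervised UMAP embedding (Euclidean,
min_dist = 0.11, n_neighbors = 199, fixed random state) fit on a labelled
synthetic nine-metric set, or that 9-D normalized space directly. The
9-D route is the pipeline default: it is fast, exactly deterministic, and
equally accurate on synthetic data; no externally derived embedding ships
with the package. The reference sampler draws per-type kinematics from
the configured main sequences; its max−median entries are type-independent
noise because the generator's minimum-jerk steps never overshoot — a
reference model with a fictitious overshoot systematically displaced
optokinetic reset saccades in the normalized space.

The main sequence is V = Vmax(1 − e^(−A/A0)), fit by nonlinear least
squares (positive bounds; initial Vmax from the sample maximum). The fit
flags A0 as weakly identified when its relative standard error exceeds
0.5 or all amplitudes sit far above A0. Model comparison per eye uses the
Gaussian AIC, n ln(RSS/n) + 2k, with k = 2 pooled and k = 4 for the
type-specific pair; we report the per-eye ΔAIC, the fraction of eyes
preferring the two-model fit, the mean Akaike weight (an "AIC
percentage" summary admits either reading, so both are reported), and a
signed-rank p across eyes.

## zF standardization

Frames with motion error above 5 μm are replaced by linear interpolation
per ROI. Baseline is the per-ROI median. The noise denominator is a
high-frequency PSD estimate: the mean one-sided Welch power over the
upper quarter of the spectrum, converted to an SD. This estimator is
unbiased for white noise (a N(10, 2) trace yields noise ≈ 2) and ignores
slow calcium transients; it is the same idea as the baseline-noise
routines used by spike-inference toolboxes. Zero-noise (constant) traces
are flagged and floored at machine scale so zF stays finite. zF is
invariant to affine rescaling of the raw fluorescence.

## d′ and its permutation null

d′ pools every (event, frame) sample in a 2 s post-onset and 1 s
pre-onset window. If both variances vanish, d′ is 0 for equal means and
±100 otherwise (clipped). The null redraws onset frames uniformly over
positions where both windows fit, preserving the event count, 1000 times;
an ROI is active for a type if its observed d′ exceeds the null's 95th
percentile. Uniform redrawing can place shuffled windows closer together
than real inter-saccade intervals, which inflates the null spread
slightly and makes the test marginally conservative (measured type-I
error ≈ 4–5% on pure-noise ROIs at the default event density).

## Encoding model

The 33 regressors are: 4 saccade-onset one-hots (ConvL/ConvR/ConjL/ConjR
at the nearest frame), 2 rectified nasal eye positions (nasal-positive
position minus its experiment-wide median, temporal side zeroed), 8 swim
one-hots (direction × per-session vigour quartile), 2 grating-direction
indicators, 16 moving-spot one-hots (4 azimuth bins spanning −60° to
+60° × 2 directions × 2 contrast polarities — the bin count chosen to
make 18 stimulus predictors), and the motion-error trace. All but the
motion column are convolved with the CIRF h(t) = (1 − e^(−t/τon))
e^(−t/τoff), t ∈ [0, 5τoff], unit maximum, τon = 0.2 s, and shifted by
the frame offset.

Hyperparameters (τoff ∈ {3, 4, 5} s, offset ∈ {0..3} frames) are chosen
by exhaustive OLS; ROIs gate into ridge regression when the best OLS
R² > 0.05. Ridge standardizes the regressors, centres the response, and
selects λ from 13 log-spaced values in [10⁻³, 10³] by 10-fold
cross-validation on contiguous time blocks (contiguous folds limit
leakage through the CIRF's autocorrelation). cvR² is the pooled
out-of-fold R². ΔcvR² circularly permutes one regressor at a time by a
seeded random shift at least 10 frames from zero, refits with the same λ
and folds (Gram matrices are cached and updated per column, so the 33
refits cost one tall matrix-vector product each), and reports the change
in cvR². One permutation per regressor per ROI, with the shift recorded.

The tuned-classification null pools positive ΔcvR² values (random fit
improvements) across all gated ROIs and regressors, mirrored about zero;
at least 50 pooled values are required. Criteria: (i) most negative
ΔcvR² is oculomotor, (ii) some oculomotor ΔcvR² < −P95, (iii) motion
ΔcvR² > −P95. Signed comparison is the default; an absolute-value
variant is available. Duplicated (perfectly collinear) regressors each
show ΔcvR² ≈ 0 despite joint importance — a documented property of the
method, and the reason the synthetic schedule decorrelates spots from the
convergent saccades they evoke.

## Tuning metrics

Normalized saccade-triggered fluorescence (STF): 2 s post-onset sum of zF
minus its 1 s pre-onset mean, divided per ROI by the 95th percentile
across saccades (non-positive percentiles normalize by magnitude and
flag). Rectilinear fits scan 41 evenly spaced breakpoints; baseline is
the median of the values at or below the candidate, the ramp slope is
least squares on the remainder anchored at the baseline, and the ramp is
accepted only when its fitted excursion exceeds twice the baseline-only
RMSE (the 2×RMSE acceptance rule is a package choice and configurable). The saccade-type index matches each
conjugate adducting saccade to the nearest convergent saccade within
Euclidean radius 0.1 in normalized (post-position, velocity) space —
position normalized by the maximum nasal post-saccadic position, velocity
by the 95th percentile of nasal velocities — and takes the median
convergent-minus-conjugate STF difference; convergent saccades may serve
several conjugates (a without-replacement variant exists). OKR power
builds the median response per grating direction on a common epoch grid,
concatenates them into one alternation cycle and reads the one-sided PSD
at the alternation frequency 1/(2 T_epoch); any fixed PSD normalization
satisfies the ordering properties, and the metric is DC-invariant by
construction. PC1 standardizes (saccade-type index, OKR power) across
ROIs and projects on the first principal component, sign-oriented so the
index loads positively. Directionality preference sums ΔcvR² over the
leftward triple (LConj, ConvL, right-eye nasal position) versus the
rightward triple and takes the more negative; ties default leftward with
a flag.

## Perturbation metrics

Ablation deficits are post-minus-pre differences of per-animal medians of
post-saccadic position and peak speed, per eye and saccade type, with at
least 5 saccades per epoch per cell; both lateralized and pooled
(Conv/Conj) groupings are emitted so either pooling convention can be
consumed downstream. Across-animal tests report both signed-rank and
paired-t p values. The Conv−Conj residual is regressed on the median
saccade-type index of the manipulated cells by OLS (≥ 4 animals).
Optogenetic position change is the median over the 250 ms window ending
at stimulus offset minus the median over the 250 ms window ending at
onset, per eye; epochs shorter than 500 ms are rejected.

## Synthetic data: what it emulates, and what it does not

Saccades are minimum-jerk position steps whose duration is set so the
analytic peak velocity 1.875·A/T equals the type's main-sequence value —
so noiseless traces lie exactly on the configured curves. Defaults:
conjugate (Vmax = 700 deg/s, A0 = 6°) saturates; convergent
(Vmax = 1600 deg/s, A0 = 25°) barely saturates over the behavioural
range. These are configuration, not claims about any animal. Convergent
events relax back toward rest (τ = 4 s after a 0.8 s hold) — vergence is
transient in real animals, and the relaxation velocity (~2 deg/s) sits
far below detection threshold. OKR epochs alternate direction every 4 s
with a 2.5 deg/s slow phase and a reset saccade per epoch that exactly
cancels the drift. Moving spots sweep ±60° of azimuth and evoke a
lateralized convergent saccade with probability 0.6 at a jittered ~1.5 s
lag; spontaneous convergent saccades also occur. The stochastic response
and jitter are essential: if every spot deterministically preceded a
convergent saccade, the spot and saccade regressors would be collinear
and circular permutation would (correctly) assign neither unique
variance. Swim bouts are Poisson (0.1 Hz) with a positive lognormal
"vigour" scalar; vigour quartiles are computed per session. Ground-truth
convergent laterality follows the operational definition (sign of the
noiseless post-saccadic version), so it agrees with what the analysis
measures even when the eyes start off-centre.

Fluorescence is baseline + weights·regressors + Gaussian noise, with
per-class effect sizes expressed per unit regressor SD in units of the
calcium noise SD (2–3 for driving regressors), generated with the true
CIRF at τoff = 4 s and offset 2 frames. Motion error is 0–2 μm baseline
jitter with ~1%-of-frames excursions to 6–10 μm, which exercises the
> 5 μm interpolation rule. ROI classes: mrmn_both (convergent + one
conjugate direction + position), mrmn_conv (convergent only), inn_like
and lrmn_like (one conjugate direction + position), locomotor (swim
one-hots), motion_artifact (motion column), silent.

The generator does **not** emulate: measurement point-spread or
segmentation errors, slow fluorescence drift or bleaching, non-Gaussian
or correlated noise, saccade-velocity measurement bias of real video
trackers, eye-position-dependent noise, or any anatomical structure.
Passing the synthetic suites therefore demonstrates internal
correctness — each stage recovers what the generator planted, at
realistic noise — not robustness to every artifact of real recordings.

## Problem sizes and determinism

Validation runs use 5–10-minute sessions at 60 Hz eye rate and 4.8 Hz
imaging, 200-saccade detection runs, 20-seed Monte-Carlo checks for the
statistical calibrations, and 42-ROI sessions for the encoding
confusion analyses; these sizes give stable statistics while keeping the
whole suite around a minute of compute. All randomness flows from
explicit integer seeds through `numpy.random.Generator`; the pipeline
spawns per-stage seeds from one master seed, records the config hash and
seed in every output, and reruns are byte-identical. The UMAP route is
deterministic given its fixed random state but slower; the default
9-D kNN route is exactly reproducible and used everywhere speed matters.

## Known limitations

- The coarse detector cannot separate events closer than ~0.5 s (1 Hz
  low-pass); real data with saccade bursts would need a higher cutoff.
- Measured peak velocities at a 60 Hz eye rate underestimate the true
  peak (finite differencing of an undersampled waveform); per-session
  z-scoring absorbs this for classification, but absolute velocity fits
  should use 300 Hz traces.
- The ΔcvR² attribution is blind to variance shared among collinear
  regressors; interpretation must respect the design's correlation
  structure.
- The d′ permutation null is slightly conservative at high event density
  (overlapping shuffled windows).
- The saccade-type index is undefined for ROIs whose sessions contain no
  kinematically matched pairs; it is reported missing, never imputed.
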