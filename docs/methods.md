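# Methods

This note documents the models, parameter choices and numerical decisions
behind `ipdr`, and what the synthetic test bed does and does not establish
about real data.

## Signal model and units

The canonical record is a uniformly sampled 6-axis sequence at a nominal
200 Hz: accelerometer in m/s², gyroscope in deg/s.  Degrees per second are
canonical because every gait threshold in the pipeline (the 0.6 deg/s
zero-velocity rule, the 1 deg/s stillness ceiling) is naturally stated in
them; radians appear only inside the strapdown integrator.  Unit conversion
(g → m/s², rad/s → deg/s) happens once at load time.  Non-uniform
timestamps are linearly resampled onto a uniform grid; single-sample
dropouts (NaN runs ≤ 0.1 s) are linearly interpolated and logged, longer
gaps are an error — there is nothing defensible to integrate through.

Gyroscope bias is modelled as constant per recording and estimated as the
per-axis mean over a standing-still interval — user-supplied, or
auto-detected as the longest quiet prefix (per-axis std < 1 deg/s, grown in
0.5 s blocks).  The minimum interval is 2 s (configurable); ≥ 10 s is
recommended and is the synthetic generator's default lead-in.  The mean
accelerometer norm over the same interval provides the local gravity
magnitude and is rejected outside [9.0, 10.5] m/s².

## Synthetic gait generator

The generator is "inverse strapdown": an exact foot trajectory is laid
down first, then differentiated into body-frame signals.

* **Stride structure.** Swing then stance.  Stance: position and yaw
  constant, velocity exactly zero.  Stance fraction 0.6 for walking, 0.4
  for jogging/running (defaults; configurable in (0.1, 0.8)).  Default
  stride times/lengths: walk 1.0 s / 1.4 m, jog 0.8 s / 2.0 m, run
  0.7 s / 2.4 m — ordinary adult values.
* **Swing kinematics.** Forward velocity is a raised cosine (displacement
  `L·(τ − sin 2πτ / 2π)`), vertical lift a raised-cosine bump (0.15–0.30 m
  by activity); both are C¹ against the flat stance.  Heading changes
  blend smoothly during swing while the displacement vector uses the
  stride's heading, so closed paths close exactly by construction.
* **Sagittal pitch.** The swing angular rate is
  `r(τ) ∝ −sin²(πτ)(cos 2πτ + ½)`: a negative dip after the foot leaves
  the ground, a dominant positive peak at mid-swing, a negative dip before
  heel strike, zero net rotation per stride.  Its zero-crossing before the
  peak (τ = 1/3 of swing) is the ground-truth Toe-Off; Heel-Strike is the
  first stance sample; Mid-Stance the stance centre.  Peak pitch
  amplitudes default to 35°/55°/70° for walk/jog/run: swing durations are
  similar across gaits, so the roughly-doubled peak angular rate of
  running relative to walking must come from amplitude, as it does in real
  foot-mounted recordings.
* **Stance micro-structure.** Two small zero-net pitch dips (default 4°)
  occupy the first 25% (loading response) and last 20% (pre-swing) of
  stance.  Without them a perfectly flat stance makes the minimum-energy
  definition of Mid-Stance degenerate — every stance window ties at zero.
  The foot's position stays fixed (rotation about the sensor point), so
  stance remains a true zero-velocity interval.
* **Exactness.** Ground-truth velocities are forward differences of the
  positions; the synthesized gyroscope is `log(C_kᵀC_{k+1})/dt` and the
  specific force `C_kᵀ((v_{k+1}−v_k)/dt + g)`.  These are precisely the
  inverses of the first-order strapdown update, so the noise-free round
  trip is exact to floating-point rounding — integrator correctness is
  tested against machine precision, not against a tolerance hiding model
  mismatch.
* **Noise.** Additive white noise (defaults: accelerometer 0.05 m/s²,
  gyroscope 0.2 deg/s) plus a constant gyroscope bias (default 0.5 deg/s
  per axis), all driven by one integer seed; optional ±10%-range
  per-stride time/length jitter (5% used in the tests).

**What the generator does not emulate:** physiological joint kinematics,
sensor scale-factor and misalignment errors, bias instability/random walk,
soft-tissue and impact artefacts, vibration at heel strike, magnetic or
temperature effects, and non-stride movements (shuffling, side steps,
sitting down).  Passing tests therefore demonstrate algorithmic
correctness and noise robustness under this model, not field performance
on arbitrary hardware; the real-data error budget is dominated by exactly
the unmodelled terms above.

## Stride templates and msDTW

Templates are 200-sample gyroscope-z waveforms: each labelled stride is
linearly interpolated onto a 200-point grid spanning the full stride
(endpoints preserved) and averaged sample-wise.  Linear interpolation
introduces no ringing and matches the sample-by-sample averaging.  Stride
boundaries run dip-to-dip (the negative valley before the swing phase),
so templates begin and end negative.  Shipped defaults are generated from
the synthetic model; users with labelled data should build their own.

The segmenter computes the subsequence-DTW accumulated cost matrix
(template rows, signal columns; first row = local cost only so matches may
start anywhere) with local cost |Δ| and steps {(1,1),(1,0),(0,1)},
unweighted.  Start columns are propagated alongside the costs
(predecessor ties break diagonal > up > left).  Candidates are local
minima of the last row at or below the threshold (plateaus collapse to
their leftmost index), length-limited to [M/4, 2M] against degenerate
warps, and accepted greedily in ascending (cost, start) order without
overlap.  Both signal and template are divided by the template's
max-absolute value before costing, making the threshold scale-free; the
default threshold of 25 was calibrated with `sweep_threshold` on noisy
synthetic bouts of all three activities, where the F-score plateau spans
roughly 5–30 and false positives (template warps onto flat low-rate
stretches) appear above ~33.  A historical threshold of 65 presupposes an
unstated normalisation and is retained only as documentation
(`LEGACY_THRESHOLD`).  The brute-force oracle used in the tests recomputes
every per-end best cost by classic boundary-anchored DTW over all windows
— an O(N²M) independent route that the production DP must match exactly.

## Gait events

**Toe-Off**: the last zero-crossing (`s[i−1] ≤ 0 < s[i]`) at or before the
*global* maximum of the stride.  Anchoring on the global peak rather than
the first crossing is what makes the detector robust to the early positive
blips of jogging/running strides.  If no crossing precedes the peak the
stride start is returned flagged low-confidence; a stride with no positive
sample raises an error.

**Mid-Stance**: the stride is interpolated to 200 samples; the search is
restricted to [global max, 160] (stance occupies the last ~60%/40% of the
stride, so MS lies before the 80% mark); Heel-Strike is that portion's
global minimum; from HS to 160, 20-sample windows with 10-sample overlap
are scored by Σs², earliest window wins ties (deterministic, and earlier
is closer to foot-flat); the window centre maps back to the nearest
original sample.  If HS falls within one window of the 80% bound the
window is slid back so exactly one fits.

**Restitching**: TO is detected inside every msDTW segment; strides span
consecutive TOs.  Every TO starts a stride — the terminal stride runs to
the end of the signal, so the bout's final stance (and with it the
closed-loop endpoint) is kept.  Spans over 2 s (standing, sitting) are
truncated to their first 1.5 s, scaled by the actual sampling rate;
strides under 40 samples are dropped.  On a truncated terminal stride the
minimum-energy window can land in the trailing stand-still rather than in
stance; this is positionally harmless (the filter holds position constant
there) but is why event-detector scores are evaluated on per-stride
windows.

## Activity classification

1 s windows, 50% overlap; per axis: trapezoidal integrals of accelerometer
(gravity deliberately left in — a shared offset) and gyroscope, plus both
energies — 12 features.  Features are z-scored from the training set
(kernel stability); the default estimator is an SVC with a third-order
polynomial kernel, C = 10 (chosen once on synthetic data; C = 1
underfits the phase-jittered window population).  Bout label = majority
vote, ties toward the slower activity.  The backend is pluggable
(anything with fit/predict).  Published headline accuracies for this kind
of classifier are dataset-bound; the synthetic 10-fold CV figure (~0.98)
only shows the feature/ model pairing separates the generator's classes.

## Strapdown and the ZUPT error-state filter

First-order propagation at the IMU rate with the exact Rodrigues
exponential for attitude; position integrates the pre-update velocity
(matching the generator's forward differences); attitude re-orthonormalised
(SVD projection) every 100 steps.  Initial attitude: minimal rotation
taking the mean static accelerometer direction to nav +z (gravity
levelling), yaw 0 — absolute heading is unobservable without a
magnetometer, so trajectories are reconstructed up to a planar rotation,
which leaves closed-loop RPE unchanged.  Gravity magnitude comes from
calibration, not a constant.

The 9-state error filter (attitude error φ, velocity error δv, position
error δp, navigation frame) propagates
`δv ← δv − [f_nav]× φ dt`, `δp ← δp + δv dt`, with process noise
`diag(σ_w², σ_a², 0)·dt²` and defaults σ_a = 0.01 m/s², σ_w = 0.01 rad/s.
At every zero-velocity sample the strapdown velocity is the measurement of
δv (H = [0 I 0], R = σ_v² I); the posterior error is fed back
(C ← exp(−[φ̂]×)·C, v −= δv̂, p −= δp̂) and reset.  Updates are applied at
every sample inside a zero-velocity run — standard practice, and each
update is individually consistent.  The covariance is symmetrised after
each update and monitored for loss of positive semidefiniteness.
P₀ = 10⁻¹⁰·I: the start is known (origin, level, at rest).

Zero-velocity detection: walking uses ‖ω‖ < 0.6 deg/s with a 3-sample
minimum run length to suppress single-sample chatter; jogging/running use
MS ± 5 samples (11 samples, 50 ms per side at 200 Hz).  σ_v defaults to
0.01 m/s; `sweep_sigma_v` evaluates 0.001…0.050 m/s in 0.001 steps against
a known endpoint and returns the minimiser (ties to the smaller value)
plus the full table.

## Trajectory and metrics

Stride positions are the planar navigation positions at the MS events;
SL_k is the planar norm of the increment from the previous MS (the start
position seeds the first increment), heading its atan2; total distance is
the sum of stride lengths by construction.  Event scoring matches
detections to truth events greedily nearest-first, one-to-one, within
±15% of the stride's sample count (fraction configurable).  RPE is the
planar distance from the final stride position to the known endpoint,
also as % of total distance (undefined at zero distance).  SOT tests each
MS point against the union of corridor polygons (shapely; boundary counts
as inside; invalid polygons rejected).

## Problem sizes in the shipped experiments

Round trips use ≥ 100 m closed square loops per activity; the ZUPT
experiment uses a 151 m walking loop over 20 noise seeds; oracle
comparison 100 random cases (signals ≤ 400 samples, templates ≤ 60);
event recovery 500 strides per activity at zero and 2 deg/s gyroscope
noise; the σ_v sweep a 28 m loop over the full 50-point grid.  These sizes
make the whole study reproducible in about a minute on one CPU while
keeping every statistical margin wide.

## Known limitations

* Constant-bias gyroscope model; no in-run bias tracking (no bias states
  in the filter).
* Yaw is unobservable; long one-way (non-loop) paths accumulate heading
  drift that ZUPT cannot correct.
* The msDTW threshold, although scale-free, was calibrated on synthetic
  morphology; real templates from a different sensor placement may need a
  re-sweep.
* Terminal-stride Mid-Stance is ill-defined when a bout ends in a long
  stand-still (see restitching above).
* The activity classifier ships untrained for real data; training on the
  synthetic generator transfers its idealisations.
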