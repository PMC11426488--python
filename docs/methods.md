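# Methods

`plumekin` implements a pipeline for asking how turbulent odor-plume
encounters modulate the head motions and heading of a freely searching
rodent. The inputs per trial are a head-mounted metal-oxide gas-sensor
voltage trace, a head-mounted 3-axis accelerometer trace, per-frame
nose/neck/body keypoints from a pose estimator, and arena metadata (odor-port
location, arena bounds, in-arena interval). The outputs are peri-encounter
time courses and statistics of head-pitch band power, head height, dominant
pitch frequency, body angle to the source, and head-yaw dynamics, each
compared against a surrogate (random-window) null.

## Plume-encounter detection

A metal-oxide sensor responds to an odor filament with a fast rise and a very
slow decay. We model the response as a unit-area difference of exponentials

    k(t) = (exp(-t / tau_decay) - exp(-t / tau_rise)) / (tau_decay - tau_rise),

with `tau_rise = 0.02 s` and `tau_decay = 10 s`. The raw trace is first
low-passed (zero-phase 4th-order Butterworth, 5 Hz cutoff), then deconvolved
by regularized frequency-domain division,

    X_hat(f) = Y(f) conj(K) / (|K|^2 + reg * max|K|^2).

Numerical choices:

* `reg = 1e-10` (relative Tikhonov floor). The 5 Hz low-pass already bounds
  noise amplification, so the regularizer can be small enough that the
  noiseless round trip (re-convolving the deconvolved trace) is accurate to
  a few 1e-4 of the signal range and a deconvolved kernel concentrates
  >99% of its mass in the first 3 samples.
* The sampled kernel support is 100 s (10 decay constants); shorter supports
  leave a truncation transient of order `exp(-support/tau_decay)`.
* The trace is edge-value padded by 5 s before the FFT. The inverse filter
  is approximately a second-order differential operator, so the implicit
  step between a nonzero sensor baseline and zero padding would otherwise
  deconvolve into enormous boundary spikes that dominate the min-shift used
  by the detector.

Detection works on the cumulative sum C(t) of the deconvolved signal,
shifted so its minimum is zero plus a small epsilon (1e-5); this makes C
strictly increasing, keeps every least-squares slope positive, and makes the
detector exactly invariant to DC offsets of the raw trace. At each sample
the ratio r(t) of the OLS slope of C over the following 1 s to the slope
over the preceding 1 s is formed. A maximal run of `r(t) >= threshold`
triggers one event.

Onset localization: the forward slope window looks one second ahead, so the
run *starts* up to a second before the underlying concentration rise — for
any threshold low enough to be sensitive, the first supra-threshold sample
is a biased onset estimate. The reported onset is therefore the sample of
the largest deconvolved-signal increase inside the triggering forward window
`[run_start, run_start + slope_window]`, which coincides with the
concentration rise (median error ~0.01 s on synthetic data) while the ratio
run alone determines *whether* an event is declared. The literal
first-sample rule is available (`detect_events(..., refine=False)`).

The threshold is dimensionless. The shipped default (1.3) sits between the
largest slope ratio observed on 50 minutes of blank recordings (~1.09) and
typical event peaks (~3); the principled route is `calibrate_threshold`,
which bisects for the smallest threshold whose event rate on pooled blank
(animal-free) recordings does not exceed a target false-positive rate
(default 0.1/min).

Event filters, applied in order per onset with only retained events
anchoring the separation chain: (edge) a full ±5 s window must fit in the
in-arena interval; (separation) an onset within 5 s of the previous retained
onset is dropped ("first kept" — the alternative reading, merging close
events, is not used); (proximity) the body keypoint at the nearest frame
must be more than 15 px from the port (about one adult mouse body length;
the nearest confident frame within 0.5 s substitutes when the frame is
masked).

## Head motion

Accelerometer volts are calibrated to g per axis as `(V - offset)/scale`,
low-passed at 20 Hz (zero-phase), and differentiated (central differences)
to jerk, which removes the gravity DC and whitens the oscillation spectrum.
The gravity-aligned X channel carries head pitch.

Time-frequency analysis uses an analytic Morlet wavelet applied in the
frequency domain, `psi_hat(omega) = 2 exp(-(s*omega - omega0)^2 / 2)` for
`omega > 0`, `omega0 = 6`, on 48 log-spaced frequencies over [0.5, 25] Hz.
The amplitude normalization preserves tone amplitude across scales, so
equal-amplitude oscillations at different frequencies give equal |W| and
the in-band argmax ("dominant frequency") is meaningful. Band power is the
mean of |W|^2 over the 5–14 Hz active-search band. Edge effects are handled
by zero-padding to twice the length; tests evaluate interior samples.

Head height is the difference of 1-s centered moving medians of the Z and X
channels (truncated windows at the edges). The pooled distribution of this
difference across trials is fit with 1-D Gaussian mixtures (EM, 10
restarts, fixed seed); BIC is reported for k = 1..5 but the selected model
size is fixed at 3 — in this kind of data BIC drops substantially up to
three components and only marginally beyond, and the three-component model
carries the raised/lowered interpretation. The head-raised threshold is
mean − SD of the component with the largest mean; samples above it are
"raised".

## Kinematics

Keypoints with pose likelihood below 0.9 (strictly) are masked; a frame
missing any required keypoint is invalid for that angle. All angle math is
atan2 of planar cross/dot products. Image coordinates have y pointing down;
signs are defined so that the on-screen (overhead-camera) conventions hold:

* body angle: with midpoint m of neck and body, heading h and port direction
  p = port − m, the angle is positive when h is clockwise of p on screen,
  zero when the animal is aimed at the port. The heading is the *forward*
  vector m − body. The verbal definition "vector connecting the mid-point
  with the body" literally points backward, which would score a port-facing
  animal as 180°, contradicting the small post-encounter mean angles this
  analysis is designed to show; the backward reading remains available via
  `body_angle_forward = false`.
* head yaw: angle between nose − neck and the forward body axis neck − body;
  egocentric left turns positive, right turns negative.

Yaw zero crossings are sign changes between consecutive valid frames (an
exact 0° takes the following sign; changes across masked gaps are not
counted), with linearly interpolated crossing times.

## Peri-event statistics

Real trajectories are the ±5 s windows (nearest-sample lookup, no
resampling) around retained onsets. Surrogate ("random") trajectories
resample the same trial: one surrogate per real event, its t = 0 drawn
uniformly from in-arena times with full window support, excluding ±1 s
around any real onset (real onsets may still fall elsewhere inside a
surrogate window). Matching per-trial counts keeps each animal's
contribution to the real and surrogate distributions equal.

Per-bin comparisons take each trajectory's mean within 1-s bins tiling
[−5, 5) (missing samples excluded; an all-missing bin stays missing) and
compare real vs. surrogate distributions per bin with the two-sample
Kolmogorov–Smirnov test (asymptotic p; a permutation variant is provided
and used as the test oracle; bins with fewer than 5 values per side are
flagged, not fatal). No multiple-testing correction is applied across bins
— the per-bin grid itself is the result.

Circular statistics: mean angle and resultant-vector strength R are the
argument and modulus of the mean unit vector. Angular deviations are
wrapped differences in (−180°, 180°] from each window's before/after
(3 s) circular mean. The before/after R values of each window are compared
with the paired Wilcoxon signed-rank test (exact null for ≤ 25 pairs,
normal approximation with continuity correction above).

The 0°-crossing analysis computes, per window, a rolling crossing rate
(0.5 s centered window, evaluated only where the full window fits inside
±5 s, avoiding edge artifacts), z-scores it against the window's own mean
and SD (a window with zero crossings is excluded and counted; an exactly
constant rate z-scores to flat zero), and averages across windows with SEM.
The z-curves also enter the per-bin KS grid as a fourth parameter.

## Synthetic world

The generator (`plumekin.synthetic`) produces the four streams with exact
ground truth. What it emulates, and what a green test does and does not
establish:

* Encounter times are scheduled — Poisson with a refractory of twice the
  minimum event separation — not emergent from plume physics. Tests
  therefore validate detection and peri-event statistics, not plume
  modeling.
* Each encounter is a boxcar concentration pulse of fixed area (1 V·s) and
  0.3 s dwell (an odor filament passage) through the sensor kernel, plus a
  slow sinusoidal drift (amplitude 0.025 V = 5× noise SD, period 60 s,
  emulating the sensor's temperature sensitivity) and white noise
  (SD 5 mV) on a 0.5 V standing baseline. Real plumes deliver a broad
  distribution of filament sizes and overlapping whiffs; detector
  recall/precision figures hold for this stated world, not universally.
* The pitch channel oscillates at a base 8 Hz with a slow
  Ornstein–Uhlenbeck frequency wander (SD 1 Hz, tau 2 s) and a −1 Hz offset
  while the head is raised, amplitude 0.1 g, over a raised/lowered gravity
  baseline with exponential dwells; Z carries the complementary projection
  plus 30% of the oscillation, Y is noise (SD 0.02 g per channel).
* The trajectory is a correlated random walk steered at the port (heading =
  angle-to-port + AR(1) noise, stationary SD 40°, correlation time 0.5 s,
  speed 60 px/s ≈ 0.2 m/s at ~300 px/m) in a 600×270 px arena. Reaching
  the port (25 px) returns the animal to the entry, mirroring the real
  protocol in which a trial ends at the source and the animal restarts; a
  sinusoidal head-yaw wobble (25°, 2 Hz) plus jitter rides on the heading;
  2% of frames are likelihood-0.5 dropouts.
* Injected effects mirror the phenomena under study, with windows
  configurable: pitch amplitude ×1.5 in [−1, 0) s and ×0.6 in [0, 1) s;
  +2 Hz pitch frequency, −0.15 g head height, and heading-noise SD ×0.3 in
  [0, 3) s. Effect *magnitudes* are package assumptions (the source
  analyses report per-bin significance, not effect sizes). `null_mode`
  injects nothing and is the calibration target for the surrogate
  framework.

Randomness uses numpy PCG64 (`default_rng`); cohorts spawn per-trial
`SeedSequence` children from one master seed, so generation is bit
reproducible across platforms.

## Known limitations

* The sensor forward model is linear; real metal-oxide chemistry saturates
  and its gain drifts with humidity/temperature beyond the sinusoidal drift
  emulated here.
* Acquisition rates (100 Hz sensor/accelerometer, 30 fps video) are
  declared defaults, not measured values; all computations are
  rate-parameterized.
* The onset-refinement rule assumes events appear as rises in the
  deconvolved signal; purely decreasing "offset" events would be localized
  at their steepest rise instead.
* KS p-values per bin are asymptotic and treat per-trajectory means as
  independent; windows from the same trial can overlap. Null-calibration
  tests bound the practical impact (per-parameter type-I rates 0.035–0.057
  at alpha 0.05 over 200 synthetic cohorts).
* Head-state classification feeds reporting (raised/lowered epochs) but the
  per-bin head-height comparison uses the continuous Z−X signal, so GMM
  misfit cannot bias the main statistics.
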