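# Methods

This note documents the models, parameter choices and numerical conventions
behind crowdfix, and what the synthetic-data tests do and do not establish
about real data.

## Stimulus dynamics

All geometry is in degrees of visual angle, screen-centered, x-right/y-up;
pixels-per-degree conversion is an I/O concern only.

**Crosshair.** Stationary mode pins the crosshair at the center.  Dynamic
modes move it counterclockwise on a circle (radius 0.5 deg, path speed
0.4 deg/s, hence angular speed 0.8 rad/s), starting each trial at a random
phase.  Position is evaluated in closed form per frame, so the orbit radius
is exact at every frame and the discretized path speed differs from
0.4 deg/s only by the chord-vs-arc factor sin(x)/x ≈ 1 − 7×10⁻⁶ at 60 Hz.

**Distractors.** "Brownian motion with an instantaneous speed of 1.1 deg/s"
pins the per-frame step length (speed × frame duration), not the step
distribution; we implement a fixed-magnitude step in a uniformly random
direction each frame.  Distractor motion is defined in crosshair-relative
coordinates (the swarm rides with the crosshair), which makes the 1-deg
confinement well defined while the crosshair moves.  Update order within a
frame: advance crosshair → rigid advection of distractors → Brownian steps
→ pairwise repulsion → confinement.  Confinement projects an escaping
distractor radially back onto the 1-deg boundary (deterministic clamp;
reflection/resampling alternatives were rejected for determinism).  The
inverse-square repulsion h = g·t/d² (g = 0.25 deg³/s) diverges for
coincident distractors; distances are floored at 0.05 deg (one line
thickness), which bounds the step while preserving the equal-and-opposite
structure, so the summed repulsion field is exactly zero every frame.
Initial placement is uniform in the confinement disk, resampled until all
pairs are ≥ 0.1 deg apart.  Distractors repel each other only; the
crosshair path is never perturbed.

## Trial engine

The hotspot test is boundary-inclusive (distance ≤ 0.15 deg): "inside" does
not resolve the open/closed distinction, and inclusivity gives the weaker,
more forgiving convention.  The required continuous-tracking duration is
drawn uniformly from 0.75–1.25 s at trial start and redrawn after every
tracking break.  The 30-s skip clock accumulates total time spent in the
Track phase (on- or off-crosshair); when it elapses without a completed
run, the trial is marked skipped.  Skipped trials update no staircase and
do not consume their side's quota: the side is re-queued, so a completed
block always contains exactly 35 left and 35 right trials.  The side
sequence is a random permutation of 35 L + 35 R fixed at block start, which
guarantees the exact split (per-trial coin flips would only approximate
it).  The View interval is round(0.150 s × 60 Hz) = 9 frames with the
crosshair frozen and cursor/distractors hidden; the Respond interval logs
the frozen crosshair position as the fixation reference even though the
crosshair is no longer displayed.  Responses are collected untimed; a
configurable Respond duration (default 0.5 s) exists for log realism only.

## QUEST

Discrete posterior over log₁₀ threshold spacing on a grid from −1.0 to 1.3
(0.1–20 deg) in steps of 0.005, with a Gaussian prior (mean log₁₀ 3 deg,
sd 0.5).  The psychometric function is the Weibull form
γ + (1−γ−δ)(1−exp(−10^{β(x−T)})) with γ = 1/9 (9AFC), δ = 0.01, β = 2.3 —
the slope and lapse are conventional defaults for letter identification and
are configurable; threshold estimates therefore match the procedure in
structure, not in any lab's particular constants.  Trials are placed at the
posterior mean (a mode variant is available), and the block threshold is
the 53rd posterior quantile, computed as a left-continuous inverse CDF on
the grid (smallest grid value whose cumulative mass reaches q).  The
exponent is clipped at ±30 before exponentiation, which leaves the function
exact to double precision everywhere it is not already saturated.  Bouma
factors are threshold spacing divided by eccentricity; values below 0.096
are classified abnormal with a strict inequality (0.096 itself is normal).

## Gaze pipeline

Gaze is linearly interpolated onto the 60-Hz frame clock after blink
detection, which runs on the native-rate stream using central finite
differences.  A sample belongs to a blink when speed > 1000 deg/s or
distance from the (interpolated) crosshair > 20 deg; contiguous flagged
samples merge into intervals, padded by 100 ms each side, and overlapping
padded intervals merge.  Each padded span is replaced by the constant gaze
value 100 ms after its padded end, or 100 ms before its padded start for
blinks at the end of a trial; a blink spanning the whole trial marks it
unusable rather than silently filled.  Replacement is idempotent because
the source sample lies outside every padded span.

Drift correction subtracts the mean gaze-minus-crosshair **deviation** over
the last 400 ms of Track from the whole trial.  Subtracting mean raw gaze
would inject the crosshair's own path under dynamic fixation, whereas
calibration drift — the quantity being removed — is a quasi-constant offset
in deviation space; the deviation reading preserves the correction's
purpose.  Trials whose Track phase is shorter than 400 ms are excluded with
an explicit error.

RMSE curves align trials at View onset (Track at negative time) and keep a
frame offset only when at least 80% of trials contribute, so the curve is
not dominated by the few trials with unusually long Track phases.  Relative
curves are pointwise ratios on the common support, with zero-reference
frames excluded under a warning.  Fixation breaks scan View frames by
default (a Track-inclusive switch exists, since whether anticipatory-saccade
screening should scan Track is ambiguous); break percentages are monotone
non-increasing in tolerance by construction, and reported integers use
half-up rounding (6/70 → 8.57% → 9%).  Group summaries are geometric means
with a seeded percentile bootstrap (default 10,000 resamples; 16th/84th
percentiles for the 68% level), resampling sessions with replacement.

## Synthetic observer

The observer generates the three behavioral streams from explicit latent
truth, enabling parameter-recovery tests:

* cursor = crosshair lagged 2 frames + isotropic Gaussian noise
  (sd 0.03 deg) — comfortably inside the 0.15-deg hotspot, so trials
  initiate reliably;
* gaze = pursuit gain 1.0 × crosshair + per-trial calibration drift (random
  walk, step sd 0.05 deg) + Gaussian noise (sd 0.10 deg); in Respond, gaze
  saccades to the true target location (a harmless response saccade);
* with probability `p_peek` a trial contains an anticipatory saccade: an
  instantaneous horizontal step (amplitude ~ N(3, 1) deg floored at 0.5,
  random sign uncorrelated with target side) from its onset
  (~ N(−50, 50) ms relative to View onset, clipped to ≤ +50 ms so it always
  overlaps the stimulus window) until View end;
* blinks arrive as a Poisson process (2/min default) lasting 300 ms, drawn
  as instantaneous 30-deg downward excursions, tripping both detection
  criteria; overlapping draws are merged into one blink in the truth record;
* responses follow the same Weibull model as QUEST with threshold
  log₁₀(bouma_true × eccentricity); when a peek's sign lands on the target's
  side, the effective eccentricity shrinks by the peek amplitude (floored at
  1 deg).  That effective-eccentricity mechanism is the simplest model that
  makes peeking reproduce implausibly low thresholds; it is a modeling
  choice, not an empirical claim.

Saccades are instantaneous position steps — no main-sequence dynamics —
which suffices because every metric in scope thresholds positions, not
velocities (blink detection sees the instantaneous jump as unbounded
speed).  The noise, lag, drift and blink constants are fixtures chosen as
realistic for a cooperative adult with a mouse and a research-grade
tracker; they are not fitted to any dataset.  Consequently, passing tests
demonstrate that the algorithms are correct and mutually consistent and
that the pipeline recovers known generative truth; they do not certify
performance against human idiosyncrasies (smooth-pursuit catch-up saccades,
partial blinks, asymmetric noise) that the generator does not emulate.

## Problem sizes and determinism

All randomness flows from explicit seeds (`numpy.random.Generator`); the
same seed yields byte-identical logs.  The test suite uses desk-scale
sizes chosen as its own design: 10⁵ frames for the confinement sweep, 200
seeded 35-trial staircases for threshold recovery (median absolute error
< 0.1 log₁₀ units), 50 seeded 70-trial sessions for end-to-end Bouma
recovery (median within 15% of truth), and 6 sessions per peek level for
the peeking-direction check.  Group-level human results (relative RMSE
percentages, per-participant threshold distributions) depend on a 20-person
sample and are out of scope for desk-scale verification.

## Known limitations

* The eye-tracker stream is simulated at 100 Hz; real 1-kHz recordings are
  accepted by the same pipeline but are not emulated.
* No font rendering: letters are identities plus geometry.
* The psychometric slope/lapse and the QUEST prior are conventions, so
  absolute threshold estimates carry those assumptions.
* Fixation-break screening of Track frames, and the open question of
  whether drift correction should use raw gaze rather than deviation, are
  resolved by documented switches/choices rather than empirical evidence.
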