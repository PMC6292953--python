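# Methods

This note documents the models, algorithms, parameter choices and known
limitations of the steptime package: what each stage computes, why the
defaults are what they are, and what the synthetic-data generator does and
does not emulate.

## The stepping task and its measurement chain

The task: a player stands at the centre of a circle of six numbered tennis
balls and taps them with the feet in the order of a projected digit series
(left foot for digits 1/3/5, right foot for 2/4/6), repeating the series as
fast and accurately as possible for 20 s.  Performance is scored from the
tap sequence; movement quality is quantified from 120 Hz 3D trajectories of
the knee, ankle and toe markers of each leg over the window from trial
start to the sixth tap.

The chain is: gap filling → trial validation → zero-phase smoothing →
tap detection and scoring → kinematic outcomes → mixed-design statistics.
All positions are in millimetres in a right-handed lab frame with z
vertical; frames are 0-based and windows half-open.

## Synthetic trials

Each point-to-point foot transport follows a minimum-jerk profile
(normalized position 10τ³ − 15τ⁴ + 6τ⁵), the standard model for smooth
goal-directed movement.  Its speed is a single bell with peak 1.875·A/T for
amplitude A and duration T, so a clean transport contributes exactly one
movement unit — an analytic ground truth that real recordings lack.  The
vertical lift arc is parameterized by *path* fraction, not time, so every
velocity component vanishes at both ends of a transport and the
single-peak property survives.

Geometry defaults (the task layout gives the shape but not dimensions, so
these are declared, not inferred): circle radius 550 mm; odd-digit balls on
the left half-plane, even on the right, 60° apart; ball-contact height
35 mm; stance offset ±100 mm from the centre; toe lift 60 mm.  The knee and
ankle markers move as scaled copies of the toe displacement (0.35 and 0.85)
at their resting heights — adequate for testing the measurement chain,
not a biomechanical joint model.

Timing defaults: transport duration 0.75 s and dwell 0.2 s, which place the
sixth tap at 5.5 s and fit 21 taps into a 20 s trial, matching the scale of
a quick six-step sequence in this population.  The digit series repeats
cyclically; each move's planned contact time is the transport arrival,
recorded to the frame.

**Planted sub-movements.**  Corrective sub-movements are planted as one-way
minimum-jerk adjustment steps executed immediately after target arrival
(alternating x/y directions, peak speed `submovement_amplitude_mm_s`,
default 120 mm/s, duration 0.2 s).  Because speed returns to the noise
floor between the transport pulse and each adjustment step, every planted
step adds exactly one movement unit and the first-contact time is
untouched; the per-move ground-truth window spans transport onset to
arrival plus the planted pulses.  (A pulse overlapping the transport's
deceleration was considered and rejected: it shifts the first-contact time
and makes the planted unit count depend on the amplitude ratio, destroying
the exactness of the ground truth.)  Pulses that would not complete before
the trial ends are not planted.  The net offset of the steps stays well
inside the contact radius, and the next transport starts from the offset
position, so contacts remain exact for every later target.

Sensor noise is i.i.d. Gaussian per axis, default 1 mm — the positional
accuracy class of optoelectronic systems.  This is a deliberately harsh
model: real marker jitter is temporally correlated and usually smaller
frame-to-frame, while calibration bias (the dominant 1 mm term in practice)
is smooth and harmless to derivatives.  Consequences are quantified below.
Marker dropout is planted as explicit gaps ((marker, start, length)
triples) and via `n_corrupt_trials` in cohorts (a >20-frame unfillable gap).

**Cohorts.**  The outcome-generating model is additive per trial:
participant random intercept + group×test interaction (applied to the SMT
post cell only) + trial noise; per-participant metronome asynchrony is
drawn once per test occasion.  Defaults: 12 players per group, 8 trials per
test, baseline 14 correct taps (between-SD 2.5, trial-SD 2.0), six-tap
duration 6.5 s (0.8/0.6 s), asynchrony 90 ms (20/12 ms) — realistic scales
for trained adult athletes.  Note that a single-cell (SMT-post) shift
necessarily loads the *test* main effect and the interaction equally; a
design with such a shift cannot produce an interaction F that dominates the
test F on average.  The trajectory-level cohort realizes the drawn outcomes
mechanically: the six-tap duration sets the transport tempo
(T = (duration − 5·dwell)/6) and correct-tap deficits are planted as
insertion errors (an extra same-side wrong tap), so end-to-end pipeline
runs carry the planted group structure approximately; exact calibration
work uses the outcome-level generator directly.

## Preprocessing

Gap handling follows standard optoelectronic practice: runs of missing
samples shorter than 10 frames are filled automatically; runs of 10–20
frames are filled only under `manual_policy: accept` (a reproducible stand-in
for the human judgement of whether a manual fill is reliable); longer runs,
and runs touching the trial boundary, are unfillable.  Fills interpolate a
cubic spline through up to four valid frames on each side; observed frames
are never modified.  A marker with an unfillable gap inside the analysis
window invalidates its leg; either invalid leg excludes the trial from
kinematics.  Exclusion is a pure function of the gap report and the
configuration, and the run manifest accounts for every trial with explicit
reasons.

Smoothing is a second-order Butterworth low-pass at 10 Hz applied forward
and backward (zero phase; effective fourth order; the cutoff names the
per-pass −3 dB point, the common biomechanics convention) with reflective
edge padding of 3× the filter order.  The digital design attenuates a 30 Hz
component at 120 Hz sampling to ~0.5% of its amplitude.  Contacts are
detected on the *unfiltered* (gap-filled) positions — the ball markers give
contact times directly and the filter's settling would bias them by 1–2
frames — while all derivatives use the filtered signal.

## Tap detection and scoring

A tap is a contact episode of a toe marker with a target: a maximal run of
frames with toe-to-ball distance below the contact radius (default 60 mm ≈
ball radius plus boot clearance).  One tap is reported per episode, timed
at the first local minimum of the distance after entry; a new tap on the
same target also requires the 0.25 s refractory interval.  One-per-episode
is the robust form of "local minimum below the radius": a foot resting on
its final ball for seconds would otherwise emit a stream of noise minima
that no fixed refractory can suppress.  On noiseless trials the detected
time is exact to the frame; with 1 mm noise the tangential approach makes
the first local minimum land a few frames early (the foot covers <1 mm in
the last ~5 frames), an inherent ambiguity of spatial contact detection,
not an implementation artifact.

Scoring uses a greedy pointer over the cyclically repeated series: a tap is
correct iff it hits the expected digit with that digit's required foot, and
only correct taps advance the pointer.  Greedy matching is monotone and
auditable; a longest-common-subsequence matcher would forgive skipped
digits but make single-tap attributions ambiguous.  The first-six-taps
duration is the time of the sixth detected contact from trial start
(series presentation is synchronized with recording onset, so the window
starts at zero, not at the first tap).

Metronome sessions pair responses to beats greedily by nearest beat (each
beat used once).  Timing ability is the mean absolute signed asynchrony;
whether such scores average signed or absolute asynchronies is often left
unstated in practice — absolute is implemented, making 0 a perfect score.
Rhythmic ability is the mean absolute deviation of inter-response intervals
from the inter-onset interval.  Response classification uses integer-
millisecond semantics: |a| ≤ 15 ms on-beat, ≤ −16 early, ≥ +16 late, with
fractional values truncated toward zero.

## Movement units

The segmentation operationalizes the classic definition (an acceleration
phase followed by a deceleration phase exceeding amplitude thresholds):

1. list alternating local minima/maxima of the tangential speed, endpoints
   included, plateaus collapsed to their last frame;
2. repeatedly delete the adjacent *interior* extremum pair with the
   smallest speed difference while that difference is below `dv_min`
   (20 mm/s), breaking ties toward the earlier pair;
3. every surviving maximum whose rise and fall both reach `dv_min` is a
   candidate unit;
4. a candidate is kept only if the acceleration within it reaches both
   +`da_min` and −`da_min` (5 mm/s²).

Both thresholds are configuration values.  The acceleration threshold's
unit is physically odd for its stated magnitude (5 mm/s² is far below any
noise floor); it is retained as specified and the config gate makes the
interpretation swappable.  Speed is the Euclidean norm of the
central-difference derivative of the filtered positions; acceleration is
the central difference of speed; no additional smoothing is applied to
derivatives.  The implementation is verified exactly against a brute-force
full-rescan oracle on thousands of random series.

**Noise floor, quantified.**  i.i.d. 1 mm position noise at 120 Hz through
the 10 Hz dual-pass filter leaves ~0.43 mm of position noise whose
derivative has σ ≈ 12.8 mm/s per axis; the rectified 3-axis speed floor at
rest is ~20 mm/s.  Two consequences:

- *Window-level MU counts are noise-dominated.*  Over a first-six-taps
  window each foot rests about half the time, and rest-period speed
  wiggles routinely exceed the 20 mm/s threshold, so window counts at the
  default noise (≈18/leg in the worked example) sit far above the clean
  count (3/leg).  This mirrors real recordings, where trial-level MU counts
  are much larger than the number of discrete transports.
- *Per-move counts are nearly, not exactly, noise-invariant.*  Within
  per-move windows (transport onset → arrival + planted pulses) the speed
  is high and steep almost everywhere, and per-move counts match the
  planted truth in ~98–99% of moves at 1 mm noise.  The residual 1–2% are
  wiggles crossing 20 mm/s at the two flat regions a move offers (the
  minimum-jerk bell top, ~7 frames; the transport/sub-movement junction
  dip).  Exact invariance is not attainable at these constants; the
  package reports the agreement rate rather than pretending otherwise.

Cumulative 3D distance is the summed frame-to-frame displacement over the
half-open window; average velocity is distance over window duration.  The
per-leg composite of each outcome is the unweighted arithmetic mean of the
knee, ankle and toe values, computed per marker first (whether the original
analyses counted per marker before compositing is unstated; per-marker-
then-mean is implemented).

## Statistics

With two within-subject levels the 2×2 mixed ANOVA reduces exactly to
three orthogonal F tests with (1, N−2) degrees of freedom: a one-way ANOVA
on the unit means (group), and tests of the unweighted grand mean and the
between-group contrast of the post−pre differences (test, interaction).
Unequal group sizes are handled with unweighted (Type III) cell means; on
balanced data the results match pingouin's mixed ANOVA to machine
precision, and the test suite verifies both routes.  Sphericity holds
trivially at two levels, so the Greenhouse–Geisser ε is an identity
pass-through (reported as 1.0).  Partial eta-squared uses the
F-statistic identity ηp² = F·df₁/(F·df₁+df₂), asserted internally on every
result.

The analysis unit is configurable: `participant` (trials averaged per
participant × test) or `trial` (each participant's trial index paired
across tests; incomplete pairs dropped).  The pipeline mirrors common
practice for this design: participant-level for the metronome metrics, and
trial-level for stepping and kinematic outcomes — with the standing caveat
that trial-level analysis treats trials of one player as independent.
Under the package's own generating model the trial-level interaction test
is nevertheless exactly calibrated, because pairing post−pre within a trial
cancels the participant intercept; the Monte-Carlo acceptance check
verifies type-I error at α = 0.05.

Scheffé post hoc contrasts compare all pairs of the four cell means against
(k−1)·F_α(k−1, df) using the pooled between+within error mean square (the
error-term choice for mixed-design post hocs is not standardized; pooling
is the common software default and is conservative).  Scheffé p-values
dominate unadjusted pairwise p-values by construction.  Pearson
correlations use the standard product-moment estimator with a two-sided
t-based p (via scipy).  α = 0.05 throughout, two-tailed, no
multiple-testing correction across outcome ANOVAs.

## Determinism and problem sizes

All randomness flows from explicit integer seeds; cohort stages derive
child streams from the master seed, so identical (config, seed, input)
yields byte-identical summary tables, ANOVA tables and manifests.  The
test suite and the acceptance script use deliberately modest sizes — 1000
random series for the oracle equivalence, ~190 planted taps per noise
condition, 500 null and 200 power replicates at the full 12+12 × 2 × 8
design, one end-to-end 384-trial pipeline run — chosen so the full suite
completes in well under two minutes while keeping Monte-Carlo standard
errors small relative to the margins being tested.

## Limitations

- The generator tests the measurement chain, not human motor control: no
  joint coupling, balance dynamics, ground reaction, or speed–accuracy
  trade-off; insertion errors are the only error mode.
- Tap detection assumes targets are well separated relative to the contact
  radius (true for this layout); overlapping target shells would need
  nearest-target arbitration.
- The i.i.d. noise model overstates frame-to-frame jitter at a given RMS;
  passing recovery tests under it is therefore conservative evidence, but
  no synthetic test can establish validity on real recordings.
- Manual gap-fill judgement is modelled by a single accept/reject policy
  flag; no reproducible criterion can stand in for frame-by-frame visual
  inspection.
- The mixed ANOVA supports exactly the 2×2 design it is used for; larger
  factorial structures are out of scope.
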