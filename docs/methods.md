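# Methods

## The problem

Eye trackers embedded in head-mounted displays report gaze in a
*VR-centered* frame: each sample is the 3-D point where the gaze ray
strikes the virtual scene, together with the 3-D head position, both in
world coordinates.  Because the head moves freely, classic 2-D
fixation-identification algorithms do not apply directly, and because
samples are delivered through the render loop, the effective acquisition
rate fluctuates well below the sensor's nominal rate.  `vrfix` implements
a dispersion-threshold (I-DT) fixation classifier adapted to this setting
and a rule-based procedure for calibrating its two thresholds.

## The classifier

A fixation is a maximal run of consecutive samples that (a) spans at least
`time_window` seconds, (b) contains no inter-sample gap longer than
`1 / freq_floor` seconds, and (c) has angular dispersion at most
`dispersion_th` degrees.  Dispersion is the largest pairwise angle between
the direction vectors `d_n = g_n − h̄`, where `g_n` are the member gaze
points and `h̄` is the mean head position of the *current* members —
re-averaged every time a candidate sample joins the window, which
compensates for head translation during the fixation.

The scan is the classic sliding-window I-DT: seed the shortest run
spanning the time window; on violation of the gap or dispersion rule
advance the start by one sample; otherwise grow one sample at a time
(re-averaging `h̄` and re-checking both rules over the full window at
every step) and emit when no further sample fits.  Choices fixed here
because the procedure leaves them open:

* dispersion comparison is inclusive (`≤ threshold` passes); differences
  arise only on measure-zero inputs;
* the frequency floor is operationalized as a strict per-gap rule — any
  consecutive `Δt > 1/freq_floor` breaks candidacy, so a window can never
  straddle a render stall; this is the strictest local, deterministic
  reading of "reject classifications below a frequency threshold";
* seed rejection drops only the first sample, maximizing detected
  fixations;
* the emitted `head_mean` is the final running mean at emission time, and
  the stored dispersion is re-evaluated against it;
* the pairwise maximum is computed exactly (O(n²) with full recomputation
  after every growth step); incremental shortcuts are avoided so that the
  implementation is bit-comparable to a brute-force reference.

Coordinates are treated as an abstract right-handed Cartesian frame in
meters.  Engine handedness does not affect angles, so no conversion is
performed.  Angles are degrees at every public boundary; timestamps are
seconds.

Default guards follow common practice for HMD data: `freq_floor = 30 Hz`
(the lowest rate at which fast eye movements remain separable) and
`blink_cutoff = 0.75` on the per-eye eyelid-closure coefficient, with
strictly-greater comparison (a coefficient exactly at the cutoff is
retained).  Blink removal precedes detection; removed blinks create gaps
that the frequency guard then handles organically.

## Preprocessing

`remove_blinks` drops samples whose eyelid coefficient exceeds the cutoff
in either eye.  `trim_to_protocol` keeps the closed interval between the
first and last lit squares of the AoI event log.  `frequency_profile`
bins each recording into half-open 1-second bins from its own first
timestamp and reports the across-subject mean and *population* SD of the
per-bin counts (the divisor-n convention is fixed for reproducibility).

## Calibration

Four features are evaluated on a (dispersion × window) grid, each averaged
across subjects:

1. **n_fixations** — mean fixations per subject.  Acceptable cells lie
   strictly *after* the row-wise count maximum (ties resolve to the first
   peak): below and at the peak the classification is unstable.
2. **pct_points** — mean percentage of samples inside fixations.  Its
   elbow coincides with the count maximum, so the elbow rule is evaluated
   on the count surface; beyond the elbow the feature should be as high
   as possible, which makes it the selection objective rather than a
   bound.
3. **mean_fix_time** — mean fixation duration, averaged per subject and
   then across subjects (subjects with no fixations are excluded; the
   cell value is 0 when no subject has any).  Acceptable strictly below
   `t_max = 1.5 s`, an upper bound suited to guided tasks in immersive VR
   where dwell times run much longer than in screen-based reading or
   search.
4. **pct_in_aoi** — percentage of fixations whose centroid lies inside
   the concurrently lit square.  A fixation is assigned to the event
   containing its temporal midpoint (midpoint in no event → excluded from
   the denominator); "inside" means the centroid projects within the
   rectangle and sits within `plane_tol = 0.05 m` of its plane, a
   tolerance absorbing ray/mesh discretization.  Acceptable where the
   curve is *stable*: after a centered 3-point moving average (shrinking
   to 2 points at the edges), the absolute forward difference along the
   dispersion axis stays below 2 percentage points per 0.1° step; the
   last cell of a row inherits the preceding difference.  The derivative
   is taken along the dispersion axis of the across-subject mean surface.

The grid defaults to dispersion 0.1–2.5° in 0.1° steps and windows
0.10–0.50 s in 0.05 s steps.  The nominal 0° endpoint is dropped: a zero
threshold admits no fixation and leaves every feature undefined.

Calibration runs in two phases: phase 1 intersects the AoI-free rules
(after-peak/elbow, mean-time) and selects the cell maximizing
`pct_points`; phase 2 adds the AoI stability rule and re-selects.  Ties
in the objective break toward smaller dispersion, then smaller window
(the procedure itself does not specify a tie rule; this one prefers the
most conservative thresholds).  The phase-2 region is a subset of phase 1
by construction.  An empty region raises an explicit error rather than
returning a fabricated optimum.

## The synthetic protocol generator

No public recordings exist for this task, so the package ships a
generator that replays the guided study design: two 4×4 panels of
numbered squares — a frontal panel spanning ±14.93° of azimuth from the
viewer and a second panel of the same physical size placed to the right
spanning 25.02–45.00°, forcing head movement — with 15 squares lit for
3 s each in the fixed sequence 1, 16, 4, 13, 6, 11, 7, 10, 17, 32, 22,
10, 20, 5, 30, after a 60 s free-exploration lead-in that exercises the
trimming step.  Panel geometry is solved from the angular extents
(frontal distance 2.5 m, eye height 1.6 m); the second panel faces the
viewer at the bisector azimuth so its edges subtend exactly the quoted
range.

Each simulated stream emulates an HMD eye tracker driven by the render
loop:

* **Timing** — inter-sample intervals of `1/45 s` plus Gaussian jitter
  (SD 2 ms, floored at 1 ms), matching the ~45 Hz effective rate typical
  of such set-ups; Poisson render-stall dropouts (0.1/min, 0.3 s) delete
  sample runs.
* **Head** — a slow smooth sway (sinusoids at 0.03–0.10 Hz, amplitude
  5 cm) around the viewer position.
* **Gaze during a dwell** — the subject fixates the lit square with
  probability `adherence = 0.95`, otherwise a different square.  The
  within-fixation wander is the sum of a slow drift (per-dwell sinusoids
  at 0.25–0.7 Hz, amplitude 0.53×SD per component) and fast per-sample
  jitter (0.45×SD per component, radially clipped at 0.65×SD), both
  scaled by the noise parameter (default SD 0.3°).  The radial budget is
  capped at 1.4×SD, so a labeled fixation's pairwise dispersion stays
  below ~2.8×SD and ground-truth segments satisfy the classifier's
  invariants whenever `dispersion_th ≥ 3×SD`.  The drift is what gives
  the mean-fixation-time surface its gradual ramp with dispersion —
  fixations split where the threshold undercuts the drift span — while
  the jitter sets the floor below which no window qualifies.
* **Noise placement** — offsets are laid out directly in the panel plane,
  scaled by the per-sample viewing distance.  Perturbing the ray
  direction and intersecting with the plane was rejected: under oblique
  viewing the intersection stretches the in-plane spread by up to
  1/cos β (≈10% at panel corners), letting the realized dispersion
  escape the declared noise cone.
* **Saccades** — gaze travels between square centers along a steep
  sigmoid position profile (peak velocity mid-flight).  In-flight samples
  whose angular distance to either endpoint is below 5.5×SD snap onto
  it: the capture radius exceeds the noise cone (3×SD) plus its radial
  half-width (1.4×SD), so an unsnapped sample is either clearly outside
  any plausible fixation cone or exactly at an endpoint — it cannot
  linger just beyond the cone boundary, which would otherwise seed
  spurious splits.  Distracted (non-adherent) targets exclude both the
  lit square and the currently fixated one.
* **Blinks** — episodes (4/min, 0.12 s) raise both eyelid coefficients
  to 0.8–0.995; baseline coefficients are uniform on [0, 0.3].  Episodes
  start at gaze-shift onsets, reflecting blink–saccade coupling; at this
  rate and duration the removed fraction (~0.8% of samples) matches the
  magnitude reported for cohorts on this hardware.
* **Labels** — every sample carries a class (`fixation`, `saccade`,
  `blink`, `free`) plus the generating square and the concurrently lit
  square, so detection and features can be scored against ground truth.

The generator does **not** model oculomotor fine structure (main-sequence
saccade dynamics, microsaccades, smooth pursuit, pupil size), per-eye
vergence, tracker calibration error, or gaze-contingent rendering
artifacts.  Passing tests on this synthetic cohort therefore demonstrate
the correctness and self-consistency of the pipeline under the stated
study design, not the behavior of any particular human cohort; headline
feature values from real 57-subject data are not reproducible here.

Default test cohorts use 10 subjects with seeds spawned from one master
seed; sessions are bit-reproducible given the seed.

## Numerical choices

* Dot products are clamped to [−1, 1] before `arccos`.
* A single-sample set has dispersion 0; antipodal directions give 180°.
* Gaze CSV floats are written at 9 significant digits and round-trip
  exactly at that precision.
* Degenerate geometry (gaze point equal to the head origin) raises an
  error naming the sample index rather than propagating NaNs.

## Known limitations

* The grid search re-runs detection per cell per subject with exact
  O(n²) dispersion; the full default grid over 10 subjects takes a few
  minutes of one CPU.  The structure favors auditability over speed.
* `pct_points` is not provably monotone in the dispersion threshold for
  sliding-window I-DT; the suite checks the expected increasing trend
  beyond the count peak empirically with a small tolerance rather than
  asserting strict monotonicity.
* Vendor log formats (SRanipal/engine exports) are out of scope; inputs
  use the documented CSV/JSON dialects.
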