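# Methods

This note documents the models, estimators, parameters and design choices
behind `penlaws`, and what the synthetic cohorts do and do not show about
real pen recordings.

## Data model and units

A trial is an ordered run of pen samples (t in seconds, x/y in
millimetres, pen-down flag, optional pressure in [0,1]). After reading a
session file, all coordinates are canonical: millimetres, y-up, origin at
the canvas bottom-left. The on-disk device header (`pixels_per_mm`,
`y_axis`, `canvas_height_px`) drives the conversion, so speeds and lengths
are comparable across devices. Timestamps are kept as recorded — sampling
jitter is tolerated, every downstream formula uses actual Δt — but the
low-pass stage refuses signals whose within-stroke intervals deviate more
than 20% from the median, since a fixed-cutoff filter presumes a
near-uniform rate. Trials violating an invariant (non-monotone time,
missing metadata, item/game mismatches) are quarantined with reasons, never
silently dropped; analyses see only valid trials.

A *stroke* is a maximal contiguous pen-down run; the first and last frames
on the surface delimit a symbol in sequence items.

## Copy-game kinematics

Per-execution mean speed is the composition

1. trim the first and last ⌊0.05·N⌋ samples (pen landing/lift transients;
   interpreted by sample count — the trim targets temporal border effects,
   and a time- or arc-based variant is one config key away),
2. discrete-difference speed v_i = ‖Δ(x,y)‖/Δt at pair midpoints, pairs
   spanning a pen-up gap excluded (the airborne pen is unobserved),
3. zero-phase 4th-order Butterworth low-pass at 10 Hz (forward–backward,
   so segmentation timing downstream is unbiased; negative outputs clamped
   to 0); profiles shorter than 16 points skip the filter,
4. arithmetic mean over the filtered profile.

Defaults (`trim_fraction` 0.05, `lowpass_cutoff_hz` 10, `filter_order` 4)
are exposed as configuration.

Note one estimator property that matters for group comparisons: additive
coordinate noise inflates discrete-difference speed (E‖v̂‖ grows with
σ²/d² where d is the true step length), so noisier writers measure
slightly faster at equal true speed. Within-subject modality contrasts are
unaffected (the bias is common to all modalities at equal true speed), but
between-group contrasts on raw mean speed partially reflect tremor rather
than pace; on synthetic cohorts where the kindergarten group has 1.5×
lateral noise this shows up as a borderline group effect on spontaneous
speed.

## Segmentation and the homothety statistic

Cursive words are split at the lowest point between letters: local minima
of canonical y along the pen-down trace (strokes concatenated in time, so
an unexpected pen lift is itself a candidate), smoothed by a zero-phase
moving average spanning ~0.15 s (letter transitions are slow events;
sample-level noise would otherwise jitter the argmin), accepted
lowest-first under a mutual separation of 5% of traced arc length, with
candidates within 5% of either trace end ineligible. If fewer qualifying
minima exist than needed the trial is flagged for manual boundaries; a
`manual_boundaries` list in the JSON dialect overrides the search.

Sequences are split at pen lifts, one element per stroke. An element's
fraction time is its duration over the summed element durations; by
default inter-symbol pen-up time counts for neither numerator nor
denominator (an element runs from its first to its last ink frame; a flag
attributes gaps to the preceding element instead). Fractions are positive
and sum to 1 by construction.

## Tunnel-game steering analysis

Geometry: a center polyline with width W, amplitude A (perimeter for
closed symbols, path length for the word, both at the tunnel center) and
ID = A/W. The word path carries a lead-in and lead-out around its "ele"
core, with measurement gates at the dips bounding the first and last "e"
(arc fractions ~0.13/0.87 from the template; overridable).

Accuracy: a traced segment is outside the tunnel when its midpoint lies
farther than W/2 from the center path; trials with outside arc fraction
strictly greater than 0.40 are excluded (a trace at exactly 0.40 is
retained).

Movement time: each sample is projected to its arc position on the center
path (nearest-point projection; for closed paths the progress is unwrapped
with minimal-wrap increments and a hysteresis that ignores jumps above 25%
of the perimeter, preventing aliasing at near passes). Two-lap symbol
trials measure the central full lap, progress 0.5P → 1.5P — equivalently,
discarding the first and last semicircles of a circle or the first two and
last two sides of a square. Word trials measure first start-gate crossing
to last end-gate crossing. Crossing times are linearly interpolated
between samples. Traces that never reach the landmarks raise an
incomplete-trial error and are logged, not skipped silently.

Fit: ordinary least squares of MT on ID per subject and item (≥3 measured
trials spanning ≥2 IDs). Reported: a, b with its standard error,
R² = 1 − SSres/SStot, RMSE = √(SSres/n), the slope's F(1, n−2) p-value,
IP = 1/b only when the fit is significant at α with b > 0, and the global
MT (median MT across all retained trials). The analytic significance
threshold `critical_r2(df, α) = F/(F+df)` evaluates to 0.2835 at 12 df,
α = .05 — the R² > 0.28 criterion for 14-trial designs.

Default ID sets (configurable): symbols {8, 12, 18, 27, 40}, word
{6, 9, 14, 21, 32} — near-geometric progressions give even leverage in the
regression; 14 trials per item (5 IDs, repeats 3/3/3/3/2, residual df 12).

## Statistical battery

All tests are rank-based with midrank ties, two-sided by default
(one-sided available). Exact null distributions are used at small n —
signed-rank and U statistics via count-generating recursions over doubled
midranks (so ties are exact too), Friedman via full within-block
permutation for designs up to 6×4 — and the standard normal/chi-square
approximations with tie and continuity corrections otherwise; the
thresholds (n ≤ 12 for the paired/two-sample tests) keep cohort-sized
inputs (n = 15/19) on the conventional approximations. Exact two-sided
p-values use the doubling convention min(1, 2·min(P≤, P≥)). A fully tied
Friedman design returns statistic 0, p = 1, flagged degenerate. The
post-hoc companion to a significant Friedman omnibus is all pairwise
Wilcoxon signed-rank tests with Bonferroni multiplier m = C(k,2);
Dunn-type alternatives were considered but pairwise Wilcoxon is the
standard paired companion and keeps the battery self-contained. Subjects
with missing cells are dropped from that Friedman only, and logged.

## Synthetic cohorts

The generator emulates the study protocol, not any particular child:

* **Copy trials.** A shape template (unit arc length; cursive words built
  from sinusoidal letter arches joined by dips 0.12 units below the
  baseline — the dip minima are the programmed letter transitions) is
  scaled by the modality size factor (spontaneous ×1, big ×2, small ×0.5,
  fast/slow ×1) and traced with per-element minimum-jerk bell speed
  profiles. Executed speed is `base_speed · size_ratio^β · speed_factor`
  (fast ×1.5, slow ×0.6): β = 1 is full isochrony compliance (duration
  invariant to size), β = 0 a violation profile (duration scales with
  size). Element durations follow a fraction template perturbed by
  multiplicative lognormal noise (sd 0.03) and renormalized — homothety
  holds in distribution across modalities by construction. Additive
  Gaussian coordinate noise (sd 0.3 mm) models sensor/tremor jitter.
  Ground truth (programmed fractions, boundary arc positions, per-sample
  true arc fractions) rides along on `trial.truth` and is never
  serialized.
* **Tunnel trials.** The central-section movement time is drawn from
  MT* = a + b·ID + N(0, σ_MT), redrawn while nonpositive; the pen moves at
  the implied constant speed over the full trace (two laps for symbols).
  Lateral deviation is an Ornstein–Uhlenbeck process (correlation time
  0.15 s) with controllable stationary sd, so the outside-borders fraction
  is steerable; programmed excursions offset a contiguous arc fraction by
  W to exercise the exclusion rule (on curved paths the realized outside
  fraction differs from the nominal by the curvature ratio).
* **Cohort defaults** mirror the study conditions: 15 primary-school
  subjects (copy word + symbols) and 19 kindergartners (symbols only; both
  groups steer the tunnel word), base speed 50 mm/s (lognormal 15% CV
  across subjects, equal across groups — free-execution pace does not
  differ by age), primary steering a ≈ 0.8 s, b ≈ 0.12 s/ID;
  kindergarten b ×1.8, MT noise ×2 (0.2 s), lateral noise ×1.5 — the
  developmental direction (longer MT, worse fit, lower IP) without
  claiming real-cohort magnitudes. Copy size 120 mm keeps spontaneous
  executions near 2.4 s at 50 Hz. All randomness flows from
  `numpy.random.SeedSequence` spawns of one integer seed; identical
  (config, seed) reproduce byte-identical session files.

What passing tests on these cohorts show: the measurement chain —
filtering, segmentation, projection, exclusion, regression, rank tests —
recovers programmed effects at realistic noise and sample sizes, and stays
calibrated under the null. What they do not show: robustness to real
children's handwriting variability (letter-shape idiosyncrasy, hesitation,
in-air re-entries, pressure effects), hardware quirks (touch rejection,
variable latency), or the study's empirical effect magnitudes, none of
which the generator models.

## Monte-Carlo problem sizes

The calibration drivers (`penlaws.evaluation`) use 150–500 replicates of
15-subject cohorts per question — enough for rate estimates with binomial
standard errors under ~0.02 while keeping a full run in minutes on one
core. The acceptance script reports: critical R² (analytic), noiseless fit
error (≤1e-15), 3-SE slope coverage (~0.99 at σ_MT = 0.1 s, n = 14),
exclusion fixtures at 0.41/0.39, isochrony power 1.0 at β = 1 and
big-small false-alarm ~0.01–0.04 at β = 0, homothety false-rejection
~0.04–0.05 (nominal 0.05, chi-square approximation slightly conservative
at n = 15), segmentation recovery 1.0 at 2% amplitude noise, plus
cohort-level fractions from a full simulated session.

## Known limitations

* Letter segmentation assumes a y-valley between adjacent letters; scripts
  whose connecting strokes do not dip (e.g. some block or tangled cursive
  styles) need manual boundaries.
* Arc-length positions measured on a noisy polyline are inflated where the
  pen moves slowly (phantom arc from jitter near valleys); comparisons
  against programmed positions are therefore done in the generator's true
  arc frame, and real-data users should treat arc fractions near
  near-stationary regions with care.
* The steering analysis presumes the trace progresses monotonically along
  the tunnel; deliberate backtracking beyond 25% of the perimeter between
  samples is treated as projection noise, not motion.
* Mean-speed group contrasts inherit the noise-inflation bias described
  above; a derivative-of-smoothed-position estimator would trade this
  against attenuation of genuine speed peaks.
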