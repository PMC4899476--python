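# Methods

This note documents the models and procedures implemented in `vitalmvpa`, the
assumptions behind the synthetic data generator, the parameters that matter,
and the numerical choices made where the design was genuinely open.

## Scientific setting

Observers watching an object-directed arm action can judge either its
*velocity* (fast / medium / slow) or its *vitality form* (rude / neutral /
gentle) — the action's style.  The analysis asks whether multivoxel activity
patterns in the insula distinguish these two processing modes when the visual
stimuli are identical, using task-context decoding: vitality-task trials vs.
velocity-task trials at matched stimulus level (rude vs fast, neutral vs
medium, gentle vs slow).  Because no real data ship with the package, a
simulator generates cohorts with a known planted signal, and the analysis
stack is validated by parameter recovery rather than by re-estimating the
original data.

## Stimulus kinematics

Each of the 36 behavioral stimuli (3 objects x 12 execution times from 500 to
1600 ms) is represented by a minimum-jerk speed profile
`s(tau) = 30 (L/T) tau^2 (1 - tau)^2`, the classic single-peaked form for
point-to-point reaching, sampled at 100 Hz and rescaled so the sampled mean
speed is exactly `L/T`.  Path lengths for the three scanner-level stimuli are
0.636 / 0.570 / 0.532 m at 600 / 1000 / 1400 ms so that mean velocities are
1.06 / 0.57 / 0.38 m/s.  A small (3%) deterministic object-specific shape
modulation and a seeded jitter of the movement direction differentiate
objects without changing mean speed.

DTW is the classic dynamic program with local cost `|a_i - b_j|`, the
symmetric step pattern (insert / delete / match, no weights), boundary
`D(0,0) = cost(0,0)`, and the unnormalized terminal cumulative cost.  It is
verified against exhaustive enumeration of all monotone warping paths for
series up to length 6.  Whether to normalize by path length is not settled
usage; an optional `normalize=True` divides by `len(a)+len(b)` and the
default is unnormalized.  On the synthetic stimulus set the mean
within-duration distance is far below the between-duration mean, which is
the property that justifies collapsing objects within each duration level.

Judgment scores are simulated as `clip(a + b ln(t), 1, 5) + N(0, sd)` per
subject and execution time.  Defaults (`a = 20.44 / 20.61` for vitality /
velocity, `b = -2.58`, `sd = 0.4`, 18 subjects) reproduce mean scores of
2.66 and 2.83, i.e. the velocity task shifted above the vitality task, and a
log fit with R² near 1 at this noise level.  Scores are kept continuous: the
analysis target is the regression of mean score on log execution time, and a
clipped continuous score is the natural smooth stand-in for a 5-point scale
averaged over repetitions.

## Scan design

Each subject completes 4 runs — vitality task in runs 1–2, velocity in runs
3–4 (fixed order, as in the emulated design, to avoid velocity-task carryover
into vitality judgments).  A run holds 50 events of 2 s (45 experimental: 3
objects x 3 levels x 5 repetitions, plus 5 catch trials at random slots with
a question cue 0.5 s after video offset), preceded by 12 s fixation, with
ISIs drawn i.i.d. from {12, 14, 16} s.  ISIs are discretized to multiples of
the 2 s TR so every onset falls on a volume boundary; a schedule that would
push the last trial's estimation window past the 416th volume is redrawn.
The minimum onset-to-onset spacing is therefore 14 s = 7 TRs, which
guarantees that per-trial estimation windows are signal-disjoint (below).
Catch trials are probe trials: they evoke responses in the simulation but are
excluded from all pattern matrices, leaving 45 decodable trials per run (15
per level).

## BOLD simulation

Geometry.  ROIs are contiguous near-spherical blobs on a 2.5 mm lattice with
the voxel counts 1533 (left insula), 1346 (right insula), 500 (white-matter
control), 750 (BA21 control).  `GeometryConfig.scaled(f)` produces a
reduced-resolution variant (ROI sizes scaled by `f`) used for cohort-level
validation; all sizes below refer to the study-scale defaults.

Tuning annotation.  Within each insula, a fraction `frac_vitality_voxels`
(default 0.25) forms a contiguous dorso-central cluster of
vitality-preferring voxels whose canonical location is shared across subjects
up to a Gaussian displacement (`cluster_displacement_sd_vox`, default 0.25
voxels — the stand-in for good anatomical correspondence after
normalization); a fraction `frac_velocity_voxels` (default 0.05) of
velocity-preferring voxels is scattered at subject-specific positions.

Signal model.  Every in-mask voxel receives a common evoked response
(`common_amplitude`, 1% signal) per trial.  Insula voxels additionally carry
a *push-pull preference axis* `g`: +1 on vitality-preferring voxels,
`-n_vit/n_vel` on velocity-preferring voxels, 0 elsewhere, so that the ROI
mean of `g` is exactly zero.  A trial under the vitality task adds
`+(delta + h_t)/2 * g` and under the velocity task `-(delta + h_t)/2 * g`,
where `delta` (default 0.75%) is the task-contrast amplitude and
`h_t ~ N(0, gain_sd)` (default 2.86%) is a shared trial-to-trial gain
fluctuation of the tuning pattern.  Two properties follow by construction:

- the ROI-mean signal is identical under both tasks (the planted effect is
  multivariate only), so the univariate ROI comparison between vitality and
  velocity runs is null, as it must be;
- the gain noise lies exactly along the discriminative axis, so no linear
  classifier can exceed an accuracy ceiling set by `delta / gain_sd`.  This
  is the mechanism that keeps decoding in the mid-50s% band while individual
  voxel weights remain reliable — with independent voxel noise alone, either
  the accuracy saturates or the weight maps are uninformative, never the
  observed combination.

An optional level-specific pattern (`level_delta`, default 0) supports
positive-control experiments in which within-task levels become decodable;
at the default of 0, within-task contrasts decode at chance.  Per-trial,
per-voxel amplitude jitter (`pattern_jitter_sd`, 0.2%) adds independent
amplitude noise.  Control-ROI voxels receive the common response only.

Hemodynamics and noise.  The HRF is the standard double-gamma (peak delay
6 s, undershoot delay 16 s, 1:6 ratio) convolved with the 2 s stimulus
boxcar, unit-peak normalized.  The kernel is smoothly tapered to zero at
10 s post-stimulus, giving the event response compact support below 12 s:
with the 14 s minimum onset spacing, a trial's estimation window then
contains signal from that trial alone, which makes the noise-free
single-trial estimator exactly unbiased.  The cost is the (small) late
undershoot; nothing in the pipeline depends on it.  Voxel noise is an AR(1)
process (coefficient 0.35, stationary sd 4 intensity units on a baseline of
1000, i.e. 0.4% — representative of residual noise in preprocessed, smoothed
data; the simulator produces "already clean" runs and preprocessing is out
of scope) plus a demeaned slow cosine drift (amplitude 6 units, random phase
per voxel).

Percent-signal scaling.  Embedded amplitudes are defined in % of the voxel's
run-mean intensity.  Since evoked responses themselves contribute to the run
mean, the simulator solves the baseline per voxel,
`M = B / (1 - mean evoked mass / 100)`, so that the definition is exact and
the beta round trip recovers amplitudes to machine precision with noise off.

## Single-trial estimation

For each trial, the 6-volume window holds the pre-onset volume and the five
volumes after the onset volume.  Within the window, ordinary least squares
fits [HRF-convolved event regressor, constant]; the regressor coefficient,
divided by the voxel's run mean, is the trial beta in % signal change.  No
nuisance regressors are used.  The ISI guarantee means windows never overlap
a neighbouring trial's response, so this windowed estimator coincides with a
full least-squares-all model on these designs.

## Decoding

Cross-validation uses the four alternate-run splits (train 1,3 / test 2,4;
2,4 / 1,3; 2,3 / 1,4; 1,4 / 2,3): every fold trains on one run of each task
and tests on the other two, giving 15 + 15 training and 15 + 15 test trials
per cross-task contrast.  Features are z-scored with training-set statistics
and divided by the voxel count; the classifier is `SVC(kernel="linear")`
with cost C = 1.  At this feature scale C = 1 operates in the strongly
regularized soft-margin regime (all dual coefficients at the cap), where the
weight vector equals the difference of class centroids in standardized
space.  This choice is deliberate: with unit-scale z-scored features and 30
training patterns in ~1500 dimensions, C = 1 is effectively a hard-margin
fit whose weights are dominated by the margin geometry of noise dimensions
(measured sign consistency of planted voxels ~0.66, versus ~1.0 for centroid
weights), which destroys the discriminative maps while barely changing
accuracy.  The scaling keeps both accuracies and weight maps comparable
across ROIs of different sizes.  Fold accuracies are aggregated by
unweighted mean.

Permutation chance level: training labels are shuffled and the SVM refit,
test labels intact; 1000 permutations by default.  Shuffling is stratified
within training runs when a run contains both classes (within-task
contrasts).  For cross-task contrasts, class membership coincides with run
membership, so a within-run shuffle would be the identity; labels are
instead exchanged across the whole training set.  The chance estimate is the
null mean (empirically 50.0%); the empirical p-value is
`(1 + #{null >= observed}) / (n_perm + 1)`.

Group inference: exact one-sided Wilcoxon signed-rank test of the 16
per-subject accuracies against chance, zeros discarded, average ranks for
ties, and the null distribution of W+ enumerated over all 2^n sign
assignments for n <= 20 (normal approximation beyond).  A paired t-test of
mean in-mask intensity between vitality and velocity runs serves as the
univariate control analysis.

## Group discriminative maps

Per subject, signed voxel weights are averaged over the four folds and over
the three cross-task contrasts (the collapsed map); voxels are ranked by
|weight| (ties broken by voxel id) and the top fraction f selected (f = 0.5
by default, 0.35 supported).  Positive weight means vitality-preferring.
The group map counts per-voxel subject overlap, split by sign; a group
voxel's sign is the sign with the larger count.

Null model: under the assumption that subject maps are spatially unrelated,
the overlap count at any voxel is Binomial(S = 16, f).  Both the exact
binomial tail and a Monte Carlo version (each subject selects round(f·V)
voxels uniformly without replacement; tails pooled across voxels, default
10,000 iterations) are provided, and they agree to Monte Carlo error.  Maps
are thresholded by Benjamini–Hochberg FDR at q = 0.05 on the per-voxel tail
probabilities.

A caveat worth making explicit: the marginal tail of overlap >= 10 of 16 at
f = 0.5 is 14893/65536 ≈ 0.227, which can never pass BH FDR at q = 0.05 on
its own — a per-voxel independence null admits only overlaps of ~14+ as
survivors at these map sizes.  A maximum-overlap (family-wise) Monte Carlo
null is also implemented (`monte_carlo_max_overlap_null`) for users who want
a cluster-free corrected threshold; neither variant is claimed to match any
particular published threshold exactly.

## Calibration and validation scales

The default `SignalConfig` was calibrated by simulation, as the generator's
definition of the study conditions: with `delta = 0.75`, `gain_sd = 2.86`
and the noise defaults, a 16-subject cohort at reduced resolution
(`geometry_scale = 0.1`, insulae of 153 / 135 voxels) yields cohort-mean
cross-task insula accuracy of 0.57–0.58, control ROIs and within-task
contrasts at 0.50–0.51, planted-voxel weight sign consistency ~1.0, and
FDR-surviving group-map voxels lying entirely inside the planted cluster
with positive sign (minimum surviving overlap 13–14 of 16).  The reduced
scale keeps the full cohort run near ten seconds; the acceptance script runs
one full-geometry subject (1533-voxel insula) with the complete
1000-permutation null.

## What the synthetic data do and do not show

The generator reproduces the design's timing, trial counts, ROI sizes and
the qualitative signal structure (task-context information without
univariate differences, clustered vitality preference, rare velocity
preference), with independent-across-voxels noise and perfect anatomical
correspondence up to a small displacement.  It does not emulate spatially
correlated physiological noise, motion, susceptibility artifacts,
between-subject variability in HRF shape, or imperfect inter-subject
registration.  Passing the recovery tests therefore demonstrates that the
analysis code is correct and well-calibrated under the stated model — not
that the effect exists in any real brain, nor that real data of this size
would yield the same statistical power.

## Known limitations

- The windowed single-trial GLM relies on the compact-support HRF; for
  designs with ISIs shorter than ~12 s it would need regularized
  least-squares-separate estimation instead.
- The exact Wilcoxon enumeration is O(2^n) and switches to the normal
  approximation above n = 20.
- The Monte Carlo overlap null pools tail counts across voxels, which is
  valid under the exchangeable independence null but not for
  spatially-structured alternatives.
- Catch-trial behavior (responses, reaction times) is flagged but not
  modeled.
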