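# Methods

`mempattern` re-implements, as a tested pipeline on synthetic data, a
multivoxel pattern analysis (MVPA) that asks whether individual episodic
memories can be decoded from fMRI activity patterns in medial temporal lobe
structures — hippocampus (HC), entorhinal cortex (EC) and parahippocampal
gyrus (PHG) — and whether the informative voxels cluster consistently across
people.  This note records the model, the parameters that matter, the
numerical choices, and what the synthetic benchmark does and does not show.

## The experimental structure being emulated

One continuous functional run per subject contains a cued-recall block of 21
trials (three well-rehearsed memories, seven trials each, pseudorandom order
with no memory repeated twice in a row), a ~30 s rest gap, and a free-recall
block of 30 trials in which the subject chooses which memory to recall.
Volumes arrive every TR = 3.5 s; voxels are 1.5 mm isotropic.  The default
analysis collapses both conditions (51 trials); per-condition analyses are
available through a filter.

Free-recall memory choices are drawn uniformly subject to every memory
occurring at least once: the real per-class counts produced by participants'
free choices are unknown, so they are configuration, not an asserted fact,
and class imbalance in the free block is allowed and recorded.

## Signal model of the generator

Each voxel's time-series is

    y(t) = baseline + drift_slope * t + noise,   noise ~ N(0, noise_sd^2),

independently per voxel, plus — only at "informative" voxels — an additive
class-specific amplitude in a boxcar window of `pattern_window_volumes`
volumes starting `hemodynamic_delay_volumes` after each trial onset.
Informative voxels are the union of small euclidean balls
(`cluster_radius_vox`, default 1 → 7-voxel clusters) around cluster centers
drawn uniformly from the ROI; a cohort can share one set of centers (maximal
group overlap) or draw them independently from the same uniform prior.

Class patterns are random sign patterns, ±`effect_size` per informative
voxel, redrawn until pairwise distinct.  Their expected pairwise correlation
is zero, so between-class discriminability scales directly with
`effect_size / noise_sd`.

Deliberate simplifications (and why they are safe here):

- **Boxcar instead of a hemodynamic response function.**  The pipeline only
  consumes window averages of the signal; convolving with an HRF would change
  the effective amplitude but not the logic of any stage, while the boxcar
  keeps the pattern-recovery oracles exact.
- **White noise, no motion, no physiological confounds, single run.**
  Passing the recovery suite therefore shows the *analysis* is correct, not
  that real hippocampal data of this effect size would decode at these
  accuracies.
- Default effect size 3.0 (in units of noise SD) is intentionally strong: it
  is the "recoverable regime" used to validate selection and decoding;
  effect size 0 gives the null subject used for chance calibration.

Defaults: `n_informative_clusters=2`, `noise_sd=1.0`, `drift_slope=0.02`
per volume (a visible but modest drift over a ~315-volume run),
`baseline=100`, delay 2 volumes (7 s at TR 3.5 s — a typical hemodynamic
peak delay), window 2 volumes.  Trial spacing is 6 volumes (21 s) within
blocks and a 9-volume (~31.5 s) rest gap, mirroring the paced recall-trial
structure.  Per-subject seeds are `master_seed + subject_index` so any
subject regenerates in isolation.

## Preprocessing

- **Linear detrend**: per voxel, an ordinary-least-squares first-order
  polynomial (intercept + slope over volume index) is fitted to the *whole
  run* — both blocks and the rest gap — and subtracted.  Residuals have zero
  mean and zero least-squares slope; the operation is idempotent to 1e-10.
- **Onset shift**: every onset moves later by the hemodynamic delay
  (default 2 volumes); shifting past the end of the run is an error.
- **Trial patterns**: one row per trial — the mean of the
  `window_volumes`-volume window (default 2, averaged) at the shifted onset,
  restricted to the ROI's voxels in fixed lexicographic order.  Intervals
  are half-open everywhere.

## Searchlight feature selection

Every ROI voxel is visited in turn; its neighborhood is all *mask* voxels
within `radius_vox` under a chebyshev (default; radius 1 → up to 27 voxels)
or euclidean metric.  Searchlights never reach outside the mask, matching a
mask-defined analysis; neighborhoods smaller than `min_neighborhood`
(default 9) score zero.  The voxel's score is the stratified 5-fold
cross-validated accuracy of the multiclass linear SVM on its neighborhood
columns (per-voxel z-scoring uses inner-training-fold statistics only).
Five inner folds, not leave-one-out, keep the inner loop tractable — it runs
once per voxel per outer fold.  The information map keeps the `n_select`
(default 100) highest-scoring voxels; score ties break toward the
lexicographically first voxel so selection is deterministic.

## Decoder

Binary classifier: soft-margin linear SVM, objective
`0.5 ||w||^2 + Σ_i C_i · hinge(y_i (w·x_i + b))`, with the study's fixed
C = 1.  The solver is dual coordinate descent (liblinear-style) with the
bias as an augmented, weakly regularized constant feature; the coordinate
sweep order is shuffled by a fixed-seed xorshift generator, so fits are
bit-reproducible.  Stopping: projected-gradient gap below `tol = 1e-4`
within `max_iter = 50 000` sweeps; non-convergence is flagged on the result
and warned about, never silent.  The test suite checks this solver against
libsvm (sklearn's `SVC`, the implementation the original analysis used) on
predictions and on the objective value.

Multiclass: one-vs-one.  One binary SVM per unordered class pair, trained
on that pair's trials; prediction is majority vote, with vote ties broken by
the largest summed signed pairwise margin and then by the lowest class id —
a fully deterministic chain.

**Class-balanced costs (default).**  Per pair, each class's per-trial cost
is scaled to `C · n_pair / (2 n_class)`, so both classes carry equal total
cost.  Rationale: under leave-one-trial-out CV the training set is short
exactly one trial of the tested class; on signal-free data an unweighted SVM
drifts toward the majority classes and systematically votes *against* the
held-out trial's class, depressing null accuracy measurably below the
theoretical 1/3 (we measured ≈ 0.295 unweighted vs ≈ 0.33–0.35 balanced at
the default problem size).  Balancing removes this artifact of the CV
scheme while keeping the average cost at C = 1; `class_weight="none"`
restores the plain C-SVM.

Cross-validation: leave-one-trial-out (k = number of trials, 51 by
default).  Within every outer fold, searchlight scoring and top-`n_select`
selection are recomputed on the training trials only, features are z-scored
with training-fold statistics, the SVM is trained on the selected voxels,
and the held-out trial is predicted — the nested scheme that prevents
selection leakage ("double dipping").  A deliberately leaky
`selection="whole"` test mode selects once on all trials; the test suite
demonstrates its optimistic bias on permuted labels and it is never used
for reported accuracy.  The reported per-subject information map is the
selection computed on all trials — used for anatomical mapping only, never
for accuracy.

Chance is estimated by permutation: labels are shuffled within condition
and the complete nested pipeline is rerun per permutation;
`p = (1 + #{null ≥ observed}) / (n_perm + 1)`.

## Group maps

Subject information maps (shared grid) are summed into an integer frequency
heat map — at most `n_subjects` (10 in the default cohort) per voxel.  Each
count k is tested against Binomial(n_subjects, p0) with the inclusive upper
tail P(X ≥ k), summed term-by-term from the exact mass function.  The null
probability p0 is a required, logged parameter; its documented default is
`n_select / |ROI|`, the per-subject selection probability if selection were
uniform within the ROI.  The published analysis did not state its p0, so
which frequency counts pass a given α depends on this choice and is
parameterized, never asserted.  Thresholding is strict (p < α), uncorrected
by default (α = 0.001 in the pipeline), with an optional Bonferroni flag.
For externally aligned maps only nearest-neighbor affine resampling is
provided; nonlinear stereotactic normalization is out of scope.

## Problem sizes of the bundled benchmark

The demo cohort lives on a 20³ grid of 1.5 mm voxels with three disjoint
ellipsoidal ROI analogs: HC 141, EC 41, PHG 83 voxels — deliberate
scaled-down stand-ins for structures that really hold thousands of voxels,
chosen so the complete nested pipeline (searchlight × leave-one-trial-out ×
permutations) remains a desk-scale computation:

- **Chance calibration** runs on the EC analog with `n_select=15`,
  ≥ 20 within-condition label permutations of a signal-free subject.
- **Recovery** runs on the HC analog with the default `n_select=100`
  against implanted clusters (accuracy, map Jaccard, group overlap).
- **Leakage demonstration** uses radius-0 searchlights (single-voxel
  selection, `min_neighborhood=1`) over the HC analog: with neighborhoods
  of radius 1 adjacent searchlights share 26 of 27 voxels, scores are
  spatially smooth, and whole-data selection has little room to overfit a
  specific label permutation — single-voxel selection is the configuration
  in which double dipping shows its bias clearly.

## Known limitations

- The generator's noise model is white; autocorrelated fMRI noise would
  widen all sampling distributions.
- Within-pair solver convention (regularized bias) differs from libsvm's
  free bias; decisions can differ for points essentially on the boundary.
- Group inference is voxelwise and uncorrected by design (matching the
  published analysis); no cluster-extent or permutation-based group
  statistics are provided.
- Accuracies on synthetic cohorts say nothing quantitative about real
  hippocampal decodability; they validate the machinery, not the biology.
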