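# Methods

## Problem and model

Sarcopenia — age-related loss of skeletal muscle mass and quality — is
reflected in cross-sectional imaging of the paraspinal muscles at the L3/4
level: affected muscle shows fatty infiltration (a higher fat fraction
inside the muscle compartment) and a smaller cross-sectional volume.  The
package quantifies this with *cohort-level unsupervised habitat
segmentation*: ROI voxel intensities from all training subjects are pooled
into one global vector, a two-class intensity model is fitted to that
vector, a single scalar muscle/fat threshold is derived per modality, and
the frozen threshold is applied to every subject (training and validation
alike).  Pooling across the cohort, rather than clustering each case
separately, stabilises the threshold and makes per-subject features
comparable.

The working assumption is that within an ROI the intensity distribution is
approximately a two-component mixture: on CT, fat ~ −90 HU and muscle
~ +50 HU; on non-fat-suppressed T2-weighted MRI, fat is hyperintense
relative to muscle on an arbitrary scale.  The modality determines the
polarity of the decision rule (CT: intensity ≤ threshold → fat; MRI:
intensity ≥ threshold → fat).

## Threshold fitting

Three routes produce an initial muscle/fat boundary from the pooled
training intensities:

* **Otsu** — 256 equal-width bins over the pooled range; every interior
  bin boundary `t` is scored by the between-class variance
  `w0 w1 (mu0 − mu1)^2` and the maximiser returned.  Ties — which occur
  *exactly* when bins between well-separated modes are empty — resolve to
  the smallest boundary, using a 1e-12 relative band so that float
  summation order cannot break a mathematically exact tie arbitrarily.
* **k-means** (k = 2) — k-means++ initialisation, Lloyd iterations until
  the assignment stabilises (max 300), 10 restarts keeping the best
  within-cluster sum of squares; an emptied cluster is reseeded at the
  point farthest from the surviving centroid.  In 1-D the decision flips
  at the centroid midpoint, which is the initial boundary.
* **GMM** — a two-component Gaussian mixture fitted by EM, initialised
  from the k-means partition (weights = cluster proportions, variances =
  within-cluster variances).  Convergence: relative log-likelihood change
  < 1e-6, max 500 iterations; variances are floored at 1e-6 × the pooled
  variance so no component can collapse.  The initial boundary is the
  intensity between the two means where the posterior responsibilities are
  equal, found by root bracketing of the weighted log-density ratio (exact
  for any weights/variances; midpoint fallback if no crossing lies between
  the means).

Whatever the route, the boundary is then **refined**: the smoothed pooled
histogram (centred moving average, window 5 bins) is scanned for its two
dominant peaks, and Otsu is re-run on the sample restricted to the closed
interval between the peaks that flank the initial boundary.  A *peak* must
be a local maximum at least `n_bins/16` bins from its neighbours, with
prominence at least half its own height and height at least 5 % of the
dominant mode — raw "two highest local maxima" would pick two noise bumps
on a single mode.  If fewer than two such peaks flank the boundary
(unimodal or heavily smeared data, e.g. jittered MRI), refinement is
skipped with a warning and the initial boundary is kept.  On cleanly
bimodal data the refined value coincides with unrestricted Otsu to within
one bin width; a visible consequence is that the three methods typically
converge to (nearly) the same final CT threshold, differing mainly in
their initial boundaries.

## Habitat features and prediction models

For each subject the label map (0 outside / 1 muscle / 2 fat) yields six
candidate predictors: fat and muscle mean intensity, volume (voxel count ×
voxel volume; 1 mm³ after isotropic resampling), and volume percentage
(stored as fractions, so fat + muscle = 1 exactly).  The mean of an empty
habitat is missing (NaN), never 0.

Model building mirrors the standard clinical protocol: stratified 6:4
train/validation split (per-class training count = round(0.6·n));
univariate logistic screening at p < 0.05 (Wald; likelihood-ratio fallback
when Wald inference degenerates under quasi-separation); multivariate
logistic regression with backward stepwise elimination of the largest Wald
p while it exceeds 0.05 (stopping with at least one predictor); evaluation
by ROC AUC with DeLong 95 % CI, operating point by the Youden index
(candidate cutoffs are midpoints of consecutive distinct scores plus
sentinels; ties break to higher sensitivity, then lower cutoff), with
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total; and stratified five-fold cross-validation that refits the
*entire* recipe (screen → stepwise → fit) in each fold.  Logistic fits run
on internally standardised predictors for numerical stability, with
estimates mapped back to per-original-unit scale; rank-deficient designs
raise an error, perfect separation is flagged (`converged = False`) rather
than raised.  Rows missing a model predictor are dropped listwise per
model.  Inter-/intra-rater reliability uses ICC(2,1) — two-way random
effects, single measure, absolute agreement — from the two-way ANOVA mean
squares.

## Synthetic cohorts

No public imaging accompanies this design, so development and testing run
on synthetic cohorts with known ground truth.  Each subject is an
ellipsoidal ROI (default grid 24×24×12 at 1 mm³, ~2 600 voxels ≈ a
few-slice paraspinal ROI) whose voxels draw from the two-tissue mixture;
the generator emulates, deliberately minimally:

* **Group structure** — per-subject fat fraction ~ N(0.15, 0.08²) for
  non-sarcopenia and N(0.45, 0.08²) for sarcopenia (clipped to [0, 1]): a
  strong fatty-infiltration effect.  Sarcopenic ROIs are shrunk by 0.85
  per semi-axis (~39 % volume loss), emulating atrophy.
* **Tissue intensities** — CT: muscle +50 HU, fat −90 HU, SD 15 HU; MRI:
  muscle 300, fat 900, SD 120 (arbitrary units).  Values are plausible
  rather than fitted to any particular scanner.
* **Partial volume** — 5 % of ROI voxels are interface voxels whose mean
  mixes the two tissues with a uniform majority-tissue weight in
  (0.5, 1); their ground-truth label is the majority tissue.  Besides
  realism, this matters numerically: without it the pooled histogram has
  an exactly empty gap between the modes and the Otsu objective is
  exactly constant over many bins, making the threshold an arbitrary
  plateau edge.
* **Scanner effects** — a per-subject additive intensity offset
  (CT: SD 5 HU; MRI: SD 150) and, for MRI only, a multiplicative gain
  ~ N(1, 0.35²) clipped below at 0.2; MRI voxel values are floored at 0,
  as magnitude MR images are non-negative.  HU are calibrated; unnormalised
  T2-weighted intensities across two vendors are not, and this
  gain/offset heterogeneity is what degrades the MRI pipelines relative
  to CT when a single pooled threshold is applied — the qualitative
  CT-over-MRI ordering the evaluation checks.  MRI performance is
  intrinsically high-variance at these cohort sizes; the ordering is
  asserted on the fixed-seed default run, not as an almost-sure event.
* **Clinical covariates** — independent group-conditional normals (age
  68.13 ± 6.88 vs 71.65 ± 7.01 y; BMI 24.99 ± 3.40 vs 22.83 ± 3.18 kg/m²;
  albumin 37.89 ± 3.09 vs 35.90 ± 3.32 g/L; haemoglobin 136.76 ± 18.03 vs
  130.77 ± 16.31 g/L; RBC 4.50 ± 0.54 vs 4.36 ± 0.48 ×10¹²/L), matching
  published demographic profiles of elderly surgical cohorts.  Covariate
  correlations are not modelled.

Randomness is split per subject off the master seed
(`SeedSequence(seed, spawn_key=(index,))`) into covariate, label and
rendering streams, so anatomy and covariates are identical across
modalities at a fixed seed: CT and MRI cohorts are *paired*, as when each
patient receives both scans.  Default cohort size is 100 + 100 subjects —
large enough for stable thresholds and CV folds, small enough that the
complete experiment runs in seconds on one CPU.

What the generator does **not** emulate: anatomical muscle shapes, spatial
intensity correlation, bias fields, partial ROI mis-delineation, covariate
correlation, or the selection processes of a real cohort.  Passing tests
therefore demonstrate correctness of the estimators and the qualitative
mechanism (pooled thresholds transfer well on calibrated CT, poorly on
unstandardised MRI), not clinical performance on real patients.

## Numerical choices and degenerate inputs

* Resampling: trilinear for intensities, nearest-neighbour for masks, on
  a voxel-centre lattice anchored at the origin; output dimensions
  `round(dim × spacing / target)`, minimum 1; constant fields resample
  exactly.
* ROI extraction order is C/raster order (slowest axis first), fixed so
  pooled vectors and downstream CSVs are byte-reproducible.
* Boundary intensities exactly at the threshold classify as fat on both
  modalities (the ≤ / ≥ rules); a measure-zero choice made deterministic.
* All-identical intensities, empty ROIs, single-class label vectors,
  rank-deficient designs and zero between-subject ICC variance raise
  typed errors rather than returning numbers.
* Every stochastic step (generator, split, k-means restarts, CV folds)
  takes an explicit seed; identical configuration + seeds reproduce every
  output byte-for-byte.

## Known limitations

* The refinement step couples the three methods: on clean bimodal cohorts
  they return near-identical final thresholds, so differences between
  Otsu/k-means/GMM pipelines are mostly visible on smeared (MRI-like)
  data where refinement falls back to the method-specific boundary.
* Per-subject median normalisation of MRI before pooling is available as
  an explicit preprocessing choice for users but is off by default; the
  default pipeline deliberately reproduces the unnormalised-pooling
  design.
* DeLong CIs are asymptotic and degenerate at AUC = 1 (zero width); small
  validation sets make them optimistic.
* The stepwise procedure inherits the usual caveats of p-value-driven
  selection (unstable with collinear features); collinear screened sets
  are pruned greedily before the multivariate fit.
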