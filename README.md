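# sarcohab

Cohort-level unsupervised muscle/fat habitat segmentation of paraspinal
CT/MRI regions of interest, and sarcopenia prediction from the resulting
habitat features.

## The problem

Sarcopenia — age-related loss of skeletal muscle mass and quality — shows
up in routine cross-sectional imaging of the paraspinal muscles at the
L3/4 level as fatty infiltration (a rising fat fraction inside the muscle
compartment) and muscle atrophy.  Quantifying this without voxel-level
annotation calls for *unsupervised* tissue segmentation: within a muscle
ROI, voxel intensities are approximately a two-component mixture (CT: fat
≈ −90 HU, muscle ≈ +50 HU; non-fat-suppressed T2-weighted MRI: fat
hyperintense), so a single intensity threshold separates the two
*habitats*.

`sarcohab` implements the cohort-level variant of this idea for
researchers in body-composition and musculoskeletal imaging:

1. ROI voxel intensities of all **training** subjects are pooled into one
   global vector;
2. a two-class model is fitted to the pooled vector by one of three
   methods — **Otsu** (maximising the between-class variance
   `w₀w₁(μ₀−μ₁)²` over histogram bin boundaries), **k-means** (k = 2,
   k-means++ with restarts; boundary = centroid midpoint), or a
   **Gaussian mixture** fitted by EM from the k-means solution (boundary
   = equal-posterior intensity between the means) — and refined by
   re-running Otsu between the two dominant histogram peaks;
3. the frozen threshold classifies every subject's ROI voxels into muscle
   and fat habitats, yielding six per-subject features: fat/muscle mean
   intensity, volume (mm³) and volume percentage;
4. sarcopenia prediction models are built per modality × method:
   univariate logistic screening (p < 0.05), multivariate logistic
   regression with backward stepwise selection, ROC/AUC with DeLong 95 %
   CI, Youden-optimal operating point
   (sensitivity = TP/(TP+FN), specificity = TN/(TN+FP)), and stratified
   five-fold cross-validation.  ICC(2,1) is available for rater
   reliability.

No public imaging accompanies this design, so the package ships a
first-class synthetic cohort generator with known per-voxel ground truth:
paired CT/MRI subjects with group-dependent fat fractions, sarcopenic ROI
atrophy, partial-volume interface voxels, per-subject scanner gain/offset
jitter (much larger for MRI, whose intensities are not calibrated), and
clinical covariates (age, BMI, albumin, haemoglobin, RBC) drawn from
group-specific normals.  See `docs/methods.md` for the model, parameter
defaults and their rationale, and what the generator deliberately does
not emulate.

## Worked example

```python
from sarcohab import RunConfig, run_experiment

report = run_experiment(RunConfig())   # default synthetic cohort, seed 0
cols = ["model", "split", "auc", "sensitivity", "specificity", "youden",
        "cutoff"]
print(report.summary_frame()[cols].round(3).to_string(index=False))
```

prints

```
         model      split   auc  sensitivity  specificity  youden  cutoff
clinical_model   training 0.762          0.6        0.817   0.417   0.544
clinical_model validation 0.866          0.8        0.825   0.625   0.456
       otsu_CT   training 1.000          1.0        1.000   1.000   0.500
       otsu_CT validation 1.000          1.0        1.000   1.000   0.526
     kmeans_CT   training 1.000          1.0        1.000   1.000   0.500
     kmeans_CT validation 1.000          1.0        1.000   1.000   0.526
        gmm_CT   training 1.000          1.0        1.000   1.000   0.500
        gmm_CT validation 1.000          1.0        1.000   1.000   0.526
      otsu_MRI   training 0.993          1.0        0.950   0.950   0.365
      otsu_MRI validation 0.909          1.0        0.825   0.825   0.280
    kmeans_MRI   training 0.992          1.0        0.933   0.933   0.250
    kmeans_MRI validation 0.906          1.0        0.825   0.825   0.281
       gmm_MRI   training 0.988          1.0        0.933   0.933   0.225
       gmm_MRI validation 0.892          1.0        0.800   0.800   0.205
```

Each row is one prediction model on one split: `auc` is the area under
the ROC curve of the logistic model's predicted sarcopenia probability,
`cutoff` the Youden-optimal probability threshold, and `youden` =
sensitivity + specificity − 1 at that cutoff.  On this synthetic cohort
the CT pipelines separate the groups essentially perfectly — the fitted
CT muscle/fat threshold lands within ~2 HU of the generating mixture's
equal-posterior boundary, so estimated fat percentages track each
subject's true fat fraction — while the MRI pipelines degrade because a
single pooled threshold transfers poorly across subjects with
uncalibrated per-scanner intensity scales.  The clinical model (age, BMI,
albumin, haemoglobin, RBC) sits in between.

The same experiment is available stage-by-stage from the shell:

```sh
sarcohab generate --out run/ --seed 0
sarcohab segment  --out run/ --method gmm --modality ct
sarcohab features --out run/ --method gmm --modality ct
sarcohab model    --out run/ --method gmm --modality ct
sarcohab evaluate --out run/
# or everything at once:
sarcohab run-all  --out run/ --seed 0
```

`generate` writes NIfTI volumes/masks and the subject CSV; `segment`
writes the fitted cluster model (JSON) and per-subject habitat label
maps; `model`/`evaluate` write per-model results and the comparison
table.

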