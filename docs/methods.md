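# Methods

This note documents the models and procedures implemented in `dynbag`,
the assumptions of the synthetic-cohort generator, and the numerical and
design choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Connectivity estimation

**Input.** Per-scan component time courses (T × C at repetition time TR
seconds), as produced by a spatially constrained group-ICA pipeline.
ICA estimation itself is out of scope; the 53-component / 7-network
template partition ships as a data fixture (with the published network
sizes — SCN 5, AUD 2, SMN 9, VSN 9, CCN 17, DMN 7, CBN 4 — and generic
component ids).

**Denoising** (`fnc.clean_timecourses`), each stage optional:

1. least-squares removal of a polynomial trend up to cubic order;
2. regression of supplied nuisance covariates (e.g. realignment
   parameters) and their temporal derivatives;
3. outlier clipping at median ± 3.5 scaled median absolute deviations
   per column (the MAD is scaled by 1.4826 to be consistent for a
   Gaussian; clipping rather than sample deletion keeps the time axis
   intact for windowing);
4. zero-phase low-pass Butterworth filter (order 5, applied
   forward-backward) below 0.15 Hz. A cut-off at or above the Nyquist
   frequency 1/(2·TR) is rejected with the computed value.

**Static FNC** is the C × C Pearson correlation matrix; its strict
upper triangle in row-major order — (0,1), (0,2), …, (C−2,C−1) — is the
feature vector (length C(C−1)/2; 1378 for C = 53). `matrix_from_upper`
is the documented inverse.

**Tapered window.** A rectangle of length L = 20 TR is convolved with a
Gaussian kernel of σ = 3 TR. The kernel is truncated at ±4σ, the
central L samples of the full convolution are retained, and the peak is
normalized to 1. Truncation point, cropping and normalization are not
fixed by the sliding-window literature; the shipped construction is
checked against a direct discrete-convolution oracle, and σ → 0
recovers the rectangle.

**Dynamic FNC.** Windows start at 0, L is exclusive on the right
([s, s+L)), the stride defaults to 1 TR (the demonstration analyses use
5 TR to shorten sequences), and the window count is
W = floor((T−L)/stride) + 1. Within each window a weighted Pearson
correlation is used in which the taper weights enter the mean, the
covariance and both variances identically; uniform weights reduce it
exactly to the plain correlation, and a full-length uniform window
reproduces the static FNC. Windows with (numerically) zero weighted
variance raise an error naming the window. Scans of unequal length are
truncated to the cohort minimum before windowing so all sequences align.
No Fisher z-transform is applied anywhere (`fisher_z` exists as an
opt-in utility only).

## Brain-age models

Three architectures sit behind one training contract
(`brainage.train_brainage_cv`):

* **linear_baseline** — closed-form ridge regression (α = 1) on
  standardized features; dFNC sequences are time-averaged over windows
  first. Deterministic; used for fast calibration studies and as a
  transparent reference.
* **connectome_gcn** — the sFNC matrix acts both as weighted adjacency
  (absolute value, row-normalized; the unit diagonal is the self loop)
  and as node features. Two graph-convolution layers with ReLU, global
  mean pooling, linear output head.
* **bilstm** — stacked bidirectional LSTM over the window-ordered dFNC
  feature sequence, inverted dropout between recurrent layers, temporal
  mean pooling, linear head.

Both gradient-trained models use Adam on mean absolute error with
global-norm gradient clipping at 5, feature/target standardization by
training-set statistics, and single-precision arithmetic during
training (inference runs in double precision and is deterministic —
dropout is disabled). All gradients are hand-derived and verified
against central finite differences in the test suite.

**Cross-validation.** Grouped K = 5-fold: fold assignment is by subject
id, so multiple scans of one person never straddle train and
validation. Per-epoch validation MAE is recorded fold by fold
(`cv_report`); the selected epoch minimizes the mean across folds, and
the final model is refit on all data at that epoch budget. Out-of-fold
predictions at the selected epoch are retained so downstream brain-age
gaps are out-of-sample. A single master seed fans out (via
`numpy.random.SeedSequence`) to fold assignment, parameter
initialization, batch order and dropout.

**Profiles.** The full-scale configuration uses 3 recurrent layers of
128 hidden units, dropout 0.1, Adam(lr 10⁻³), batch 64, 100 epochs.
The desk-scale profile used by every shipped study is 1 bidirectional
layer of 32 hidden units, 20 epochs, Adam(lr 5·10⁻³), batch 32: at a
few hundred training scans the full-scale schedule yields only ~50
optimizer steps in 10 epochs, far too few for the regressors to move
off their initialization, so the desk profile takes a larger step size
and smaller batches. The CV scheme (K = 5) is never scaled down.

No post-hoc brain-age bias correction is applied; age and age² enter
the association model as covariates instead.

## Brain-age gaps and association testing

BAG = predicted − chronological age, exactly. For each (modality,
scope) pair the outcome (attention vigilance or working memory) is
regressed by OLS on [intercept, BAG, age, sex, site, age², age × sex,
diagnosis], with:

* a strict age filter (> 38 years, where FNC brain-age models are
  reliable) applied before fitting;
* age mean-centered before squaring — this tames the age/age²
  collinearity and, being an affine reparameterization, leaves the BAG
  coefficient unchanged;
* sex and diagnosis as 0/1 indicators (M, SZ); site as treatment
  dummies against the lexicographically first site;
* a rank check that raises a singularity error naming the collinear
  columns.

Reported per test: β (score points per year of BAG) with conventional
OLS standard error, a normal-approximation 95% CI (β ± 1.96·SE), the
raw p-value, and **r**, defined here as the partial correlation between
outcome and BAG given the covariates, computed as t/√(t² + df) — it is
sign-consistent with β by construction.

FDR correction is Benjamini–Hochberg step-up, applied within each test
family separately per outcome: the wide-brain family (sFNC + dFNC, 2
tests) and the sub-network family (7 networks × 2 modalities, 14
tests). Outcomes are corrected separately, modalities within an outcome
together.

## Synthetic cohort generator

The generator (`synthcohort`) emulates the statistical structure the
analysis assumes, not fMRI physics:

* **Phenotypes.** Ages uniform on [age_low, age_high] (uniform
  maximizes identifiability for recovery studies; real cohorts are
  skewed). Sex fair Bernoulli; site uniform over n_sites; diagnosis
  Bernoulli(prop_patients). Each subject carries a latent brain-age
  acceleration `true_bag` ~ N(δ, σ_bag²) for patients and N(0, σ_bag²)
  for controls; cognitive scores are baseline + γ·true_bag +
  N(0, σ_cog²). The latent column is written to disk but dropped by the
  loader unless explicitly requested, so the pipeline cannot peek.
* **Connectivity target.** A cohort-wide base correlation matrix comes
  from a 3-factor loading model (realistic positive/negative blocks).
  A designated edge set drifts linearly: edge value = base +
  slope·(age + true_bag − age_mid). Patients therefore look δ years
  older on exactly the edges that carry age information — the simplest
  mechanism consistent with "older-appearing" connectivity. Values are
  clipped to [−0.99, 0.99] and the matrix projected to the nearest
  positive semi-definite correlation (eigenvalue clipping at 0 with
  unit-diagonal renormalization, tolerance 10⁻⁸; non-convergence is an
  explicit error). Defaults: 2C edges with slope 0.008/yr — a 0.32
  swing over a 40-year span, readable by a regressor yet inside the
  valid correlation range.
* **Time courses.** Zero-mean Gaussian process whose instantaneous
  covariance is the subject's target correlation plus a slowly drifting
  symmetric perturbation (random walk, per-step scale
  `dynamic_drift_sd` = 0.02 by default), re-projected to a valid
  correlation at every step (batched eigenvalue clipping). With zero
  drift the process is stationary and the whole-scan sample correlation
  converges to the target. Defaults T = 160, TR = 2 s mirror a typical
  clinical resting-state protocol.
* **Determinism.** The entire cohort is a pure function of the
  `CohortSpec` including its seed; scans draw per-scan seeds from a
  spawned `SeedSequence`.

What the generator does **not** emulate: voxel-level signal, head
motion, scanner drift, hemodynamic autocorrelation, ICA estimation
error, site-dependent effects, or skewed age distributions. Passing
recovery tests therefore demonstrates that the pipeline measures what
it claims under its own assumptions — not that those assumptions hold
in any particular real dataset.

## Shipped studies and problem sizes

* **Effect recovery** (20 replicates): n = 400 subjects, C = 20,
  T = 160, δ = 5 y, γ = −0.5, desk-profile models (ridge for sFNC,
  biLSTM for dFNC), out-of-fold BAGs, wide-brain family. The dFNC
  BAG–attention association is counted as recovered when β < 0 with
  FDR p < 0.05.
* **Null calibration** (13 replicates × 32 tests = 416 p-values):
  n = 160, C = 14, T = 120, δ = 0, γ = 0, ridge models at all 16
  (modality, scope) pairs; the raw false-positive rate at α = 0.05 and
  a Kolmogorov–Smirnov uniformity check are reported.
* **Age-signal sanity**: n = 250, C = 20, T = 300, zero drift,
  controls only; 175/75 subject-level split. Held-out correlation for
  the ridge baseline and held-out MAE for the recurrent and connectome
  models against the mean-age predictor.

These sizes keep each study within minutes on a single CPU while
leaving the injected effects comfortably detectable.

## Pipeline and reproducibility

`pipeline.run_pipeline` executes simulate → fnc → train → predict →
associate, persisting every stage's outputs (CSV/TSV tables, HDF5
arrays, NPZ model states) under the run directory with a JSON manifest
(config echo, per-stage output hashes, wall-clock, library versions).
Existing stage outputs are reused, so deleting a downstream file and
re-running only the later stages reproduces it; with ridge models the
whole run is bit-reproducible from the master seed. Every consumed seed
is logged. Configuration is YAML-serializable with an exact round trip.

## Known limitations

* The connectome regressor is one member of the family of
  graph-convolutional connectome models (fixed row-normalized adjacency,
  two layers); other message-passing variants satisfying the same
  activation contract would be equally valid.
* The recurrent model's desk profile trades capacity for runtime; its
  cross-validated MAE on small synthetic cohorts should not be read as
  an estimate of full-scale performance.
* The association model assumes homoscedastic Gaussian residuals; no
  robust-SE option is provided.
* Sub-network age signal depends on how many drifting edges fall inside
  a network's block; with the default random edge set, small networks
  may carry little or no recoverable signal — as in real data, a null
  sub-network association is an expected outcome, not a failure.
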