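# Methods

This note documents the models, conventions and numerical choices
behind `radstab`, and what the synthetic-data tests do and do not show
about real data.

## Inputs and the shared-grid contract

The pipeline consumes nine co-registered 3D parametric maps — ADC
(diffusion), nCBV/nCBF (perfusion normalized to normal-appearing white
matter), MTT/TTP (transit timing), CTH/COV (capillary transit
heterogeneity and its coefficient of variation), OEF/CMRO2 (oxygen
extraction and metabolism) — plus an integer ROI labelmap
(0 background, 1 CET, 2 NEL, 3 necrosis), all NIfTI volumes on one
voxel grid. Registration and resampling are upstream concerns:
`image_io` refuses mismatched shapes or affines rather than resampling,
because silent resampling hides alignment errors. Necrosis is
segmented separately and excluded from both CET and NEL statistics.
Voxel spacing comes from the NIfTI affine; indexing is 0-based.

## Radiomics feature dictionary

The 1720-entry vector is pinned by `radstab.schema` (names, families,
canonical order; `schema.write_schema_json` dumps it). Family
membership follows the widely used open-source feature dictionary for
first-order (18), GLCM (24), GLRLM (16), GLSZM (16), GLDM (14), NGTDM
(5) and shape (14) features. Choices the counts do not determine:

- **Discretization**: fixed bin count (default 32) over the per-ROI
  min–max range. Fixed count is scale-free across maps with
  heterogeneous units (ADC in 10⁻³ mm²/s vs. dimensionless nCBV).
  Consequence: adding a constant to a map changes no texture feature
  (tested), while first-order location features shift by the constant.
- **GLCM/GLRLM aggregation**: distance-1 offsets over the 13 unique 3D
  directions, symmetric GLCM, feature values averaged over directions.
  Direction-aggregated features are invariant to 90° rotations of map
  and mask together (tested to float precision).
- **GLSZM/GLDM/NGTDM** use the 26-neighbourhood; GLDM dependence is
  neighbours with identical discretized level (α = 0), dependence size
  = dependent neighbours + 1.
- **Degenerate conventions**: a constant ROI returns variance 0,
  entropy 0, uniformity 1, skewness/kurtosis 0, GLCM joint energy 1,
  contrast 0, correlation 1 — finite limits rather than NaN, so
  constant phantoms do not crash the pipeline. NGTDM coarseness of a
  flat region saturates at 10⁶.
- **Shape**: mesh volume and surface from a marching-cubes mesh of the
  mask. The binary mask is mildly Gaussian-smoothed (σ = 0.8 voxels)
  before meshing: the raw staircase surface overestimates area by
  ~8–10%, which would bias sphericity of a digital ball to ~0.91; with
  anti-aliasing a radius-10 ball scores ~0.99 with volume within 5% of
  4/3·π·r³ (tested against the closed form). Axis lengths are
  4·√eigenvalue of the voxel-coordinate covariance; 2D diameters are
  max in-plane surface-voxel distances with the fixed-axis convention
  (axis 0 → "Slice", 1 → "Column", 2 → "Row"). Single-voxel masks fall
  back to voxel-box surrogates, flagged `degenerate` in the metadata.
- **No resegmentation, no intensity clipping, no filtered-image
  (wavelet/LoG) features, no 2D mode.**

A reference radiomics package is not available in this environment, so
the cross-checks are targeted instead of wholesale: GLCM construction
is verified against `skimage.feature.graycomatrix` on 2D slabs,
first-order moments against `scipy.stats`, shape against the analytic
sphere, and every texture family against hand-enumerated matrices.

## Spatial heterogeneity

Per map, CET and NEL voxel intensities are binned on shared edges
spanning the pooled CET∪NEL min–max (default 64 bins; exposed as
config). All bins are half-open `[lo, hi)` except the last (closed), so
hand examples are exact; values outside the range clip into the end
bins; a degenerate range yields a single bin of mass 1.

Two metrics per map: intersection `Σ min(H1ᵢ, H2ᵢ)` and the **bounded**
Bhattacharyya distance `√(1 − BC)` with `BC = Σ √(H1ᵢH2ᵢ)`. The
bounded form is used because it satisfies the required endpoints — 0
for identical histograms, 1 for disjoint supports — which the
unbounded form −ln BC cannot (it diverges at BC = 0). Mass differences
below 10⁻¹² are snapped to 0 so identical histograms return exactly
0.0. Both metrics are symmetric, bounded in [0, 1], invariant to joint
bin permutations, and empirically anti-correlated across random
histogram pairs (all tested).

## Temporal stability (ICC)

Variant: **ICC(A,1)** — two-way mixed effects, absolute agreement,
single measurement — computed from the two-way ANOVA mean squares:

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)(MSC − MSE)),  k = 2.

Rationale: the two occasions (initial, recurrence) are fixed
conditions of the same measurement system, and a systematic
initial-vs-recurrence shift should count against agreement. The
implementation matches `pingouin`'s ICC(A,1) to 10⁻⁸ (tested).
Negative estimates are kept as computed (truncation would bias the
filter); a feature at exactly 0.5 is excluded (strict threshold); no
multiple-testing correction is applied because the filter is a
point-estimate threshold, not a test. The IDH context uses all
longitudinal subjects; the EGFR context only subjects with concordant
amplification status at both surgeries (callers pass the subject list).
Subjects missing a timepoint are reported, never silently dropped.

## Models

Two-stage construction for both flavors:

1. **Selection**: L1-penalized logistic regression on z-scored features
   (training-set statistics; penalty fairness across units). λ is on
   the mean-loss scale (`C = 1/(n·λ)` for the solver), grid geometric
   from λ_max (the smallest λ with all coefficients zero) down 3
   decades, 25 points. λ chosen by stratified 10-fold cross-validated
   binomial deviance at the minimum (λ_min, default) or the sparsest
   value within one standard error (λ_1se, config). Exactly duplicated
   columns are collapsed to their first occurrence before fitting: the
   L1 optimum is non-unique across exact duplicates and the solver
   splits weight arbitrarily, so collapsing restores the canonical
   "one of each duplicated group" selection, deterministically.
2. **Refit**: unpenalized logistic regression on the selected features.
   Perfect separation (all fitted probabilities within 10⁻³ of their
   labels, or runaway coefficients) falls back to a ridge-stabilized
   fit, flagged in the model metadata. An empty selection yields a
   flagged intercept-only model rather than an error, so null
   simulations run to completion.

The *concordant* flavor restricts the search space to the stable set
before step 1 and is trained on the cross-sectional table (both flavors
are evaluated on the same cohorts, which implies a common training
cohort; fitting on the longitudinal table instead is possible by
passing that table). The decision threshold stored with each model is
the Youden-optimal cutoff on its training probabilities and is reused
on every evaluation cohort (no re-optimization on test data; the
report records the cutoff source). A `ModelSpec` serializes to JSON
with selected names, center/scale, coefficients, λ, threshold and seed,
and scores new tables bit-reproducibly.

No class weighting is applied despite the ~75/25 imbalance, no nested
cross-validation, no external validation, no calibration analysis —
performance on the training cohort is apparent (resubstitution)
performance by design.

## Evaluation

- **AUC**: midrank (ties = ½) estimator — identical to brute-force
  concordant-pair counting (tested to 10⁻¹² on random instances). 95%
  CI from the DeLong structural-component variance; coverage under the
  null verified to fall in [92%, 98%] over 500 simulations.
- **Youden cutoff**: exhaustive over midpoints between adjacent
  distinct scores plus ±∞; classification is `score > cutoff`;
  objective ties resolve to the lowest qualifying cutoff and are
  flagged. Equals exhaustive search on every tested instance.
- **Group comparisons**: independent-samples t-test; chi-square
  *without* continuity correction, so small hand tables (e.g.
  ((30,70),(70,30)) → χ² = 32) are exact. Two-sided p; the
  conventional significance level is 0.05, and both tests' type-I
  error is calibration-tested to [0.03, 0.08] at that level.
- **Sample size**: smallest total n for which the asymptotic AUC z-test
  (null 0.5) reaches the target power, with Hanley–McNeil
  exponential-model variances under both hypotheses and an explicit
  negatives-per-positive allocation ratio. For AUC 0.8, α = 0.05,
  power 80%, 1:3 allocation this gives 32 (one-sided) / 40 (two-sided);
  published figures near 36 for this configuration depend on the
  unstated variance model and sidedness, so the implementation is
  checked against a band rather than a single integer.
- **Longitudinal evaluation** pools both timepoints (2 × n rows), each
  scan scored with its surgery-matched genotype label.

## Synthetic data: what it emulates, and what it does not

**Feature-level cohorts** (`simulate_feature_cohort`): Gaussian
marginals, class effect in the mean only (Cohen's d), unit within-class
SD — so the single-feature AUC has the closed form Φ(d/√2) used as a
test oracle. Timepoint pairs are a bivariate-normal copula with
per-feature correlation ρ; the t2 class effect is attenuated by the
same ρ, so unstable features lose their genotype signal on the
recurrence scan. Class allocation is fixed-count
(round(n·prevalence)), giving reproducible confusion-matrix
denominators. Defaults mirror the study design this pipeline targets:
cross-sectional n = 312 at 25% positive prevalence, longitudinal
n = 38 with two timepoints.

**Study scenarios** (`simulate_study`): the stable-signal (IDH-like)
scenario gives 10 strong informative features (d = 2.0) low stability
(ρ = 0.1, no recurrence signal) and 10 weaker ones (d = 1.2) high
stability (ρ = 0.95, full recurrence signal), with all 20 sharing a
latent factor (pairwise correlation 0.6) — they read the same
underlying biology, so the L1 selection leans on the strong unstable
group and the best model degrades longitudinally. The unstable-signal
(EGFR-like) scenario makes the cross-sectional association vanish in
the longitudinal cohort entirely (effect 0 there), emulating a
genotype whose imaging correlate is spatially/temporally sporadic;
both models then sit at chance longitudinally. These parameters were
fixed from pilot runs of the generator and are the package's designed
study conditions, not tunables.

**Phantoms** (`simulate_phantom_pair`): three strictly nested ellipsoid
shells (necrosis core, CET shell, NEL shell) on grids up to 96³
(default 48³); per-map per-region means/SDs with plausible magnitudes
(e.g. nCBV 3.5 in CET vs. 1.5 in NEL); noise is white Gaussian
convolved with a Gaussian kernel (correlation length 1.5 voxels) and
renormalized to unit marginal variance. Because the field is spatially
correlated, ROI means wander more than an iid bound suggests; tests
allow for this.

Not emulated: realistic tumor morphology, DSC time series/AIF/
deconvolution, scanner or protocol effects, non-Gaussian feature
marginals, missingness. Passing tests therefore demonstrate the
*machinery* — feature bookkeeping, metric identities, estimator
consistency, the stability-filter mechanism — under designed
conditions; they do not certify diagnostic performance on real gliomas,
and the real patient-data results this kind of analysis reports are not
reproducible from synthetic inputs.

## Determinism and problem sizes

Every random stage consumes a seed spawned from one master seed
(`numpy` SeedSequence; solver seeds < 2³¹); identical config + seed is
bit-identical, and pipeline reruns produce byte-identical artifacts
(tested). Default test problem sizes — 48³ phantoms, cohorts of a few
hundred patients, 20-seed scenario replicates — were chosen so the full
suite exercises every stage at desk scale; they are stated in the tests
themselves.
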