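# radstab

Radiomics **spatial heterogeneity** and **temporal stability** for
multi-parametric glioma MRI.

`radstab` is a tested, reusable implementation of an imaging-based
molecular-characterization analysis for adult-type diffuse gliomas:
quantitative features are extracted from diffusion and perfusion
parametric maps over the contrast-enhancing tumor (CET) and the
non-enhancing lesion (NEL), screened for test–retest stability across
longitudinal scan pairs, and fed into L1-penalized logistic models that
diagnose genotype (IDH mutation; EGFR amplification in IDH-wildtype
tumors). Every stage is exercisable end-to-end on synthetic cohorts and
phantoms, so the pipeline is testable without any patient data.

It is intended for quantitative-imaging researchers who want the
analysis chain — not a segmentation or perfusion-processing tool; it
consumes co-registered NIfTI parametric maps and ROI labelmaps produced
upstream.

## The analysis

**Feature vector (1720 per patient-timepoint).** For each of nine
parametric maps (ADC, nCBV, nCBF, MTT, TTP, CTH, COV, OEF, CMRO2) and
each ROI (CET, NEL): 18 first-order + 24 GLCM + 16 GLRLM + 16 GLSZM +
14 GLDM + 5 NGTDM = 93 intensity/texture features. Plus 14 shape
features per ROI and 2 spatial-heterogeneity metrics per map:

    (93 × 9 × 2) + (14 × 2) + (9 × 2) = 1720

**Spatial heterogeneity.** With H1, H2 the unit-sum intensity
histograms of CET and NEL on shared bin edges,

    D_intersection(H1, H2) = Σᵢ min(H1ᵢ, H2ᵢ)               ∈ [0, 1]
    D_bhattacharyya(H1, H2) = √(1 − Σᵢ √(H1ᵢ · H2ᵢ))        ∈ [0, 1]

Intersection is 1 for identical histograms and 0 for disjoint supports;
the (bounded-form) Bhattacharyya distance runs the opposite way.

**Temporal stability.** For patients whose genotype is unchanged
between initial and recurrence surgery, each feature's agreement across
the two scans is the two-way mixed-effects, absolute-agreement,
single-measurement ICC; features with ICC > 0.5 (strict) are kept.

**Models.** The *best* model: LASSO-logistic feature selection (λ by
stratified 10-fold cross-validated deviance) over all features of the
cross-sectional cohort, followed by an unpenalized logistic refit. The
*concordant* model: the same construction restricted to the temporally
stable feature set. Evaluation: rank-based AUC with DeLong 95% CI,
Youden-optimal cutoff, sensitivity/specificity/accuracy with counts —
on the cross-sectional cohort and on the pooled longitudinal cohort
(both scans per patient, 2 × n rows).

## Worked example

`examples/` holds one short script per capability. The central one:

```bash
python examples/04_best_vs_concordant.py
```

```
stable features: 189/200
best selected 9 features, concordant 23 (all stable)
best       cross-sectional AUC 0.948 | pooled longitudinal AUC 0.707
concordant cross-sectional AUC 0.950 | pooled longitudinal AUC 0.779
```

The simulated study gives the strongest cross-sectional features a low
between-scan correlation (ρ = 0.1) and a weaker, correlated subset a
high one (ρ = 0.95). Both models look equally strong on the
cross-sectional cohort; on the pooled longitudinal cohort the best
model's selected features have lost their genotype signal and its AUC
drops, while the stability-filtered concordant model holds up — the
qualitative pattern the pipeline is built to expose.

Other examples: phantom simulation + full 1720-feature extraction
(`01`), histogram-overlap metrics with hand-checkable numbers (`02`),
the ICC stability filter (`03`), AUC-based sample size and Youden
operating points (`05`).

## Command line

A thin CLI wraps the library:

```bash
radstab simulate --seed 3 --grid 48 --out phantom/
radstab extract --maps-dir phantom/ --labelmap phantom/labelmap.nii.gz --out features.csv
radstab heterogeneity --maps-dir phantom/ --labelmap phantom/labelmap.nii.gz
radstab run-all --seed 1 --out run/
```

`run-all` executes simulate → stability → train → evaluate behind one
config (YAML via `--config`); every artifact records the config hash,
and reruns with the same seed are byte-identical.

## Layout

- `src/radstab/` — the library (`synthetic`, `image_io`, `firstorder`,
  `shape`, `texture`, `extract`, `heterogeneity`, `stability`,
  `modeling`, `evaluation`, `pipeline`, `cli`, `schema`)
- `tests/` — unit, property and acceptance suites
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — models, conventions, numerical choices, limits
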