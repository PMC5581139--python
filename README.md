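# tumortex

Whole-tumor CT texture analysis for pathologic grading of lung
adenocarcinoma — a 3D radiomics feature engine plus the statistical
workflow that links image heterogeneity to grade.

Invasive lung adenocarcinoma is classified by its predominant growth
pattern (IASLC/ATS/ERS): lepidic, acinar or papillary predominant
tumors form the *intermediate* grade group, while solid,
micropapillary, colloid predominant and invasive mucinous tumors form
the *high* grade group with worse prognosis. Biopsies sample a fraction
of a heterogeneous tumor; contrast-enhanced CT sees all of it. This
package quantifies that whole-tumor information and asks, cohort-wide,
whether texture predicts grade better than clinical variables do.

It is written for imaging researchers who have (a) CT volumes in HU
with co-registered binary tumor masks (NRRD or NIfTI) and a clinical
covariate table, or (b) no images at all — a synthetic phantom
generator reproduces the full pipeline behavior, and a counts-only mode
refits the clinical model from a published 2×2 table.

## What it computes

**54 features per tumor** (ids `F1`–`F54`):

| Family | Features | Basis |
|---|---|---|
| First-order | F1–F14 (energy, entropy, moments, uniformity…) | ROI intensity histogram |
| Shape | F15–F22 (volume, surface area, compactness, sphericity…) | binary mask + spacing |
| GLCM texture | F23–F43 (contrast, correlation, homogeneity, IMC1…) | co-occurrence matrices, 13 directions |
| GLRLM texture | F44–F54 (SRE, LRE, GLN, RLN, run percentage…) | run-length matrices, 13 directions |

**Cohort statistics**, statsmodels-style (`GradeModel(...).fit()` →
results object with `summary()`):

* univariate screen per feature — Welch *t* (mean ± SD) or
  Mann–Whitney U (mean ranks), gated by Shapiro–Wilk normality;
* logistic models by Newton/IRLS with Wald inference: predictors enter
  at univariable p < 0.15 and are backward-eliminated at p > 0.05,
  with odds ratios exp(β) and 95% CIs exp(β ± 1.96·SE);
* ROC curves with tie-corrected AUC = (#concordant + ½·#ties)/(n₁n₀),
  DeLong confidence intervals, the Youden-optimal operating point, and
  the DeLong test comparing the correlated texture- and clinical-model
  AUCs;
* Cohen's kappa (with the standard qualitative bands) and
  chi-square/Fisher 2×2 association for categorical covariates.

## Worked example

The clinical model alone needs nothing but a smoking-by-grade count
table (rows: never smokers, smokers; columns: intermediate, high):

```sh
$ tumortex report --counts 68,13,45,22
smoking OR 0.391 (95% CI 0.179-0.855), p=0.01865
chi-square association p = 0.01675
AUC 0.615; sensitivity 62.9%, specificity 60.2% (high grade positive)
```

Read: smokers have 0.391 times the odds of being intermediate (rather
than high) grade; as a lone classifier of high grade, smoking achieves
AUC 0.615, and at the Youden cutoff identifies 62.9% of high-grade
tumors while clearing 60.2% of intermediate ones.

The full pipeline on a synthetic cohort (113 intermediate + 35
high-grade phantoms whose high-grade class carries twice the fine-scale
texture amplitude):

```sh
tumortex simulate --out sim/ --exact-smoking-counts --seed 2026
tumortex extract  --manifest sim/manifest.csv --out features.csv
tumortex analyze  --features features.csv --out analysis/
```

which prints (abridged):

```
cohort: 113 intermediate, 35 high grade
univariate screen: 30/54 features with p < 0.05

Clinical model
  smoking          OR 0.391 (95% CI 0.179-0.855), p=0.01865
  AUC 0.615 (95% CI 0.522-0.708); sens 62.9%, spec 60.2% at Youden cutoff

Texture model (per-SD odds ratios)
  ...
  AUC 0.991 (95% CI 0.981-1.000); sens 91.4%, spec 100.0% at Youden cutoff

DeLong texture vs clinical: ΔAUC = +0.376, z = 7.996, p = 1.281e-15
```

The homogeneity-family features (F33 Homogeneity 1, F38 Inverse
Variance) are flagged by the screen — the heterogeneous high-grade
class is less homogeneous — and the texture model outperforms the
clinical model, with the DeLong test quantifying the AUC difference.
`analysis/` holds the univariate listing, model tables (JSON), ROC
points and plot, and the resolved configuration for provenance.

The same objects are available as a library:

```python
import pandas as pd
from tumortex import GradeModel, extract_features, read_volume_with_mask

v = read_volume_with_mask("case01_image.nrrd", "case01_mask.nrrd")
features = extract_features(v, ng=64)          # pandas Series, F1..F54
res = GradeModel(cohort_df).fit()              # cohort_df: features + covariates + grade
print(res.summary())
```

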