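# rectex

Texture analysis of single-slice rectal-cancer MRI for discriminating
low (T1/2) from high (T3/4) local-invasion stage, packaged as a tested,
reproducible pipeline — together with a synthetic cohort generator that
stands in for patient data.

## Who this is for

Radiomics/imaging-informatics researchers who want a transparent,
end-to-end reference implementation of the classic two-sequence
(sagittal fat-suppression + transverse T2-weighted) texture workflow:
manual single-slice ROIs, a small fixed feature set, univariate group
statistics, ROC operating points, and a dichotomized logistic model —
rather than a large black-box radiomics platform.

## The method

Each case contributes one ROI per sequence type. From the raw in-ROI
intensities and their min–max quantization to Ng = 32 gray levels, the
pipeline computes 12 features per sequence (24 per case):

* **Histogram** — skewness SKE = m₃/m₂^{3/2} and Pearson kurtosis
  KUR = m₄/m₂² (normal → 3) of the raw intensities.
* **GLCM** (distance 1; angles 0°, 45°, 90°, 135°, averaged) —
  correlation CORR = Σᵢⱼ(i−μ)(j−μ)P(i,j)/σ², dissimilarity
  DISS = Σᵢⱼ|i−j|P(i,j), entropy ENTR = −Σᵢⱼ P ln P.
* **GRLM** (same four angles, averaged) — long-run emphasis
  LRE = (1/N_r)Σ R(i,j)·j², gray-level non-uniformity
  GLN = (1/N_r)Σᵢ(Σⱼ R(i,j))², low gray-level run emphasis
  LGLRE = (1/N_r)Σ R(i,j)/i².
* **Haar DWT** (2 levels on the mean-filled, reflect-padded ROI
  bounding box) — mean |coefficient| of the level-2 approximation
  (Harr-L) and of the horizontal / vertical / diagonal detail subbands
  (Harr-H, Harr-V, Harr-D).

The statistical stage mirrors standard clinical-imaging practice:
Kolmogorov–Smirnov normality dispatch to Mann–Whitney U or pooled
t-test; χ²/Fisher for categorical covariates; per-marker ROC with
DeLong 95% CIs and Youden-index cutoffs (markers auto-oriented so
AUC ≥ 0.5); pairwise DeLong comparison of AUCs; VIF > 10 collinearity
exclusion; a multivariate logistic model on the cutoff-dichotomized
significant features, whose Wald-significant ("independent")
predictors are refit as the combined model; Spearman correlation of
each feature with stage; and two-rater reliability as ICC(2,1).

Because no patient images are distributed, `rectex.synthetic`
generates a two-group cohort with the structure the analysis assumes:
bright irregular lesions whose in-ROI texture is a structured core
plus a Gaussian random field, with systematically more gray-level
disorder (weaker organized core, rougher field) in the T3/4 group, a
perturbed second-rater mask per case, and clinical covariates with no
group effect.

## Worked example

```bash
cat > run.yaml <<EOF
cohort:
  n_low: 60
  n_high: 60
EOF
rectex run-all --config run.yaml --out demo --seed 3
```

prints

```
INFO rectex: cohort: 120 cases ({'T12': 60, 'T34': 60})
INFO rectex: univariately significant: ['sag_SKE', 'sag_KUR', 'sag_CORR',
  'sag_DISS', 'sag_ENTR', 'sag_LRE', 'sag_LGLRE', 'sag_Harr-L', 'tra_SKE',
  'tra_KUR', 'tra_CORR', 'tra_DISS', 'tra_ENTR', 'tra_LRE', 'tra_LGLRE',
  'tra_Harr-L']
done: 120 cases, 16 significant features, combined AUC 0.863
```

and writes `features.csv`, `covariates.csv`, `univariate.csv`,
`roc.csv`, `delong.csv`, `model.json` and `icc.csv` under `demo/`.
In this run 16 of 24 features separate the groups univariately
(e.g. `sag_SKE`: 1.550 ± 0.616 vs 0.948 ± 0.589, t-test p = 0.0003);
the VIF screen excludes six collinear features (worst VIF 61.1); the
best single marker is `tra_CORR` with AUC 0.788 (sensitivity 76.7%,
specificity 75.0% at its Youden cutoff); three predictors survive the
multivariate Wald test (odds ratios 3.8–10.8), and the combined model
built from them reaches AUC 0.863 (95% CI 0.799–0.926, sensitivity
71.7%, specificity 88.3%) — better than any single marker. The
two-rater ICC stage reports a median ICC(2,1) of 0.869 across the 24
features. Identical config and seed reproduce every output file
byte-for-byte.

The same stages are available as library functions
(`rectex.extract_features`, `rectex.univariate_report`,
`rectex.roc_report`, `rectex.multivariate_report`,
`rectex.icc_report`, `rectex.run_full_pipeline`) and as separate CLI
steps (`rectex simulate`, `rectex extract`, `rectex analyze
univariate|roc|multivariate`).

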