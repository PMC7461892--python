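# Methods

This note records the models, conventions and numerical choices behind
`rectex`, in the order the pipeline applies them, and what the
synthetic cohort does and does not emulate.

## ROI handling and quantization

A case is two single-slice ROIs (sagittal fat-suppression type and
transverse type). Masks are binarized at > 0 (non-binary masks warn);
an ROI must contain at least 16 pixels (configurable) because the
matrix features below are ill-conditioned on smaller regions.

Gray levels are assigned by per-ROI min–max binning,

    level = min(Ng, floor((x − min)/(max − min) · Ng) + 1),

with min/max taken over the ROI only, so levels are invariant to
affine intensity rescaling of the whole ROI — texture is measured
relative to the lesion's own dynamic range, not the scanner's. The
default Ng = 32 is a common radiomics choice; the level 0 is reserved
for "outside the ROI" everywhere. A constant ROI maps to level 1 with
a warning, and features that are undefined there (SKE, KUR, CORR) are
flagged as missing rather than failing the case.

Pixel-grid angle convention (row-major): 0° steps along a row toward
increasing column, 45° up-right, 90° up a column, 135° up-left.

## Texture features

* Histogram features use the **raw** in-ROI intensities (not the
  quantized levels): quantization is a matrix-feature device, and raw
  moments preserve distribution shape. Kurtosis is Pearson
  (non-excess; normal → 3).
* GLCM: symmetric accumulation (each ordered pair counted both ways)
  at distance 1 for the four angles, each matrix normalized to sum 1;
  the feature is the unweighted mean over angles. Angles with no valid
  in-mask pair (thin ROIs) are dropped with a warning rather than
  failing the case; CORR is undefined when only one gray level occurs.
  Entropy is natural-log by default (`log_base` rescales).
* GRLM: maximal runs of equal level along the four angle line
  families; out-of-mask pixels terminate runs. Features averaged over
  angles as above.
* Haar DWT: the mask bounding box is cut from the raw image,
  outside-mask pixels replaced by the in-ROI mean (minimizing the
  artificial edge at the ROI border), the box reflect-padded to
  multiples of 4, and a 2-level orthonormal Haar transform applied
  (periodization mode — exact energy conservation on these even
  sizes). Features are the mean absolute coefficient of the four
  level-2 subbands. Subband orientation is fixed and tested: Harr-H is
  the subband high-passed across the row index, i.e. it responds to
  horizontal edges (an image with rows a,a,b,b gives Harr-H = 2|a−b|);
  Harr-V is its transpose counterpart. Boxes smaller than 4×4 are
  rejected.

The per-case vector is exactly 24 named features (`sag_`/`tra_`
prefix × 12 names). Printed magnitudes of some features in the
clinical literature differ from integer-level conventions by
undocumented normalizations in in-house software; this implementation
fixes and documents its own conventions rather than reverse-engineer
magnitudes.

## Statistical stages

**Univariate.** Each feature is tested for normality per group with a
one-sample KS test against Normal(mean, SD) (parameters estimated, no
Lilliefors correction — matching common "1-Sample K-S" usage in
clinical software; anti-conservative for this purpose, documented as
such). The t-test is used only when *both* groups pass at α = 0.05
(conservative resolution of an ambiguous convention); otherwise
Mann–Whitney U (exact when n₁+n₂ ≤ 20 without ties, else the
tie-corrected normal approximation). Summaries are mean ± SD or
median ± IQR to match the test. No multiple-testing correction is
applied, matching the emulated workflow; the consequences are
quantified below.

**ROC.** AUC is the Mann–Whitney statistic with ties counted ½;
markers with raw AUC < 0.5 are re-oriented (`less_is_positive`) and
the orientation recorded so cutoffs stay interpretable. CIs are Wald
intervals from DeLong's structural-component variance, clipped to
[0, 1]; with degenerate placements the CI collapses to the point
estimate. Youden cutoffs search the observed score values with a
strictly-greater positive call; ties break toward higher sensitivity,
then the lower oriented threshold. The paired DeLong test works on
raw scores (the two-sided z is orientation-insensitive) and returns
p = 1 for markers with identical placements.

**Multivariate.** Univariately significant features enter a VIF
screen (VIF_j = 1/(1−R_j²), iteratively removing the worst feature
while any VIF > 10; exact dependence recorded as infinite VIF). The
retained features are dichotomized at their Youden cutoffs
(indicator = oriented score strictly above the cutoff) and fitted by
an unpenalized IRLS logistic regression (convergence max|Δβ| < 1e−8,
≤ 100 iterations; |β| > 15 is flagged as quasi-separation and the fit
marked non-converged rather than silently reported). Wald p < 0.05
defines the "independent predictors"; the combined model refits on
those only — with none, it degenerates to intercept-only (combined
AUC 0.5). Spearman ρ of each (continuous) entrant against the stage
label is reported alongside.

**Reliability.** Two-rater agreement is ICC(2,1) — two-way random
effects, absolute agreement, single measurement — computed from the
ANOVA mean squares, with the conventional bands (≤ 0.4 poor, ≤ 0.6
moderate, ≤ 0.8 good, else excellent). The emulated design is
inter-rater (two readers), and the output says so.

## The synthetic cohort

Each slice is a darker noisy background (smooth field, SD 4) carrying
a bright irregular lesion: a thresholded smoothed blob (largest
connected component), not a disk, so irregular masks are exercised.
In-ROI intensity = plateau (+30 over background) + a compact bright
Gaussian core (the organized, dense tumor focus; radius 0.35 of the
ROI) + a Gaussian random field (white noise smoothed to a correlation
length, rescaled to a target SD). A 0.6-px Gaussian point-spread blur
is applied to the composed image, giving realistic partial-volume
edges; intensities are rounded to integers (16-bit range), so the PNG
round-trip is lossless and in-memory and on-disk pipelines agree
exactly.

The deterministic core is essential: per-ROI min–max quantization
makes a *pure* scaled noise field quantize identically at every SD,
so a fixed structural contrast must anchor the intensity window for
the disorder features to respond. Group structure (defaults, chosen
once as the study conditions):

* T1/2: correlation length 2.0 px, field SD 6.0, core contrast 58;
* T3/4: correlation length 1.85 px, field SD 6.6, core contrast 38 —
  high-stage tumors lose organized internal architecture and are
  relatively more disordered, which raises DISS/ENTR and lowers
  CORR/LRE/SKE/KUR, at univariate AUCs around 0.7–0.8 (the moderate
  regime in which combining markers genuinely adds value; a stronger
  separation makes single markers unbeatable and the multivariate
  stage pointless).
* Per-case lognormal spread around the group values (σ = 0.5 for the
  field SD, 0.6× that for the core, 0.3× for the correlation length),
  drawn independently for the two sequence types: the two imaging
  planes cut different parts of the tumor, and this cross-sequence
  independence is exactly what lets the combined model beat the best
  single marker. ROI radius is uniform on 16–28 px in 128-px images.

Cohort sizes default to 62/112 (a typical retrospective cohort split); the test
and acceptance protocols use 60 + 60. Covariates (sex, age, location,
diameter, differentiation, N stage) are sampled i.i.d. within group
from fixed marginals with *no* group effect, so covariate comparisons
are a null-calibration check of the categorical/quantitative test
dispatch.

Second-rater masks displace the boundary by a smoothed noise field
clipped to ±1 and scaled by the jitter (default 1 px), thresholded on
the half-pixel signed distance contour: displacement is bounded by
the jitter, jitter 0 reproduces the mask exactly, and jitter 1 gives
Dice ≈ 0.95 on typical lesions.

What the generator does **not** emulate: MRI physics (coil profiles,
bias fields, Rician noise), 3-D tumor geometry, necrosis/gas
exclusion, any covariate–texture dependence, or cross-sequence
intensity calibration. Passing tests therefore demonstrate that the
pipeline recovers planted textural group structure and is calibrated
in the engineered null — not that the features have clinical validity
on real scans.

## Known behaviors and limitations

* **Selection effects are real and visible.** With 24 features
  screened at α = 0.05, no correction, and Youden cutoffs optimized
  in-sample, a fully null cohort still yields at least one
  "significant" feature in roughly a third to a half of runs, and the
  in-sample DeLong CI of the resulting one-predictor combined model
  then excludes 0.5. The test suite asserts the idealized calibration
  expectation (CI covering 0.5 in ≥ 80% of null runs) and that
  assertion fails at the measured ~70%: the workflow itself — not the
  implementation — is optimistically biased under the null. Users
  should treat the combined-model CI as descriptive, not inferential.
* The Wald screen on many correlated dichotomized predictors splits
  credit; occasionally a single predictor survives and the reduced
  combined model underperforms the best single marker. This
  instability is a property of the select-then-refit procedure at
  n ≈ 120.
* ICC on the synthetic cohort (median ≈ 0.85 at jitter 1) reflects
  between-case parameter spread versus mask-perturbation sensitivity;
  window-sensitive features (LGLRE, CORR, SKE) are genuinely fragile
  to 1-px boundary changes and can fall to poor agreement — a finding
  that mirrors how strongly single-slice texture reliability depends
  on ROI delineation.
* Problem sizes in tests and the acceptance script (60 + 60 cases,
  20-seed protocols, 128-px slices) were chosen as the smallest
  cohorts at which the two-group design and its power are
  representative.
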