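"""Between-group univariate statistics and two-rater reliability.

The comparison protocol for a quantitative variable is: test each group
for normality with a one-sample Kolmogorov-Smirnov test against
Normal(mean, SD); if either group is non-normal (p < 0.05) compare with
the Mann-Whitney U test and summarize as median +/- IQR, otherwise use the
pooled-variance independent t-test and summarize as mean +/- SD.
Categorical variables use Pearson's chi-square, falling back to Fisher's
exact test for 2x2 tables with a small expected count.  Rater agreement
uses the two-way random-effects, absolute-agreement, single-measurement
intraclass correlation ICC(2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError


@dataclass(frozen=True)
class UnivariateResult:
    feature: str
    test: str                      # "mann_whitney" | "t_test"
    low_summary: str               # T1/2 group, "center ± spread"
    high_summary: str              # T3/4 group
    low_center: float
    high_center: float
    p_value: float
    significant: bool


@dataclass(frozen=True)
class ICCResult:
    icc: float
    form: str
    band: str


# ---------------------------------------------------------------------------

def ks_normality(sample) -> float:
    """One-sample KS p-value against Normal(sample mean, sample SD).

    Parameters are estimated from the data and the asymptotic Kolmogorov
    distribution is used without a Lilliefors correction, mirroring the
    common "1-Sample K-S" usage in clinical statistics software; the
    resulting p-values are anti-conservative for the normality question
    but are what the dispatch rule expects.  A constant sample is
    non-normal by convention (p = 0).
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 4:
        raise DegenerateDataError("need n >= 4 for the KS normality test")
    sd = x.std(ddof=1)
    if sd == 0:
        warnings.warn("constant sample: non-normal by convention",
                      stacklevel=2)
        return 0.0
    return float(
        sps.kstest(x, "norm", args=(x.mean(), sd), method="asymp").pvalue
    )


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Exact enumeration when n1 + n2 <= 20 and there are no ties; otherwise
    the tie-corrected normal approximation with continuity correction.
    Returns (U, p) with U counting (x > y) pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateDataError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 20 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def t_test_independent(x, y) -> tuple[float, float]:
    """Two-sided pooled-variance (Student) independent-samples t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateDataError("need n >= 2 per group")
    if x.std() == 0 and y.std() == 0:
        raise DegenerateDataError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def compare_feature(
    x, y, name: str = "", alpha: float = 0.05
) -> UnivariateResult:
    """Normality-dispatched group comparison (x = low group, y = high).

    The t-test is used only when BOTH groups pass the KS normality check.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normal = ks_normality(x) >= alpha and ks_normality(y) >= alpha
    if normal:
        _, p = t_test_independent(x, y)
        test = "t_test"
        cx, cy = x.mean(), y.mean()
        sx, sy = x.std(ddof=1), y.std(ddof=1)
    else:
        _, p = mann_whitney_u(x, y)
        test = "mann_whitney"
        cx, cy = np.median(x), np.median(y)
        sx = np.subtract(*np.percentile(x, [75, 25]))
        sy = np.subtract(*np.percentile(y, [75, 25]))
    return UnivariateResult(
        feature=name,
        test=test,
        low_summary=f"{cx:.3f} ± {sx:.3f}",
        high_summary=f"{cy:.3f} ± {sy:.3f}",
        low_center=float(cx),
        high_center=float(cy),
        p_value=float(p),
        significant=bool(p < alpha),
    )


def categorical_tests(table, alternative: str = "two-sided") -> float:
    """p-value for independence in an r x c count table.

    Pearson chi-square without continuity correction; Fisher's exact test
    (two-sided by the point-probability rule) for a 2x2 table whenever any
    expected count falls below 5.  ``alternative`` is honored only on the
    Fisher path.
    """
    t = np.asarray(table, dtype=float)
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table must hold nonnegative integer counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise DegenerateDataError("zero row or column margin")
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    if t.shape == (2, 2) and expected.min() < 5:
        return float(
            sps.fisher_exact(t.astype(int), alternative=alternative).pvalue
        )
    chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return float(p)


def icc_two_rater(ratings1, ratings2) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA mean squares of the n x 2 rating
    matrix.  The agreement band follows the conventional cuts 0-0.4 poor,
    0.41-0.6 moderate, 0.61-0.8 good, 0.81-1 excellent.
    """
    r1 = np.asarray(ratings1, dtype=float)
    r2 = np.asarray(ratings2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("ratings must be paired 1-D arrays")
    n = r1.size
    if n < 3:
        raise DegenerateDataError("need n >= 3 subjects")
    X = np.column_stack([r1, r2])
    k = 2
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    grand = X.mean()
    if np.allclose(row_means.var(), 0):
        raise DegenerateDataError("zero between-subject variance")
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    mse = (
        ((X - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
        / ((n - 1) * (k - 1))
    )
    icc = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc <= 0.4:
        band = "poor"
    elif icc <= 0.6:
        band = "moderate"
    elif icc <= 0.8:
        band = "good"
    else:
        band = "excellent"
    return ICCResult(icc=float(icc), form="ICC(2,1) inter-rater", band=band)
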