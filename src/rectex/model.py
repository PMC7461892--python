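"""Multivariate stage: collinearity screening, cutoff dichotomization,
logistic regression, Spearman correlation and the combined-model ROC.

Features entering the multivariate model are first screened for
collinearity with the variance inflation factor (VIF > 10 excludes the
worst offender, iteratively), then converted to binary indicators at
their Youden cutoffs, and finally entered into an unpenalized logistic
regression fitted by iteratively reweighted least squares.  Odds ratios
with Wald intervals are reported per predictor; predictors with Wald
p < 0.05 are flagged as independent predictors and a reduced model refit
on those alone provides the combined-model ROC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError
from .roc import GREATER, ROCResult, roc_analysis

VIF_THRESHOLD = 10.0
SEPARATION_BETA = 15.0


@dataclass(frozen=True)
class VIFReport:
    vif: dict                     # retained feature -> VIF
    excluded: list = field(default_factory=list)  # (feature, VIF at exclusion)

    @property
    def retained(self) -> list:
        return list(self.vif)


@dataclass
class LogisticModelResult:
    predictors: list
    beta: np.ndarray              # slopes, aligned with predictors
    intercept: float
    se: np.ndarray                # slope standard errors
    odds_ratio: np.ndarray
    or_ci: np.ndarray             # (p, 2) Wald 95% interval for the OR
    p_values: np.ndarray
    probabilities: np.ndarray     # fitted P(high stage) per case
    converged: bool
    separated: bool
    iterations: int


def _r_squared(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of y regressed on X plus an intercept, via least squares."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise DegenerateDataError("constant feature in VIF screen")
    return float(1.0 - (resid ** 2).sum() / tss)


def vif_screen(
    features: pd.DataFrame, threshold: float = VIF_THRESHOLD
) -> VIFReport:
    """Iteratively exclude the highest-VIF feature while any VIF exceeds
    ``threshold``.

    VIF_j = 1 / (1 - R_j^2) from regressing feature j on all the others
    (with intercept).  Exact linear dependence is reported as infinite
    VIF.  With a single remaining feature the VIF is 1 by definition.
    """
    df = features.astype(float)
    n, p = df.shape
    if p < 2:
        return VIFReport(vif={c: 1.0 for c in df.columns})
    if n <= p + 1:
        raise DegenerateDataError("need n > p + 1 for the VIF screen")
    excluded = []
    cols = list(df.columns)

    def vifs_of(cols):
        out = {}
        for c in cols:
            others = [o for o in cols if o != c]
            if not others:
                out[c] = 1.0
                continue
            r2 = _r_squared(df[c].to_numpy(), df[others].to_numpy())
            out[c] = math.inf if r2 > 1 - 1e-12 else 1.0 / (1.0 - r2)
        return out

    while True:
        v = vifs_of(cols)
        worst = max(cols, key=lambda c: v[c])
        if v[worst] > threshold and len(cols) > 1:
            excluded.append((worst, v[worst]))
            cols.remove(worst)
        else:
            return VIFReport(vif=v, excluded=excluded)


def dichotomize(
    features: pd.DataFrame, roc_results: dict[str, ROCResult]
) -> pd.DataFrame:
    """Binary indicators from Youden cutoffs, honoring marker orientation.

    indicator = 1 when the oriented score strictly exceeds its cutoff
    (score > cutoff for ``greater_is_positive`` markers, score < cutoff
    otherwise); equality maps to 0.
    """
    out = {}
    for col in features.columns:
        if col not in roc_results or roc_results[col].cutoff is None:
            raise KeyError(f"no ROC cutoff available for feature {col!r}")
        r = roc_results[col]
        x = features[col].to_numpy(dtype=float)
        if r.orientation == GREATER:
            out[col] = (x > r.cutoff).astype(int)
        else:
            out[col] = (x < r.cutoff).astype(int)
    return pd.DataFrame(out, index=features.index)


def fit_logistic(design, labels, max_iter: int = 100,
                 tol: float = 1e-8) -> LogisticModelResult:
    """Unpenalized logistic regression by IRLS with Wald inference.

    Convergence when max |delta beta| < ``tol``; a coefficient drifting
    beyond |beta| > 15 is taken as (quasi-)separation and the fit is
    flagged non-converged rather than silently reported.
    """
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(labels, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise DegenerateDataError("need n > predictors + 1")
    if y.min() == y.max():
        raise DegenerateDataError("both classes must be present")
    A = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = A.T @ (A * w[:, None])
        g = A.T @ (y - mu)
        try:
            delta = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(H, g, rcond=None)[0]
        beta = beta + delta
        if np.abs(beta).max() > SEPARATION_BETA:
            separated = True
            break
        if np.abs(delta).max() < tol:
            converged = True
            break
    eta = A @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    H = A.T @ (A * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    slopes, slope_se = beta[1:], se[1:]
    z = np.divide(slopes, slope_se, out=np.zeros_like(slopes),
                  where=slope_se > 0)
    return LogisticModelResult(
        predictors=names,
        beta=slopes,
        intercept=float(beta[0]),
        se=slope_se,
        odds_ratio=np.exp(slopes),
        or_ci=np.exp(np.clip(
            np.column_stack([slopes - 1.96 * slope_se,
                             slopes + 1.96 * slope_se]), -700, 700
        )),
        p_values=2 * sps.norm.sf(np.abs(z)),
        probabilities=np.clip(mu, 1e-12, 1 - 1e-12),
        converged=converged,
        separated=separated,
        iterations=it,
    )


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation with t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DegenerateDataError("need n >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateDataError("zero rank variance")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def combined_model_roc(model: LogisticModelResult, labels) -> ROCResult:
    """ROC of the model's fitted probabilities, with Youden operating
    point."""
    return roc_analysis(model.probabilities, labels)
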