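"""ROC analysis: AUC with DeLong confidence intervals, Youden-index
operating points, and paired DeLong comparison of correlated AUCs.

The AUC is the Mann-Whitney probability P(score+ > score-) with ties
counted 1/2.  Markers whose raw AUC falls below 0.5 are re-oriented
(``less_is_positive``) so the reported AUC is always >= 0.5, and the
orientation is recorded so cutoffs stay interpretable on the original
scale.  Variances and covariances of AUCs use DeLong's structural
components (per-observation placement values), giving Wald 95% intervals
clipped to [0, 1] and the paired z-test for two markers scored on the
same cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError

GREATER = "greater_is_positive"
LESS = "less_is_positive"


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple
    orientation: str
    cutoff: Optional[float] = None
    sensitivity: Optional[float] = None
    specificity: Optional[float] = None

    @property
    def youden(self) -> Optional[float]:
        if self.sensitivity is None:
            return None
        return self.sensitivity + self.specificity - 1.0


def _check_classes(labels: np.ndarray):
    if labels.min() == labels.max():
        raise DegenerateDataError("both classes must be present")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values (V10 per positive, V01 per negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    cmp_ = (pos[:, None] > neg[None, :]).astype(float)
    cmp_ += 0.5 * (pos[:, None] == neg[None, :])
    return cmp_.mean(axis=1), cmp_.mean(axis=0)


def roc_auc(scores, labels) -> ROCResult:
    """AUC with DeLong 95% CI; no operating point.

    The marker is auto-oriented so AUC >= 0.5 and the orientation
    recorded.  With degenerate placements (e.g. all scores tied) the CI
    collapses to the point estimate.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_classes(labels)
    v10, v01 = _placements(scores, labels)
    auc = float(v10.mean())
    orientation = GREATER
    if auc < 0.5:
        orientation = LESS
        v10, v01 = 1.0 - v10, 1.0 - v01
        auc = 1.0 - auc
    m, n = v10.size, v01.size
    var = 0.0
    if m > 1:
        var += v10.var(ddof=1) / m
    if n > 1:
        var += v01.var(ddof=1) / n
    se = math.sqrt(var)
    ci = (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return ROCResult(auc=auc, ci95=ci, orientation=orientation)


def youden_cutoff(scores, labels, orientation: Optional[str] = None):
    """Operating point maximizing J = sensitivity + specificity - 1.

    Candidate thresholds are the unique observed scores; a case is called
    positive when its (oriented) score is strictly greater than the
    cutoff.  Ties in J break toward the highest sensitivity, then the
    lowest oriented cutoff.  Returns (cutoff, sensitivity, specificity)
    with the cutoff on the original score scale.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_classes(labels)
    if orientation is None:
        orientation = roc_auc(scores, labels).orientation
    s = scores if orientation == GREATER else -scores
    pos = s[labels == 1]
    neg = s[labels == 0]
    best = None
    for c in np.unique(s):
        sens = float((pos > c).mean())
        spec = float((neg <= c).mean())
        j = sens + spec - 1.0
        key = (j, sens, -c)  # maximize J, then sens, then prefer low cutoff
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, c, sens, spec = best
    cutoff = float(c) if orientation == GREATER else float(-c)
    return cutoff, sens, spec


def roc_analysis(scores, labels) -> ROCResult:
    """Full single-marker ROC result: AUC, CI, and Youden operating point."""
    base = roc_auc(scores, labels)
    cutoff, sens, spec = youden_cutoff(scores, labels, base.orientation)
    return replace(base, cutoff=cutoff, sensitivity=sens, specificity=spec)


def delong_paired_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """Two-sided DeLong z-test comparing the AUCs of two markers scored on
    the same cases.

    Identical or monotonically related markers have zero-variance AUC
    difference and return (0, 1).  A zero-variance difference between
    markers with *different* AUCs (e.g. two distinct perfect markers) is
    degenerate and raises.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("markers must score the same cases")
    _check_classes(labels)
    va10, va01 = _placements(a, labels)
    vb10, vb01 = _placements(b, labels)
    auc_a, auc_b = va10.mean(), vb10.mean()
    m, n = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    S = s10 / m + s01 / n
    var_diff = S[0, 0] + S[1, 1] - 2 * S[0, 1]
    if var_diff <= 1e-15:
        if abs(auc_a - auc_b) < 1e-12:
            return 0.0, 1.0
        raise DegenerateDataError(
            "zero variance of the AUC difference with unequal AUCs"
        )
    z = float((auc_a - auc_b) / math.sqrt(var_diff))
    p = float(2 * sps.norm.sf(abs(z)))
    return z, p
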