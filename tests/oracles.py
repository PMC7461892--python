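"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized implementations:
pair/run enumeration is done pixel by pixel, the Haar transform by
explicit pairwise averaging/differencing, the Mann-Whitney p-value by
enumerating group assignments, and the AUC by counting score pairs.
"""

import itertools
import math

import numpy as np

OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_brute(levels, ng, d=1, theta=0):
    """Co-occurrence matrix by explicit pixel-pair enumeration."""
    dr, dc = (d * o for o in OFFSETS[theta])
    P = np.zeros((ng, ng))
    H, W = levels.shape
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                a, b = levels[r, c], levels[r2, c2]
                if a > 0 and b > 0:
                    P[a - 1, b - 1] += 1
                    P[b - 1, a - 1] += 1
    s = P.sum()
    return P / s if s else P


def grlm_brute(levels, ng, theta=0):
    """Run-length matrix by explicit line walking."""
    dr, dc = OFFSETS[theta]
    H, W = levels.shape
    lmax = max(H, W)
    R = np.zeros((ng, lmax), dtype=int)
    starts = [
        (r, c)
        for r in range(H)
        for c in range(W)
        if not (0 <= r - dr < H and 0 <= c - dc < W)
    ]
    for r0, c0 in starts:
        r, c = r0, c0
        run_level, run_len = 0, 0
        while 0 <= r < H and 0 <= c < W:
            v = levels[r, c]
            if v == run_level:
                run_len += 1
            else:
                if run_level > 0:
                    R[run_level - 1, run_len - 1] += 1
                run_level, run_len = v, 1
            r, c = r + dr, c + dc
        if run_level > 0:
            R[run_level - 1, run_len - 1] += 1
    return R


def glcm_stats_brute(P):
    """(CORR, DISS, ENTR) from a normalized GLCM, by explicit sums."""
    ng = P.shape[0]
    diss = 0.0
    entr = 0.0
    for i in range(ng):
        for j in range(ng):
            p = P[i, j]
            diss += abs(i - j) * p
            if p > 0:
                entr -= p * math.log(p)
    px = P.sum(axis=1)
    mu = sum((i + 1) * px[i] for i in range(ng))
    var = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    if var <= 0:
        corr = math.nan
    else:
        corr = sum(
            (i + 1 - mu) * (j + 1 - mu) * P[i, j]
            for i in range(ng)
            for j in range(ng)
        ) / var
    return corr, diss, entr


def grlm_stats_brute(R):
    """(LRE, GLN, LGLRE) from a run-length count matrix, explicit sums."""
    nr = R.sum()
    lre = sum(
        R[i, j] * (j + 1) ** 2
        for i in range(R.shape[0])
        for j in range(R.shape[1])
    ) / nr
    gln = sum(R[i, :].sum() ** 2 for i in range(R.shape[0])) / nr
    lglre = sum(
        R[i, j] / (i + 1) ** 2
        for i in range(R.shape[0])
        for j in range(R.shape[1])
    ) / nr
    return lre, gln, lglre


def haar2d_level(a):
    """One orthonormal 2-D Haar level by pairwise sums/differences.

    Returns (LL, row-highpassed, col-highpassed, both) where
    "row-highpassed" differences along the row index (axis 0), i.e. the
    horizontal-edge detail.
    """
    s2 = math.sqrt(2.0)
    lo0 = (a[0::2, :] + a[1::2, :]) / s2
    hi0 = (a[0::2, :] - a[1::2, :]) / s2
    ll = (lo0[:, 0::2] + lo0[:, 1::2]) / s2
    lh = (lo0[:, 0::2] - lo0[:, 1::2]) / s2   # high-pass along columns
    hl = (hi0[:, 0::2] + hi0[:, 1::2]) / s2   # high-pass along rows
    hh = (hi0[:, 0::2] - hi0[:, 1::2]) / s2
    return ll, hl, lh, hh


def dwt2_features_brute(box):
    """Mean |coef| of the level-2 subbands via the manual Haar."""
    ll1, _, _, _ = haar2d_level(box)
    ll2, h2, v2, d2 = haar2d_level(ll1)
    return (
        np.abs(ll2).mean(),
        np.abs(h2).mean(),
        np.abs(v2).mean(),
        np.abs(d2).mean(),
    )


def mwu_exact_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating group assignments."""
    x, y = list(x), list(y)
    pooled = x + y
    n1 = len(x)
    u_obs = sum(1 for xi in x for yj in y if xi > yj) \
        + 0.5 * sum(1 for xi in x for yj in y if xi == yj)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n1):
        gx = [pooled[i] for i in comb]
        gy = [pooled[i] for i in range(len(pooled)) if i not in comb]
        us.append(
            sum(1 for xi in gx for yj in gy if xi > yj)
            + 0.5 * sum(1 for xi in gx for yj in gy if xi == yj)
        )
    us = np.array(us)
    p_ge = np.mean(us >= u_obs - 1e-12)
    p_le = np.mean(us <= u_obs + 1e-12)
    return min(1.0, 2.0 * min(p_ge, p_le))


def auc_pair_counting(scores, labels):
    """P(score+ > score-) + 1/2 P(=) by explicit pair counting."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
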