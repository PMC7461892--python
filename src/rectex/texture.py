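"""The 12 per-image texture features: histogram, GLCM, GRLM and Haar DWT.

Each case contributes two slices (sagittal fat-suppression and transverse),
and each slice yields 12 features, 24 per case:

* histogram — skewness SKE and (non-excess, Pearson) kurtosis KUR of the
  raw in-ROI intensities;
* GLCM — correlation CORR, dissimilarity DISS and entropy ENTR of the
  symmetric gray-level co-occurrence matrix at distance 1, averaged over
  the four angles 0°, 45°, 90°, 135°;
* GRLM — long-run emphasis LRE, gray-level non-uniformity GLN and low
  gray-level run emphasis LGLRE of the run-length matrix, averaged over
  the same four angles;
* DWT — mean absolute coefficient of the four second-level subbands of an
  orthonormal 2-D Haar decomposition of the ROI bounding box (Harr-L
  approximation, Harr-H horizontal-edge detail, Harr-V vertical-edge
  detail, Harr-D diagonal detail).

Angle convention (row-major grid): 0° steps along a row toward increasing
column; 45° up-right; 90° up a column (decreasing row); 135° up-left.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pywt

from .errors import EmptyMaskError, UndefinedFeatureError
from .roi_io import QuantizedROI, SliceROI, quantize_roi

#: angle -> (drow, dcol) unit offset
ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}

ANGLES = (0, 45, 90, 135)

#: the 12 per-sequence feature names, in report order
FEATURE_NAMES = (
    "SKE", "KUR", "CORR", "DISS", "ENTR",
    "LRE", "GLN", "LGLRE",
    "Harr-L", "Harr-H", "Harr-V", "Harr-D",
)


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric, normalized gray-level co-occurrence matrix for one
    (distance, angle)."""

    P: np.ndarray
    d: int
    theta: int


@dataclass(frozen=True)
class RunLengthMatrix:
    """Gray-level run-length count matrix R[level-1, length-1] for one angle."""

    R: np.ndarray
    theta: int

    @property
    def n_runs(self) -> int:
        return int(self.R.sum())


# ---------------------------------------------------------------------------
# histogram features
# ---------------------------------------------------------------------------

def histogram_features(roi: SliceROI) -> tuple[float, float]:
    """Skewness and Pearson kurtosis of the raw in-ROI intensities.

    SKE = m3 / m2^(3/2) and KUR = m4 / m2^2 with central sample moments
    m_k; a normal distribution gives KUR = 3.  Raises
    :class:`UndefinedFeatureError` on a zero-variance ROI.
    """
    x = roi.roi_values
    if x.size < 3:
        raise EmptyMaskError("need >= 3 in-mask pixels for moments")
    m = x.mean()
    d = x - m
    m2 = np.mean(d ** 2)
    if m2 == 0:
        raise UndefinedFeatureError("SKE/KUR", "zero in-ROI variance")
    ske = float(np.mean(d ** 3) / m2 ** 1.5)
    kur = float(np.mean(d ** 4) / m2 ** 2)
    return ske, kur


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

def compute_glcm(q: QuantizedROI, d: int = 1, theta: int = 0) -> GLCMatrix:
    """Symmetric co-occurrence matrix at offset ``d`` pixels along ``theta``.

    Only pairs with both pixels in-mask are counted; each ordered pair is
    accumulated in both directions and the matrix normalized to sum 1.
    Raises :class:`UndefinedFeatureError` when the angle admits no valid
    pair (e.g. a one-pixel-wide ROI probed across its width).
    """
    if theta not in ANGLE_OFFSETS:
        raise ValueError(f"theta must be one of {tuple(ANGLE_OFFSETS)}")
    dr, dc = (d * o for o in ANGLE_OFFSETS[theta])
    L = q.levels
    nr, nc = L.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    a = L[r0:r1, c0:c1]
    b = L[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        raise UndefinedFeatureError(
            "GLCM", f"no in-mask pixel pair at distance {d}, angle {theta}"
        )
    i = a[valid] - 1
    j = b[valid] - 1
    P = np.zeros((q.ng, q.ng), dtype=float)
    np.add.at(P, (i, j), 1.0)
    np.add.at(P, (j, i), 1.0)
    P /= P.sum()
    return GLCMatrix(P=P, d=d, theta=theta)


def _glcm_stats(P: np.ndarray,
                scaled_levels: bool = False) -> tuple[float, float, float]:
    """(CORR, DISS, ENTR) of one normalized symmetric GLCM; CORR is NaN
    when only a single gray level occurs.

    ``scaled_levels`` maps the level indices i, j from 1..Ng to (0, 1]
    (i/Ng); CORR and ENTR are invariant, DISS scales by 1/Ng.  Off by
    default — integer indices are the standard convention.
    """
    ng = P.shape[0]
    idx = np.arange(1, ng + 1, dtype=float)
    if scaled_levels:
        idx /= ng
    px = P.sum(axis=1)
    mu = float(idx @ px)
    var = float((idx - mu) ** 2 @ px)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    diss = float(np.abs(ii - jj).ravel() @ P.ravel())
    nz = P[P > 0]
    entr = float(-(nz * np.log(nz)).sum())
    if var <= 0:
        corr = math.nan
    else:
        corr = float(((ii - mu) * (jj - mu) * P).sum() / var)
    return corr, diss, entr


def glcm_features(
    q: QuantizedROI,
    d: int = 1,
    angles: tuple = ANGLES,
    log_base: float = math.e,
    scaled_levels: bool = False,
) -> tuple[float, float, float]:
    """(CORR, DISS, ENTR) averaged over the available angles.

    Angles with no valid pixel pair are dropped with a warning.  Entropy is
    natural-log by default (``log_base`` rescales it).  CORR is undefined
    when every usable angle sees a single occupied gray level; in that case
    an :class:`UndefinedFeatureError` is raised after DISS/ENTR have been
    determined — callers wanting the partial result should catch it and use
    :func:`glcm_features_partial`.
    """
    corr, diss, entr = glcm_features_partial(q, d=d, angles=angles,
                                             log_base=log_base,
                                             scaled_levels=scaled_levels)
    if math.isnan(corr):
        raise UndefinedFeatureError("CORR", "single occupied gray level")
    return corr, diss, entr


def glcm_features_partial(
    q: QuantizedROI,
    d: int = 1,
    angles: tuple = ANGLES,
    log_base: float = math.e,
    scaled_levels: bool = False,
) -> tuple[float, float, float]:
    """As :func:`glcm_features` but returns CORR = NaN instead of raising."""
    per_angle = []
    for theta in angles:
        try:
            per_angle.append(
                _glcm_stats(compute_glcm(q, d, theta).P, scaled_levels)
            )
        except UndefinedFeatureError:
            warnings.warn(
                f"GLCM angle {theta} has no valid pair; dropped from average",
                stacklevel=2,
            )
    if not per_angle:
        raise UndefinedFeatureError("GLCM", "no angle has a valid pixel pair")
    arr = np.array(per_angle, dtype=float)
    corrs = arr[:, 0]
    corr = float(np.mean(corrs[~np.isnan(corrs)])) if (~np.isnan(corrs)).any() \
        else math.nan
    diss = float(arr[:, 1].mean())
    entr = float(arr[:, 2].mean())
    if log_base != math.e:
        entr /= math.log(log_base)
    return corr, diss, entr


# ---------------------------------------------------------------------------
# GRLM
# ---------------------------------------------------------------------------

def _lines_for_angle(L: np.ndarray, theta: int) -> list:
    """Decompose the level image into the 1-D scan lines of one angle.

    The order of pixels within a line does not affect run decomposition;
    out-of-mask pixels carry level 0 and terminate runs.
    """
    if theta == 0:
        return list(L)
    if theta == 90:
        return list(L.T)
    if theta == 45:  # lines of constant r + c
        F = np.fliplr(L)
        return [F.diagonal(k) for k in range(-L.shape[0] + 1, L.shape[1])]
    if theta == 135:  # lines of constant r - c
        return [L.diagonal(k) for k in range(-L.shape[0] + 1, L.shape[1])]
    raise ValueError(f"theta must be one of {tuple(ANGLE_OFFSETS)}")


def compute_grlm(q: QuantizedROI, theta: int = 0) -> RunLengthMatrix:
    """Run-length matrix along ``theta``: R[i-1, j-1] counts maximal runs
    of gray level i with length j.  Mask boundaries break runs."""
    L = q.levels
    if not (L > 0).any():
        raise EmptyMaskError("empty ROI")
    lines = _lines_for_angle(L, theta)
    # concatenate lines with 0 separators, then run-length encode once
    parts = []
    for ln in lines:
        parts.append(np.asarray(ln))
        parts.append(np.zeros(1, dtype=L.dtype))
    v = np.concatenate(parts)
    change = np.flatnonzero(np.r_[True, v[1:] != v[:-1]])
    lengths = np.diff(np.r_[change, v.size])
    vals = v[change]
    keep = vals > 0
    vals, lengths = vals[keep], lengths[keep]
    lmax = max(L.shape)
    R = np.zeros((q.ng, lmax), dtype=np.int64)
    np.add.at(R, (vals - 1, lengths - 1), 1)
    return RunLengthMatrix(R=R, theta=theta)


def _grlm_stats(rlm: RunLengthMatrix) -> tuple[float, float, float]:
    R = rlm.R.astype(float)
    nr = R.sum()
    j = np.arange(1, R.shape[1] + 1, dtype=float)
    i = np.arange(1, R.shape[0] + 1, dtype=float)
    lre = float((R * j ** 2).sum() / nr)
    gln = float((R.sum(axis=1) ** 2).sum() / nr)
    lglre = float((R / i[:, None] ** 2).sum() / nr)
    return lre, gln, lglre


def grlm_features(
    q: QuantizedROI, angles: tuple = ANGLES
) -> tuple[float, float, float]:
    """(LRE, GLN, LGLRE) averaged over the four angles.

    LRE = (1/Nr) sum R(i,j) j^2, GLN = (1/Nr) sum_i (sum_j R(i,j))^2,
    LGLRE = (1/Nr) sum R(i,j) / i^2.
    """
    stats = np.array(
        [_grlm_stats(compute_grlm(q, theta)) for theta in angles], dtype=float
    )
    lre, gln, lglre = stats.mean(axis=0)
    return float(lre), float(gln), float(lglre)


# ---------------------------------------------------------------------------
# Haar DWT
# ---------------------------------------------------------------------------

def dwt_features(roi: SliceROI) -> tuple[float, float, float, float]:
    """Mean |coefficient| of the four level-2 subbands of a 2-D Haar DWT.

    The mask bounding box is cut from the raw image, outside-mask pixels
    replaced by the in-ROI mean (to avoid an artificial edge at the ROI
    border), and the box reflect-padded so both dimensions are multiples
    of 4.  The orthonormal Haar transform is applied for two levels; the
    features are the mean absolute value of the level-2 approximation
    (Harr-L), the horizontal-edge detail (Harr-H, high-passed across
    rows), the vertical-edge detail (Harr-V) and the diagonal detail
    (Harr-D).
    """
    rows = np.flatnonzero(roi.mask.any(axis=1))
    cols = np.flatnonzero(roi.mask.any(axis=0))
    box = roi.intensities[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1].copy()
    bmask = roi.mask[rows[0]:rows[-1] + 1, cols[0]:cols[-1] + 1]
    if box.shape[0] < 4 or box.shape[1] < 4:
        raise EmptyMaskError(
            f"ROI bounding box {box.shape} smaller than 4x4"
        )
    box[~bmask] = roi.roi_values.mean()
    pr = (-box.shape[0]) % 4
    pc = (-box.shape[1]) % 4
    box = np.pad(
        box,
        ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)),
        mode="symmetric",
    )
    cA2, (cH2, cV2, cD2) = pywt.wavedec2(
        box, "haar", mode="periodization", level=2
    )[:2]
    return (
        float(np.abs(cA2).mean()),
        float(np.abs(cH2).mean()),
        float(np.abs(cV2).mean()),
        float(np.abs(cD2).mean()),
    )


# ---------------------------------------------------------------------------
# per-case extraction
# ---------------------------------------------------------------------------

_PREFIX = {"sagittal_fs": "sag", "transverse": "tra"}


def slice_features(roi: SliceROI, ng: int = 32,
                   glcm_scaled_levels: bool = False) -> dict:
    """The 12 features of one slice, keyed by FEATURE_NAMES.

    Undefined features (constant ROI, single gray level) are returned as
    NaN; every other feature is still computed.
    """
    out = dict.fromkeys(FEATURE_NAMES, math.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q = quantize_roi(roi, ng)
        try:
            out["SKE"], out["KUR"] = histogram_features(roi)
        except UndefinedFeatureError:
            pass
        corr, diss, entr = glcm_features_partial(
            q, scaled_levels=glcm_scaled_levels)
        out["CORR"], out["DISS"], out["ENTR"] = corr, diss, entr
        out["LRE"], out["GLN"], out["LGLRE"] = grlm_features(q)
        (out["Harr-L"], out["Harr-H"],
         out["Harr-V"], out["Harr-D"]) = dwt_features(roi)
    return out


def extract_case_features(
    sag: SliceROI, tra: SliceROI, ng: int = 32,
    glcm_scaled_levels: bool = False,
) -> dict:
    """All 24 features of one case: 12 per sequence, keyed
    ``sag_<FEAT>`` / ``tra_<FEAT>``."""
    feats = {}
    for roi in (sag, tra):
        prefix = _PREFIX[roi.sequence_type]
        for name, value in slice_features(roi, ng,
                                          glcm_scaled_levels).items():
            feats[f"{prefix}_{name}"] = value
    return feats
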