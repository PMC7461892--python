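"""Synthetic two-group imaging cohort with controllable intra-ROI
heterogeneity.

No patient data ships with this package, so every downstream stage is
exercised on a generated stand-in cohort.  Each case carries two slices
("sagittal fat-suppression"-type and "transverse"-type): a bright,
irregularly shaped lesion on a darker noisy background.  Inside the
lesion the intensity is a uniform plateau plus a compact bright core
(the organized, dense tumor focus) plus a Gaussian random field —
white noise convolved with a Gaussian kernel — whose correlation length
and standard deviation are the group's heterogeneity parameters.
High-stage (T3/4) cases have a slightly shorter correlation length and
larger field SD and, above all, a markedly weaker core contrast: the
loss of organized internal architecture makes their in-ROI texture
relatively more disordered, which is the structure the gray-level
disorder features (dissimilarity, entropy, ...) are meant to detect.
A second-rater segmentation is emulated by a bounded random boundary
perturbation of each mask.

The deterministic core matters: gray-level quantization is min-max
normalized per ROI, so a pure scaled noise field would be quantized
identically at every SD.  The core fixes the intensity range against
which the field is measured (while its steep edge occupies few pixels),
making GLCM entropy and dissimilarity increase monotonically with the
field SD and fall with the core contrast.

Clinical covariates (sex, age, location, diameter, differentiation,
N stage) are drawn i.i.d. within group from the same marginal
distributions, encoding no group effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import EmptyMaskError, RectexError

GROUPS = ("T12", "T34")

MANIFEST_COLUMNS = [
    "case_id", "group",
    "sag_image", "sag_mask", "tra_image", "tra_mask",
    "sag_mask_r2", "tra_mask_r2",
    "sex", "age", "location", "diameter_cm", "differentiation", "n_stage",
]


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; the defaults define the emulated study
    conditions.

    ``hetero_low`` / ``hetero_high`` are (correlation length px, field SD
    intensity units) per group.  ``rater_jitter`` bounds the boundary
    displacement of the second-rater masks, in pixels.
    """

    n_low: int = 62
    n_high: int = 112
    image_size: int = 128
    roi_radius_range: tuple = (16.0, 28.0)
    hetero_low: tuple = (2.0, 6.0)     # (corr length, SD) for T1/2
    hetero_high: tuple = (1.85, 6.6)   # (corr length, SD) for T3/4
    rater_jitter: float = 1.0
    seed: int = 0
    background_level: float = 100.0
    background_noise: tuple = (1.5, 4.0)
    lesion_uplift: float = 30.0        # plateau signal above background
    core_boost_low: float = 58.0       # core-to-plateau contrast, T1/2
    core_boost_high: float = 38.0      # T3/4: less organized structure
    core_radius_frac: float = 0.35     # core radius as a fraction of the ROI
    case_param_jitter: float = 0.5     # lognormal sigma on per-case params
    psf_sigma: float = 0.6             # scanner point-spread blur, pixels

    def __post_init__(self):
        if self.n_low < 2 or self.n_high < 2:
            raise ValueError("need at least 2 cases per group")
        for name in ("hetero_low", "hetero_high"):
            cl, sd = getattr(self, name)
            if cl <= 0 or sd < 0:
                raise ValueError(f"{name} must have positive correlation "
                                 f"length and nonnegative SD")
        lo, hi = self.roi_radius_range
        if not (0 < lo <= hi):
            raise ValueError("invalid roi_radius_range")
        if hi >= self.image_size / 2 - 2:
            raise ValueError(
                f"roi radius {hi} too large for image size {self.image_size}"
            )


@dataclass(frozen=True)
class CaseData:
    sag_image: np.ndarray
    sag_mask: np.ndarray
    tra_image: np.ndarray
    tra_mask: np.ndarray


def _smooth_field(rng, shape, corr_len: float, sd: float) -> np.ndarray:
    """Gaussian random field: white noise smoothed to ``corr_len`` and
    rescaled to standard deviation ``sd`` (zeros when sd = 0)."""
    if sd == 0:
        return np.zeros(shape)
    f = ndimage.gaussian_filter(rng.standard_normal(shape), corr_len,
                                mode="reflect")
    s = f.std()
    return f / s * sd if s > 0 else np.zeros(shape)


def _lesion_mask(rng, size: int, radius: float):
    """Irregular blob mask: a disk of the given radius with a smoothed
    random boundary perturbation, largest connected component kept."""
    for _ in range(10):
        center = size / 2 + rng.uniform(-2, 2, size=2)
        rr, cc = np.mgrid[0:size, 0:size]
        dist = np.hypot(rr - center[0], cc - center[1])
        wobble = _smooth_field(rng, (size, size), radius / 3, 1.0)
        shape_val = radius - dist + 0.3 * radius * wobble
        mask = shape_val > 0
        lab, n = ndimage.label(mask)
        if n == 0:
            continue
        largest = np.argmax(ndimage.sum_labels(mask, lab, range(1, n + 1))) + 1
        mask = lab == largest
        if mask.sum() >= 16:
            return mask, center, dist
    raise RectexError("failed to generate a non-degenerate lesion mask")


def _case_slice(rng, config: CohortConfig, corr_len: float, sd: float,
                core_boost: float, radius: float):
    """One (image, mask) pair: noisy background plus a lesion made of a
    uniform plateau, a compact bright core (the dense tumor focus), and
    the heterogeneity field.  Intensities are non-negative integers
    (16-bit range).

    The core fixes the in-ROI intensity range while its steep edge
    occupies few pixels, so the gray-level quantization window is
    structure-dominated and the local-disorder features respond to the
    field SD rather than being normalized away.
    """
    size = config.image_size
    mask, _, dist = _lesion_mask(rng, size, radius)
    bg_corr, bg_sd = config.background_noise
    bg = config.background_level + _smooth_field(rng, (size, size),
                                                 bg_corr, bg_sd)
    core = core_boost * np.exp(
        -(dist / (config.core_radius_frac * radius)) ** 2
    )
    lesion = (config.background_level + config.lesion_uplift + core
              + _smooth_field(rng, (size, size), corr_len, sd))
    img = np.where(mask, lesion, bg)
    if config.psf_sigma > 0:
        img = ndimage.gaussian_filter(img, config.psf_sigma)
    return np.round(np.clip(img, 0, 65535)), mask


def generate_case(config: CohortConfig, group: str,
                  case_seed: int) -> CaseData:
    """Generate the two slices of one case, deterministically.

    The two sequence types are independent field draws sharing the
    group-level heterogeneity parameters; the per-case lognormal jitter
    around those parameters is drawn independently per sequence, since
    the two orientations image different slices through the tumor.
    """
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}")
    gidx = GROUPS.index(group)
    rng = np.random.default_rng([config.seed, int(case_seed), gidx])
    base_cl, base_sd = config.hetero_low if group == "T12" \
        else config.hetero_high
    base_core = config.core_boost_low if group == "T12" \
        else config.core_boost_high
    jit = config.case_param_jitter
    radius = rng.uniform(*config.roi_radius_range)
    slices = []
    for _ in range(2):
        # per-sequence draws: the two views cut different planes through
        # the tumor, so each sees its own local texture parameters
        # (amplitude varies most, texture scale least)
        corr_len = base_cl * rng.lognormal(0.0, 0.3 * jit)
        sd = base_sd * rng.lognormal(0.0, jit)
        core = base_core * rng.lognormal(0.0, 0.6 * jit)
        slices.append(_case_slice(rng, config, corr_len, sd, core, radius))
    (sag_image, sag_mask), (tra_image, tra_mask) = slices
    return CaseData(sag_image, sag_mask, tra_image, tra_mask)


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap of two binary masks."""
    a = a > 0
    b = b > 0
    denom = a.sum() + b.sum()
    if denom == 0:
        raise EmptyMaskError("both masks empty")
    return float(2.0 * (a & b).sum() / denom)


def perturb_mask(mask: np.ndarray, jitter: float, seed: int,
                 max_tries: int = 5):
    """Second-rater mask: random boundary displacement bounded by
    ``jitter`` pixels.

    The mask's signed Euclidean distance map (boundary at the half-pixel
    contour) is shifted by a smoothed noise field clipped to unit
    amplitude and scaled by ``jitter``, then re-thresholded, so no
    boundary point moves by more than ``jitter`` (+ half a pixel of grid
    quantization).  Returns (perturbed mask, Dice overlap with the
    original).  jitter = 0 reproduces the mask exactly.
    """
    mask = np.asarray(mask) > 0
    if not mask.any():
        raise EmptyMaskError("cannot perturb an empty mask")
    inside = ndimage.distance_transform_edt(mask)
    outside = ndimage.distance_transform_edt(~mask)
    signed = np.where(mask, inside - 0.5, -(outside - 0.5))
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        if jitter == 0:
            new = mask.copy()
        else:
            u = np.clip(_smooth_field(rng, mask.shape, 2.0, 1.0), -1.0, 1.0)
            new = (signed + jitter * u) > 0
        if new.any():
            return new, dice(mask, new)
    raise RectexError("mask perturbation emptied the mask repeatedly")


# ---------------------------------------------------------------------------
# clinical covariates
# ---------------------------------------------------------------------------

#: marginal frequencies of the emulated cohort (shared by both groups)
_COVARIATE_MARGINALS = {
    "sex": (("M", "F"), (106 / 174, 68 / 174)),
    "location": (("upper", "middle", "lower"),
                 (50 / 174, 90 / 174, 34 / 174)),
    "differentiation": (("moderate_high", "low"), (156 / 174, 18 / 174)),
    "n_stage": (("N0", "N1_2"), (94 / 174, 80 / 174)),
}


def sample_covariates(rng) -> dict:
    """Draw one case's clinical covariates; identical marginals in both
    groups (the generator encodes no covariate effect)."""
    out = {}
    for name, (levels, probs) in _COVARIATE_MARGINALS.items():
        out[name] = rng.choice(levels, p=probs)
    out["age"] = int(np.clip(np.round(rng.normal(65.0, 7.0)), 50, 92))
    out["diameter_cm"] = float(np.round(np.clip(rng.normal(4.0, 1.0),
                                                1.0, 8.0), 1))
    return out


# ---------------------------------------------------------------------------
# on-disk cohort
# ---------------------------------------------------------------------------

def _write_image(arr: np.ndarray, path: Path, fmt: str):
    if fmt == "png":
        import imageio.v3 as iio

        iio.imwrite(path, np.asarray(arr, dtype=np.uint16))
    elif fmt == "nifti":
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32),
                                 np.eye(4)), str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def generate_cohort(config: CohortConfig, out_dir,
                    fmt: str = "png") -> pd.DataFrame:
    """Write a full cohort (images, masks, second-rater masks, manifest
    CSV) to ``out_dir`` and return the manifest.

    Paths in the manifest are relative to the manifest's directory.
    Identical (config, seed) produce byte-identical output.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise RectexError(f"cannot create output directory {out_dir}: {exc}")
    ext = "png" if fmt == "png" else "nii.gz"
    rows = []
    case_index = 0
    for group, count in (("T12", config.n_low), ("T34", config.n_high)):
        for _ in range(count):
            case_index += 1
            cid = f"case_{case_index:04d}"
            case = generate_case(config, group, case_index)
            aux = np.random.default_rng([config.seed, case_index, 7])
            row = {"case_id": cid, "group": group}
            for tag, img, msk in (
                ("sag", case.sag_image, case.sag_mask),
                ("tra", case.tra_image, case.tra_mask),
            ):
                img_name = f"{cid}_{tag}.{ext}"
                msk_name = f"{cid}_{tag}_mask.{ext}"
                r2_name = f"{cid}_{tag}_mask_r2.{ext}"
                _write_image(img, out_dir / img_name, fmt)
                _write_image(msk.astype(np.uint16), out_dir / msk_name, fmt)
                r2, _ = perturb_mask(
                    msk, config.rater_jitter,
                    int(aux.integers(0, 2 ** 31)),
                )
                _write_image(r2.astype(np.uint16), out_dir / r2_name, fmt)
                row[f"{tag}_image"] = img_name
                row[f"{tag}_mask"] = msk_name
                row[f"{tag}_mask_r2"] = r2_name
            row.update(sample_covariates(aux))
            rows.append(row)
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
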