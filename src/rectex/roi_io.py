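"""Reading image/mask pairs and gray-level quantization of single-slice ROIs.

The analysis operates on one manually delineated lesion region per image
slice.  This module loads an image and its aligned binary mask, validates
them, and converts the in-mask intensities to integer gray levels 1..Ng by
min-max binning over the ROI itself.  Level 0 is reserved as the
"outside the ROI" sentinel for every downstream matrix feature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import EmptyMaskError, ShapeMismatchError

#: sequence identifiers used throughout the pipeline
SEQUENCE_TYPES = ("sagittal_fs", "transverse")

#: matrix texture features are ill-conditioned on tiny regions
MIN_ROI_PIXELS = 16


@dataclass(frozen=True)
class SliceROI:
    """A single-slice region of interest: raw intensities plus binary mask.

    Parameters
    ----------
    intensities
        2-D array of non-negative, finite pixel intensities.
    mask
        Boolean array of the same shape; True marks in-ROI pixels.
    sequence_type
        One of :data:`SEQUENCE_TYPES`.
    case_id
        Free-form case identifier carried through to reports.
    min_pixels
        Minimum allowed in-mask pixel count (default 16).
    """

    intensities: np.ndarray
    mask: np.ndarray
    sequence_type: str = "transverse"
    case_id: str = ""
    min_pixels: int = field(default=MIN_ROI_PIXELS, repr=False)

    def __post_init__(self):
        inten = np.asarray(self.intensities, dtype=float)
        mask = np.asarray(self.mask)
        if mask.dtype != bool:
            if not np.isin(mask, (0, 1)).all():
                warnings.warn(
                    "non-binary mask values binarized at > 0", stacklevel=3
                )
            mask = mask > 0
        if inten.ndim != 2:
            raise ShapeMismatchError(f"expected 2-D image, got {inten.ndim}-D")
        if inten.shape != mask.shape:
            raise ShapeMismatchError(
                f"image shape {inten.shape} != mask shape {mask.shape}"
            )
        if not np.isfinite(inten).all():
            raise ValueError("intensities must be finite")
        n_in = int(mask.sum())
        if n_in < self.min_pixels:
            raise EmptyMaskError(
                f"mask has {n_in} pixels; at least {self.min_pixels} required"
            )
        if self.sequence_type not in SEQUENCE_TYPES:
            raise ValueError(
                f"sequence_type must be one of {SEQUENCE_TYPES}"
            )
        object.__setattr__(self, "intensities", inten)
        object.__setattr__(self, "mask", mask)

    @property
    def roi_values(self) -> np.ndarray:
        """In-mask raw intensities as a flat array."""
        return self.intensities[self.mask]


@dataclass(frozen=True)
class QuantizedROI:
    """Integer gray levels 1..Ng inside the mask, 0 outside.

    ``raw_stats`` records (min, max, mean) of the raw in-ROI intensities so
    the quantization is auditable after the fact.
    """

    levels: np.ndarray
    ng: int
    raw_stats: tuple = (np.nan, np.nan, np.nan)

    def __post_init__(self):
        levels = np.asarray(self.levels, dtype=np.int64)
        if self.ng < 2:
            raise ValueError("ng must be >= 2")
        inside = levels[levels > 0]
        if inside.size and (inside.min() < 1 or inside.max() > self.ng):
            raise ValueError("in-mask levels must lie in [1, ng]")
        object.__setattr__(self, "levels", levels)

    @property
    def mask(self) -> np.ndarray:
        return self.levels > 0


def _read_gray(path: Path) -> np.ndarray:
    """Read a grayscale 2-D array from PNG (8/16-bit) or NIfTI."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
        if arr.ndim == 3:
            if arr.shape[2] > 1:
                warnings.warn(
                    f"{path.name}: 3-D volume, using first slice", stacklevel=3
                )
            arr = arr[:, :, 0]
        return np.asarray(arr, dtype=float)
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:  # collapse any color axis
        arr = arr[..., 0]
    return np.asarray(arr, dtype=float)


def load_slice(
    image_path,
    mask_path,
    sequence_type: str = "transverse",
    case_id: str = "",
    min_pixels: int = MIN_ROI_PIXELS,
) -> SliceROI:
    """Load an image/mask pair into a validated :class:`SliceROI`.

    The mask is binarized at > 0.  Raises :class:`ShapeMismatchError` when
    the grids differ and :class:`EmptyMaskError` when the mask is (nearly)
    empty.
    """
    image = _read_gray(image_path)
    mask = _read_gray(mask_path)
    return SliceROI(
        intensities=image,
        mask=mask,
        sequence_type=sequence_type,
        case_id=case_id,
        min_pixels=min_pixels,
    )


def quantize_roi(roi: SliceROI, ng: int = 32) -> QuantizedROI:
    """Min-max bin the in-ROI intensities to integer levels 1..``ng``.

    level = min(ng, floor((x - min) / (max - min) * ng) + 1), with min/max
    taken over the ROI only, making the levels invariant to affine
    rescaling x -> a*x + b (a > 0) of the whole ROI.  A constant ROI maps
    every pixel to level 1 with a warning.
    """
    if ng < 2:
        raise ValueError("ng must be >= 2")
    vals = roi.roi_values
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(roi.intensities.shape, dtype=np.int64)
    if hi == lo:
        warnings.warn(
            "constant ROI: all pixels quantized to level 1", stacklevel=2
        )
        levels[roi.mask] = 1
    else:
        x = roi.intensities[roi.mask]
        binned = np.floor((x - lo) / (hi - lo) * ng).astype(np.int64) + 1
        levels[roi.mask] = np.minimum(binned, ng)
    return QuantizedROI(
        levels=levels, ng=ng, raw_stats=(lo, hi, float(vals.mean()))
    )
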