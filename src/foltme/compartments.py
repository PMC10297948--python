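"""Follicle segmentation: intrafollicular mask and extrafollicular complement.

Neoplastic follicles are delineated by the CD21+ follicular-dendritic-cell
meshwork; thresholding the deconvolved CD21 concentration channel, closing
the meshwork texture, filling holes and discarding small debris yields the
intrafollicular (IF) mask.  The extrafollicular (EF) mask is its exact
complement, so every ROI pixel belongs to exactly one compartment.

The study's masks were drawn by a pathologist; a pre-drawn binary mask
(PNG, 0 = EF, 255 = IF) can therefore be supplied instead and takes
precedence over automatic segmentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk, remove_small_objects

__all__ = ["CompartmentMask", "segment_follicles", "compartment_masks",
           "coverage_report", "load_mask_png", "save_mask_png"]


@dataclass
class CompartmentMask:
    """Binary IF/EF partition of one ROI."""

    if_mask: np.ndarray
    ef_mask: np.ndarray
    roi_id: str = ""
    empty_flag: bool = False

    def __post_init__(self):
        if self.if_mask.shape != self.ef_mask.shape:
            raise ValueError("mask shapes differ")
        if np.any(self.if_mask & self.ef_mask):
            raise ValueError("IF and EF masks overlap")
        if not np.all(self.if_mask | self.ef_mask):
            raise ValueError("IF and EF masks do not cover the ROI")

    @property
    def if_fraction(self) -> float:
        return float(self.if_mask.mean())


def segment_follicles(cd21_channel: np.ndarray,
                      threshold_method: str = "otsu",
                      close_radius: int = 15,
                      min_area: int = 2000,
                      threshold_value: float | None = None) -> np.ndarray:
    """Segment the IF mask from a CD21 concentration channel.

    Threshold (Otsu by default) -> morphological closing (bridges the
    meshwork texture) -> hole filling -> removal of components below
    ``min_area`` px^2.  An effectively empty channel returns an all-false
    mask with a warning rather than an error, so batch runs survive
    follicle-free ROIs.
    """
    ch = np.asarray(cd21_channel, float)
    if ch.ndim != 2:
        raise ValueError("CD21 channel must be a 2D concentration image")
    if threshold_method not in ("otsu", "fixed"):
        raise ValueError(f"unknown threshold method {threshold_method!r}")
    if ch.max() - ch.min() < 1e-9:
        warnings.warn("CD21 channel is empty/constant; returning empty mask",
                      stacklevel=2)
        return np.zeros(ch.shape, dtype=bool)
    if threshold_method == "fixed":
        if threshold_value is None:
            raise ValueError("threshold_value required for 'fixed' method")
        thr = threshold_value
    else:
        thr = threshold_otsu(ch)
    binary = ch > thr
    if close_radius > 0:
        binary = closing(binary, disk(close_radius)).astype(bool)
    binary = ndimage.binary_fill_holes(binary)
    if min_area > 1:
        # discard components strictly smaller than min_area
        binary = remove_small_objects(binary, max_size=min_area - 1)
    return binary


def compartment_masks(if_mask: np.ndarray, roi_id: str = "",
                      empty_flag: bool | None = None) -> CompartmentMask:
    """Derive the EF complement; the partition invariants hold exactly."""
    if_mask = np.asarray(if_mask).astype(bool)
    return CompartmentMask(if_mask=if_mask, ef_mask=~if_mask, roi_id=roi_id,
                           empty_flag=bool(~if_mask.any())
                           if empty_flag is None else empty_flag)


def coverage_report(masks: list[CompartmentMask]) -> tuple[pd.DataFrame, float]:
    """Per-ROI IF fraction table plus the cohort mean."""
    if not masks:
        raise ValueError("no masks supplied")
    df = pd.DataFrame({"roi_id": [m.roi_id for m in masks],
                       "if_fraction": [m.if_fraction for m in masks]})
    return df, float(df["if_fraction"].mean())


def save_mask_png(mask: np.ndarray, path) -> None:
    """Write a mask PNG: 0 = EF/background, 255 = IF."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def load_mask_png(path) -> np.ndarray:
    """Read a mask PNG written by :func:`save_mask_png` (>=128 -> IF)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path))
    if img.ndim == 3:
        img = img[..., 0]
    return img >= 128
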