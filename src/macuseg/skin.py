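"""Stage 1 — skin-region segmentation.

The skin region of a lower-limb photograph is found by AND-ing two
binary masks:

* a **hue mask**: pixels whose hexcone hue falls in a fixed red-orange
  band (default [0.01, 0.1], closed interval), where skin tones of all
  shades live;
* a **chroma mask**: pixels whose Cb/Cr values fall inside a per-image
  *dynamic range* — ``min(Cb) <= Cb <= mean(Cb)`` and
  ``mean(Cr) <= Cr <= max(Cr)`` — which self-tunes to the subject's skin
  tone (skin sits in the low-Cb / high-Cr corner of the chroma plane
  relative to typical backgrounds).

A small amount of morphological cleanup (closing, small-object removal,
hole filling) turns the raw conjunction into a single solid leg mask.
The cleanup is plumbing, not part of the thresholding rule, and is fully
configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import morphology

from .colorspaces import rgb_to_hsv, rgb_to_ycbcr

logger = logging.getLogger(__name__)

__all__ = [
    "DynamicRange",
    "skin_mask_hue",
    "compute_dynamic_range",
    "skin_mask_ycbcr",
    "combine_masks",
    "clean_skin_mask",
    "segment_skin",
]


@dataclass(frozen=True)
class DynamicRange:
    """Per-image Cb/Cr interval that outlines the chroma skin mask."""

    cb_low: float
    cb_high: float
    cr_low: float
    cr_high: float

    def __post_init__(self) -> None:
        if self.cb_low > self.cb_high or self.cr_low > self.cr_high:
            raise ValueError("dynamic range bounds must be ordered")


def skin_mask_hue(hsv: np.ndarray, lo: float = 0.01, hi: float = 0.1) -> np.ndarray:
    """Binary mask of pixels whose hue lies in the closed band [lo, hi]."""
    if not 0.0 <= lo < hi <= 1.0:
        raise ValueError(f"invalid hue band [{lo}, {hi}]")
    hue = hsv[..., 0]
    return (hue >= lo) & (hue <= hi)


def compute_dynamic_range(
    ycbcr: np.ndarray, exclude_black_border: bool = False
) -> DynamicRange:
    """Chroma statistics over the whole image: [min Cb, mean Cb] x [mean Cr, max Cr].

    With ``exclude_black_border=True``, pixels with Y = Cb - 128 =
    Cr - 128 = 0 (exact black, as produced by scanner borders) are left
    out of the statistics.
    """
    if ycbcr.size == 0:
        raise ValueError("cannot compute a dynamic range on an empty image")
    cb = ycbcr[..., 1]
    cr = ycbcr[..., 2]
    if exclude_black_border:
        keep = ~(
            (ycbcr[..., 0] == 0.0) & (cb == 128.0) & (cr == 128.0)
        )
        if not keep.any():
            raise ValueError("image is entirely exact-black border")
        cb = cb[keep]
        cr = cr[keep]
    rng = DynamicRange(
        cb_low=float(cb.min()),
        cb_high=float(cb.mean()),
        cr_low=float(cr.mean()),
        cr_high=float(cr.max()),
    )
    logger.info(
        "dynamic chroma range: Cb in [%.2f, %.2f], Cr in [%.2f, %.2f]",
        rng.cb_low, rng.cb_high, rng.cr_low, rng.cr_high,
    )
    return rng


def skin_mask_ycbcr(ycbcr: np.ndarray, rng: DynamicRange) -> np.ndarray:
    """Binary mask of pixels inside the dynamic Cb/Cr range (closed intervals)."""
    cb = ycbcr[..., 1]
    cr = ycbcr[..., 2]
    return (
        (cb >= rng.cb_low)
        & (cb <= rng.cb_high)
        & (cr >= rng.cr_low)
        & (cr <= rng.cr_high)
    )


def combine_masks(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Pixel-wise AND of two binary masks of identical shape."""
    if m1.shape != m2.shape:
        raise ValueError(f"mask shapes differ: {m1.shape} vs {m2.shape}")
    return np.logical_and(m1, m2)


def clean_skin_mask(
    mask: np.ndarray, min_object: int = 50, close_radius: int = 5
) -> np.ndarray:
    """Morphological cleanup: closing, small-object removal, hole filling."""
    mask = mask.astype(bool)
    if close_radius > 0:
        # pad before closing so regions touching the frame are not eroded
        r = close_radius
        padded = np.pad(mask, r)
        padded = ndi.binary_closing(padded, structure=morphology.disk(r))
        mask = padded[r:-r, r:-r]
    if min_object > 0:
        labels, n = ndi.label(mask, structure=np.ones((3, 3)))
        if n:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            mask = np.isin(labels, np.flatnonzero(sizes >= min_object))
    mask = ndi.binary_fill_holes(mask)
    return mask


def segment_skin(
    img: np.ndarray,
    hue_lo: float = 0.01,
    hue_hi: float = 0.1,
    min_object_frac: float = 0.001,
    close_radius: int = 5,
    exclude_black_border: bool = False,
) -> np.ndarray:
    """Full Stage 1: hue mask AND dynamic chroma mask, then cleanup.

    ``min_object_frac`` is the small-object threshold as a fraction of
    total image area (default 0.1%).
    """
    hsv = rgb_to_hsv(img)
    ycbcr = rgb_to_ycbcr(img)
    m_hue = skin_mask_hue(hsv, hue_lo, hue_hi)
    rng = compute_dynamic_range(ycbcr, exclude_black_border=exclude_black_border)
    m_chroma = skin_mask_ycbcr(ycbcr, rng)
    combined = combine_masks(m_hue, m_chroma)
    min_object = int(round(min_object_frac * combined.size))
    return clean_skin_mask(combined, min_object=min_object, close_radius=close_radius)
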