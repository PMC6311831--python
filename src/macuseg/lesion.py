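"""Stage 2 — lesion-region enhancement and thresholding.

Inside the Stage 1 skin region the pipeline:

1. converts the photograph to CIE L*a*b* and **saturates luminosity**: a
   percentile-based linear stretch of the L plane so healthy and damaged
   skin separate (dark pixels become darker, light ones lighter);
2. projects each pixel's (L, a, b) value onto the **first principal
   component** of the skin-pixel color distribution, yielding a grayscale
   plane whose contrast is maximal for the colors actually present;
3. flags the **dark tail** of the skin-pixel grayscale histogram — by
   default the lowest ~10% of values — as the candidate lesion region.

A damage percentage (lesion pixels as a share of skin pixels) summarizes
the state of the extremity.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .colorspaces import rgb_to_lab

logger = logging.getLogger(__name__)

__all__ = [
    "LesionThreshold",
    "DamageReport",
    "saturate_luminosity",
    "pca_grayscale",
    "threshold_lesions",
    "damage_percentage",
    "segment_lesions",
]


@dataclass(frozen=True)
class LesionThreshold:
    """The grayscale interval [a, b] actually selected by the quantile rule."""

    fraction: float
    low: float
    high: float


@dataclass(frozen=True)
class DamageReport:
    """Lesion burden of the extremity, as % of skin pixels flagged."""

    damage_percent: float
    n_skin: int
    n_lesion: int


def saturate_luminosity(
    lab: np.ndarray,
    skin: np.ndarray | None = None,
    p_lo: float = 2.0,
    p_hi: float = 98.0,
) -> np.ndarray:
    """Linearly stretch the L plane so percentiles p_lo/p_hi map to 0/100.

    Statistics are taken over skin pixels when a mask is given (the
    background would otherwise dominate the histogram).  Values outside
    the stretch interval are clipped to [0, 100]; a and b pass through
    unchanged.  A constant L plane is returned unchanged with a warning.
    """
    lightness = lab[..., 0]
    sample = lightness[skin.astype(bool)] if skin is not None else lightness
    lo, hi = np.percentile(sample, [p_lo, p_hi])
    if hi <= lo:
        warnings.warn("constant L plane: luminosity saturation is a no-op")
        return lab
    stretched = np.clip((lightness - lo) / (hi - lo) * 100.0, 0.0, 100.0)
    out = lab.copy()
    out[..., 0] = stretched
    return out


def pca_grayscale(lab: np.ndarray, skin: np.ndarray) -> np.ndarray:
    """Project (L, a, b) pixels onto their first principal component.

    The component is fitted on skin pixels only, oriented so the score
    correlates positively with L (dark lesions end up in the low tail),
    and affinely rescaled so skin-pixel scores span [0, 1].  Pixels
    outside the mask receive scores by the same affine rule, clipped to
    [0, 1].
    """
    skin = skin.astype(bool)
    pixels = lab[skin]
    if pixels.shape[0] < 2 or np.ptp(pixels, axis=0).max() == 0.0:
        raise ValueError("PCA grayscale needs at least 2 distinct skin-pixel colors")
    mean = pixels.mean(axis=0)
    centered = pixels - mean
    cov = centered.T @ centered / centered.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)
    direction = eigvecs[:, -1]
    if direction[0] < 0:  # orient toward increasing L
        direction = -direction
    logger.info(
        "PCA grayscale direction (L, a, b) = (%.4f, %.4f, %.4f), "
        "explained %.1f%% of skin-color variance",
        *direction, 100.0 * eigvals[-1] / eigvals.sum(),
    )
    scores = (lab - mean) @ direction
    skin_scores = scores[skin]
    lo, hi = skin_scores.min(), skin_scores.max()
    if hi <= lo:
        raise ValueError("degenerate PCA projection: all skin scores equal")
    return np.clip((scores - lo) / (hi - lo), 0.0, 1.0)


def threshold_lesions(
    gray: np.ndarray, skin: np.ndarray, fraction: float = 0.10
) -> tuple[np.ndarray, LesionThreshold]:
    """Flag the dark fraction-quantile tail of skin-pixel grayscale values.

    A skin pixel is a lesion candidate when its grayscale value is <= the
    ``fraction`` quantile over skin pixels (ties included, so on heavily
    quantized images the selected share can exceed the nominal fraction).
    Returns the mask and the selected interval [min selected, threshold].
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    skin = skin.astype(bool)
    if not skin.any():
        raise ValueError("empty skin mask")
    values = gray[skin]
    threshold = float(np.quantile(values, fraction))
    lesion = skin & (gray <= threshold)
    selected = gray[lesion]
    info = LesionThreshold(
        fraction=fraction,
        low=float(selected.min()) if selected.size else float("nan"),
        high=threshold,
    )
    logger.info(
        "lesion threshold: fraction=%.3f selected grayscale interval [%.4f, %.4f]",
        fraction, info.low, info.high,
    )
    return lesion, info


def damage_percentage(lesion: np.ndarray, skin: np.ndarray) -> DamageReport:
    """Damage of the extremity: 100 * |lesion| / |skin|."""
    skin = skin.astype(bool)
    lesion = lesion.astype(bool)
    if not skin.any():
        raise ValueError("empty skin mask")
    if (lesion & ~skin).any():
        raise ValueError("lesion mask must be contained in the skin mask")
    n_skin = int(skin.sum())
    n_lesion = int(lesion.sum())
    return DamageReport(
        damage_percent=100.0 * n_lesion / n_skin,
        n_skin=n_skin,
        n_lesion=n_lesion,
    )


def segment_lesions(
    img: np.ndarray,
    skin: np.ndarray,
    fraction: float = 0.10,
    p_lo: float = 2.0,
    p_hi: float = 98.0,
) -> tuple[np.ndarray, np.ndarray, DamageReport, LesionThreshold]:
    """Full Stage 2: Lab -> luminosity stretch -> PCA grayscale -> quantile.

    Returns ``(lesion_mask, gray, damage_report, threshold)``; the PCA
    grayscale plane is returned because Stage 3 measures intensity
    features on it.
    """
    lab = rgb_to_lab(img)
    lab = saturate_luminosity(lab, skin, p_lo=p_lo, p_hi=p_hi)
    gray = pca_grayscale(lab, skin)
    lesion, thr = threshold_lesions(gray, skin, fraction)
    report = damage_percentage(lesion, skin)
    return lesion, gray, report, thr
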