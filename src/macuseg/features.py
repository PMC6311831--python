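"""Stage 3 — macule labeling and feature extraction.

Connected components of the lesion mask become macule candidates.  Each
candidate is characterized by 11 features in a fixed order:

morphologic
    area (pixels), major axis, minor axis (lengths of the ellipse with
    the same normalized second central moments), perimeter (length of
    the traced outer boundary polygon), solidity (area as % of the
    convex-hull area, hull taken over pixel squares);
intensity
    maximum and minimum of the Stage 2 PCA grayscale over the region;
shade indices
    per-channel ratios of the macule's mean raw RGB to the mean over a
    ring of healthy skin around it:
    ``ShI_R = mean(M_red) / mean(HS_red)`` (green, blue analogous) and
    ``ShI_BR = (mean(M_red) + mean(M_blue)) / (mean(HS_red) + mean(HS_blue))``.

Because both numerator and denominator see the same local illumination
and skin tone, shade indices are invariant to global multiplicative
lighting changes and comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull
from skimage import measure, morphology

__all__ = [
    "FEATURE_NAMES",
    "CLASS_NAMES",
    "MaculeRegion",
    "MorphFeatures",
    "IntensityFeatures",
    "ShadeIndices",
    "label_macules",
    "morph_features",
    "intensity_features",
    "shade_indices",
    "characterize",
]

#: The 11 feature names, in canonical (reporting) order.
FEATURE_NAMES = (
    "Area (pixels)",
    "Major axis (pixels)",
    "Minor axis (pixels)",
    "Perimeter (pixels)",
    "Solidity (%)",
    "Maximum intensity",
    "Minimum intensity",
    "ShI_R",
    "ShI_G",
    "ShI_B",
    "ShI_BR",
)

#: The four macule classes, in label-encoding order.
CLASS_NAMES = ("vascular", "petechiae", "trophic", "trauma")


@dataclass
class MaculeRegion:
    """One 8-connected lesion component plus its healthy reference ring."""

    label: int
    mask: np.ndarray  # bool raster, True on the component
    ring: np.ndarray  # bool raster, True on the healthy ring

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    @property
    def coords(self) -> np.ndarray:
        return np.argwhere(self.mask)

    @property
    def centroid(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return float(rows.mean()), float(cols.mean())


@dataclass(frozen=True)
class MorphFeatures:
    area: float
    major_axis: float
    minor_axis: float
    perimeter: float
    solidity: float  # percent


@dataclass(frozen=True)
class IntensityFeatures:
    max_intensity: float
    min_intensity: float


@dataclass(frozen=True)
class ShadeIndices:
    shi_r: float
    shi_g: float
    shi_b: float
    shi_br: float


def label_macules(
    lesion: np.ndarray,
    skin: np.ndarray,
    min_area: int = 5,
    ring_width: int = 5,
) -> list[MaculeRegion]:
    """Split the lesion mask into macule candidates with healthy rings.

    Components are 8-connected; those below ``min_area`` pixels are
    dropped.  Each ring is the dilation of the component by
    ``ring_width`` with *all* lesion pixels removed and restricted to the
    skin mask, so the reference never contains lesion tissue.
    """
    lesion = lesion.astype(bool)
    skin = skin.astype(bool)
    if (lesion & ~skin).any():
        raise ValueError("lesion mask must be contained in the skin mask")
    labels, n = measure.label(lesion, connectivity=2, return_num=True)
    selem = morphology.disk(ring_width)
    regions: list[MaculeRegion] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < min_area:
            continue
        ring = ndi.binary_dilation(comp, structure=selem) & skin & ~lesion
        regions.append(MaculeRegion(label=len(regions) + 1, mask=comp, ring=ring))
    return regions


def _convex_hull_area(mask: np.ndarray) -> float:
    """Area of the convex hull of the region's pixel squares.

    Each pixel (r, c) contributes its four unit-square corners, so a
    single pixel has hull area 1 and a plus-shaped pentomino the exact
    hand-computed hull area 7.
    """
    coords = np.argwhere(mask).astype(float)
    corners = np.concatenate(
        [coords + off for off in ([-0.5, -0.5], [-0.5, 0.5], [0.5, -0.5], [0.5, 0.5])]
    )
    if coords.shape[0] == 1:
        return 1.0
    hull = ConvexHull(corners)
    return float(hull.volume)  # in 2-D, .volume is the polygon area


def _boundary_perimeter(mask: np.ndarray) -> float:
    """Length of the traced outer boundary polygon of the region."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5, fully_connected="high")
    if not contours:
        return 0.0
    longest = max(contours, key=lambda c: c.shape[0])
    return float(np.sqrt((np.diff(longest, axis=0) ** 2).sum(axis=1)).sum())


def morph_features(region: MaculeRegion) -> MorphFeatures:
    """Morphologic properties of one macule region."""
    mask = region.mask
    if not mask.any():
        raise ValueError("empty macule region")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = float(mask.sum())
    return MorphFeatures(
        area=area,
        major_axis=float(props.axis_major_length),
        minor_axis=float(props.axis_minor_length),
        perimeter=_boundary_perimeter(mask),
        solidity=100.0 * area / _convex_hull_area(mask),
    )


def intensity_features(region: MaculeRegion, gray: np.ndarray) -> IntensityFeatures:
    """Max / min of the PCA grayscale over the region's pixels."""
    values = gray[region.mask]
    return IntensityFeatures(
        max_intensity=float(values.max()), min_intensity=float(values.min())
    )


def shade_indices(region: MaculeRegion, img: np.ndarray) -> ShadeIndices:
    """Shade indices of a macule against its healthy reference ring.

    Means are taken over the raw 8-bit channels of the original image.
    Raises if the ring is empty or a ring channel mean is zero.
    """
    if not region.ring.any():
        raise ValueError("macule has an empty healthy-skin reference ring")
    rgb = img.astype(np.float64)
    macule_mean = rgb[region.mask].mean(axis=0)
    ring_mean = rgb[region.ring].mean(axis=0)
    if np.any(ring_mean == 0.0):
        raise ZeroDivisionError("healthy-ring channel mean is zero")
    mr, mg, mb = macule_mean
    hr, hg, hb = ring_mean
    return ShadeIndices(
        shi_r=mr / hr,
        shi_g=mg / hg,
        shi_b=mb / hb,
        shi_br=(mr + mb) / (hr + hb),
    )


def characterize(
    img: np.ndarray,
    gray: np.ndarray,
    lesion: np.ndarray,
    skin: np.ndarray,
    min_area: int = 5,
    ring_width: int = 5,
) -> tuple[list[MaculeRegion], np.ndarray]:
    """Full Stage 3: label macules and build one 11-feature row per region.

    Returns ``(regions, matrix)`` where ``matrix`` has shape
    ``(n_regions, 11)`` with columns ordered as :data:`FEATURE_NAMES`.
    """
    regions = label_macules(lesion, skin, min_area=min_area, ring_width=ring_width)
    rows = []
    for region in regions:
        morph = morph_features(region)
        inten = intensity_features(region, gray)
        shade = shade_indices(region, img)
        rows.append(
            [
                morph.area,
                morph.major_axis,
                morph.minor_axis,
                morph.perimeter,
                morph.solidity,
                inten.max_intensity,
                inten.min_intensity,
                shade.shi_r,
                shade.shi_g,
                shade.shi_b,
                shade.shi_br,
            ]
        )
    matrix = np.array(rows, dtype=float).reshape(len(rows), 11)
    return regions, matrix
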