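"""Pixel-wise color-space transforms used by the segmentation stages.

All transforms operate on 8-bit RGB rasters (``H x W x 3`` arrays of
integers in [0, 255]) and are pure, pixel-wise functions:

* :func:`rgb_to_hsv` — hexcone HSV with H, S, V all in [0, 1].  RGB is
  normalized to [0, 1] before the six-case hue rule is applied.
* :func:`rgb_to_ycbcr` — ITU-R BT.601-style luma/chroma on the [0, 255]
  scale, ``[Y, Cb, Cr] = [0, 128, 128] + M @ [r, g, b]``, clipped to
  [0, 255].
* :func:`rgb_to_lab` — CIE 1976 L*a*b* through a fixed linear RGB→XYZ
  matrix.  The white point is the image of ``r = g = b = 1`` under the
  matrix (its row sums), so the transform is self-consistent: pure gray
  maps to ``a = b = 0`` exactly and white to ``L = 100``.

No gamma decoding or ICC management is performed; the linear formulas are
applied to the raw channel values.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "validate_rgb",
    "rgb_to_hsv",
    "rgb_to_ycbcr",
    "rgb_to_lab",
    "YCBCR_MATRIX",
    "RGB_TO_XYZ",
    "LAB_WHITE_POINT",
]

#: RGB -> YCbCr transform matrix (applied to channels on the [0, 255] scale).
YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.169, -0.331, 0.500],
        [0.500, -0.419, -0.081],
    ]
)

#: Linear RGB -> CIE XYZ matrix (applied to channels normalized to [0, 1]).
RGB_TO_XYZ = np.array(
    [
        [0.4125, 0.3576, 0.1804],
        [0.2127, 0.7152, 0.0722],
        [0.0193, 0.1192, 0.9502],
    ]
)

#: Reference white (Xn, Yn, Zn): the image of r=g=b=1 under RGB_TO_XYZ.
LAB_WHITE_POINT = RGB_TO_XYZ.sum(axis=1)


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check that *img* is an H x W x 3 raster of 8-bit channel values.

    Returns the validated array (unchanged).  Raises ``ValueError`` on a
    wrong number of channels or out-of-range values.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(
            f"expected an H x W x 3 RGB image, got shape {img.shape}"
        )
    if img.size and (img.min() < 0 or img.max() > 255):
        raise ValueError("RGB channel values must lie in [0, 255]")
    return img


def rgb_to_hsv(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to HSV with all planes in [0, 1].

    V = max(r, g, b), S = (V - X)/V with X = min(r, g, b), both on
    channels normalized to [0, 1].  Hue follows the six-case hexcone rule
    (sector selected by which channel attains the max/min), divided by 6
    so that H spans [0, 1].  Degenerate pixels use H = 0 when V = X
    (achromatic) and S = 0 when V = 0 (black).
    """
    img = validate_rgb(img)
    rgb = img.astype(np.float64) / 255.0
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]

    v = rgb.max(axis=-1)
    x = rgb.min(axis=-1)
    c = v - x

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(v > 0, c / np.where(v > 0, v, 1.0), 0.0)

        safe_c = np.where(c > 0, c, 1.0)
        # Six hue sectors; each case is the classic hexcone formula.
        h = np.zeros_like(v)
        r_is_max = r == v
        g_is_max = (g == v) & ~r_is_max
        b_is_max = ~r_is_max & ~g_is_max

        h = np.where(r_is_max & (g == x), 5.0 + (v - b) / safe_c, h)
        h = np.where(r_is_max & (g != x), 1.0 - (v - g) / safe_c, h)
        h = np.where(g_is_max & (b == x), 1.0 + (v - r) / safe_c, h)
        h = np.where(g_is_max & (b != x), 3.0 - (v - b) / safe_c, h)
        h = np.where(b_is_max & (r == x), 3.0 + (v - g) / safe_c, h)
        h = np.where(b_is_max & (r != x), 5.0 - (v - r) / safe_c, h)
        h = h / 6.0
        h = np.where(c > 0, h, 0.0)
        # Pure red evaluates to sector 6/6; wrap to 0 so H stays in [0, 1).
        h = np.where(h >= 1.0, h - 1.0, h)

    return np.stack([h, s, v], axis=-1)


def rgb_to_ycbcr(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to YCbCr on the [0, 255] scale.

    Affine per-pixel map ``[Y, Cb, Cr] = [0, 128, 128] + M @ [r, g, b]``
    with :data:`YCBCR_MATRIX`; results are clipped to [0, 255].  Gray
    input (r = g = b) maps to Cb = Cr = 128 exactly.
    """
    img = validate_rgb(img)
    rgb = img.astype(np.float64)
    out = np.einsum("ij,...j->...i", YCBCR_MATRIX, rgb)
    out += np.array([0.0, 128.0, 128.0])
    return np.clip(out, 0.0, 255.0)


def rgb_to_lab(img: np.ndarray) -> np.ndarray:
    """Convert an 8-bit RGB image to CIE 1976 L*a*b*.

    Channels are normalized to [0, 1], mapped to XYZ by
    :data:`RGB_TO_XYZ`, and referenced to the matrix's own white point
    (:data:`LAB_WHITE_POINT`).  L uses the two-branch rule: the cube-root
    law ``116 (Y/Yn)^(1/3) - 16`` above ``Y/Yn = 0.008856`` and the
    linear law ``903.3 Y/Yn`` below.  a and b are the scaled cube-root
    differences of the X/Y and Y/Z ratios.
    """
    img = validate_rgb(img)
    rgb = img.astype(np.float64) / 255.0
    xyz = np.einsum("ij,...j->...i", RGB_TO_XYZ, rgb)
    ratios = xyz / LAB_WHITE_POINT

    xr, yr, zr = ratios[..., 0], ratios[..., 1], ratios[..., 2]
    cbrt = np.cbrt(ratios)

    lightness = np.where(yr > 0.008856, 116.0 * cbrt[..., 1] - 16.0, 903.3 * yr)
    a = 500.0 * (cbrt[..., 0] - cbrt[..., 1])
    b = 200.0 * (cbrt[..., 1] - cbrt[..., 2])
    return np.stack([lightness, a, b], axis=-1)
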