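"""Seed-controlled synthetic lower-limb scenes and feature samples.

The clinical photographs behind this method are access-restricted, so the
package ships a generator that emulates what those photographs look like
to the segmentation pipeline:

* a **leg**: a tapered vertical capsule of a base skin tone from a
  light-to-dark palette, over a non-skin (blue-gray) background;
* **illumination**: a multiplicative horizontal gradient applied to the
  whole frame;
* **macules**: roughened ellipses whose colors are the *local* skin color
  multiplied by per-channel shade factors in (0, 1] — so the painted
  shade factor is exactly the quantity the Stage 3 shade indices are
  designed to recover;
* **pixel noise**: additive per-channel Gaussian noise, clipped to
  [0, 255].

Every scene is deterministic for a given seed and comes with ground
truth (skin mask, per-macule masks, labels, true areas and factors).

The module also samples 11-feature vectors directly from the published
per-class mean ± SD morphometry/intensity/shade statistics (truncated
Gaussians, features independent within a class), which is how the
classifier's reference experiment is driven.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import CLASS_NAMES, FEATURE_NAMES

__all__ = [
    "PALETTE",
    "CLASS_FEATURE_STATS",
    "CLASS_SHADE_FACTORS",
    "MaculeSpec",
    "SceneSpec",
    "GroundTruth",
    "PlacementError",
    "make_scene",
    "scatter_macules",
    "sample_feature_vectors",
]

#: Six nominal skin tones, light to dark; all fall inside the Stage 1 hue
#: band [0.01, 0.1] and show the low-Cb / high-Cr chroma pattern.
PALETTE = (
    (236, 188, 160),
    (224, 172, 138),
    (198, 140, 102),
    (172, 112, 70),
    (140, 84, 48),
    (110, 64, 36),
)

#: Published per-class feature statistics (mean, SD), in FEATURE_NAMES
#: order, for vascular / petechiae / trophic / trauma macules.
CLASS_FEATURE_STATS: dict[str, tuple[tuple[float, float], ...]] = {
    "vascular": (
        (1010.29, 1893.99), (46.97, 48.96), (23.76, 17.75), (143.90, 154.46),
        (72.56, 12.76), (0.55, 0.18), (0.35, 0.18),
        (0.90, 0.06), (0.84, 0.08), (0.82, 0.11), (0.87, 0.11),
    ),
    "petechiae": (
        (18.50, 5.99), (6.48, 1.60), (3.88, 1.08), (15.83, 4.76),
        (88.00, 12.97), (0.61, 0.14), (0.55, 0.14),
        (0.95, 0.03), (0.90, 0.07), (0.87, 0.09), (0.92, 0.04),
    ),
    "trophic": (
        (2152.90, 1541.85), (109.97, 54.13), (30.67, 13.49), (289.46, 116.72),
        (70.40, 11.96), (0.47, 0.16), (0.28, 0.19),
        (0.88, 0.07), (0.84, 0.09), (0.84, 0.08), (0.87, 0.07),
    ),
    "trauma": (
        (2133.60, 3684.09), (59.08, 63.30), (29.85, 24.87), (166.16, 173.27),
        (79.87, 9.31), (0.62, 0.13), (0.31, 0.21),
        (0.86, 0.08), (0.74, 0.14), (0.68, 0.15), (0.79, 0.10),
    ),
}

#: Per-class painting factors (f_r, f_g, f_b): the published mean shade
#: indices of each class, so a perfect pipeline recovers them.
CLASS_SHADE_FACTORS = {
    name: (stats[7][0], stats[8][0], stats[9][0])
    for name, stats in CLASS_FEATURE_STATS.items()
}

#: Per-class rendering phenomenology: (area trunc lo, area trunc hi,
#: eccentricity, boundary roughness).  Petechiae are pinhead-sized and
#: round; trophic patches are the largest and most elongated.
_CLASS_SHAPE = {
    "vascular": (30.0, 4000.0, 0.70, 0.25),
    "petechiae": (5.0, 60.0, 0.60, 0.15),
    "trophic": (100.0, 6000.0, 0.90, 0.30),
    "trauma": (50.0, 6000.0, 0.75, 0.30),
}


class PlacementError(ValueError):
    """A macule was placed (partly) outside the leg."""


@dataclass(frozen=True)
class MaculeSpec:
    """One macule to paint: placement, geometry and shade factors."""

    mtype: str  # one of CLASS_NAMES
    center: tuple[float, float]  # (row, col)
    area: float  # target pixel area
    eccentricity: float = 0.6
    roughness: float = 0.2
    factors: tuple[float, float, float] = (0.9, 0.85, 0.8)

    def __post_init__(self) -> None:
        if self.mtype not in CLASS_NAMES:
            raise ValueError(f"unknown macule type {self.mtype!r}")
        if not all(0.0 < f <= 1.0 for f in self.factors):
            raise ValueError("shade factors must lie in (0, 1]")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must lie in [0, 1)")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic lower-limb scene."""

    shape: tuple[int, int] = (320, 240)  # (rows, cols)
    background: tuple[int, int, int] = (70, 90, 130)
    skin_tone: tuple[int, int, int] = PALETTE[2]
    illumination: float = 0.15  # multiplicative gradient amplitude
    noise_sd: float = 4.0  # per-channel Gaussian SD, 8-bit units
    macules: tuple[MaculeSpec, ...] = ()
    seed: int = 0


@dataclass
class GroundTruth:
    """Emitted truth of a rendered scene."""

    skin: np.ndarray  # bool leg mask
    macule_masks: list[np.ndarray] = field(default_factory=list)
    labels: list[str] = field(default_factory=list)
    areas: list[int] = field(default_factory=list)
    factors: list[tuple[float, float, float]] = field(default_factory=list)


def _leg_mask(shape: tuple[int, int]) -> np.ndarray:
    """Tapered vertical capsule: thigh-to-ankle leg silhouette."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    r0, r1 = 0.12 * h, 0.88 * h
    t = np.clip((rows - r0) / (r1 - r0), 0.0, 1.0)
    nearest_r = r0 + t * (r1 - r0)
    dist = np.hypot(rows - nearest_r, cols - 0.5 * w)
    radius = (0.30 - 0.08 * t) * w  # tapers toward the ankle
    return dist <= radius


def _macule_mask(
    spec: MaculeSpec, shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Rasterize one roughened ellipse at pixel centers."""
    ratio = 1.0 / np.sqrt(1.0 - spec.eccentricity**2)  # major/minor
    b_ax = np.sqrt(spec.area / (np.pi * ratio))
    a_ax = ratio * b_ax
    theta = rng.uniform(0.0, np.pi)
    # smooth angular modulation of the boundary radius
    n_harm = 3
    amps = rng.normal(0.0, 1.0, size=(2, n_harm))
    phases = np.arange(2, 2 + n_harm)

    h, w = shape
    margin = int(np.ceil(a_ax * (1.0 + abs(spec.roughness) * 2.0))) + 2
    r_c, c_c = spec.center
    r_lo, r_hi = int(r_c) - margin, int(r_c) + margin + 1
    c_lo, c_hi = int(c_c) - margin, int(c_c) + margin + 1
    mask = np.zeros(shape, dtype=bool)
    rows, cols = np.mgrid[max(r_lo, 0):min(r_hi, h), max(c_lo, 0):min(c_hi, w)]
    dr, dc = rows - r_c, cols - c_c
    u = np.cos(theta) * dr + np.sin(theta) * dc
    v = -np.sin(theta) * dr + np.cos(theta) * dc
    rho = np.sqrt((u / a_ax) ** 2 + (v / b_ax) ** 2)
    phi = np.arctan2(v, u)
    mod = np.zeros_like(phi)
    for k in range(n_harm):
        mod += amps[0, k] * np.cos(phases[k] * phi)
        mod += amps[1, k] * np.sin(phases[k] * phi)
    boundary = 1.0 + spec.roughness * mod / (np.sqrt(2.0 * n_harm))
    boundary = np.clip(boundary, 0.3, 1.6)
    mask[rows, cols] = rho <= boundary
    return mask


def make_scene(spec: SceneSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene; bit-identical for identical specs.

    Raises :class:`PlacementError` if any macule leaves the leg.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    skin = _leg_mask(spec.shape)

    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(spec.background, dtype=float)
    img[skin] = np.asarray(spec.skin_tone, dtype=float)

    # multiplicative horizontal illumination gradient
    cols = np.arange(w, dtype=float)
    illum = 1.0 + spec.illumination * (cols / max(w - 1, 1) - 0.5)
    img *= illum[None, :, None]

    truth = GroundTruth(skin=skin)
    for m in spec.macules:
        mask = _macule_mask(m, spec.shape, rng)
        if not mask.any():
            raise PlacementError(f"macule at {m.center} rasterized to nothing")
        if (mask & ~skin).any():
            raise PlacementError(f"macule at {m.center} extends outside the leg")
        img[mask] *= np.asarray(m.factors)
        truth.macule_masks.append(mask)
        truth.labels.append(m.mtype)
        truth.areas.append(int(mask.sum()))
        truth.factors.append(m.factors)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return img, truth


def scatter_macules(
    mtype: str,
    n: int,
    shape: tuple[int, int],
    rng: np.random.Generator,
    factors: tuple[float, float, float] | None = None,
    min_separation: float | None = None,
    area_bounds: tuple[float, float] | None = None,
) -> tuple[MaculeSpec, ...]:
    """Draw *n* non-overlapping macule specs of one type inside the leg.

    Areas are drawn from the published per-class area distribution,
    truncated below by the class bound and above by the largest macule
    the leg interior can contain; shade factors default to the class's
    published mean shade indices; centers are rejection-sampled inside
    the eroded leg so that macules never overlap each other or leave
    the leg.
    """
    from scipy import ndimage as ndi

    if mtype not in CLASS_NAMES:
        raise ValueError(f"unknown macule type {mtype!r}")
    mean, sd = CLASS_FEATURE_STATS[mtype][0]
    lo, hi, ecc, rough = _CLASS_SHAPE[mtype]
    if area_bounds is not None:
        lo, hi = area_bounds
    factors = factors or CLASS_SHADE_FACTORS[mtype]

    skin = _leg_mask(shape)
    dist = ndi.distance_transform_edt(skin)
    # the leg must contain each macule (plus boundary roughness slack):
    # truncate the area draw so the widest macule still fits
    ratio = 1.0 / np.sqrt(1.0 - ecc**2)
    max_semi = (dist.max() - 4.0) / 1.6
    fit_hi = np.pi * max_semi**2 / ratio
    if fit_hi < lo:
        raise PlacementError("leg interior too small for the requested macules")
    hi = min(hi, fit_hi)
    areas = _truncated_normal(rng, mean, sd, lo, hi, size=n)

    # clearance per macule: rotated semi-major axis with roughness slack
    clearance = np.sqrt(areas * ratio / np.pi) * 1.6 + 2.0
    order = np.argsort(-clearance)  # place the big ones first
    centers = np.full((n, 2), np.nan)
    for i in order:
        interior = dist > clearance[i] + 1.0
        candidates = np.argwhere(interior)
        if candidates.shape[0] == 0:
            raise PlacementError("leg interior too small for the requested macules")
        placed = False
        for _ in range(400):
            cand = candidates[rng.integers(candidates.shape[0])].astype(float)
            ok = True
            for j in range(n):
                if j == i or np.isnan(centers[j, 0]):
                    continue
                need = clearance[i] + clearance[j] + 2.0
                if min_separation is not None:
                    need = max(need, min_separation)
                if np.hypot(*(cand - centers[j])) < need:
                    ok = False
                    break
            if ok:
                centers[i] = cand
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place {n} non-overlapping {mtype} macules"
            )

    return tuple(
        MaculeSpec(
            mtype=mtype,
            center=(float(c[0]), float(c[1])),
            area=float(a),
            eccentricity=ecc,
            roughness=rough,
            factors=factors,
        )
        for c, a in zip(centers, areas)
    )


# ----------------------------------------------- feature-vector sampling


def _truncated_normal(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    """Rejection-sampled Gaussian truncated to [lo, hi]."""
    out = rng.normal(mean, sd, size=size)
    for _ in range(1000):
        bad = (out < lo) | (out > hi)
        if not bad.any():
            return out
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return np.clip(out, lo, hi)  # pathological parameters only


#: Validity bounds per feature (index into FEATURE_NAMES).
_FEATURE_BOUNDS = (
    (1.0, np.inf),  # area
    (0.1, np.inf),  # major axis
    (0.1, np.inf),  # minor axis
    (0.1, np.inf),  # perimeter
    (1e-6, 100.0),  # solidity
    (0.0, 1.0),  # max intensity
    (0.0, 1.0),  # min intensity
    (1e-6, np.inf),  # ShI_R
    (1e-6, np.inf),  # ShI_G
    (1e-6, np.inf),  # ShI_B
    (1e-6, np.inf),  # ShI_BR
)


def sample_feature_vectors(
    n_per_class: int, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Sample labeled 11-feature vectors from the per-class statistics.

    Each feature is drawn independently from a Gaussian with the
    published class mean ± SD, truncated to its validity range; the
    ordering constraints minor <= major and min <= max intensity are
    enforced by resampling the offending pairs.  Returns
    ``(features, labels)`` with integer labels indexing CLASS_NAMES.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for cls_idx, name in enumerate(CLASS_NAMES):
        stats = CLASS_FEATURE_STATS[name]
        cols = [
            _truncated_normal(rng, m, s, lo, hi, n_per_class)
            for (m, s), (lo, hi) in zip(stats, _FEATURE_BOUNDS)
        ]
        block = np.column_stack(cols)
        for big, small in ((1, 2), (5, 6)):  # major>=minor, max>=min
            for _ in range(1000):
                bad = block[:, big] < block[:, small]
                if not bad.any():
                    break
                k = int(bad.sum())
                block[bad, big] = _truncated_normal(
                    rng, *stats[big], *_FEATURE_BOUNDS[big], k
                )
                block[bad, small] = _truncated_normal(
                    rng, *stats[small], *_FEATURE_BOUNDS[small], k
                )
        blocks.append(block)
        labels.extend([cls_idx] * n_per_class)
    return np.vstack(blocks), np.asarray(labels, dtype=int)
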