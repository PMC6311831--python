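"""Image, mask and report I/O.

Images are read with Pillow and validated to 8-bit RGB (grayscale and
RGBA inputs are converted; CMYK, 16-bit and palette-with-transparency
inputs are rejected with explicit errors).  Masks travel as 8-bit PNG
with 0/255 values; feature tables as CSV with the canonical 11 feature
columns plus region id and centroid; reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .features import FEATURE_NAMES, MaculeRegion

__all__ = [
    "read_rgb",
    "write_rgb",
    "read_mask",
    "write_mask",
    "features_to_frame",
    "write_features",
    "read_features",
    "write_json",
]

#: CSV columns in front of the 11 feature columns.
META_COLUMNS = ("region_id", "centroid_row", "centroid_col")


def read_rgb(path: str | Path) -> np.ndarray:
    """Read an image file as an H x W x 3 uint8 array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        if im.mode in ("CMYK", "YCbCr", "LAB", "HSV"):
            raise ValueError(f"unsupported color mode {im.mode!r}: expected RGB")
        if im.mode in ("I", "I;16", "F", "I;16B", "I;16L"):
            raise ValueError("16-bit/float images are not supported; provide 8-bit RGB")
        if im.mode != "RGB":
            im = im.convert("RGB")
        return np.asarray(im, dtype=np.uint8)


def write_rgb(path: str | Path, img: np.ndarray) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 PNG mask as a boolean array."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr >= 128


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit 0/255 PNG."""
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def features_to_frame(
    regions: list[MaculeRegion], matrix: np.ndarray
) -> pd.DataFrame:
    """Tabulate per-macule features with region ids and centroids."""
    rows = []
    for region, feats in zip(regions, np.asarray(matrix, dtype=float)):
        r, c = region.centroid
        rows.append((region.label, r, c, *feats))
    return pd.DataFrame(rows, columns=list(META_COLUMNS) + list(FEATURE_NAMES))


def write_features(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def read_features(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in FEATURE_NAMES if c not in frame.columns]
    if missing:
        raise ValueError(f"feature CSV is missing columns: {missing}")
    return frame


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
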