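"""End-to-end pipeline: Stages 1-3 plus optional classification.

``run_pipeline`` chains skin segmentation, lesion thresholding and
feature extraction on one photograph and writes the full report bundle
(skin mask, lesion mask, features CSV, damage report, optional per-macule
class predictions).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .classify import NetworkParams, predict
from .config import PipelineConfig
from .features import CLASS_NAMES, MaculeRegion, characterize
from .lesion import DamageReport, segment_lesions
from .skin import segment_skin

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "analyze_image", "run_pipeline"]


@dataclass
class PipelineResult:
    """In-memory outcome of one pipeline run."""

    skin: np.ndarray
    lesion: np.ndarray
    gray: np.ndarray
    damage: DamageReport | None
    regions: list[MaculeRegion]
    features: pd.DataFrame
    predictions: list[str] = field(default_factory=list)


def analyze_image(
    img: np.ndarray,
    config: PipelineConfig | None = None,
    model: NetworkParams | None = None,
) -> PipelineResult:
    """Run Stages 1-3 (and optionally the classifier) on an RGB array."""
    cfg = config or PipelineConfig()
    skin = segment_skin(
        img,
        hue_lo=cfg.hue_lo,
        hue_hi=cfg.hue_hi,
        min_object_frac=cfg.min_object_frac,
        close_radius=cfg.close_radius,
        exclude_black_border=cfg.exclude_black_border,
    )
    if not skin.any():
        logger.warning("no skin region found; emitting empty outputs")
        empty = np.zeros(img.shape[:2], dtype=bool)
        return PipelineResult(
            skin=empty,
            lesion=empty.copy(),
            gray=np.zeros(img.shape[:2]),
            damage=None,
            regions=[],
            features=mio.features_to_frame([], np.empty((0, 11))),
        )
    lesion, gray, damage, _thr = segment_lesions(
        img,
        skin,
        fraction=cfg.lesion_fraction,
        p_lo=cfg.stretch_p_lo,
        p_hi=cfg.stretch_p_hi,
    )
    regions, matrix = characterize(
        img, gray, lesion, skin, min_area=cfg.min_area, ring_width=cfg.ring_width
    )
    frame = mio.features_to_frame(regions, matrix)
    result = PipelineResult(
        skin=skin,
        lesion=lesion,
        gray=gray,
        damage=damage,
        regions=regions,
        features=frame,
    )
    if model is not None and matrix.shape[0]:
        idx, _ = predict(model, matrix)
        result.predictions = [CLASS_NAMES[i] for i in idx]
        result.features = frame.assign(predicted_class=result.predictions)
    return result


def run_pipeline(
    image_path: str | Path,
    outdir: str | Path,
    config: PipelineConfig | None = None,
    model: NetworkParams | None = None,
) -> PipelineResult:
    """File-level entry point: read the photograph, write the bundle.

    Writes ``skin_mask.png``, ``lesion_mask.png``, ``features.csv`` and
    ``report.json`` under *outdir*.
    """
    img = mio.read_rgb(image_path)
    result = analyze_image(img, config=config, model=model)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mio.write_mask(outdir / "skin_mask.png", result.skin)
    mio.write_mask(outdir / "lesion_mask.png", result.lesion)
    mio.write_features(outdir / "features.csv", result.features)
    report = {
        "image": str(image_path),
        "n_macules": len(result.regions),
        "damage_percent": None
        if result.damage is None
        else result.damage.damage_percent,
        "n_skin_pixels": 0 if result.damage is None else result.damage.n_skin,
        "n_lesion_pixels": 0 if result.damage is None else result.damage.n_lesion,
        "predictions": result.predictions,
    }
    mio.write_json(outdir / "report.json", report)
    return result
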