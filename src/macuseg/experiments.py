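"""Reference experiments: end-to-end validation runs on synthetic data.

Each function here builds its own inputs with the synthetic generator,
executes the pipeline or classifier, and measures the outcome.  They are
used by the validation suite and the reproduction script; nothing in
them is precomputed.
"""

from __future__ import annotations

import numpy as np

from .classify import TrainConfig, train_network
from .features import MaculeRegion
from .pipeline import analyze_image
from .synthetic import (
    CLASS_SHADE_FACTORS,
    GroundTruth,
    SceneSpec,
    make_scene,
    sample_feature_vectors,
    scatter_macules,
)

__all__ = [
    "classifier_reference_experiment",
    "lesion_fraction_experiment",
    "petechiae_recovery_experiment",
]


def classifier_reference_experiment(
    n_seeds: int = 20, n_per_class: int = 10, base_seed: int = 0
) -> dict:
    """Train the 11-4-4-4 network on sampled class-statistics vectors.

    For each seed: draw ``n_per_class`` 11-feature vectors per macule
    class from the published per-class truncated Gaussians, split 60/40
    stratified, train by Levenberg–Marquardt, and evaluate on the
    held-out split.  Returns per-seed and mean held-out accuracy (%),
    target/output Pearson R, and pooled train+test accuracy.
    """
    accs, accs_all, rs = [], [], []
    for k in range(n_seeds):
        seed = (base_seed + k) % (2**31)
        features, labels = sample_feature_vectors(n_per_class, seed=seed)
        _params, report = train_network(features, labels, TrainConfig(seed=seed))
        accs.append(report.accuracy)
        accs_all.append(report.accuracy_all)
        rs.append(report.regression_r)
    return {
        "n_seeds": n_seeds,
        "mean_accuracy_percent": float(np.mean(accs)),
        "mean_accuracy_all_percent": float(np.mean(accs_all)),
        "mean_regression_r": float(np.mean(rs)),
        "accuracy_per_seed": accs,
        "r_per_seed": rs,
        "model_accuracy_ceiling_percent": _bayes_accuracy_ceiling(base_seed),
    }


def _bayes_accuracy_ceiling(seed: int, n: int = 20000) -> float:
    """Accuracy of the Bayes classifier that knows the sampling model.

    Because the generator draws features independently per class, the
    exact class-conditional densities are known; classifying a large
    Monte Carlo sample by maximum likelihood bounds what any classifier
    trained on such vectors can achieve on average.
    """
    from scipy.stats import norm

    from .features import CLASS_NAMES
    from .synthetic import CLASS_FEATURE_STATS

    per_class = n // len(CLASS_NAMES)
    features, labels = sample_feature_vectors(per_class, seed=seed)
    means = np.array([[s[0] for s in CLASS_FEATURE_STATS[c]] for c in CLASS_NAMES])
    sds = np.array([[s[1] for s in CLASS_FEATURE_STATS[c]] for c in CLASS_NAMES])
    loglik = np.stack(
        [norm.logpdf(features, means[c], sds[c]).sum(axis=1) for c in range(4)],
        axis=1,
    )
    return 100.0 * float((loglik.argmax(axis=1) == labels).mean())


def lesion_fraction_experiment(seed: int = 0) -> dict:
    """Flagged share of skin pixels on a macule-free default scene."""
    img, truth = make_scene(SceneSpec(seed=seed))
    result = analyze_image(img)
    return {
        "damage_percent": result.damage.damage_percent,
        "n_skin": result.damage.n_skin,
        "n_lesion": result.damage.n_lesion,
        "skin_recall": float(
            (result.skin & truth.skin).sum() / truth.skin.sum()
        ),
    }


def _match_regions(
    truth: GroundTruth, regions: list[MaculeRegion]
) -> list[MaculeRegion | None]:
    """Pair each true macule with the detected region overlapping it most.

    A match requires the overlap to cover at least half of the true
    area; unmatched macules yield ``None``.
    """
    matches: list[MaculeRegion | None] = []
    for t_mask, t_area in zip(truth.macule_masks, truth.areas):
        best, best_overlap = None, 0
        for region in regions:
            overlap = int((region.mask & t_mask).sum())
            if overlap > best_overlap:
                best, best_overlap = region, overlap
        matches.append(best if best_overlap >= 0.5 * t_area else None)
    return matches


def petechiae_recovery_experiment(
    n_legs: int = 5,
    per_leg: int = 12,
    seed: int = 0,
    factors: tuple[float, float, float] | None = None,
) -> dict:
    """Paint petechiae on uniform-tone legs and recover them end to end.

    Petechiae areas are drawn from the published petechiae area
    distribution (truncated at 5 px); shade factors default to the
    published petechiae shade indices.  Stages 1–3 run at default
    configuration; detected regions are matched back to the ground-truth
    macules and their measured shade index red and pixel area averaged.
    """
    factors = factors or CLASS_SHADE_FACTORS["petechiae"]
    shi_r_values, area_values, true_areas = [], [], []
    n_painted = n_matched = 0
    for leg in range(n_legs):
        leg_seed = (seed + 1000 * (leg + 1)) % (2**31)
        rng = np.random.default_rng(leg_seed)
        shape = (320, 240)
        specs = scatter_macules("petechiae", per_leg, shape, rng, factors=factors)
        scene = SceneSpec(
            shape=shape, seed=leg_seed, illumination=0.0, macules=specs
        )
        img, truth = make_scene(scene)
        result = analyze_image(img)
        matches = _match_regions(truth, result.regions)
        n_painted += len(specs)
        feature_rows = result.features
        for match, t_area in zip(matches, truth.areas):
            if match is None:
                continue
            n_matched += 1
            row = feature_rows.loc[feature_rows["region_id"] == match.label]
            shi_r_values.append(float(row["ShI_R"].iloc[0]))
            area_values.append(float(row["Area (pixels)"].iloc[0]))
            true_areas.append(t_area)
    return {
        "n_painted": n_painted,
        "n_detected": n_matched,
        "mean_shi_r": float(np.mean(shi_r_values)),
        "mean_area": float(np.mean(area_values)),
        "mean_true_area": float(np.mean(true_areas)),
        "painted_factor_r": factors[0],
    }
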