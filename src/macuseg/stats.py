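"""Pairwise Student's t-tests between macule types.

For every unordered pair of macule classes and every one of the 11
features, a two-sided two-sample t-test is run.  The classic
pooled-variance Student's test is the default (Welch's unequal-variance
variant is available via ``equal_var=False``); significance is flagged
at α = 0.05 with no multiple-testing correction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import CLASS_NAMES, FEATURE_NAMES

__all__ = ["PairResult", "compare_groups", "comparison_table"]

ALPHA = 0.05


@dataclass(frozen=True)
class PairResult:
    feature: str
    class_a: str
    class_b: str
    t_statistic: float
    df: float
    p_value: float
    significant: bool


def compare_groups(
    features: np.ndarray,
    labels: np.ndarray,
    equal_var: bool = True,
    alpha: float = ALPHA,
) -> list[PairResult]:
    """t-test every feature between every unordered pair of classes.

    ``labels`` are integer class indices into :data:`CLASS_NAMES`.
    Pairs where either class has fewer than 2 examples are skipped with
    a warning.
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if features.ndim != 2 or features.shape[1] != len(FEATURE_NAMES):
        raise ValueError(f"expected (n, {len(FEATURE_NAMES)}) feature matrix")
    by_class = {c: features[labels == c] for c in range(len(CLASS_NAMES))}

    results: list[PairResult] = []
    for a, b in itertools.combinations(range(len(CLASS_NAMES)), 2):
        xa, xb = by_class[a], by_class[b]
        if xa.shape[0] < 2 or xb.shape[0] < 2:
            warnings.warn(
                f"skipping pair {CLASS_NAMES[a]} vs {CLASS_NAMES[b]}: "
                "fewer than 2 examples in a class"
            )
            continue
        for j, name in enumerate(FEATURE_NAMES):
            res = sps.ttest_ind(xa[:, j], xb[:, j], equal_var=equal_var)
            df = (
                xa.shape[0] + xb.shape[0] - 2
                if equal_var
                else float(res.df)
            )
            results.append(
                PairResult(
                    feature=name,
                    class_a=CLASS_NAMES[a],
                    class_b=CLASS_NAMES[b],
                    t_statistic=float(res.statistic),
                    df=float(df),
                    p_value=float(res.pvalue),
                    significant=bool(res.pvalue < alpha),
                )
            )
    return results


def comparison_table(results: list[PairResult]) -> pd.DataFrame:
    """Pivot pair results into a feature x class-pair table of p values."""
    records = [
        {
            "feature": r.feature,
            "pair": f"{r.class_a} vs {r.class_b}",
            "p_value": r.p_value,
        }
        for r in results
    ]
    table = pd.DataFrame(records).pivot(
        index="feature", columns="pair", values="p_value"
    )
    return table.reindex(index=list(FEATURE_NAMES))
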