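"""Aging and disease risk scores from a bagged regression-tree ensemble.

The aging score is the output of 100 bootstrap-aggregated regression trees
trained on young (0) vs healthy aged (1) samples over the aging-marker
sites; disease risk scores reuse the same machinery with control (0) vs
disease (1) labels over disease markers.  Chronological age enters through
the sigmoid transform

    transformed_age = 1 / (1 + exp(-(age - 50) / 50)),

and the age-adjusted score is ``b * aging_score - transformed_age`` where
``b`` is the OLS slope of the transformed age on the aging score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.ensemble import RandomForestRegressor

from .dataset import CONTROL, DISEASES

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (50, 55, 60, 65, 70, 75, 80)


def fit_score_regressor(
    X_markers, y, n_trees: int = 100, seed: int = 0, max_depth: int | None = 2
) -> RandomForestRegressor:
    """Bagged regression trees mapping marker profiles to the 0/1 group code.

    ``max_features=1.0`` makes this plain bootstrap aggregation (no random
    feature subsetting); the prediction is the unclipped mean of the tree
    outputs, a real-valued score.  Trees are depth-limited (default 2,
    matching the classifier's weak learners): deep trees memorize the 0/1
    codes and saturate the score at the extremes, whereas shallow trees
    keep it graded within the aged range — which is what downstream
    age-stratified comparisons need.
    """
    yarr = np.asarray(y, dtype=float)
    if np.unique(yarr).size < 1:
        raise ValueError("empty target")
    model = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=1.0,
        bootstrap=True,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
    )
    model.fit(pd.DataFrame(X_markers), yarr)
    return model


def transform_age(age) -> np.ndarray | float:
    """Sigmoid age transform, 0.5 at age 50, limits 0 and 1."""
    a = np.asarray(age, dtype=float)
    out = special.expit((a - 50.0) / 50.0)  # 1 / (1 + exp(-(age-50)/50))
    return float(out) if np.isscalar(age) or out.ndim == 0 else out


def adjust_score(scores, ages) -> tuple[np.ndarray, float]:
    """Age-adjusted score ``b * score - transformed_age``.

    ``b`` is the slope of the with-intercept OLS regression of the
    transformed age on the aging score; only the slope enters the
    adjustment, by construction.
    """
    s = np.asarray(scores, dtype=float)
    if len(s) < 3:
        raise ValueError("need at least 3 samples")
    if np.std(s) == 0:
        raise ValueError("aging scores have zero variance")
    t = transform_age(np.asarray(ages, dtype=float))
    b = float(stats.linregress(s, t).slope)
    return b * s - t, b


def ks_normality_test(scores) -> tuple[float, float]:
    """One-sample Kolmogorov-Smirnov against Normal(mean, SD of the sample)."""
    s = np.asarray(scores, dtype=float)
    if len(s) < 8:
        raise ValueError("need at least 8 samples")
    sd = s.std(ddof=1)
    if sd == 0:
        logger.warning("degenerate (constant) scores; reporting p = 0")
        return 1.0, 0.0
    res = stats.kstest(s, "norm", args=(s.mean(), sd))
    return float(res.statistic), float(res.pvalue)


def kruskal_wallis_by_age_group(
    scores,
    groups,
    ages,
    thresholds=DEFAULT_THRESHOLDS,
    nd_groups: tuple[str, ...] = DISEASES,
    control_group: str = CONTROL,
) -> pd.DataFrame:
    """Kruskal-Wallis ND-vs-control comparison restricted to age >= t strata.

    Returns one row per threshold with group sizes, the tie-corrected H
    statistic and its chi-square p-value; strata lacking either arm are
    skipped with a log message.
    """
    s = np.asarray(scores, dtype=float)
    g = np.asarray(groups)
    a = np.asarray(ages, dtype=float)
    rows = []
    for t in thresholds:
        mask = a >= t
        nd = s[mask & np.isin(g, nd_groups)]
        ctrl = s[mask & (g == control_group)]
        if nd.size == 0 or ctrl.size == 0:
            logger.info("threshold %s: empty stratum, skipped", t)
            continue
        H, p = stats.kruskal(nd, ctrl)
        rows.append(
            {"threshold": t, "n_nd": nd.size, "n_control": ctrl.size,
             "H": float(H), "p": float(p),
             "median_nd": float(np.median(nd)), "median_control": float(np.median(ctrl))}
        )
    return pd.DataFrame(rows)


@dataclass
class ScoreTable:
    """Per-sample aging score with its age transform and adjustment."""

    frame: pd.DataFrame  # sample_id index; aging_score, transformed_age, adjusted_score
    b: float
    disease_scores: pd.DataFrame | None = None

    @classmethod
    def build(cls, sample_ids, aging_scores, ages, disease_scores=None) -> "ScoreTable":
        adjusted, b = adjust_score(aging_scores, ages)
        frame = pd.DataFrame(
            {
                "aging_score": np.asarray(aging_scores, dtype=float),
                "transformed_age": transform_age(np.asarray(ages, dtype=float)),
                "adjusted_score": adjusted,
            },
            index=pd.Index(sample_ids, name="sample_id"),
        )
        return cls(frame=frame, b=b, disease_scores=disease_scores)
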