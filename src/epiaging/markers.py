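"""Marker selection: ReliefF ranking and a discrete AdaBoost tree ensemble.

The classifier is the classical discrete AdaBoost scheme over depth-limited
decision trees: with per-round sample weights D_n (D_1 = 1/m), the weighted
error eps_n = sum_i D_n(i) [y_i != h_n(x_i)] gives the classifier weight

    alpha_n = 1/2 * ln((1 - eps_n) / eps_n),

misclassified samples are up-weighted by sqrt((1-eps)/eps), correctly
classified ones down-weighted by sqrt(eps/(1-eps)), and weights are
renormalized.  The strong classifier is the sign of sum_n alpha_n (2 h_n - 1).

Marker sets come from ranking all sites with ReliefF and sweeping the top-k
prefix (k = 1..k_max) under stratified cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

logger = logging.getLogger(__name__)

_EPS_CLIP = 1e-10
_MAX_RESAMPLE = 5


# ---------------------------------------------------------------------------
# ReliefF
# ---------------------------------------------------------------------------

def relieff_rank(
    X,
    y,
    n_neighbors: int = 10,
    seed: int = 0,
) -> pd.Series:
    """Rank features by the ReliefF near-hit/near-miss margin.

    Every instance is used (no subsampling).  Features are scaled to unit
    range for both the distance metric and the per-feature differences, the
    standard normalization so each feature's contribution lies in [0, 1].
    Returns a Series of scores indexed by feature name, sorted descending
    (ties broken by feature name for determinism).
    """
    X = pd.DataFrame(X)
    yarr = np.asarray(y)
    classes = np.unique(yarr)
    if classes.size < 2:
        raise ValueError("ReliefF requires both classes present")
    if classes.size > 2:
        raise ValueError("only binary labels are supported")

    M = X.to_numpy(dtype=float)
    n, p = M.shape
    del seed  # every instance is used; kept in the API for subsampling variants

    span = M.max(axis=0) - M.min(axis=0)
    span[span == 0] = 1.0  # constant features contribute zero margin
    N = M / span

    D = cdist(N, N)
    np.fill_diagonal(D, np.inf)

    w = np.zeros(p)
    k = n_neighbors
    for i in range(n):
        same = np.flatnonzero(yarr == yarr[i])
        diff = np.flatnonzero(yarr != yarr[i])
        same = same[same != i]
        if same.size == 0:
            continue
        hits = same[np.argsort(D[i, same], kind="stable")[: min(k, same.size)]]
        misses = diff[np.argsort(D[i, diff], kind="stable")[: min(k, diff.size)]]
        w += np.abs(N[misses] - N[i]).mean(axis=0) - np.abs(N[hits] - N[i]).mean(axis=0)
    w /= n

    scores = pd.Series(w, index=X.columns)
    # descending score, ties broken lexicographically by feature name
    return scores.sort_index(kind="stable").sort_values(ascending=False, kind="stable")


# ---------------------------------------------------------------------------
# Discrete AdaBoost
# ---------------------------------------------------------------------------

@dataclass
class BoostedEnsemble:
    """Ordered weak tree learners with their classifier weights alpha_n."""

    learners: list[DecisionTreeClassifier]
    alphas: list[float]
    feature_names: list[str]
    classes: tuple[int, int] = (0, 1)
    train_errors: list[float] = field(default_factory=list)

    @property
    def n_estimators(self) -> int:
        return len(self.learners)

    def margins(self, X) -> np.ndarray:
        """Real-valued voting margin sum_n alpha_n (2 h_n(x) - 1)."""
        X = self._check_features(X)
        out = np.zeros(len(X))
        for tree, alpha in zip(self.learners, self.alphas):
            out += alpha * (2.0 * tree.predict(X) - 1.0)
        return out

    def predict(self, X) -> np.ndarray:
        """Labels in {0, 1}: 1 where the margin is strictly positive."""
        return (self.margins(X) > 0).astype(int)

    def _check_features(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            if missing:
                raise KeyError(f"feature columns absent from input: {missing[:5]}")
            return X[self.feature_names].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.feature_names):
            raise KeyError(
                f"expected {len(self.feature_names)} features, got {X.shape[1]}"
            )
        return X


def boost_fit(
    X,
    y,
    n_estimators: int = 100,
    max_depth: int = 2,
    seed: int = 0,
    sample_weight=None,
) -> BoostedEnsemble:
    """Fit the discrete AdaBoost ensemble of depth-limited trees.

    Rounds with eps_n = 0 terminate boosting with that learner dominant;
    rounds with eps_n >= 0.5 reset the weight state (to the initial
    weights) and retry with a fresh tree seed, a bounded number of times.
    """
    Xf = pd.DataFrame(X)
    feature_names = [str(c) for c in Xf.columns]
    M = Xf.to_numpy(dtype=float)
    yarr = np.asarray(y).astype(int)
    if np.unique(yarr).size < 2:
        raise ValueError("both classes must be present")

    m = len(yarr)
    if sample_weight is None:
        w0 = np.full(m, 1.0 / m)
    else:
        w0 = np.asarray(sample_weight, dtype=float)
        w0 = w0 / w0.sum()
    w = w0.copy()

    rng = np.random.default_rng(seed)
    learners: list[DecisionTreeClassifier] = []
    alphas: list[float] = []
    errors: list[float] = []
    resamples = 0
    rounds = 0
    while rounds < n_estimators:
        tree = DecisionTreeClassifier(
            max_depth=max_depth, random_state=int(rng.integers(2**31 - 1))
        )
        tree.fit(M, yarr, sample_weight=w * m)  # scale-invariant for the tree
        pred = tree.predict(M)
        mis = pred != yarr
        eps = float(w[mis].sum())

        if eps >= 0.5:
            resamples += 1
            if resamples > _MAX_RESAMPLE:
                logger.warning("weak learner stuck at eps >= 0.5; stopping at %d rounds", rounds)
                break
            logger.info("round %d: eps=%.3f >= 0.5, resetting weights and resampling", rounds, eps)
            w = w0.copy()
            continue

        eps_c = min(max(eps, _EPS_CLIP), 1.0 - _EPS_CLIP)
        alpha = 0.5 * np.log((1.0 - eps_c) / eps_c)
        learners.append(tree)
        alphas.append(float(alpha))
        errors.append(eps)
        rounds += 1

        if eps == 0.0:
            logger.info("round %d: perfect weak learner, terminating boosting", rounds)
            break

        ratio = np.sqrt((1.0 - eps_c) / eps_c)
        w = w * np.where(mis, ratio, 1.0 / ratio)
        w = w / w.sum()

    return BoostedEnsemble(learners, alphas, feature_names, train_errors=errors)


def boost_predict(model: BoostedEnsemble, X) -> tuple[np.ndarray, np.ndarray]:
    """Convenience wrapper returning ``(labels, margins)``."""
    margins = model.margins(X)
    return (margins > 0).astype(int), margins


# ---------------------------------------------------------------------------
# Top-k cross-validation sweep
# ---------------------------------------------------------------------------

@dataclass
class MarkerSet:
    """Ranked sites, the CV-selected prefix size, and the refit final model."""

    ranked_site_ids: list[str]
    scores: pd.Series
    selected_k: int
    cv_accuracy_by_k: pd.Series
    final_model: BoostedEnsemble

    @property
    def selected_site_ids(self) -> list[str]:
        return self.ranked_site_ids[: self.selected_k]

    def to_frame(self) -> pd.DataFrame:
        """Delimited-text view: rank, cpg_id, score, selected flag."""
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.ranked_site_ids) + 1),
                "cpg_id": self.ranked_site_ids,
                "score": self.scores.loc[self.ranked_site_ids].to_numpy(),
                "selected": [
                    i < self.selected_k for i in range(len(self.ranked_site_ids))
                ],
            }
        )


def select_top_k_cv(
    X,
    y,
    ranked_sites: pd.Series | list[str],
    k_max: int = 50,
    folds: int = 10,
    n_estimators: int = 100,
    seed: int = 0,
    sample_weight=None,
) -> MarkerSet:
    """Sweep top-k prefixes of the ranking under stratified k-fold CV.

    ``k`` maximizing mean CV accuracy wins (ties -> smallest k); the final
    model is refit on all data with that prefix.
    """
    if k_max < 1 or folds < 2:
        raise ValueError("k_max >= 1 and folds >= 2 required")
    X = pd.DataFrame(X)
    yarr = np.asarray(y).astype(int)
    if isinstance(ranked_sites, pd.Series):
        scores = ranked_sites
        ranked = list(ranked_sites.index)
    else:
        ranked = list(ranked_sites)
        scores = pd.Series(np.nan, index=ranked)
    k_max = min(k_max, len(ranked))

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(X, yarr))
    w = None if sample_weight is None else np.asarray(sample_weight, dtype=float)

    acc = np.zeros(k_max)
    for ki in range(1, k_max + 1):
        cols = ranked[:ki]
        Xk = X[cols]
        fold_acc = []
        for fold_i, (tr, te) in enumerate(splits):
            model = boost_fit(
                Xk.iloc[tr],
                yarr[tr],
                n_estimators=n_estimators,
                seed=seed * 1000 + fold_i,
                sample_weight=None if w is None else w[tr],
            )
            fold_acc.append(float((model.predict(Xk.iloc[te]) == yarr[te]).mean()))
        acc[ki - 1] = float(np.mean(fold_acc))

    selected_k = int(np.argmax(acc)) + 1  # argmax takes the first max: smallest k
    final = boost_fit(
        X[ranked[:selected_k]],
        yarr,
        n_estimators=n_estimators,
        seed=seed,
        sample_weight=w,
    )
    return MarkerSet(
        ranked_site_ids=ranked,
        scores=scores,
        selected_k=selected_k,
        cv_accuracy_by_k=pd.Series(acc, index=np.arange(1, k_max + 1), name="cv_accuracy"),
        final_model=final,
    )


def balanced_disease_fit(
    X_controls,
    X_disease,
    n_subgroups: int,
    k_max: int = 50,
    folds: int = 10,
    n_estimators: int = 100,
    n_neighbors: int = 10,
    seed: int = 0,
) -> MarkerSet:
    """Disease-vs-control selection with random control subgrouping.

    Controls are partitioned into ``n_subgroups`` near-equal random
    subgroups; each subgroup is paired with the full disease sample to form
    a balanced task, per-pairing ReliefF rankings are combined by rank-sum,
    and the final model is trained on all controls plus the disease samples
    with per-sample weights equalizing the two class masses.
    """
    if n_subgroups < 1:
        raise ValueError("n_subgroups must be >= 1")
    Xc = pd.DataFrame(X_controls)
    Xd = pd.DataFrame(X_disease)
    if len(Xc) > 10 * n_subgroups * len(Xd):
        logger.warning(
            "control subgroups exceed the disease sample by >10x; pairings stay unbalanced"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(Xc))
    chunks = np.array_split(perm, n_subgroups)

    rank_sum = pd.Series(0.0, index=Xc.columns)
    selected_ks = []
    for j, chunk in enumerate(chunks):
        Xj = pd.concat([Xc.iloc[chunk], Xd], axis=0)
        yj = np.concatenate([np.zeros(len(chunk), dtype=int), np.ones(len(Xd), dtype=int)])
        ranking = relieff_rank(Xj, yj, n_neighbors=n_neighbors, seed=seed + j)
        rank_sum += pd.Series(
            np.arange(1, len(ranking) + 1), index=ranking.index, dtype=float
        )
        ms = select_top_k_cv(
            Xj, yj, ranking, k_max=k_max, folds=folds,
            n_estimators=n_estimators, seed=seed + j,
        )
        selected_ks.append(ms.selected_k)

    combined = rank_sum.sort_index().sort_values(kind="stable")  # low rank-sum = best
    ranked = list(combined.index)
    k_final = int(round(float(np.mean(selected_ks))))
    k_final = max(1, min(k_final, len(ranked)))

    X_all = pd.concat([Xc, Xd], axis=0)
    y_all = np.concatenate([np.zeros(len(Xc), dtype=int), np.ones(len(Xd), dtype=int)])
    w = class_mass_weights(y_all)
    final = boost_fit(
        X_all[ranked[:k_final]], y_all,
        n_estimators=n_estimators, seed=seed, sample_weight=w,
    )
    score_view = pd.Series(-combined.to_numpy(), index=combined.index)
    return MarkerSet(
        ranked_site_ids=ranked,
        scores=score_view,
        selected_k=k_final,
        cv_accuracy_by_k=pd.Series(dtype=float),
        final_model=final,
    )


def class_mass_weights(y) -> np.ndarray:
    """Per-sample weights making the two class masses equal (sum to 1)."""
    yarr = np.asarray(y).astype(int)
    w = np.empty(len(yarr), dtype=float)
    for c in np.unique(yarr):
        mask = yarr == c
        w[mask] = 0.5 / mask.sum()
    return w


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate(model: BoostedEnsemble, X_test, y_test) -> dict:
    """Accuracy, ROC curve and trapezoid AUC on a held-out set."""
    yarr = np.asarray(y_test).astype(int)
    labels, margins = boost_predict(model, X_test)
    accuracy = float((labels == yarr).mean())
    if np.unique(yarr).size < 2:
        raise ValueError("single-class test set: AUC undefined")
    fpr, tpr, thresholds = roc_curve(yarr, margins)
    auc = float(np.trapezoid(tpr, fpr))
    return {
        "accuracy": accuracy,
        "auc": auc,
        "roc": pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds}),
        "margins": margins,
    }
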