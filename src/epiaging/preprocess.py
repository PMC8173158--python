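"""Cohort pre-processing: site/sample filtering, KNN imputation,
reference z-scoring, SVD batch correction and train/test splitting.

The canonical order is: (1) drop sites with too many missing values,
(2) KNN-impute the rest, (3)-(4) drop samples without age and early-onset
(age <= 50) disease samples, (5) z-score against the healthy aged
reference, (6) remove the top reference principal components, (7) z-score
against the reference again, then split train/test stratified by group.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from sklearn.impute import KNNImputer

from .dataset import (
    CONTROL,
    DISEASES,
    SPLIT_TEST,
    SPLIT_TRAIN,
    MethylationDataset,
)

logger = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    """A filtering step removed everything."""


def filter_sites_by_missingness(
    data: MethylationDataset, max_frac: float = 0.30
) -> MethylationDataset:
    """Drop sites whose missing fraction is >= ``max_frac`` (strict keep-below)."""
    if not 0.0 <= max_frac <= 1.0:
        raise ValueError("max_frac must lie in [0, 1]")
    frac = data.values.isna().mean(axis=0)
    keep = frac.index[frac.to_numpy() < max_frac]
    if len(keep) == 0:
        raise DegenerateInputError("all sites removed by missingness filter")
    if len(keep) < data.n_sites:
        logger.info("missingness filter removed %d/%d sites", data.n_sites - len(keep), data.n_sites)
    return data.select_sites(keep)


def knn_impute(
    data: MethylationDataset, k: int = 10, stratify_by: str | None = None
) -> MethylationDataset:
    """Replace missing entries by the unweighted mean of the k nearest samples.

    Distance is Euclidean over mutually observed sites, rescaled by the
    shared-site count.  With ``stratify_by`` (a metadata column, e.g. a
    brain-region annotation) neighbors are sought within the same stratum;
    strata smaller than ``k + 1`` fall back to however many neighbors exist.
    Observed entries are never altered.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not data.values.isna().to_numpy().any():
        return data

    def impute_block(frame: pd.DataFrame) -> pd.DataFrame:
        n_eff = min(k, max(1, len(frame) - 1))
        if n_eff < k:
            logger.warning(
                "stratum of %d samples has fewer than k=%d neighbors; using %d",
                len(frame), k, n_eff,
            )
        imputer = KNNImputer(n_neighbors=n_eff, weights="uniform")
        out = imputer.fit_transform(frame.to_numpy())
        return pd.DataFrame(out, index=frame.index, columns=frame.columns)

    if stratify_by is None:
        filled = impute_block(data.values)
    else:
        if stratify_by not in data.meta.columns:
            raise ValueError(f"no metadata column {stratify_by!r}")
        blocks = [
            impute_block(data.values.loc[idx])
            for _, idx in data.meta.groupby(stratify_by, sort=True).groups.items()
        ]
        filled = pd.concat(blocks).loc[data.values.index]
    return data.with_values(filled)


def filter_samples(data: MethylationDataset) -> MethylationDataset:
    """Drop samples without age, and early-onset (age <= 50) disease samples."""
    age = data.age
    has_age = age.notna()
    early_nd = data.group.isin(DISEASES) & (age <= 50)
    keep = (has_age & ~early_nd).to_numpy()
    if not keep.any():
        raise DegenerateInputError("sample filtering removed every sample")
    dropped = int((~keep).sum())
    if dropped:
        logger.info("sample filter removed %d/%d samples", dropped, data.n_samples)
    return data.select_samples(keep)


def reference_zscore(
    data: MethylationDataset, reference_group: tuple[str, ...] = (CONTROL,)
) -> MethylationDataset:
    """Standardize every site by the mean/SD of the reference (healthy aged) samples.

    Sites with zero reference variance are dropped with a warning.
    """
    ref_mask = data.group_mask(*reference_group)
    if not ref_mask.any():
        raise ValueError(f"reference group {reference_group} is empty")
    ref = data.values.loc[ref_mask]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    bad = sd <= 0
    if bad.any():
        logger.warning("dropping %d zero-variance reference sites", int(bad.sum()))
    keep = sd.index[~bad]
    z = (data.values[keep] - mu[keep]) / sd[keep]
    return data.with_values(z)


def svd_batch_correct(
    data: MethylationDataset,
    reference_group: tuple[str, ...] = (CONTROL,),
    n_components: int = 3,
) -> MethylationDataset:
    """Remove the top right-singular directions of the reference submatrix.

    Components are estimated on the reference samples' column-centered
    matrix; every sample's projection onto them is subtracted, so
    inter-sample (batch) variation aligned with the leading reference
    principal components is eliminated.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1; skip the stage for identity")
    ref_mask = data.group_mask(*reference_group)
    if not ref_mask.any():
        raise ValueError(f"reference group {reference_group} is empty")
    X = data.values.to_numpy(dtype=float)
    ref = X[ref_mask]
    center = ref.mean(axis=0)
    _, s, vt = np.linalg.svd(ref - center, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if n_components > rank:
        logger.warning("n_components=%d exceeds reference rank %d; reduced", n_components, rank)
        n_components = rank
    V = vt[:n_components].T  # sites x components
    centered = X - center
    corrected = centered - (centered @ V) @ V.T + center
    return data.with_values(
        pd.DataFrame(corrected, index=data.values.index, columns=data.values.columns)
    )


def split_train_test(
    data: MethylationDataset, ratio: tuple[int, int] = (2, 1), seed: int = 0
) -> MethylationDataset:
    """Assign a stratified train/test split, recorded in the split field.

    Within each group label, samples are shuffled deterministically under
    ``seed`` and the first ``ratio[0] : ratio[1]`` share goes to train.
    Groups with fewer than 2 samples go entirely to train.
    """
    if min(ratio) <= 0:
        raise ValueError("ratio parts must be positive")
    rng = np.random.default_rng(seed)
    frac_train = ratio[0] / (ratio[0] + ratio[1])
    split = pd.Series("", index=data.meta.index, dtype=object)
    for g in sorted(data.group.unique()):
        ids = data.meta.index[data.group == g].to_numpy()
        if len(ids) < 2:
            logger.warning("group %s has <2 samples; all assigned to train", g)
            split.loc[ids] = SPLIT_TRAIN
            continue
        ids = ids[rng.permutation(len(ids))]
        n_train = int(round(frac_train * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        split.loc[ids[:n_train]] = SPLIT_TRAIN
        split.loc[ids[n_train:]] = SPLIT_TEST
    meta = data.meta.copy()
    meta["split"] = split
    return MethylationDataset(data.values.copy(), meta)


def preprocess(
    data: MethylationDataset,
    max_missing: float = 0.30,
    knn_k: int = 10,
    stratify_by: str | None = None,
    reference_group: tuple[str, ...] = (CONTROL,),
    svd_components: int = 3,
    split_ratio: tuple[int, int] = (2, 1),
    seed: int = 0,
) -> MethylationDataset:
    """Run the full seven-step pre-processing pipeline in canonical order."""
    out = filter_sites_by_missingness(data, max_missing)
    out = knn_impute(out, knn_k, stratify_by)
    out = filter_samples(out)
    out = reference_zscore(out, reference_group)
    if svd_components >= 1:
        out = svd_batch_correct(out, reference_group, svd_components)
    out = reference_zscore(out, reference_group)
    out = split_train_test(out, split_ratio, seed)
    return out
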