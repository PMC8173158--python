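"""Synthetic methylation cohorts with planted aging/disease structure.

The generator emulates the statistical shape of multi-cohort brain
methylation studies: a Gaussian (M-value-like) site matrix, a block of
age-correlated marker sites, per-disease mean-shifted marker sites, an
inflated aging slope in disease samples ("accelerated aging"), additive
per-cohort batch offsets, and missing-completely-at-random entries.
Ground truth is recorded so recovery can be scored downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import (
    CONTROL,
    DISEASES,
    SPLIT_UNASSIGNED,
    YOUNG,
    MethylationDataset,
    make_meta,
)

logger = logging.getLogger(__name__)

#: multiplier applied to the aging slope in disease samples; the analysis
#: only assumes the accelerated pattern exists, not its size.
DEFAULT_ACCELERATION = 1.5


@dataclass
class GroundTruth:
    """Record of planted structure for recovery tests."""

    aging_marker_ids: list[str]
    disease_marker_ids: dict[str, list[str]]
    signflip_pairs: list[tuple[str, str]] = field(default_factory=list)
    enriched_set_name: str | None = None
    batch_offsets: np.ndarray | None = None
    seed: int = 0
    all_site_ids: list[str] = field(default_factory=list)

    @property
    def planted_site_ids(self) -> set[str]:
        out = set(self.aging_marker_ids)
        for ids in self.disease_marker_ids.values():
            out.update(ids)
        for a, b in self.signflip_pairs:
            out.update((a, b))
        return out

    @property
    def noise_site_ids(self) -> list[str]:
        planted = self.planted_site_ids
        return [s for s in self.all_site_ids if s not in planted]


def _site_ids(n: int) -> list[str]:
    return [f"cg{i:06d}" for i in range(n)]


def generate_dataset(
    n_young: int = 120,
    n_old: int = 150,
    n_per_disease: dict[str, int] | None = None,
    n_cpg: int = 500,
    n_aging_markers: int = 20,
    n_disease_markers: int = 10,
    aging_effect: float = 0.5,
    disease_effect: float = 0.5,
    acceleration: float = DEFAULT_ACCELERATION,
    batch_sd: float = 0.0,
    missing_frac: float = 0.0,
    n_cohorts: int = 3,
    seed: int = 0,
) -> tuple[MethylationDataset, GroundTruth]:
    """Generate a cohort with planted aging and disease signal.

    Parameters
    ----------
    aging_effect
        Standardized mean shift per decade of age (relative to age 50)
        added to each aging-marker site.
    disease_effect
        Standardized mean shift added to each disease-marker site, in the
        matching disease's samples only.
    acceleration
        Multiplier on the aging slope in disease samples (planted
        accelerated aging; 1.0 disables it).
    batch_sd
        SD of the per-cohort, per-site additive offsets.
    missing_frac
        Fraction of entries set missing completely at random.

    Returns
    -------
    (MethylationDataset, GroundTruth)
    """
    if n_per_disease is None:
        n_per_disease = {"AD": 100}
    if min(n_young, n_old, n_cpg, n_aging_markers, 1) < 1:
        raise ValueError("all counts must be >= 1")
    if any(v < 1 for v in n_per_disease.values()):
        raise ValueError("disease sample counts must be >= 1")
    unknown = set(n_per_disease) - set(DISEASES)
    if unknown:
        raise ValueError(f"unknown diseases: {sorted(unknown)}")
    total_markers = n_aging_markers + n_disease_markers * len(n_per_disease)
    if total_markers > n_cpg:
        raise ValueError(
            f"{total_markers} marker sites requested but only {n_cpg} CpG columns"
        )
    if not 0.0 <= missing_frac < 1.0:
        raise ValueError("missing_frac must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    diseases = sorted(n_per_disease)

    groups = [YOUNG] * n_young + [CONTROL] * n_old
    for d in diseases:
        groups += [d] * n_per_disease[d]
    n = len(groups)
    groups = np.asarray(groups)

    # integer ages: young uniform on [20, 50], everyone else on [51, 90]
    age = np.where(
        groups == YOUNG,
        rng.integers(20, 51, size=n),
        rng.integers(51, 91, size=n),
    ).astype(float)

    sites = _site_ids(n_cpg)
    values = rng.standard_normal((n, n_cpg))

    # disjoint random marker positions
    perm = rng.permutation(n_cpg)
    aging_idx = perm[:n_aging_markers]
    disease_idx: dict[str, np.ndarray] = {}
    pos = n_aging_markers
    for d in diseases:
        disease_idx[d] = perm[pos : pos + n_disease_markers]
        pos += n_disease_markers

    # aging markers: slope per decade relative to age 50, inflated in disease
    slope = np.full(n, aging_effect)
    slope[~np.isin(groups, (YOUNG, CONTROL))] *= acceleration
    values[:, aging_idx] += (slope * (age - 50.0) / 10.0)[:, None]

    # disease markers: mean shift in that disease's samples only
    for d in diseases:
        values[np.ix_(groups == d, disease_idx[d])] += disease_effect

    # per-cohort additive offsets, one vector over sites per cohort
    cohort = rng.integers(0, n_cohorts, size=n)
    offsets = rng.normal(0.0, batch_sd, size=(n_cohorts, n_cpg)) if batch_sd > 0 else np.zeros((n_cohorts, n_cpg))
    values += offsets[cohort]

    if missing_frac > 0:
        mask = rng.random((n, n_cpg)) < missing_frac
        values = np.where(mask, np.nan, values)

    sample_ids = [f"S{i:05d}" for i in range(n)]
    frame = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=sites)
    meta = make_meta(sample_ids, age, groups, [SPLIT_UNASSIGNED] * n)
    meta["cohort"] = cohort
    data = MethylationDataset(frame, meta)

    truth = GroundTruth(
        aging_marker_ids=[sites[i] for i in aging_idx],
        disease_marker_ids={d: [sites[i] for i in disease_idx[d]] for d in diseases},
        batch_offsets=offsets,
        seed=seed,
        all_site_ids=sites,
    )
    return data, truth


def plant_signflip_pairs(
    data: MethylationDataset,
    truth: GroundTruth,
    n_pairs: int,
    rho: float = 0.8,
    seed: int = 0,
    age_coupling: float | None = None,
) -> tuple[MethylationDataset, GroundTruth]:
    """Rewrite pairs of noise sites with a group-dependent correlation sign.

    Each pair correlates at about ``+rho`` in control-aged (and young)
    samples and about ``-rho`` in disease samples, via a Gaussian-copula
    construction.  One member of each pair additionally loads on the
    within-group standardized-age latent (loading ``age_coupling``,
    default the maximal feasible sqrt(1 - rho^2)): the planted pairs sit
    on the aging axis, so conditioning on an aging score reshapes their
    correlation and the flip becomes visible to the marginal-vs-partial
    differential edge rule.  The latent is standardized per group, so the
    pair sites carry no young-vs-aged mean gradient and do not compete
    with the planted aging markers in marker selection.

    Returns a new dataset and the truth record with ``signflip_pairs``
    appended.  ``n_pairs = 0`` is a no-op.
    """
    if n_pairs == 0:
        return data, truth
    if not 0.0 < rho < 1.0:
        raise ValueError("rho must lie in (0, 1)")
    noise = truth.noise_site_ids
    if len(noise) < 2 * n_pairs:
        raise ValueError(
            f"need {2 * n_pairs} noise sites for {n_pairs} pairs, have {len(noise)}"
        )
    a = float(np.sqrt(1.0 - rho**2)) if age_coupling is None else float(age_coupling)
    if a > np.sqrt(1.0 - rho**2) + 1e-12:
        raise ValueError("age_coupling must be <= sqrt(1 - rho^2)")

    rng = np.random.default_rng(seed)
    chosen = list(rng.choice(len(noise), size=2 * n_pairs, replace=False))
    pair_sites = [(noise[chosen[2 * i]], noise[chosen[2 * i + 1]]) for i in range(n_pairs)]

    values = data.values.copy()
    groups = data.group.to_numpy()
    age = data.age.to_numpy(dtype=float)
    # age latent standardized within each group: within-group aging
    # coupling without a between-group mean gradient
    u = np.zeros(len(age))
    for g in np.unique(groups):
        mask = groups == g
        sd_g = age[mask].std()
        u[mask] = (age[mask] - age[mask].mean()) / (sd_g if sd_g > 0 else 1.0)

    disease = ~np.isin(groups, [YOUNG, CONTROL])
    # residual correlation needed so the total pair correlation is +/-rho
    rho_e = rho / np.sqrt(1.0 - a**2)
    rho_e = min(rho_e, 1.0)
    n = len(groups)
    for sa, sb in pair_sites:
        e = rng.standard_normal(n)
        f = rng.standard_normal(n)
        x = a * u + np.sqrt(1.0 - a**2) * e
        sign = np.where(disease, -1.0, 1.0)
        y = sign * (rho_e * e + np.sqrt(max(0.0, 1.0 - rho_e**2)) * f)
        values[sa] = x
        values[sb] = y

    new_truth = GroundTruth(
        aging_marker_ids=list(truth.aging_marker_ids),
        disease_marker_ids={k: list(v) for k, v in truth.disease_marker_ids.items()},
        signflip_pairs=list(truth.signflip_pairs) + pair_sites,
        enriched_set_name=truth.enriched_set_name,
        batch_offsets=truth.batch_offsets,
        seed=truth.seed,
        all_site_ids=list(truth.all_site_ids),
    )
    return data.with_values(values), new_truth


def generate_annotation_and_genesets(
    site_ids: list[str],
    n_genes: int,
    n_sets: int,
    set_size: int,
    seed: int = 0,
    marker_site_ids: list[str] | None = None,
    enriched_set_name: str = "PLANTED_MARKER_SET",
) -> tuple[pd.DataFrame, dict[str, list[str]], str]:
    """Build a surjective CpG->gene annotation plus gene sets.

    One set (the returned name) is constructed to contain the genes of
    ``marker_site_ids`` (padded with random genes up to ``set_size``); the
    other ``n_sets`` sets are uniform random draws.

    Returns ``(annotation, gene_sets, enriched_set_name)`` where the
    annotation has columns ``cpg_id`` and ``gene``.
    """
    n_cpg = len(site_ids)
    if n_genes > n_cpg:
        raise ValueError("n_genes must be <= number of CpG sites (surjective map)")
    if set_size > n_genes:
        raise ValueError("set_size must be <= n_genes")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]

    # surjectivity: the first n_genes sites each claim a distinct gene,
    # remaining sites map to random genes
    assignment = list(range(n_genes)) + list(rng.integers(0, n_genes, size=n_cpg - n_genes))
    order = rng.permutation(n_cpg)
    gene_of_site = {site_ids[order[i]]: genes[assignment[i]] for i in range(n_cpg)}
    annotation = pd.DataFrame(
        {"cpg_id": site_ids, "gene": [gene_of_site[s] for s in site_ids]}
    )

    sets: dict[str, list[str]] = {}
    for i in range(n_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        sets[f"RANDOM_SET_{i:03d}"] = sorted(members)

    marker_genes: list[str] = []
    if marker_site_ids:
        marker_genes = sorted({gene_of_site[s] for s in marker_site_ids if s in gene_of_site})
    pad = [g for g in genes if g not in marker_genes]
    rng.shuffle(pad)
    planted = marker_genes + pad[: max(0, set_size - len(marker_genes))]
    sets[enriched_set_name] = sorted(planted)
    logger.info(
        "planted enriched set %s with %d marker genes (%d total members)",
        enriched_set_name, len(marker_genes), len(planted),
    )
    return annotation, sets, enriched_set_name
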