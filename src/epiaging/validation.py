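"""Recovery and calibration experiments on planted synthetic cohorts.

Each function runs one self-contained experiment at the package's synthetic
conditions — planted effect sizes, group sizes and thresholds — and
returns the measured quantities.  The experiments are what the package's
acceptance checks and the analysis drivers execute; they never look up
expected values, they measure them.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from . import diffnet, markers, preprocess, scoring, sensitivity, synthetic
from .dataset import CONTROL, SPLIT_TEST, SPLIT_TRAIN, YOUNG

logger = logging.getLogger(__name__)


def null_label_calibration(
    n_reseeds: int = 20,
    n_per_class: int = 75,
    n_cpg: int = 100,
    k_max: int = 10,
    folds: int = 3,
    n_estimators: int = 20,
    seed: int = 0,
) -> dict:
    """Marker selection + evaluation on label-permuted cohorts.

    The young/aged labels are shuffled before ranking and selection, so any
    departure of test accuracy or AUC from 0.5 is selection bias.  Returns
    the reseed-mean accuracy and AUC together with the binomial/rank-based
    2*SE bands for the means.
    """
    accs, aucs, n_tests = [], [], []
    for r in range(n_reseeds):
        data, _ = synthetic.generate_dataset(
            n_young=n_per_class, n_old=n_per_class, n_per_disease={},
            n_cpg=n_cpg, n_aging_markers=20, aging_effect=0.5, seed=seed + 1000 * r,
        )
        rng = np.random.default_rng(seed + 1000 * r + 1)
        y = (data.group == CONTROL).astype(int).to_numpy()
        y = rng.permutation(y)
        split = preprocess.split_train_test(data, (2, 1), seed=seed + r)
        tr = (split.split == SPLIT_TRAIN).to_numpy()
        te = ~tr
        ranking = markers.relieff_rank(data.values.loc[tr], y[tr], seed=seed + r)
        ms = markers.select_top_k_cv(
            data.values.loc[tr], y[tr], ranking,
            k_max=k_max, folds=folds, n_estimators=n_estimators, seed=seed + r,
        )
        ev = markers.evaluate(
            ms.final_model, data.values.loc[te, ms.selected_site_ids], y[te]
        )
        accs.append(ev["accuracy"])
        aucs.append(ev["auc"])
        n_tests.append(int(te.sum()))
    n_test = int(np.mean(n_tests))
    se_acc = float(np.sqrt(0.25 / (n_test * n_reseeds)))
    n1 = n_test // 2
    se_auc = float(np.sqrt((n_test + 1) / (12 * n1 * (n_test - n1)) / n_reseeds))
    return {
        "mean_accuracy": float(np.mean(accs)),
        "mean_auc": float(np.mean(aucs)),
        "se_accuracy": se_acc,
        "se_auc": se_auc,
        "n_reseeds": n_reseeds,
        "n_test": n_test,
    }


def planted_marker_recovery(
    n_reseeds: int = 10,
    n_per_class: int = 100,
    n_cpg: int = 500,
    n_markers: int = 20,
    aging_effect: float = 0.5,
    k_max: int = 50,
    folds: int = 10,
    n_estimators: int = 20,
    seed: int = 0,
) -> dict:
    """Fraction of planted aging markers recovered by the selection sweep.

    Conditions: ``n_markers`` planted sites with a 0.5 SD/decade age slope
    among ``n_cpg`` columns, ``n_per_class`` samples per class; recovery is
    the overlap of the CV-selected prefix with the planted list.
    """
    fractions, ks = [], []
    for r in range(n_reseeds):
        data, truth = synthetic.generate_dataset(
            n_young=n_per_class, n_old=n_per_class, n_per_disease={},
            n_cpg=n_cpg, n_aging_markers=n_markers, aging_effect=aging_effect,
            seed=seed + 997 * r,
        )
        y = (data.group == CONTROL).astype(int).to_numpy()
        ranking = markers.relieff_rank(data.values, y, seed=seed + r)
        ms = markers.select_top_k_cv(
            data.values, y, ranking, k_max=k_max, folds=folds,
            n_estimators=n_estimators, seed=seed + r,
        )
        hit = len(set(ms.selected_site_ids) & set(truth.aging_marker_ids))
        fractions.append(hit / n_markers)
        ks.append(ms.selected_k)
    return {
        "mean_recovery": float(np.mean(fractions)),
        "per_reseed": fractions,
        "selected_k": ks,
        "n_reseeds": n_reseeds,
    }


def accelerated_aging_detection(
    n_reseeds: int = 20,
    n_young: int = 150,
    n_old: int = 440,
    n_disease: int = 330,
    acceleration: float = 1.5,
    min_per_arm: int = 20,
    seed: int = 0,
) -> dict:
    """Kruskal-Wallis detection of the planted accelerated-aging pattern.

    Disease samples carry a 1.5x aging slope; the aging score is fit on
    young-vs-aged controls over the planted aging markers and compared
    between disease and control in every age stratum with at least
    ``min_per_arm`` samples per arm.  Arm sizes are about 440 aged
    controls vs 330 pooled ND samples.  Returns how many
    reseeds reject in every eligible stratum at p < 0.05.
    """
    all_sig = 0
    worst_p = []
    medians_trend = []
    for r in range(n_reseeds):
        data, truth = synthetic.generate_dataset(
            n_young=n_young, n_old=n_old, n_per_disease={"AD": n_disease},
            n_cpg=120, n_aging_markers=20, aging_effect=0.5,
            disease_effect=0.0, acceleration=acceleration, seed=seed + 7919 * r,
        )
        data = preprocess.reference_zscore(data)
        healthy = data.select_samples(data.group_mask(YOUNG, CONTROL))
        scorer = scoring.fit_score_regressor(
            healthy.values[truth.aging_marker_ids],
            (healthy.group == CONTROL).astype(int).to_numpy(),
            n_trees=100, seed=seed + r,
        )
        scores = scorer.predict(data.values[truth.aging_marker_ids])
        kw = scoring.kruskal_wallis_by_age_group(
            scores, data.group.to_numpy(), data.age.to_numpy()
        )
        eligible = kw[(kw["n_nd"] >= min_per_arm) & (kw["n_control"] >= min_per_arm)]
        if len(eligible) and (eligible["p"] < 0.05).all():
            all_sig += 1
        worst_p.append(float(eligible["p"].max()) if len(eligible) else np.nan)
        # monotone trend of the ND median score across thresholds
        from scipy import stats as _st

        if len(eligible) > 2 and eligible["median_nd"].nunique() > 1:
            rho = _st.spearmanr(eligible["threshold"], eligible["median_nd"]).statistic
            medians_trend.append(float(rho))
    return {
        "n_all_strata_significant": all_sig,
        "n_reseeds": n_reseeds,
        "worst_p_per_reseed": worst_p,
        "median_trend_spearman": float(np.mean(medians_trend)) if medians_trend else np.nan,
    }


def signflip_network_recovery(
    n_pairs: int = 10,
    rho: float = 0.8,
    n_per_group: int = 150,
    n_young: int = 100,
    n_cpg: int = 80,
    fdr: float = 0.1,
    seed: int = 0,
) -> dict:
    """End-to-end recovery of planted sign-flip pairs by the edge rule.

    Builds the full differential network at ``n_per_group`` samples per
    group, measures sensitivity on the planted pairs and the false-edge
    rate among non-planted pairs, then repeats network construction on a
    2:1 train/test split and tests edge-overlap with Fisher's exact test.
    """
    data, truth = synthetic.generate_dataset(
        n_young=n_young, n_old=n_per_group, n_per_disease={"AD": n_per_group},
        n_cpg=n_cpg, n_aging_markers=15, n_disease_markers=5,
        aging_effect=0.5, seed=seed,
    )
    data, truth = synthetic.plant_signflip_pairs(data, truth, n_pairs, rho, seed=seed + 1)
    data = preprocess.reference_zscore(data)

    healthy = data.select_samples(data.group_mask(YOUNG, CONTROL))
    scorer = scoring.fit_score_regressor(
        healthy.values[truth.aging_marker_ids],
        (healthy.group == CONTROL).astype(int).to_numpy(),
        n_trees=100, seed=seed,
    )
    score = pd.Series(
        scorer.predict(data.values[truth.aging_marker_ids]), index=data.values.index
    )
    planted = {tuple(sorted(p)) for p in truth.signflip_pairs}

    def network_for(sample_mask) -> diffnet.DifferentialNetwork:
        sub = data.select_samples(sample_mask)
        ctrl = sub.select_samples(sub.group_mask(CONTROL))
        nd = sub.select_samples(sub.group_mask("AD"))
        stats = diffnet.compute_pair_stats(
            ctrl.values, nd.values,
            score.loc[ctrl.values.index].to_numpy(),
            score.loc[nd.values.index].to_numpy(),
        )
        return diffnet.build_differential_network(stats, fdr)

    full = network_for(np.ones(data.n_samples, dtype=bool))
    edges = full.edge_set
    n_all_pairs = data.n_sites * (data.n_sites - 1) // 2
    sensitivity_frac = len(planted & edges) / len(planted)
    false_edges = len(edges - planted)
    false_rate = false_edges / (n_all_pairs - len(planted))

    split = preprocess.split_train_test(data, (2, 1), seed=seed + 2)
    tr_net = network_for((split.split == SPLIT_TRAIN).to_numpy())
    te_net = network_for((split.split == SPLIT_TEST).to_numpy())
    sites = data.site_ids
    universe = [(a, b) for i, a in enumerate(sites) for b in sites[i + 1 :]]
    _, fisher_p = diffnet.network_similarity_fisher(tr_net, te_net, universe)
    return {
        "sensitivity": sensitivity_frac,
        "false_edge_rate": false_rate,
        "n_edges": len(edges),
        "train_test_fisher_p": fisher_p,
        "n_pairs": n_pairs,
    }


def planted_driver_sensitivity(
    n_reseeds: int = 10,
    n_sites: int = 20,
    n_samples: int = 4000,
    burn_in: int = 1000,
    seed: int = 0,
) -> dict:
    """Does the MCMC K-S differential surface a marker driving one scorer?

    Half the sites belong to the aging scorer, half to a disease scorer;
    one aging site solely drives the aging outcome.  Counts the reseeds in
    which that site's |differential| lands in the top decile of all sites.
    """
    top_decile_hits = 0
    n_top = max(1, int(np.ceil(n_sites / 10)))
    for r in range(n_reseeds):
        rng = np.random.default_rng(seed + 31 * r)
        sites = [f"cg{i:03d}" for i in range(n_sites)]
        aging_sites = sites[: n_sites // 2]
        dis_sites = sites[n_sites // 2 :]
        n = 300
        X = pd.DataFrame(rng.standard_normal((n, n_sites)), columns=sites)
        y_aging = (X[aging_sites[0]] > 0).astype(float)
        y_dis = (X[dis_sites[0]] > 0).astype(float)
        aging_scorer = scoring.fit_score_regressor(X[aging_sites], y_aging, 30, seed + r)
        dis_scorer = scoring.fit_score_regressor(X[dis_sites], y_dis, 30, seed + r + 1)
        result = sensitivity.run_sensitivity(
            pd.Series(0.0, index=sites), pd.Series(1.0, index=sites),
            aging_scorer, aging_sites, {"AD": dis_scorer}, {"AD": dis_sites},
            n_samples=n_samples, burn_in=burn_in, seed=seed + r,
        )
        ranked = result.differential["AD"].abs().sort_values(ascending=False)
        if aging_sites[0] in ranked.index[:n_top]:
            top_decile_hits += 1
    return {"top_decile_hits": top_decile_hits, "n_reseeds": n_reseeds, "n_top": n_top}


def planted_enrichment_recovery(n_reseeds: int = 10, seed: int = 0) -> dict:
    """Rank of the planted enriched gene set across reseeded cohorts."""
    from . import enrichment as enr

    rank_one = 0
    for r in range(n_reseeds):
        rng_seed = seed + 101 * r
        sites = [f"cg{i:06d}" for i in range(150)]
        rng = np.random.default_rng(rng_seed)
        marker_sites = list(rng.choice(sites, size=12, replace=False))
        ann, sets, name = synthetic.generate_annotation_and_genesets(
            sites, n_genes=90, n_sets=20, set_size=12, seed=rng_seed,
            marker_site_ids=marker_sites,
        )
        coll = enr.GeneSetCollection(sets=sets, universe=sorted(ann["gene"].unique()))
        query = enr.map_paths_to_genes([marker_sites], ann)
        res = enr.enrich(query, coll)
        if res.table.iloc[0]["set"] == name and res.table.iloc[0]["q"] < 0.05:
            rank_one += 1
    return {"rank_one_hits": rank_one, "n_reseeds": n_reseeds}
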