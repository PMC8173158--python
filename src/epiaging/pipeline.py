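"""End-to-end orchestration of the aging-acceleration analysis.

One :class:`RunConfig` drives all seven stages — synthetic cohort
generation, pre-processing, marker selection, scoring, differential
networks, MCMC sensitivity, and enrichment — with named seed streams
derived from a single master seed, so stages are reproducible in
isolation.  Every run writes its artifacts plus a manifest (config hash,
seeds, library versions) into one directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffnet, enrichment, markers, preprocess, scoring, sensitivity, synthetic
from .dataset import CONTROL, DISEASES, SPLIT_TEST, SPLIT_TRAIN, YOUNG, MethylationDataset

logger = logging.getLogger(__name__)

ALL_STAGES = ("synthetic", "preprocess", "markers", "score", "network", "sensitivity", "enrich")

#: control subgrouping used to balance each disease comparison
DEFAULT_SUBGROUPS = {"AD": 3, "PD": 9, "PSP": 7, "FTD": 3}


def stream_seed(master: int, name: str) -> int:
    """Deterministic named sub-seed below 2**31."""
    return (int(master) * 2654435761 + zlib.crc32(name.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """All thresholds and sizes of the pipeline with their standard
    defaults (missingness 0.3, KNN k=10, SVD 3 components, 2:1
    split, top-50 CV sweep with 10 folds, 100-tree ensembles, network
    FDR 0.1, enrichment FDR 0.05)."""

    seed: int = 0
    out_dir: str = "run"
    stages: tuple[str, ...] = ALL_STAGES

    # synthetic cohort
    synthetic_params: dict = field(default_factory=dict)
    n_signflip_pairs: int = 10
    signflip_rho: float = 0.8
    n_genes: int = 150
    n_gene_sets: int = 20
    gene_set_size: int = 15

    # preprocessing
    max_missing: float = 0.30
    knn_k: int = 10
    svd_components: int = 3
    split_ratio: tuple[int, int] = (2, 1)

    # marker selection
    k_max: int = 50
    folds: int = 10
    n_estimators: int = 100
    relieff_neighbors: int = 10
    subgroups: dict = field(default_factory=lambda: dict(DEFAULT_SUBGROUPS))

    # scoring
    n_score_trees: int = 100

    # differential network
    network_fdr: float = 0.1
    network_rule: str = "per-group-delta"
    universe_top_var: int = 500
    n_perm: int = 1000

    # sensitivity
    mcmc_samples: int = 20_000
    mcmc_burn_in: int = 5_000
    proposal_scale: float | None = None
    top_n_pairs: int = 50

    # enrichment
    enrichment_fdr: float = 0.05

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["stages"] = tuple(raw.get("stages", ALL_STAGES))
        raw["split_ratio"] = tuple(raw.get("split_ratio", (2, 1)))
        return cls(**raw)

    def as_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        d["split_ratio"] = list(self.split_ratio)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def run_all(config: RunConfig) -> dict:
    """Execute the enabled stages in canonical order; returns the artifacts.

    Stage dependencies are linear; disabling an upstream stage skips the
    dependents with a log message.  Artifacts are written as delimited
    text under ``config.out_dir`` together with ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    artifacts: dict = {}
    timings: dict[str, float] = {}

    def enabled(stage: str) -> bool:
        return stage in config.stages

    def done(stage: str) -> None:
        timings[stage] = round(time.time() - t0, 2)
        logger.info("stage %s finished at %.1fs", stage, timings[stage])

    # -- synthetic ---------------------------------------------------------
    if enabled("synthetic"):
        data, truth = synthetic.generate_dataset(
            seed=stream_seed(config.seed, "synthetic"), **config.synthetic_params
        )
        if config.n_signflip_pairs:
            data, truth = synthetic.plant_signflip_pairs(
                data, truth, config.n_signflip_pairs, config.signflip_rho,
                seed=stream_seed(config.seed, "signflip"),
            )
        annotation, gene_sets, enriched_name = synthetic.generate_annotation_and_genesets(
            data.site_ids, config.n_genes, config.n_gene_sets, config.gene_set_size,
            seed=stream_seed(config.seed, "genesets"),
            marker_site_ids=sorted(truth.planted_site_ids),
        )
        data.to_files(out_dir / "matrix.tsv", out_dir / "meta.tsv")
        annotation.to_csv(out_dir / "annotation.tsv", sep="\t", index=False)
        enrichment.write_gmt(gene_sets, out_dir / "gene_sets.gmt")
        artifacts.update(
            data=data, truth=truth, annotation=annotation,
            gene_sets=gene_sets, enriched_set_name=enriched_name,
        )
        done("synthetic")
    else:
        logger.info("synthetic stage disabled; downstream stages need inputs in artifacts")

    # -- preprocess --------------------------------------------------------
    if enabled("preprocess"):
        if "data" not in artifacts:
            raise RuntimeError("preprocess needs the synthetic stage (or preloaded data)")
        clean = preprocess.preprocess(
            artifacts["data"],
            max_missing=config.max_missing,
            knn_k=config.knn_k,
            svd_components=config.svd_components,
            split_ratio=config.split_ratio,
            seed=stream_seed(config.seed, "split"),
        )
        clean.to_files(out_dir / "clean_matrix.tsv", out_dir / "clean_meta.tsv")
        artifacts["clean"] = clean
        done("preprocess")

    clean: MethylationDataset | None = artifacts.get("clean")
    diseases_present = (
        sorted(set(clean.group.unique()) & set(DISEASES)) if clean is not None else []
    )

    # -- markers -----------------------------------------------------------
    if enabled("markers"):
        if clean is None:
            logger.info("markers stage skipped: no preprocessed data")
        else:
            train = clean.select_samples((clean.split == SPLIT_TRAIN).to_numpy())
            healthy = train.select_samples(train.group_mask(YOUNG, CONTROL))
            y_age = (healthy.group == CONTROL).astype(int).to_numpy()
            ranking = markers.relieff_rank(
                healthy.values, y_age, n_neighbors=config.relieff_neighbors,
                seed=stream_seed(config.seed, "relieff"),
            )
            aging_set = markers.select_top_k_cv(
                healthy.values, y_age, ranking,
                k_max=config.k_max, folds=config.folds,
                n_estimators=config.n_estimators,
                seed=stream_seed(config.seed, "aging-cv"),
            )
            aging_set.to_frame().to_csv(out_dir / "aging_markers.tsv", sep="\t", index=False)
            aging_set.cv_accuracy_by_k.to_csv(out_dir / "aging_cv_curve.tsv", sep="\t")
            artifacts["aging_markers"] = aging_set

            disease_sets = {}
            for d in diseases_present:
                ctrl = train.select_samples(train.group_mask(CONTROL))
                dis = train.select_samples(train.group_mask(d))
                disease_sets[d] = markers.balanced_disease_fit(
                    ctrl.values, dis.values,
                    n_subgroups=config.subgroups.get(d, 1),
                    k_max=config.k_max, folds=config.folds,
                    n_estimators=config.n_estimators,
                    n_neighbors=config.relieff_neighbors,
                    seed=stream_seed(config.seed, f"{d}-markers"),
                )
                disease_sets[d].to_frame().to_csv(
                    out_dir / f"{d}_markers.tsv", sep="\t", index=False
                )
            artifacts["disease_markers"] = disease_sets

            # held-out evaluation
            test = clean.select_samples((clean.split == SPLIT_TEST).to_numpy())
            test_h = test.select_samples(test.group_mask(YOUNG, CONTROL))
            ev = markers.evaluate(
                aging_set.final_model,
                test_h.values[aging_set.selected_site_ids],
                (test_h.group == CONTROL).astype(int).to_numpy(),
            )
            artifacts["aging_eval"] = {"accuracy": ev["accuracy"], "auc": ev["auc"]}
            done("markers")

    # -- score -------------------------------------------------------------
    if enabled("score"):
        if "aging_markers" not in artifacts:
            logger.info("score stage skipped: marker stage did not run")
        else:
            aging_sites = artifacts["aging_markers"].selected_site_ids
            train = clean.select_samples((clean.split == SPLIT_TRAIN).to_numpy())
            healthy = train.select_samples(train.group_mask(YOUNG, CONTROL))
            scorer = scoring.fit_score_regressor(
                healthy.values[aging_sites],
                (healthy.group == CONTROL).astype(int).to_numpy(),
                n_trees=config.n_score_trees,
                seed=stream_seed(config.seed, "aging-score"),
            )
            scores = scorer.predict(clean.values[aging_sites])
            table = scoring.ScoreTable.build(clean.sample_ids, scores, clean.age.to_numpy())
            table.frame.to_csv(out_dir / "scores.tsv", sep="\t")

            disease_scorers = {}
            for d in diseases_present:
                sites_d = artifacts["disease_markers"][d].selected_site_ids
                ctrl_dis = train.select_samples(train.group_mask(CONTROL, d))
                disease_scorers[d] = scoring.fit_score_regressor(
                    ctrl_dis.values[sites_d],
                    (ctrl_dis.group == d).astype(int).to_numpy(),
                    n_trees=config.n_score_trees,
                    seed=stream_seed(config.seed, f"{d}-score"),
                )
            kw = scoring.kruskal_wallis_by_age_group(
                table.frame["aging_score"].to_numpy(), clean.group.to_numpy(),
                clean.age.to_numpy(),
            )
            kw.to_csv(out_dir / "kruskal_wallis.tsv", sep="\t", index=False)
            ks_stat, ks_p = scoring.ks_normality_test(
                table.frame.loc[clean.group_mask(*DISEASES, CONTROL), "aging_score"].to_numpy()
            )
            artifacts.update(
                scores=table, aging_scorer=scorer, disease_scorers=disease_scorers,
                kruskal_wallis=kw, ks_normality={"statistic": ks_stat, "p": ks_p},
            )
            done("score")

    # -- network -----------------------------------------------------------
    if enabled("network"):
        if "scores" not in artifacts:
            logger.info("network stage skipped: score stage did not run")
        else:
            artifacts["networks"] = {}
            artifacts["paths"] = {}
            aging_sites = artifacts["aging_markers"].selected_site_ids
            score_series = artifacts["scores"].frame["aging_score"]
            for d in diseases_present + (["ALL"] if len(diseases_present) > 1 else []):
                dis_groups = diseases_present if d == "ALL" else [d]
                marker_sites = sorted(
                    set().union(*(artifacts["disease_markers"][g].selected_site_ids
                                  for g in dis_groups))
                )
                universe = _candidate_universe(
                    clean, aging_sites, marker_sites, config.universe_top_var
                )
                net = _network_for(
                    clean, dis_groups, universe, score_series, config, provenance=d
                )
                artifacts["networks"][d] = net
                net.edges.to_csv(out_dir / f"network_{d}.tsv", sep="\t", index=False)
                paths = diffnet.shortest_paths(net, aging_sites, marker_sites)
                artifacts["paths"][d] = paths
                with open(out_dir / f"paths_{d}.txt", "w") as fh:
                    for (a, b), nodes in sorted(paths.items()):
                        fh.write("\t".join([a, b, ">".join(nodes)]) + "\n")
                if net.graph.number_of_nodes() >= 4 and paths:
                    btw = diffnet.betweenness_permutation_test(
                        net, aging_sites, marker_sites, n_perm=config.n_perm,
                        seed=stream_seed(config.seed, f"{d}-perm"),
                    )
                    btw.sort_values(["betweenness", "p"], ascending=[False, True]).to_csv(
                        out_dir / f"betweenness_{d}.tsv", sep="\t", index_label="cpg_id"
                    )
                    artifacts.setdefault("betweenness", {})[d] = btw
            done("network")

    # -- sensitivity -------------------------------------------------------
    if enabled("sensitivity"):
        if "disease_scorers" not in artifacts or not artifacts["disease_scorers"]:
            logger.info("sensitivity stage skipped: disease scorers unavailable")
        else:
            healthy_aged = clean.select_samples(clean.group_mask(CONTROL))
            dm = {d: artifacts["disease_markers"][d].selected_site_ids
                  for d in diseases_present}
            union = sorted(
                set(artifacts["aging_markers"].selected_site_ids).union(*dm.values())
            )
            result = sensitivity.run_sensitivity(
                healthy_aged.values[union].mean(axis=0),
                healthy_aged.values[union].std(axis=0, ddof=1).clip(lower=1e-9),
                artifacts["aging_scorer"],
                artifacts["aging_markers"].selected_site_ids,
                artifacts["disease_scorers"],
                dm,
                n_samples=config.mcmc_samples,
                burn_in=config.mcmc_burn_in,
                proposal_scale=config.proposal_scale,
                seed=stream_seed(config.seed, "mcmc"),
            )
            pair_table, freq = sensitivity.rank_aging_nd_pairs(
                result, artifacts["aging_markers"].selected_site_ids, dm,
                top_n=config.top_n_pairs,
            )
            pair_table.to_csv(out_dir / "aging_nd_pairs.tsv", sep="\t", index=False)
            freq.to_csv(out_dir / "aging_marker_frequency.tsv", sep="\t")
            artifacts.update(sensitivity=result, pair_table=pair_table, marker_frequency=freq)
            done("sensitivity")

    # -- enrichment --------------------------------------------------------
    if enabled("enrich"):
        if "paths" not in artifacts or "annotation" not in artifacts:
            logger.info("enrich stage skipped: paths or annotation unavailable")
        else:
            collection = enrichment.GeneSetCollection(
                sets=artifacts["gene_sets"],
                universe=sorted(artifacts["annotation"]["gene"].unique()),
            )
            artifacts["enrichment"] = {}
            for d, paths in artifacts["paths"].items():
                genes = enrichment.map_paths_to_genes(paths, artifacts["annotation"])
                if not genes:
                    continue
                res = enrichment.enrich(genes, collection, config.enrichment_fdr)
                res.table.to_csv(out_dir / f"enrichment_{d}.tsv", sep="\t", index=False)
                artifacts["enrichment"][d] = res
            done("enrich")

    manifest = {
        "config": config.as_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "timings_s": timings,
        "versions": _versions(),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["manifest"] = manifest
    return artifacts


def _candidate_universe(
    clean: MethylationDataset, aging_sites, marker_sites, top_var: int
) -> list[str]:
    """Aging + disease markers plus the top-variance sites, deduplicated."""
    var = clean.values.var(axis=0).sort_values(ascending=False)
    chosen = set(aging_sites) | set(marker_sites)
    for site in var.index:
        if len(chosen) >= len(set(aging_sites) | set(marker_sites)) + top_var:
            break
        chosen.add(site)
    return sorted(chosen)


def _network_for(
    clean: MethylationDataset,
    dis_groups: list[str],
    universe: list[str],
    score: pd.Series,
    config: RunConfig,
    provenance: str,
) -> diffnet.DifferentialNetwork:
    ctrl = clean.select_samples(clean.group_mask(CONTROL))
    nd = clean.select_samples(clean.group_mask(*dis_groups))
    stats = diffnet.compute_pair_stats(
        ctrl.values[universe], nd.values[universe],
        score.loc[ctrl.values.index].to_numpy(), score.loc[nd.values.index].to_numpy(),
    )
    return diffnet.build_differential_network(
        stats, fdr_threshold=config.network_fdr, rule=config.network_rule,
        provenance={"disease": provenance},
    )


def _versions() -> dict[str, str]:
    import networkx
    import scipy
    import sklearn
    import statsmodels

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "scikit-learn": sklearn.__version__,
        "networkx": networkx.__version__,
        "statsmodels": statsmodels.__version__,
    }
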