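"""Shared configuration for the numbered analysis drivers.

One moderate-scale synthetic cohort stands in for clinical methylation data;
all drivers derive their inputs from this config, so stage outputs are
reproducible in isolation.  Problem sizes are desk-scale; the methods
note records the sizing choices.
"""

from pathlib import Path

from epiaging import RunConfig

RESULTS = Path(__file__).resolve().parents[1] / "results"


def default_config(seed: int = 20260101 % 2**31) -> RunConfig:
    return RunConfig(
        seed=seed % (2**31 - 1),
        out_dir=str(RESULTS / "pipeline"),
        synthetic_params=dict(
            n_young=150,
            n_old=200,
            n_per_disease={"AD": 60, "PD": 40, "PSP": 40, "FTD": 50},
            n_cpg=300,
            n_aging_markers=20,
            n_disease_markers=8,
            aging_effect=0.5,
            disease_effect=0.8,
            batch_sd=0.3,
            missing_frac=0.03,
        ),
        n_signflip_pairs=10,
        n_genes=150,
        n_gene_sets=20,
        gene_set_size=15,
        k_max=30,
        folds=5,
        n_estimators=40,
        subgroups={"AD": 3, "PD": 9, "PSP": 7, "FTD": 3},
        universe_top_var=120,
        n_perm=200,
        mcmc_samples=6000,
        mcmc_burn_in=1500,
        top_n_pairs=20,
    )


def run_through(stage: str, config: RunConfig | None = None):
    """Run the pipeline through ``stage`` (inclusive) and return artifacts."""
    from epiaging.pipeline import ALL_STAGES, run_all

    cfg = config or default_config()
    idx = ALL_STAGES.index(stage)
    cfg.stages = ALL_STAGES[: idx + 1]
    return cfg, run_all(cfg)
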