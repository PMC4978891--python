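"""Simulation benchmarks that quantify the LOCO model's operating
characteristics against the traditional global-kinship MLM.

Each function defines one study condition — the panel, trait architecture
and analysis configuration are fixed here, not tuned per call site — and
returns per-seed measurements.  The headline scenario is *proximal
contamination*: a single causal marker inside a high-LD block, where
including the tested region in the kinship estimate absorbs part of the
signal and costs the global model power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .kinship import pca_covariates, vanraden_kinship
from .mlm import reml_fit, select_pcs_bic
from .pipeline import GWASConfig, run_gwas
from .sim import (
    SimConfig,
    evaluate_power_fdr,
    simulate_structured_genotypes,
    simulate_trait,
)

__all__ = [
    "proximal_contamination_trial",
    "power_comparison",
    "null_fdp_comparison",
    "bic_selection_rates",
    "heritability_recovery",
]

#: QTL-to-hit matching window for power/FDP scoring: one LD block plus slack.
POWER_WINDOW_BP = 25_000
FDR_LEVEL = 0.05


def _proximal_config(seed: int) -> SimConfig:
    """One causal marker in the interior of a high-LD block, polygenic
    background on, moderate effect: the regime where kinship contamination
    by the tested region is most costly."""
    return SimConfig(
        n_samples=300,
        n_chromosomes=10,
        markers_per_chromosome=200,
        ld_rho=0.95,
        block_size=20,
        qtl_spec=[(0, 110, 0.5)],
        h2_poly=0.4,
        seed=seed,
    )


@dataclass
class ModelComparisonTrial:
    seed: int
    causal_logp_loco: float
    causal_logp_global: float
    power_loco: float
    power_global: float
    fdp_loco: float
    fdp_global: float


def proximal_contamination_trial(seed: int) -> ModelComparisonTrial:
    """Run both models once on the proximal-contamination scenario."""
    cfg = _proximal_config(seed)
    g, truth = simulate_structured_genotypes(cfg)
    pheno = simulate_trait(g, truth, cfg)
    causal_id = truth.causal["marker"].iloc[0]
    stats: dict[str, tuple[float, float, float]] = {}
    for model in ("loco", "global"):
        run_cfg = GWASConfig(model=model, kinship_method="vanraden", seed=seed)
        table = run_gwas(run_cfg, g, pheno, "trait")
        p = table.frame.set_index("marker").loc[causal_id, "pvalue"]
        rep = evaluate_power_fdr(table, truth, POWER_WINDOW_BP, FDR_LEVEL)
        stats[model] = (-np.log10(p), rep.power, rep.fdp)
    return ModelComparisonTrial(
        seed=seed,
        causal_logp_loco=stats["loco"][0],
        causal_logp_global=stats["global"][0],
        power_loco=stats["loco"][1],
        power_global=stats["global"][1],
        fdp_loco=stats["loco"][2],
        fdp_global=stats["global"][2],
    )


def power_comparison(n_seeds: int = 25, seed0: int = 0) -> pd.DataFrame:
    """Per-seed causal-marker -log10 p and power/FDP for both models."""
    return pd.DataFrame(
        [vars(proximal_contamination_trial(seed0 + i)) for i in range(n_seeds)]
    )


def null_fdp_comparison(n_seeds: int = 25, seed0: int = 0) -> pd.DataFrame:
    """Fully null traits: realized FDP at the nominal level for both models.

    Fully null means the trait carries no genetic signal at all — no QTL,
    no structure effect and no polygenic background; any declared marker is
    a false discovery.  (With a polygenic background the trait is genetic
    genome-wide and markers tagging it are not cleanly "false"; that regime
    is a power question, not an error-control one.)
    """
    rows = []
    for i in range(n_seeds):
        cfg = SimConfig(
            n_samples=200,
            n_chromosomes=5,
            markers_per_chromosome=200,
            ld_rho=0.95,
            block_size=20,
            h2_poly=0.0,
            seed=seed0 + i,
        )
        g, truth = simulate_structured_genotypes(cfg)
        pheno = simulate_trait(g, truth, cfg)
        row = {"seed": cfg.seed}
        for model in ("loco", "global"):
            table = run_gwas(
                GWASConfig(model=model, seed=cfg.seed), g, pheno, "trait"
            )
            rep = evaluate_power_fdr(table, truth, POWER_WINDOW_BP, FDR_LEVEL)
            row[f"fdp_{model}"] = rep.fdp
            row[f"n_sig_{model}"] = rep.n_significant
        rows.append(row)
    return pd.DataFrame(rows)


def bic_selection_rates(
    n_seeds: int = 10, seed0: int = 0, max_pcs: int = 5
) -> dict[str, int]:
    """How often BIC picks structure covariates when it should (and not
    when it should not).

    Returns counts over seeds: ``structured_ge1`` — structure-confounded
    trait (FST 0.3, strong subpopulation effect) gets >= 1 PC;
    ``unstructured_zero`` — panmictic trait with no structure effect gets 0.
    """
    counts = {"structured_ge1": 0, "unstructured_zero": 0}
    for i in range(n_seeds):
        cfg = SimConfig(
            n_samples=150, n_chromosomes=2, markers_per_chromosome=200,
            n_subpops=2, fst=0.3, structure_beta=2.0, seed=seed0 + i,
        )
        g, truth = simulate_structured_genotypes(cfg)
        y = simulate_trait(g, truth, cfg).frame["trait"].to_numpy()
        n_sel, _ = select_pcs_bic(
            y, pca_covariates(g, n_pcs=max_pcs), vanraden_kinship(g)
        )
        counts["structured_ge1"] += n_sel >= 1

        cfg0 = SimConfig(
            n_samples=150, n_chromosomes=2, markers_per_chromosome=200,
            seed=seed0 + 1000 + i,
        )
        g0, truth0 = simulate_structured_genotypes(cfg0)
        y0 = simulate_trait(g0, truth0, cfg0).frame["trait"].to_numpy()
        n_sel0, _ = select_pcs_bic(
            y0, pca_covariates(g0, n_pcs=max_pcs), vanraden_kinship(g0)
        )
        counts["unstructured_zero"] += n_sel0 == 0
    return counts


def heritability_recovery(n_seeds: int = 20, seed0: int = 0) -> np.ndarray:
    """Recover vg/(vg+ve) when the truth is VG = VE = 1 on a structured
    panel (the true ratio is 0.5); returns the per-seed estimates."""
    estimates = []
    for i in range(n_seeds):
        seed = seed0 + i
        rng = np.random.default_rng([seed, 17])
        cfg = SimConfig(
            n_samples=200, n_chromosomes=2, markers_per_chromosome=250,
            n_subpops=2, fst=0.2, seed=seed,
        )
        g, _ = simulate_structured_genotypes(cfg)
        k = vanraden_kinship(g)
        lam, vec = np.linalg.eigh(2.0 * k.values)
        u = vec @ (np.sqrt(np.clip(lam, 0.0, None)) * rng.standard_normal(200))
        y = 1.0 + u + rng.standard_normal(200)
        fit = reml_fit(y, np.ones((200, 1)), k)
        estimates.append(fit.variance.vg / (fit.variance.vg + fit.variance.ve))
    return np.asarray(estimates)
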