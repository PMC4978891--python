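"""Full GWAS orchestration: QC, correction-set construction, per-chromosome
null fits, P3D scans and genome-wide FDR control.

Two models are supported per trait:

* ``global`` — the traditional unified MLM: one kinship matrix and one
  covariate set computed from all markers, one null fit, one scan.
* ``loco`` — leave-one-chromosome-out: markers on chromosome ``c`` are
  tested against kinship and covariates computed from all *other*
  chromosomes, with their own null fit; rows are concatenated genome-wide
  and Benjamini-Hochberg FDR is applied afterward across the genome.

Named presets capture the two diversity-panel recipes this package was
built around: ``goodman`` (Loiselle kinship from all markers, PCs chosen by
BIC, major-allele imputation, FDR at 5 and 10%) and ``ncrpis`` (VanRaden
kinship from a random 10% marker subsample, 5 PCs or 6 kinship
eigenvectors, heterozygote imputation, compressed MLM, FDR at 5%).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import io as gio
from .io import GenotypeMatrix, PhenotypeTable
from .kinship import (
    CovariateMatrix,
    KinshipMatrix,
    KINSHIP_ESTIMATORS,
    loco_partition,
    pca_covariates,
    kinship_eigenvectors,
    subsample_markers,
)
from .mlm import (
    NullModelFit,
    expand_group_kinship,
    optimize_compression,
    p3d_scan,
    reml_fit,
    select_pcs_bic,
)

__all__ = [
    "GWASConfig",
    "AssociationTable",
    "run_gwas",
    "bh_adjust",
    "declare_significant",
]


@dataclass
class GWASConfig:
    """All knobs of one GWAS run; see module docstring for the presets."""

    model: str = "loco"  # loco | global  ("kchr" accepted as alias of loco)
    kinship_method: str = "vanraden"  # vanraden | loiselle
    covariate_source: str = "none"  # pca | kinship_eigen | none
    n_covariates: int | str = 0  # integer, or "bic" for BIC selection
    max_bic_pcs: int = 10
    impute_mode: str = "major_allele"  # major_allele | heterozygote
    maf_min: float = 0.05
    maf_after_align: bool = True  # apply the MAF filter per-trait, post-alignment
    kinship_fraction: float = 1.0
    compression: bool = False
    compression_grid: list[int] | None = None
    fdr_levels: tuple[float, ...] = (0.05,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model == "kchr":
            self.model = "loco"
        if self.model not in ("loco", "global"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.kinship_method not in KINSHIP_ESTIMATORS:
            raise ValueError(f"unknown kinship method {self.kinship_method!r}")
        if not all(0.0 < q < 1.0 for q in self.fdr_levels):
            raise ValueError("FDR levels must lie in (0, 1)")

    @classmethod
    def goodman(cls, model: str = "loco", **overrides) -> "GWASConfig":
        """Small-panel recipe: Loiselle kinship, BIC-selected PCs,
        major-allele imputation, all markers for kinship, FDR 5 and 10%."""
        base = dict(
            model=model,
            kinship_method="loiselle",
            covariate_source="pca",
            n_covariates="bic",
            impute_mode="major_allele",
            kinship_fraction=1.0,
            fdr_levels=(0.05, 0.10),
            compression=False,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def ncrpis(cls, model: str = "loco", eigen_covariates: bool = False,
               **overrides) -> "GWASConfig":
        """Large-panel recipe: VanRaden kinship from a 10% marker subsample,
        5 PCs (or 6 kinship eigenvectors), heterozygote imputation,
        compressed MLM, FDR 5%."""
        base = dict(
            model=model,
            kinship_method="vanraden",
            covariate_source="kinship_eigen" if eigen_covariates else "pca",
            n_covariates=6 if eigen_covariates else 5,
            impute_mode="heterozygote",
            kinship_fraction=0.10,
            fdr_levels=(0.05,),
            compression=True,
        )
        base.update(overrides)
        return cls(**base)

    def digest(self) -> str:
        payload = asdict(self)
        payload["fdr_levels"] = list(self.fdr_levels)
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


@dataclass
class AssociationTable:
    """Per-marker association results plus run metadata."""

    frame: pd.DataFrame
    trait: str = ""
    model: str = ""
    config_digest: str = ""
    n_samples: int = 0
    n_markers: int = 0
    metadata: dict = field(default_factory=dict)

    def sorted(self) -> pd.DataFrame:
        return self.frame.sort_values(
            ["chromosome", "position"], kind="mergesort", na_position="last"
        ).reset_index(drop=True)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    NA entries are skipped and returned as NA; adjusted values are capped at
    1 and restored to the input order.
    """
    p = np.asarray(pvalues, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum() == 0:
        return out
    _, adj, _, _ = multipletests(p[ok], method="fdr_bh")
    out[ok] = adj
    return out


def declare_significant(table: AssociationTable, level: float) -> AssociationTable:
    """Rows with FDR-adjusted p <= level (boundary inclusive)."""
    frame = table.frame
    keep = frame["fdr_adjusted_p"] <= level
    return AssociationTable(
        frame=frame[keep.fillna(False)].reset_index(drop=True),
        trait=table.trait,
        model=table.model,
        config_digest=table.config_digest,
        n_samples=table.n_samples,
        n_markers=table.n_markers,
        metadata={**table.metadata, "fdr_level": level},
    )


def _resolve_covariates(
    config: GWASConfig,
    y: np.ndarray,
    k: KinshipMatrix,
    q_full: CovariateMatrix,
) -> CovariateMatrix:
    """Apply BIC selection when requested, else take the configured count."""
    if config.n_covariates == "bic":
        n_sel, _ = select_pcs_bic(y, q_full, k)
        return q_full.truncated(n_sel)
    return q_full


def _null_fit(config: GWASConfig, y: np.ndarray, x0: CovariateMatrix,
              k: KinshipMatrix) -> NullModelFit:
    if config.compression:
        plan = optimize_compression(y, x0, k, group_grid=config.compression_grid)
        a = expand_group_kinship(plan, k.samples)
        fit = reml_fit(y, x0, a)
        fit.n_groups = plan.n_groups
        return fit
    return reml_fit(y, x0, k)


def run_gwas(
    config: GWASConfig,
    genotypes: GenotypeMatrix,
    phenotypes: PhenotypeTable,
    trait: str,
) -> AssociationTable:
    """Run one trait through QC, model fitting and the genome-wide scan.

    QC order: restrict to the trait's phenotyped samples, drop unanchored
    markers, apply the MAF filter, impute.  In ``loco`` mode variance
    components are re-estimated per chromosome (the kinship changes with the
    excluded chromosome); FDR adjustment always pools the genome.
    """
    g, y_series = gio.align_samples(genotypes, phenotypes, trait)
    if config.maf_after_align:
        g = gio.filter_markers(g, config.maf_min, require_anchored=True)
    else:
        g = gio.filter_markers(genotypes, config.maf_min, require_anchored=True)
        g, y_series = gio.align_samples(g, phenotypes, trait)
    g = gio.impute_missing(g, config.impute_mode)
    y = y_series.to_numpy(dtype=np.float64)
    if not g.chromosomes:
        raise ValueError("no anchored chromosomes left after QC")

    marker_chrom = np.array([rec.chromosome for rec in g.markers])
    # covariate count to precompute: BIC selection needs the maximal set
    n_cov = (
        config.max_bic_pcs if config.n_covariates == "bic" else int(config.n_covariates)
    )

    if config.model == "global":
        idx = np.arange(g.n_markers)
        if config.kinship_fraction < 1.0:
            idx = subsample_markers(
                g, config.kinship_fraction, seed=[config.seed, 0]
            )
        k = KINSHIP_ESTIMATORS[config.kinship_method](g, idx)
        if config.covariate_source == "pca":
            q_full = pca_covariates(g, idx, n_cov)
        elif config.covariate_source == "kinship_eigen":
            q_full = kinship_eigenvectors(k, n_cov)
        else:
            q_full = pca_covariates(g, idx, 0)
        x0 = _resolve_covariates(config, y, k, q_full)
        fit = _null_fit(config, y, x0, k)
        frame = p3d_scan(y, x0, g, fit)
    else:
        loco = loco_partition(
            g,
            kinship_method=config.kinship_method,
            covariate_source=config.covariate_source,
            n_covariates=n_cov,
            fraction=config.kinship_fraction,
            seed=config.seed,
        )
        pieces = []
        for chrom, (k, q_full) in loco.entries.items():
            x0 = _resolve_covariates(config, y, k, q_full)
            fit = _null_fit(config, y, x0, k)
            idx_c = np.flatnonzero(marker_chrom == chrom)
            pieces.append(p3d_scan(y, x0, g, fit, marker_index=idx_c))
        frame = pd.concat(pieces, ignore_index=True)

    frame["fdr_adjusted_p"] = bh_adjust(frame["pvalue"].to_numpy())
    frame = frame[
        [
            "marker", "chromosome", "position", "maf", "effect", "se",
            "fstat", "pvalue", "fdr_adjusted_p", "r2_lr", "na_reason",
        ]
    ]
    frame = frame.sort_values(
        ["chromosome", "position"], kind="mergesort"
    ).reset_index(drop=True)
    return AssociationTable(
        frame=frame,
        trait=trait,
        model=config.model,
        config_digest=config.digest(),
        n_samples=g.n_samples,
        n_markers=g.n_markers,
        metadata={"fdr_levels": list(config.fdr_levels), "seed": config.seed},
    )
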