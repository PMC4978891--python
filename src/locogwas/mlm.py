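"""Mixed-linear-model engine: REML variance components, P3D marker tests,
kinship compression, BIC covariate selection and the likelihood-ratio R².

Model
-----
For one trait the null (no-marker) model is

    y = X v + u + e,   u ~ N(0, VG * 2K),   e ~ N(0, VE * I)

with X an intercept-plus-structure-covariate design and K a kinship matrix.
Writing A = 2K and delta = VE / VG, the covariance is VG * (A + delta I).
Because A + delta I shares the eigenvectors U of A for every delta, a single
eigendecomposition of A turns every likelihood evaluation into a weighted
least-squares problem in the rotated coordinates (U'y, U'X) — the classic
spectral (EMMA-style) trick.  REML maximizes the restricted likelihood over
delta by a log-grid profile followed by local refinement; VG is profiled out
in closed form.

Per-marker tests use P3D ("population parameters previously determined"):
the variance-component *ratio* is estimated once under the null and held
fixed, and each marker is tested by a generalized-least-squares F test with
1 numerator and n - rank(X) - 1 denominator degrees of freedom, with the
residual scale re-estimated per marker.  When VG = 0 this reduces exactly to
the ordinary-least-squares F test.

Compressed mode clusters individuals into groups that share a random effect;
the grouped kinship is the average of individual kinship over group pairs,
and is expanded back to sample level so the same spectral machinery applies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from .io import GenotypeMatrix
from .kinship import CovariateMatrix, KinshipMatrix

__all__ = [
    "VarianceComponents",
    "NullModelFit",
    "CompressionPlan",
    "ZeroVarianceError",
    "reml_fit",
    "p3d_scan",
    "compress_kinship",
    "expand_group_kinship",
    "optimize_compression",
    "select_pcs_bic",
    "r2_lr",
]

DELTA_BOUNDS = (1e-5, 1e5)
DELTA_GRID_POINTS = 101
EIGENVALUE_CLIP = -1e-8
LOG2PI = np.log(2.0 * np.pi)


class ZeroVarianceError(ValueError):
    """The trait carries no variance after projecting out the fixed effects."""


@dataclass
class VarianceComponents:
    vg: float
    ve: float
    delta: float  # VE / VG
    reml_loglik: float
    ml_loglik: float
    boundary: bool = False  # optimum pinned at the delta search bounds


@dataclass
class NullModelFit:
    """Null-model REML fit plus the eigen-rotation cache used by the scan."""

    variance: VarianceComponents
    fixed_effects: np.ndarray
    samples: list[str]
    # eigen cache
    eigenvalues: np.ndarray          # of A = 2K, ascending, clipped at 0
    eigenvectors: np.ndarray         # U, columns matching eigenvalues
    rotated_y: np.ndarray            # U'y
    rotated_x: np.ndarray            # U'X
    n_groups: int | None = None      # set when fitted on compressed kinship

    @property
    def n(self) -> int:
        return self.rotated_y.shape[0]

    @property
    def rank_x(self) -> int:
        return self.rotated_x.shape[1]


@dataclass
class CompressionPlan:
    group_map: dict[str, int]
    n_groups: int
    grouped_kinship: KinshipMatrix
    criterion_loglik: float | None = None
    flagged: bool = False
    audit: list[tuple[int, float]] = field(default_factory=list)


def _profile(delta: float, lam: np.ndarray, yt: np.ndarray, xt: np.ndarray,
             logdet_xtx: float) -> tuple[float, float, float, float, np.ndarray]:
    """Profiled restricted and full log-likelihoods at a fixed delta.

    Returns (reml_loglik, ml_loglik, vg_reml, rss, beta).
    """
    n, q = xt.shape
    w = 1.0 / (lam + delta)
    sw = np.sqrt(w)
    xw = xt * sw[:, None]
    yw = yt * sw
    xtwx = xw.T @ xw
    beta = np.linalg.solve(xtwx, xw.T @ yw)
    resid = yw - xw @ beta
    rss = float(resid @ resid)
    if rss <= 0.0:
        raise ZeroVarianceError("trait has zero residual variance under the model")
    logdet_v_shape = float(np.sum(np.log(lam + delta)))
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^{-1}X not positive definite")
    vg_reml = rss / (n - q)
    reml = -0.5 * (
        (n - q) * (LOG2PI + np.log(vg_reml) + 1.0)
        + logdet_v_shape
        + logdet_xtwx
        - logdet_xtx
    )
    vg_ml = rss / n
    ml = -0.5 * (n * (LOG2PI + np.log(vg_ml) + 1.0) + logdet_v_shape)
    return reml, ml, vg_reml, rss, beta


def reml_fit(
    y,
    x: CovariateMatrix | np.ndarray,
    k: KinshipMatrix | np.ndarray,
    delta_bounds: tuple[float, float] = DELTA_BOUNDS,
    n_grid: int = DELTA_GRID_POINTS,
) -> NullModelFit:
    """REML fit of the null mixed model by spectral profiling of delta.

    The variance ratio delta = VE/VG is profiled on a log-spaced grid over
    ``delta_bounds`` and refined locally to 1e-8 in log delta.  Optima pinned
    at the bounds (VG -> 0 or VE -> 0) are returned with ``boundary=True``.
    The full (ML) log-likelihood at the REML-estimated ratio is also
    returned, for BIC and likelihood-ratio R² computations.
    """
    samples = x.samples if isinstance(x, CovariateMatrix) else None
    xmat = x.values if isinstance(x, CovariateMatrix) else np.asarray(x, float)
    kmat = k.values if isinstance(k, KinshipMatrix) else np.asarray(k, float)
    y = np.asarray(y, dtype=np.float64)
    n, q = xmat.shape
    if np.linalg.matrix_rank(xmat) < q:
        raise np.linalg.LinAlgError("singular fixed-effect design")
    if n < q + 2:
        raise ValueError(f"need at least rank(X)+2 = {q + 2} samples, got {n}")
    if np.ptp(y) == 0.0:
        raise ZeroVarianceError("trait is constant")

    a = 2.0 * kmat
    lam, u = np.linalg.eigh((a + a.T) / 2.0)
    if lam.min() < 100 * EIGENVALUE_CLIP:
        warnings.warn(
            "kinship has noticeably negative eigenvalues "
            f"(min {lam.min():.3g}); clipping to 0", RuntimeWarning,
        )
    lam = np.clip(lam, 0.0, None)
    yt = u.T @ y
    xt = u.T @ xmat
    sign, logdet_xtx = np.linalg.slogdet(xmat.T @ xmat)

    lo, hi = np.log(delta_bounds[0]), np.log(delta_bounds[1])
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array(
        [_profile(np.exp(ld), lam, yt, xt, logdet_xtx)[0] for ld in grid]
    )
    best = int(np.argmax(vals))
    bl = grid[max(best - 1, 0)]
    bh = grid[min(best + 1, n_grid - 1)]
    res = minimize_scalar(
        lambda ld: -_profile(np.exp(ld), lam, yt, xt, logdet_xtx)[0],
        bounds=(bl, bh),
        method="bounded",
        options={"xatol": 1e-8},
    )
    log_delta = float(res.x) if -res.fun >= vals[best] else float(grid[best])
    delta = float(np.exp(log_delta))
    reml, ml, vg, rss, beta = _profile(delta, lam, yt, xt, logdet_xtx)
    boundary = log_delta <= lo + 1e-6 or log_delta >= hi - 1e-6
    variance = VarianceComponents(
        vg=vg, ve=vg * delta, delta=delta,
        reml_loglik=reml, ml_loglik=ml, boundary=boundary,
    )
    return NullModelFit(
        variance=variance,
        fixed_effects=beta,
        samples=list(samples) if samples is not None else [str(i) for i in range(n)],
        eigenvalues=lam,
        eigenvectors=u,
        rotated_y=yt,
        rotated_x=xt,
    )


#: reason codes for untestable markers
NA_MONOMORPHIC = "monomorphic"
NA_COLLINEAR = "collinear_with_covariates"


def p3d_scan(
    y,
    x0: CovariateMatrix,
    g: GenotypeMatrix,
    fit: NullModelFit,
    marker_index=None,
) -> pd.DataFrame:
    """Per-marker GLS F tests with variance parameters fixed at the null fit.

    Each marker's dosage column is appended to the null design; the test has
    1 numerator and n - rank(X0) - 1 denominator degrees of freedom.  Effects
    and standard errors are on the minor-allele-dosage scale.  Markers that
    are monomorphic in the analyzed sample, or collinear with the covariates,
    yield all-NA rows with a reason code.
    """
    if marker_index is None:
        marker_index = np.arange(g.n_markers)
    marker_index = np.asarray(marker_index, dtype=int)
    y = np.asarray(y, dtype=np.float64)
    s = g.dosage[:, marker_index]
    if np.isnan(s).any():
        raise ValueError("markers must be imputed before scanning")

    n, q = fit.n, fit.rank_x
    df2 = n - q - 1
    if df2 < 1:
        raise ValueError("no residual degrees of freedom for the marker test")
    w = 1.0 / (fit.eigenvalues + fit.variance.delta)
    sw = np.sqrt(w)
    xw = fit.rotated_x * sw[:, None]
    yw = fit.rotated_y * sw
    st = fit.eigenvectors.T @ s
    swm = st * sw[:, None]

    qmat, _ = np.linalg.qr(xw)
    r_y = yw - qmat @ (qmat.T @ yw)
    r_s = swm - qmat @ (qmat.T @ swm)
    ss = np.einsum("ij,ij->j", r_s, r_s)
    cross = r_s.T @ r_y
    rss0 = float(r_y @ r_y)

    col_norm2 = np.einsum("ij,ij->j", swm, swm)
    mono = s.std(axis=0) == 0.0
    collinear = ~mono & (ss <= 1e-10 * np.maximum(col_norm2, 1e-300))
    testable = ~(mono | collinear)

    effect = np.full(ss.shape, np.nan)
    se = np.full(ss.shape, np.nan)
    fstat = np.full(ss.shape, np.nan)
    pval = np.full(ss.shape, np.nan)
    r2 = np.full(ss.shape, np.nan)

    t = testable
    effect[t] = cross[t] / ss[t]
    explained = np.zeros_like(ss)
    explained[t] = cross[t] ** 2 / ss[t]
    rss = rss0 - explained
    sigma2 = rss / df2
    se[t] = np.sqrt(sigma2[t] / ss[t])
    fstat[t] = explained[t] / sigma2[t]
    pval[t] = stats.f.sf(fstat[t], 1, df2)
    # likelihood-ratio R^2 of marker vs null at the fixed variance ratio
    r2[t] = np.clip(1.0 - rss[t] / rss0, 0.0, np.nextafter(1.0, 0.0))

    maf = s.mean(axis=0) / 2.0
    maf = np.minimum(maf, 1.0 - maf)
    reason = np.where(mono, NA_MONOMORPHIC, np.where(collinear, NA_COLLINEAR, ""))
    recs = [g.markers[i] for i in marker_index]
    return pd.DataFrame(
        {
            "marker": [r.id for r in recs],
            "chromosome": [r.chromosome for r in recs],
            "position": [r.position for r in recs],
            "maf": maf,
            "effect": effect,
            "se": se,
            "fstat": fstat,
            "pvalue": pval,
            "r2_lr": r2,
            "na_reason": reason,
        }
    )


def compress_kinship(k: KinshipMatrix, n_groups: int) -> CompressionPlan:
    """Cluster individuals for the compressed mixed model.

    Average-linkage hierarchical clustering on the dissimilarity
    ``d_il = max(K) - K_il`` cut at ``n_groups``; the grouped kinship entry
    (a, b) is the mean of K over pairs i in a, l in b.
    """
    n = k.n_samples
    if not 1 <= n_groups <= n:
        raise ValueError(f"n_groups must be in [1, {n}]")
    if n_groups == n:
        labels = np.arange(n)
    elif n_groups == 1:
        labels = np.zeros(n, dtype=int)
    else:
        d = k.values.max() - k.values
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="average")
        labels = fcluster(z, t=n_groups, criterion="maxclust") - 1
    actual = len(np.unique(labels))
    # relabel 0..actual-1 in order of first appearance for determinism
    remap: dict[int, int] = {}
    for lab in labels:
        remap.setdefault(int(lab), len(remap))
    labels = np.array([remap[int(lab)] for lab in labels])
    grouped = np.zeros((actual, actual))
    for a in range(actual):
        ia = labels == a
        for b in range(a, actual):
            ib = labels == b
            grouped[a, b] = grouped[b, a] = k.values[np.ix_(ia, ib)].mean()
    gk = KinshipMatrix(
        samples=[f"group{a}" for a in range(actual)],
        values=grouped,
        method=k.method,
        excluded_chromosome=k.excluded_chromosome,
        marker_count=k.marker_count,
    )
    return CompressionPlan(
        group_map={s: int(lab) for s, lab in zip(k.samples, labels)},
        n_groups=actual,
        grouped_kinship=gk,
        flagged=actual == 1,  # VG confounded with the intercept
    )


def expand_group_kinship(plan: CompressionPlan, samples: list[str]) -> np.ndarray:
    """Sample-level covariance implied by the grouped kinship (Z Kg Z')."""
    labels = np.array([plan.group_map[s] for s in samples])
    return plan.grouped_kinship.values[np.ix_(labels, labels)]


def optimize_compression(
    y,
    x0: CovariateMatrix,
    k: KinshipMatrix,
    group_grid=None,
) -> CompressionPlan:
    """Pick the compression level maximizing the null REML log-likelihood.

    Default grid: ~10 geometrically spaced group counts from 1 to n.  Ties
    break toward fewer groups.  All evaluated (n_groups, loglik) pairs are
    kept in the returned plan's ``audit``.
    """
    n = k.n_samples
    if group_grid is None:
        group_grid = np.unique(
            np.round(np.geomspace(1, n, num=min(10, n))).astype(int)
        )
    audit: list[tuple[int, float]] = []
    best_plan: CompressionPlan | None = None
    best_ll = -np.inf
    for t in sorted(int(t) for t in group_grid):
        plan = compress_kinship(k, t)
        a = expand_group_kinship(plan, k.samples)
        fit = reml_fit(y, x0, a)
        ll = fit.variance.reml_loglik
        plan.criterion_loglik = ll
        audit.append((plan.n_groups, ll))
        if ll > best_ll + 1e-9:  # strict improvement; ties keep fewer groups
            best_ll, best_plan = ll, plan
    assert best_plan is not None
    best_plan.audit = audit
    return best_plan


def select_pcs_bic(
    y,
    covariate_candidates: CovariateMatrix,
    k: KinshipMatrix,
    max_pcs: int | None = None,
) -> tuple[int, pd.DataFrame]:
    """Choose the number of structure covariates by BIC over nested models.

    ``covariate_candidates`` holds the intercept plus the maximal set of
    ordered components; candidate ``j`` uses the first ``j`` of them.
    BIC = -2 * ML log-likelihood + (#fixed effects + 2) * ln(n), the +2
    counting the two variance components.  ML (not REML) likelihoods are
    used because restricted likelihoods are not comparable across different
    fixed-effect structures.  Ties break toward fewer covariates.
    """
    if max_pcs is None:
        max_pcs = covariate_candidates.n_covariates
    if max_pcs > covariate_candidates.n_covariates:
        raise ValueError("max_pcs exceeds available candidate covariates")
    n = len(covariate_candidates.samples)
    rows = []
    for j in range(max_pcs + 1):
        xj = covariate_candidates.truncated(j)
        fit = reml_fit(y, xj, k)
        n_fixed = xj.values.shape[1]
        bic = -2.0 * fit.variance.ml_loglik + (n_fixed + 2) * np.log(n)
        rows.append((j, fit.variance.ml_loglik, bic))
    table = pd.DataFrame(rows, columns=["n_pcs", "ml_loglik", "bic"])
    best = int(table.loc[table["bic"].idxmin(), "n_pcs"])  # idxmin: first = fewest
    return best, table


def r2_lr(ml_loglik_full: float, ml_loglik_null: float, n: int) -> float:
    """Likelihood-ratio R²: 1 - exp(-(2/n)(LL_full - LL_null)), in [0, 1)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if ml_loglik_full < ml_loglik_null - 1e-8:
        raise ValueError("full-model log-likelihood below null log-likelihood")
    val = 1.0 - np.exp(-(2.0 / n) * (ml_loglik_full - ml_loglik_null))
    return float(np.clip(val, 0.0, np.nextafter(1.0, 0.0)))
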