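"""Kinship estimation and population-structure covariates.

Two marker-based relatedness estimators are provided:

* VanRaden: the normalized centered cross-product
  ``K = Z Z' / (2 sum_j p_j (1 - p_j))`` with ``Z = X - 2p`` the
  column-centered dosage matrix.
* Loiselle: the allele-frequency covariance estimator with an ``(n - 1)``
  small-sample correction, in its biallelic single-allele form; negative
  off-diagonal estimates are truncated to zero (the diagonal is left as is).

:func:`loco_partition` builds the leave-one-chromosome-out (LOCO) set: for
each chromosome ``c`` a kinship matrix and structure-covariate matrix are
computed from markers *not* on ``c``, so the tested signal on ``c`` cannot be
absorbed into the correction terms (proximal contamination).  A global
(all-marker) pair is included alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "CovariateMatrix",
    "LOCOSet",
    "vanraden_kinship",
    "loiselle_kinship",
    "subsample_markers",
    "pca_covariates",
    "kinship_eigenvectors",
    "loco_partition",
    "write_kinship_csv",
    "read_kinship_csv",
]

SYMMETRY_TOL = 1e-10


@dataclass
class KinshipMatrix:
    """n x n symmetric relatedness estimate tagged with its provenance."""

    samples: list[str]
    values: np.ndarray
    method: str
    excluded_chromosome: str | None = None
    marker_count: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.samples)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match sample count")
        if not np.isfinite(self.values).all():
            raise ValueError("kinship contains non-finite entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > SYMMETRY_TOL:
            raise ValueError("kinship is not symmetric")
        self.values = (self.values + self.values.T) / 2.0

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class CovariateMatrix:
    """Fixed-effect design: an intercept column plus structure covariates."""

    samples: list[str]
    values: np.ndarray
    source: str  # pca | kinship_eigen | none
    excluded_chromosome: str | None = None
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.samples):
            raise ValueError("covariate shape does not match sample count")
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        if not self.names:
            self.names = ["intercept"] + [
                f"cov{i}" for i in range(1, self.values.shape[1])
            ]

    @property
    def n_covariates(self) -> int:
        """Structure covariates, excluding the intercept."""
        return self.values.shape[1] - 1

    def truncated(self, n_covariates: int) -> "CovariateMatrix":
        """Keep the intercept plus the first ``n_covariates`` columns."""
        if n_covariates > self.n_covariates:
            raise ValueError("cannot truncate to more covariates than present")
        return CovariateMatrix(
            samples=list(self.samples),
            values=self.values[:, : n_covariates + 1].copy(),
            source=self.source if n_covariates > 0 else "none",
            excluded_chromosome=self.excluded_chromosome,
            names=self.names[: n_covariates + 1],
        )


@dataclass
class LOCOSet:
    """Per-chromosome (kinship, covariates) pairs plus the global pair."""

    entries: dict[str, tuple[KinshipMatrix, CovariateMatrix]]
    global_entry: tuple[KinshipMatrix, CovariateMatrix]

    def __post_init__(self) -> None:
        for chrom, (k, q) in self.entries.items():
            if k.excluded_chromosome != chrom or q.excluded_chromosome != chrom:
                raise ValueError(
                    f"LOCO entry for chromosome {chrom} is tagged "
                    f"{k.excluded_chromosome!r}/{q.excluded_chromosome!r}"
                )

    def __len__(self) -> int:
        return len(self.entries) + 1


def _imputed_dosage(g: GenotypeMatrix, marker_index) -> tuple[np.ndarray, np.ndarray]:
    if marker_index is None:
        marker_index = np.arange(g.n_markers)
    marker_index = np.asarray(marker_index, dtype=int)
    if marker_index.size == 0:
        raise ValueError("empty marker index")
    x = g.dosage[:, marker_index]
    if np.isnan(x).any():
        raise ValueError("genotypes must be imputed before kinship/PCA")
    return x, marker_index


def vanraden_kinship(g: GenotypeMatrix, marker_index=None) -> KinshipMatrix:
    """Genomic relationship matrix from the centered dosage cross-product.

    Allele frequencies are computed from the same marker subset used for the
    cross-products, so the estimate is internally consistent when the index
    is a random subsample.  Monomorphic markers are dropped from the index.
    """
    x, marker_index = _imputed_dosage(g, marker_index)
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all selected markers are monomorphic")
    x, p = x[:, poly], p[poly]
    z = x - 2.0 * p
    denom = 2.0 * np.sum(p * (1.0 - p))
    k = (z @ z.T) / denom
    return KinshipMatrix(
        samples=list(g.samples),
        values=(k + k.T) / 2.0,
        method="vanraden",
        marker_count=int(poly.sum()),
    )


def loiselle_kinship(g: GenotypeMatrix, marker_index=None) -> KinshipMatrix:
    """Loiselle coancestry estimate (biallelic form, (n-1) bias correction).

    ``f_il = [sum_j (y_ij - p_j)(y_lj - p_j) + sum_j p_j(1-p_j)/(n-1)]
    / sum_j p_j(1-p_j)`` with ``y = dosage / 2``.  Negative off-diagonal
    estimates are truncated to 0; the diagonal is left untruncated.
    """
    x, marker_index = _imputed_dosage(g, marker_index)
    n = x.shape[0]
    if n <= 1:
        raise ValueError("Loiselle kinship needs at least two individuals")
    y = x / 2.0
    p = y.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all selected markers are monomorphic")
    y, p = y[:, poly], p[poly]
    pq = p * (1.0 - p)
    denom = pq.sum()
    centered = y - p
    bias = pq.sum() / (n - 1)
    f = (centered @ centered.T + bias) / denom
    off = ~np.eye(n, dtype=bool)
    f[off & (f < 0)] = 0.0
    return KinshipMatrix(
        samples=list(g.samples),
        values=(f + f.T) / 2.0,
        method="loiselle",
        marker_count=int(poly.sum()),
    )


KINSHIP_ESTIMATORS = {"vanraden": vanraden_kinship, "loiselle": loiselle_kinship}


def subsample_markers(g: GenotypeMatrix, fraction: float, seed) -> np.ndarray:
    """Uniform sample without replacement of round(fraction * m) markers.

    Deterministic given the seed; the returned index is sorted so marker
    order is preserved downstream.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    m = g.n_markers
    size = int(round(fraction * m))
    if size == 0:
        raise ValueError(f"fraction {fraction} of {m} markers selects none")
    if size == m:
        return np.arange(m)
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(m, size=size, replace=False))


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Force the largest-magnitude loading of each column positive (stable
    sign convention across platforms)."""
    for j in range(vectors.shape[1]):
        i = np.argmax(np.abs(vectors[:, j]))
        if vectors[i, j] < 0:
            vectors[:, j] = -vectors[:, j]
    return vectors


def pca_covariates(
    g: GenotypeMatrix, marker_index=None, n_pcs: int = 0
) -> CovariateMatrix:
    """Principal components of the column-standardized dosage matrix
    (center ``2p``, scale ``sqrt(2p(1-p))``), prepended with an intercept."""
    if n_pcs < 0:
        raise ValueError("n_pcs must be non-negative")
    x, marker_index = _imputed_dosage(g, marker_index)
    n = x.shape[0]
    if n_pcs >= n:
        raise ValueError(f"n_pcs={n_pcs} must be < n_samples={n}")
    if n_pcs == 0:
        return CovariateMatrix(
            samples=list(g.samples), values=np.ones((n, 1)), source="none"
        )
    p = x.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    x, p = x[:, poly], p[poly]
    xs = (x - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    # left singular vectors via the n x n Gram matrix (m can be large)
    gram = xs @ xs.T
    w, v = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1][:n_pcs]
    pcs = _fix_signs(v[:, order])
    return CovariateMatrix(
        samples=list(g.samples),
        values=np.column_stack([np.ones(n), pcs]),
        source="pca",
        names=["intercept"] + [f"PC{i + 1}" for i in range(n_pcs)],
    )


def kinship_eigenvectors(k: KinshipMatrix, n_vec: int) -> CovariateMatrix:
    """Top eigenvectors of the kinship matrix as structure covariates."""
    n = k.n_samples
    if not 0 <= n_vec < n:
        raise ValueError(f"n_vec={n_vec} must be in [0, {n})")
    if n_vec == 0:
        return CovariateMatrix(
            samples=list(k.samples),
            values=np.ones((n, 1)),
            source="none",
            excluded_chromosome=k.excluded_chromosome,
        )
    w, v = np.linalg.eigh(k.values)
    order = np.argsort(w)[::-1][:n_vec]
    vecs = _fix_signs(v[:, order])
    return CovariateMatrix(
        samples=list(k.samples),
        values=np.column_stack([np.ones(n), vecs]),
        source="kinship_eigen",
        excluded_chromosome=k.excluded_chromosome,
        names=["intercept"] + [f"EV{i + 1}" for i in range(n_vec)],
    )


def _covariates_for(
    g: GenotypeMatrix,
    idx: np.ndarray,
    k: KinshipMatrix,
    covariate_source: str,
    n_covariates: int,
) -> CovariateMatrix:
    if covariate_source == "pca":
        q = pca_covariates(g, idx, n_covariates)
    elif covariate_source == "kinship_eigen":
        q = kinship_eigenvectors(k, n_covariates)
    elif covariate_source == "none":
        q = CovariateMatrix(
            samples=list(g.samples),
            values=np.ones((g.n_samples, 1)),
            source="none",
        )
    else:
        raise ValueError(f"unknown covariate source {covariate_source!r}")
    q.excluded_chromosome = k.excluded_chromosome
    return q


def loco_partition(
    g: GenotypeMatrix,
    kinship_method: str = "vanraden",
    covariate_source: str = "none",
    n_covariates: int = 0,
    fraction: float = 1.0,
    seed: int = 0,
) -> LOCOSet:
    """Build the full leave-one-chromosome-out correction set.

    For every chromosome ``c`` present in the marker map, kinship and
    covariates are computed from the (optionally subsampled) markers not on
    ``c``; the subsample is re-drawn per chromosome from the appropriate
    complement, deterministically in ``seed``.  A global pair computed from
    all markers is included alongside.
    """
    try:
        estimator = KINSHIP_ESTIMATORS[kinship_method]
    except KeyError:
        raise ValueError(f"unknown kinship method {kinship_method!r}") from None
    chroms = g.chromosomes
    if len(chroms) < 2:
        raise ValueError(
            "LOCO partition needs at least two chromosomes; with a single "
            "chromosome no markers remain for kinship"
        )
    marker_chrom = np.array(
        [rec.chromosome if rec.chromosome is not None else "" for rec in g.markers]
    )

    def build(mask: np.ndarray, excluded: str | None, stream: int):
        idx = np.flatnonzero(mask)
        if fraction < 1.0:
            sub = g.take_markers(idx)
            idx = idx[subsample_markers(sub, fraction, seed=[seed, stream])]
        k = estimator(g, idx)
        k.excluded_chromosome = excluded
        q = _covariates_for(g, idx, k, covariate_source, n_covariates)
        return k, q

    anchored = marker_chrom != ""
    entries = {
        chrom: build(anchored & (marker_chrom != chrom), chrom, stream=ci)
        for ci, chrom in enumerate(chroms)
    }
    global_entry = build(anchored, None, stream=len(chroms))
    return LOCOSet(entries=entries, global_entry=global_entry)


def write_kinship_csv(k: KinshipMatrix, path) -> None:
    """Square CSV with sample names on both axes; a leading comment line
    records method, excluded chromosome and marker count."""
    with open(path, "w") as fh:
        fh.write(
            f"# method={k.method} excluded_chromosome="
            f"{k.excluded_chromosome if k.excluded_chromosome is not None else 'none'} "
            f"marker_count={k.marker_count}\n"
        )
        pd.DataFrame(k.values, index=k.samples, columns=k.samples).to_csv(fh)


def read_kinship_csv(path) -> KinshipMatrix:
    with open(path) as fh:
        header = fh.readline()
        tags = dict(
            item.split("=", 1) for item in header.lstrip("# ").strip().split()
        )
        df = pd.read_csv(fh, index_col=0)
    excl = tags.get("excluded_chromosome", "none")
    return KinshipMatrix(
        samples=[str(s) for s in df.index],
        values=df.to_numpy(),
        method=tags.get("method", "unknown"),
        excluded_chromosome=None if excl == "none" else excl,
        marker_count=int(tags.get("marker_count", 0)),
    )
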