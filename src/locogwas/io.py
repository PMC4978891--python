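"""Genotype, phenotype and result file handling.

Genotypes live in a :class:`GenotypeMatrix`: samples x biallelic SNPs with
dosage counting copies of the *minor* allele (recomputed per marker from the
data, never taken from file metadata).  Marker QC follows the common
diversity-panel recipe: drop markers that are not anchored to a reference
position, drop markers below a minor-allele-frequency threshold, then impute
the remaining missing calls (major-allele or heterozygote fill).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerRecord",
    "GenotypeMatrix",
    "PhenotypeTable",
    "GenotypeFormatError",
    "read_hapmap",
    "write_hapmap",
    "read_vcf",
    "read_dosage_csv",
    "read_phenotypes",
    "compute_maf",
    "filter_markers",
    "impute_missing",
    "align_samples",
    "write_results",
    "read_results",
]

#: IUPAC single-letter heterozygote codes -> unordered allele pair.
IUPAC_HET = {
    "R": ("A", "G"),
    "Y": ("C", "T"),
    "S": ("C", "G"),
    "W": ("A", "T"),
    "K": ("G", "T"),
    "M": ("A", "C"),
}
_HET_OF_PAIR = {frozenset(v): k for k, v in IUPAC_HET.items()}

HAPMAP_COLUMNS = [
    "rs#", "alleles", "chrom", "pos", "strand", "assembly#",
    "center", "protLSID", "assayLSID", "panelLSID", "QCcode",
]


class GenotypeFormatError(ValueError):
    """Raised when a genotype file violates its format contract."""


@dataclass(frozen=True)
class MarkerRecord:
    """One biallelic SNP: identifier, map position and allele labels.

    ``ref_allele`` is the major allele and ``alt_allele`` the minor allele
    under this package's dosage coding.  ``chromosome`` is ``None`` for
    markers without a reference-anchored position.
    """

    id: str
    chromosome: str | None
    position: int | None
    ref_allele: str = "A"
    alt_allele: str = "G"

    def __post_init__(self) -> None:
        if self.chromosome is not None:
            if self.position is None or self.position < 1:
                raise ValueError(
                    f"marker {self.id}: anchored markers need a 1-based position"
                )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"marker {self.id}: alleles must be distinct")


@dataclass
class GenotypeMatrix:
    """Samples x markers minor-allele dosage matrix.

    ``dosage`` is float64 with values in {0, 1, 2} and ``nan`` for missing
    calls; ``missing_mask`` is derived from it.
    """

    samples: list[str]
    markers: list[MarkerRecord]
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.float64)
        n, m = self.dosage.shape
        if n != len(self.samples) or m != len(self.markers):
            raise ValueError("dosage shape does not match samples/markers")
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample names")
        ids = [rec.id for rec in self.markers]
        if len(set(ids)) != m:
            raise ValueError("duplicate marker ids")
        with np.errstate(invalid="ignore"):
            bad = ~np.isnan(self.dosage) & ~np.isin(self.dosage, (0.0, 1.0, 2.0))
        if bad.any():
            raise ValueError("dosage values must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    @property
    def marker_ids(self) -> list[str]:
        return [rec.id for rec in self.markers]

    @property
    def chromosomes(self) -> list[str]:
        """Distinct anchored chromosomes in marker order of first appearance."""
        seen: dict[str, None] = {}
        for rec in self.markers:
            if rec.chromosome is not None:
                seen.setdefault(rec.chromosome, None)
        return list(seen)

    def marker_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": [r.id for r in self.markers],
                "chromosome": [r.chromosome for r in self.markers],
                "position": [r.position for r in self.markers],
                "ref_allele": [r.ref_allele for r in self.markers],
                "alt_allele": [r.alt_allele for r in self.markers],
            }
        )

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=[self.markers[i] for i in index],
            dosage=self.dosage[:, index].copy(),
        )

    def take_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in index],
            markers=list(self.markers),
            dosage=self.dosage[index, :].copy(),
        )


@dataclass
class PhenotypeTable:
    """Per-sample trait values; one row per sample, missing allowed."""

    frame: pd.DataFrame  # index = sample names, columns = traits

    def __post_init__(self) -> None:
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValueError(f"duplicated sample names in phenotypes: {dups}")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    @property
    def traits(self) -> list[str]:
        return list(self.frame.columns)

    def trait_values(self, trait: str) -> pd.Series:
        if trait not in self.frame.columns:
            raise KeyError(
                f"trait {trait!r} not found; available: {list(self.frame.columns)}"
            )
        return self.frame[trait]


def _minor_allele_recode(
    counts: dict[str, float], alleles_meta: tuple[str, str], marker_id: str
) -> tuple[str, str]:
    """Return (major, minor) from observed allele counts.

    Falls back to file metadata when the calls carry no allele information
    (all-missing marker).  Ties break toward the lexicographically later
    allele being minor, so the coding is deterministic.
    """
    observed = {a: c for a, c in counts.items() if c > 0}
    if len(observed) > 2:
        raise GenotypeFormatError(
            f"marker {marker_id}: more than two alleles observed: {sorted(observed)}"
        )
    if len(observed) == 0:
        return alleles_meta
    if len(observed) == 1:
        a = next(iter(observed))
        other = alleles_meta[1] if alleles_meta[0] == a else alleles_meta[0]
        if other == a:
            other = "G" if a != "G" else "A"
        return a, other  # monomorphic: observed allele is major
    (a1, c1), (a2, c2) = sorted(observed.items())
    if c1 > c2 or (c1 == c2):  # tie -> later allele (a2) is minor
        return a1, a2
    return a2, a1


def read_hapmap(path) -> GenotypeMatrix:
    """Read a HapMap-format text file (11 metadata columns + one per taxon).

    Genotype calls are single-letter IUPAC codes ('N' = missing).  The minor
    allele of each marker is recomputed from the non-missing calls.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 12:
        raise GenotypeFormatError(
            f"HapMap file needs {len(HAPMAP_COLUMNS)} metadata columns plus taxa, "
            f"got {df.shape[1]} columns"
        )
    for i, expected in enumerate(HAPMAP_COLUMNS):
        got = df.columns[i].strip()
        # Panzea exports vary in the rs column label
        if i == 0 and got.lower() in ("rs", "rs#", "rs_id", "snpid"):
            continue
        if got.lower() != expected.lower():
            raise GenotypeFormatError(
                f"HapMap header column {i + 1} should be {expected!r}, got {got!r}"
            )
    taxa = list(df.columns[11:])
    ids = df.iloc[:, 0].tolist()
    if len(set(ids)) != len(ids):
        dup = pd.Series(ids)[pd.Series(ids).duplicated()].iloc[0]
        raise GenotypeFormatError(f"duplicate marker id {dup!r}")

    calls = df.iloc[:, 11:].to_numpy(dtype="U2")
    markers: list[MarkerRecord] = []
    dosage = np.full((len(taxa), len(ids)), np.nan)
    for j, mid in enumerate(ids):
        col = np.char.upper(np.char.strip(calls[j]))
        counts: dict[str, float] = {}
        for call in col:
            if call in ("N", "", "NN", "-"):
                continue
            if call in IUPAC_HET:
                a, b = IUPAC_HET[call]
                counts[a] = counts.get(a, 0) + 1
                counts[b] = counts.get(b, 0) + 1
            elif call in "ACGT":
                counts[call] = counts.get(call, 0) + 2
            else:
                raise GenotypeFormatError(
                    f"marker {mid}: unrecognized genotype call {call!r}"
                )
        meta = str(df.iloc[j, 1])
        parts = meta.split("/") if "/" in meta else ["A", "G"]
        meta_pair = (parts[0].strip().upper() or "A",
                     (parts[1].strip().upper() if len(parts) > 1 else "G") or "G")
        if meta_pair[0] == meta_pair[1]:
            meta_pair = ("A", "G")
        major, minor = _minor_allele_recode(counts, meta_pair, mid)
        chrom_raw = df.iloc[j, 2]
        pos_raw = df.iloc[j, 3]
        anchored = (
            pd.notna(chrom_raw)
            and str(chrom_raw).strip() not in ("", "NA", "0", "UNKNOWN", "un")
            and pd.notna(pos_raw)
        )
        markers.append(
            MarkerRecord(
                id=str(mid),
                chromosome=str(chrom_raw).strip() if anchored else None,
                position=int(float(pos_raw)) if anchored else None,
                ref_allele=major,
                alt_allele=minor,
            )
        )
        het = _HET_OF_PAIR.get(frozenset((major, minor)))
        for i, call in enumerate(col):
            if call in ("N", "", "NN", "-"):
                continue
            if call == major:
                dosage[i, j] = 0.0
            elif call == minor:
                dosage[i, j] = 2.0
            elif call == het:
                dosage[i, j] = 1.0
            else:
                raise GenotypeFormatError(
                    f"marker {mid}: call {call!r} inconsistent with alleles "
                    f"{major}/{minor}"
                )
    return GenotypeMatrix(samples=taxa, markers=markers, dosage=dosage)


def write_hapmap(g: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as single-letter-call HapMap text."""
    rows = []
    for j, rec in enumerate(g.markers):
        het = _HET_OF_PAIR.get(frozenset((rec.ref_allele, rec.alt_allele)))
        if het is None:
            raise GenotypeFormatError(
                f"marker {rec.id}: allele pair {rec.ref_allele}/{rec.alt_allele} "
                "has no IUPAC heterozygote code"
            )
        code = {0.0: rec.ref_allele, 1.0: het, 2.0: rec.alt_allele}
        calls = [
            "N" if np.isnan(d) else code[d] for d in g.dosage[:, j]
        ]
        rows.append(
            [
                rec.id,
                f"{rec.ref_allele}/{rec.alt_allele}",
                rec.chromosome if rec.chromosome is not None else "NA",
                rec.position if rec.position is not None else "NA",
                "+", "NA", "NA", "NA", "NA", "NA", "NA",
                *calls,
            ]
        )
    out = pd.DataFrame(rows, columns=HAPMAP_COLUMNS + list(g.samples))
    out.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> GenotypeMatrix:
    """Read biallelic SNP records from a VCF (GT field required).

    Multi-allelic and non-SNP records are skipped (count logged).  Dosage
    counts the minor allele recomputed from the sample, not the ALT allele.
    """
    from cyvcf2 import VCF  # optional dependency, only needed for VCF input

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers: list[MarkerRecord] = []
    cols: list[np.ndarray] = []
    skipped = 0
    seen_gt = False
    for rec in vcf:
        alts = rec.ALT
        if (
            len(alts) != 1
            or len(rec.REF) != 1
            or len(alts[0]) != 1
            or rec.REF not in "ACGT"
            or alts[0] not in "ACGT"
        ):
            skipped += 1
            continue
        gts = rec.genotypes
        if gts is None or len(gts) == 0:
            raise GenotypeFormatError("VCF record lacks a GT field")
        seen_gt = True
        gt = np.asarray([row[:2] for row in gts], dtype=float)
        alt_count = np.full(len(samples), np.nan)
        ok = (gt[:, 0] >= 0) & (gt[:, 1] >= 0)
        alt_count[ok] = gt[ok, 0] + gt[ok, 1]
        nonmiss = alt_count[~np.isnan(alt_count)]
        alt_freq = nonmiss.sum() / (2 * len(nonmiss)) if len(nonmiss) else 0.0
        if alt_freq > 0.5:  # ALT is the major allele: count REF instead
            major, minor = alts[0], rec.REF
            dos = np.where(np.isnan(alt_count), np.nan, 2.0 - alt_count)
        else:
            major, minor = rec.REF, alts[0]
            dos = alt_count
        mid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}_{rec.POS}"
        markers.append(
            MarkerRecord(
                id=mid,
                chromosome=str(rec.CHROM),
                position=int(rec.POS),
                ref_allele=major,
                alt_allele=minor,
            )
        )
        cols.append(dos)
    if not seen_gt and not markers:
        raise GenotypeFormatError("no usable GT records in VCF")
    if skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records", skipped)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    g = GenotypeMatrix(samples=samples, markers=markers, dosage=dosage)
    g.n_skipped_records = skipped  # type: ignore[attr-defined]
    return g


def read_dosage_csv(path, map_path) -> GenotypeMatrix:
    """Read numeric dosages (rows = samples, header = marker ids) plus a
    sidecar map file with columns marker/chromosome/position."""
    df = pd.read_csv(path, index_col=0)
    mp = pd.read_csv(map_path, sep=None, engine="python", dtype=str)
    mp = mp.set_index(mp.columns[0])
    markers = []
    for mid in df.columns:
        if mid in mp.index:
            chrom = mp.loc[mid].iloc[0]
            pos = int(float(mp.loc[mid].iloc[1]))
            anchored = pd.notna(chrom) and str(chrom) not in ("", "NA")
        else:
            anchored = False
        markers.append(
            MarkerRecord(
                id=str(mid),
                chromosome=str(chrom) if anchored else None,
                position=pos if anchored else None,
            )
        )
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        markers=markers,
        dosage=df.to_numpy(dtype=np.float64),
    )


def read_phenotypes(path, trait_names: list[str] | None = None) -> PhenotypeTable:
    """Read a delimited phenotype table; first column is the sample name.

    Unparsable cells become missing.  Requesting an absent trait raises with
    the list of available columns.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    df.index = df.index.astype(str)
    if trait_names is not None:
        missing = [t for t in trait_names if t not in df.columns]
        if missing:
            raise KeyError(
                f"traits {missing} not in file; available: {list(df.columns)}"
            )
        df = df[list(trait_names)]
    df = df.apply(pd.to_numeric, errors="coerce")
    return PhenotypeTable(frame=df)


def compute_maf(g: GenotypeMatrix) -> np.ndarray:
    """Per-marker minor-allele frequency min(f, 1-f) over non-missing calls.

    Markers with zero non-missing calls get ``nan``.
    """
    counts = np.sum(~np.isnan(g.dosage), axis=0)
    with np.errstate(invalid="ignore"):
        f = np.where(counts > 0, np.nansum(g.dosage, axis=0), np.nan) / (
            2.0 * np.where(counts > 0, counts, 1)
        )
    return np.minimum(f, 1.0 - f)


def filter_markers(
    g: GenotypeMatrix, maf_min: float = 0.05, require_anchored: bool = True
) -> GenotypeMatrix:
    """Marker QC: drop unanchored markers (optional) and markers with
    MAF strictly below ``maf_min`` (MAF exactly at the threshold survives).
    Marker order is preserved; all markers removed is an error."""
    maf = compute_maf(g)
    keep = ~(maf < maf_min)  # nan-MAF (all-missing) markers survive the MAF rule
    if require_anchored:
        anchored = np.array([rec.chromosome is not None for rec in g.markers])
        keep &= anchored
    if not keep.any():
        raise ValueError("marker QC removed every marker")
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_markers: removed %d of %d markers", n_removed, g.n_markers)
    return g.take_markers(np.flatnonzero(keep))


def impute_missing(g: GenotypeMatrix, mode: str = "major_allele") -> GenotypeMatrix:
    """Fill missing dosages: ``major_allele`` -> 0 (conservative, since dosage
    counts the minor allele), ``heterozygote`` -> 1."""
    if mode not in ("major_allele", "heterozygote"):
        raise ValueError(f"unknown imputation mode {mode!r}")
    fill = 0.0 if mode == "major_allele" else 1.0
    dosage = g.dosage.copy()
    dosage[np.isnan(dosage)] = fill
    return GenotypeMatrix(samples=list(g.samples), markers=list(g.markers), dosage=dosage)


def align_samples(
    g: GenotypeMatrix, pheno: PhenotypeTable, trait: str
) -> tuple[GenotypeMatrix, pd.Series]:
    """Restrict to samples present in both inputs with a non-missing trait
    value, preserving the genotype file's sample order in both outputs."""
    values = pheno.trait_values(trait)
    usable = set(values.dropna().index)
    idx = [i for i, s in enumerate(g.samples) if s in usable]
    if not idx:
        raise ValueError(
            f"no samples shared between genotypes and non-missing {trait!r} values"
        )
    g2 = g.take_samples(np.array(idx))
    y = values.loc[g2.samples]
    return g2, y


RESULT_COLUMNS = [
    "marker", "chromosome", "position", "maf", "effect", "se",
    "fstat", "pvalue", "fdr_adjusted_p", "r2_lr",
]


def write_results(table, path) -> None:
    """Write an association table as TSV ordered by (chromosome, position)."""
    frame = table.frame if hasattr(table, "frame") else table
    out = frame.loc[:, RESULT_COLUMNS].copy()
    out = out.sort_values(
        ["chromosome", "position"], kind="mergesort", na_position="last"
    )
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    df["chromosome"] = df["chromosome"].astype(str)
    return df
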