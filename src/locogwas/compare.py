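"""Head-to-head comparison of two GWAS models' results.

Two procedures:

* :func:`novel_region_scan` — a marker significant under model A is in a
  *novel* genomic region if model B declares no significant marker on the
  same chromosome within a +/- window (250 kb by default, boundary
  inclusive).
* :func:`region_pvalue_test` — within a genomic region of interest, the
  paired per-marker p-values of the two models are compared by the Wilcoxon
  signed-rank test (exact enumeration for small tie-free samples, otherwise
  a tie- and continuity-corrected normal approximation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pipeline import AssociationTable, declare_significant

__all__ = [
    "NovelRegionReport",
    "RegionPvalueComparison",
    "novel_region_scan",
    "region_pvalue_test",
    "summarize_counts",
]

DEFAULT_WINDOW_BP = 250_000
EXACT_MAX_N = 25


@dataclass
class NovelRegionReport:
    """Novelty status of model A's significant markers relative to model B."""

    frame: pd.DataFrame  # marker, chromosome, position, pvalue, novel
    window_bp: int
    n_significant: int
    n_novel: int


@dataclass
class RegionPvalueComparison:
    region: tuple[str, int, int] | None
    n_markers: int
    statistic: float | None
    pvalue: float | None
    direction: str  # a_smaller | b_smaller | tied
    degenerate: bool = False
    method: str = ""

    @property
    def pvalue_display(self) -> str:
        """Journal-style display string with the customary reporting floor."""
        if self.pvalue is None:
            return "NA"
        if self.pvalue < 2.20e-16:
            return "< 2.20e-16"
        return f"{self.pvalue:.3g}"


def _sig_frame(table) -> pd.DataFrame:
    frame = table.frame if isinstance(table, AssociationTable) else table
    return frame.dropna(subset=["chromosome", "position"])


def novel_region_scan(
    sig_a, sig_b, window_bp: int = DEFAULT_WINDOW_BP
) -> NovelRegionReport:
    """Flag model-A significant markers with no model-B significant marker
    within ``window_bp`` on the same chromosome (distance inclusive)."""
    if (
        isinstance(sig_a, AssociationTable)
        and isinstance(sig_b, AssociationTable)
        and sig_a.trait and sig_b.trait
        and sig_a.trait != sig_b.trait
    ):
        raise ValueError(
            f"cannot compare tables for different traits: "
            f"{sig_a.trait!r} vs {sig_b.trait!r}"
        )
    a = _sig_frame(sig_a)
    b = _sig_frame(sig_b)
    b_by_chrom = {
        chrom: np.sort(grp["position"].to_numpy(dtype=np.int64))
        for chrom, grp in b.groupby("chromosome")
    }
    novel = []
    for _, row in a.iterrows():
        positions = b_by_chrom.get(row["chromosome"])
        if positions is None or positions.size == 0:
            novel.append(True)
            continue
        i = np.searchsorted(positions, row["position"])
        nearest = min(
            abs(int(positions[j]) - int(row["position"]))
            for j in (max(i - 1, 0), min(i, positions.size - 1))
        )
        novel.append(nearest > window_bp)
    out = a[["marker", "chromosome", "position", "pvalue"]].copy()
    out["novel"] = novel
    return NovelRegionReport(
        frame=out.reset_index(drop=True),
        window_bp=window_bp,
        n_significant=len(out),
        n_novel=int(sum(novel)),
    )


def region_pvalue_test(
    pvals_a,
    pvals_b,
    alternative: str = "two-sided",
    region: tuple[str, int, int] | None = None,
) -> RegionPvalueComparison:
    """Paired Wilcoxon signed-rank test on per-marker p-value differences.

    Differences d = p_a - p_b; zeros are dropped (classical signed-rank).
    The exact null distribution is used when the non-zero sample is small
    (n <= 25) and |d| carries no ties, otherwise the normal approximation
    with tie and continuity corrections.  All-zero differences yield a
    flagged degenerate result with no p-value.
    """
    a = np.asarray(pvals_a, dtype=np.float64)
    b = np.asarray(pvals_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired p-value vectors must have equal length")
    ok = ~np.isnan(a) & ~np.isnan(b)
    a, b = a[ok], b[ok]
    d = a - b
    nz = d[d != 0.0]
    if nz.size == 0:
        return RegionPvalueComparison(
            region=region, n_markers=int(a.size), statistic=None, pvalue=None,
            direction="tied", degenerate=True, method="degenerate",
        )
    no_ties = np.unique(np.abs(nz)).size == nz.size
    method = "exact" if (nz.size <= EXACT_MAX_N and no_ties) else "approx"
    res = stats.wilcoxon(
        a, b,
        zero_method="wilcox",
        correction=(method == "approx"),
        alternative=alternative,
        method=method,
    )
    med = np.median(nz)
    direction = "a_smaller" if med < 0 else ("b_smaller" if med > 0 else "tied")
    return RegionPvalueComparison(
        region=region,
        n_markers=int(nz.size),
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        direction=direction,
        method=method,
    )


def summarize_counts(
    tables: dict[str, dict[str, AssociationTable]],
    fdr_levels=(0.05,),
    window_bp: int = DEFAULT_WINDOW_BP,
    model_a: str = "loco",
    model_b: str = "global",
) -> pd.DataFrame:
    """Per-trait significant-association and novel-region counts.

    ``tables`` maps trait -> {model name -> full AssociationTable}.  For
    each trait and FDR level the summary reports each model's significant
    count and the novel-region counts in both directions.
    """
    rows = []
    for trait, by_model in tables.items():
        for level in fdr_levels:
            sig_a = declare_significant(by_model[model_a], level)
            sig_b = declare_significant(by_model[model_b], level)
            rep_ab = novel_region_scan(sig_a, sig_b, window_bp)
            rep_ba = novel_region_scan(sig_b, sig_a, window_bp)
            rows.append(
                {
                    "trait": trait,
                    "fdr_level": level,
                    f"n_sig_{model_a}": len(sig_a.frame),
                    f"n_sig_{model_b}": len(sig_b.frame),
                    f"n_novel_{model_a}": rep_ab.n_novel,
                    f"n_novel_{model_b}": rep_ba.n_novel,
                }
            )
    return pd.DataFrame(rows)
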