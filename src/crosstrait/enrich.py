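"""Stratified fold-enrichment of primary-trait signal given a secondary trait.

Pleiotropic enrichment of trait A conditional on trait B shows up as an
increasing proportion of trait-A-associated SNPs within subsets of SNPs
selected by progressively stringent trait-B significance.  Fold enrichment
at primary threshold t within secondary stratum c is the ratio of tail
fractions

    FE(t, c) = P(-log10 p1 >= t | -log10 p2 >= c) / P(-log10 p1 >= t),

so the all-SNP baseline stratum (c = 0) is identically 1 and an upward
deflection with increasing c is evidence of shared signal.  The curve is
restricted to sub-genome-wide-significant SNPs (-log10 p1 < 7.3, i.e.
p1 > 5e-8) to focus on polygenic effects, and reads directly as a
stratified true discovery rate: TDR = 1 - FDR with
FDR(t, c) = p(t) / P(p1 <= p(t) | stratum c).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .loci import GenomicRegion, LdTable, exclude_region_ld

__all__ = ["EnrichmentCurve", "fold_enrichment", "enrichment_to_tdr",
           "excluded_region_rerun", "DEFAULT_STRATA", "default_grid"]

#: Secondary-trait cutoffs on -log10 p2 (cumulative strata).
DEFAULT_STRATA = (0.0, 1.0, 2.0, 3.0)

#: Cap on the -log10 p1 axis: the genome-wide significance boundary.
GRID_CAP = 7.3


def default_grid(n: int = 301) -> np.ndarray:
    """Equally spaced thresholds on -log10 p1 in [0, 7.3]."""
    return np.linspace(0.0, GRID_CAP, n)


@dataclass
class EnrichmentCurve:
    """Fold-enrichment surface FE(t, c) with per-stratum bookkeeping.

    ``fe`` has shape (len(grid), len(strata)); undefined grid points
    (zero denominator count) are NaN.  ``stratum_sizes`` are total SNPs per
    stratum, ``tail_counts`` the per-(t, c) numerator counts, and
    ``empty_strata`` flags strata with no SNPs at all.
    """

    grid: np.ndarray
    strata: tuple
    fe: np.ndarray
    stratum_sizes: np.ndarray
    tail_counts: np.ndarray
    trait1: str = "trait1"
    trait2: str = "trait2"

    @property
    def empty_strata(self) -> np.ndarray:
        return self.stratum_sizes == 0

    def max_fe(self, min_tail_count: int = 1) -> np.ndarray:
        """Maximum FE per stratum over grid points with at least
        ``min_tail_count`` stratum SNPs in the tail."""
        out = np.full(len(self.strata), np.nan)
        for j in range(len(self.strata)):
            ok = (self.tail_counts[:, j] >= min_tail_count) & np.isfinite(self.fe[:, j])
            if ok.any():
                out[j] = self.fe[ok, j].max()
        return out

    def to_frame(self) -> pd.DataFrame:
        """Plot-ready long-format table (t, stratum, FE, n)."""
        rows = []
        for j, c in enumerate(self.strata):
            rows.append(pd.DataFrame({
                "neglog10_p1": self.grid,
                "stratum": c,
                "fold_enrichment": self.fe[:, j],
                "n_tail": self.tail_counts[:, j],
                "n_stratum": self.stratum_sizes[j],
            }))
        return pd.concat(rows, ignore_index=True)


def _tail_counts(x_sorted: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """#(x >= t) for each t, via a single sorted pass."""
    return len(x_sorted) - np.searchsorted(x_sorted, grid, side="left")


def fold_enrichment(pair, strata=DEFAULT_STRATA, grid: np.ndarray | None = None) -> EnrichmentCurve:
    """Fold-enrichment surface of trait 1 stratified by trait 2 significance.

    Strata are cumulative: stratum c holds SNPs with -log10 p2 >= c, so
    c = 0 is all SNPs and FE there is identically 1.  Grid points where no
    SNP at all reaches the primary threshold are NaN (undefined); an empty
    stratum yields an all-NaN column (flagged, not an error).
    """
    if len(pair) == 0:
        raise ValueError("empty pair")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    t = pair.table
    x1 = -np.log10(t["pval1"].to_numpy())
    x2 = -np.log10(t["pval2"].to_numpy())

    m = len(x1)
    all_sorted = np.sort(x1)
    denom_counts = _tail_counts(all_sorted, grid)
    denom_frac = denom_counts / m

    fe = np.full((len(grid), len(strata)), np.nan)
    tails = np.zeros((len(grid), len(strata)), dtype=np.int64)
    sizes = np.zeros(len(strata), dtype=np.int64)
    for j, c in enumerate(strata):
        sel = np.sort(x1[x2 >= c])
        sizes[j] = len(sel)
        if len(sel) == 0:
            continue
        tails[:, j] = _tail_counts(sel, grid)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = tails[:, j] / sizes[j]
            fe[:, j] = np.where(denom_counts > 0, frac / denom_frac, np.nan)
    return EnrichmentCurve(grid, tuple(strata), fe, sizes, tails,
                           trait1=pair.trait1, trait2=pair.trait2)


def enrichment_to_tdr(curve: EnrichmentCurve, pair) -> pd.DataFrame:
    """Stratified Bayes FDR/TDR per (threshold, stratum).

    FDR(t, c) = p(t) / [fraction of stratum-c SNPs with p1 <= p(t)], capped
    at 1 (and 1 when no stratum SNP reaches the threshold); TDR = 1 - FDR.
    Returns a long-format table (t, stratum, fdr, tdr).
    """
    p_at = 10.0 ** (-curve.grid)
    rows = []
    for j, c in enumerate(curve.strata):
        size = curve.stratum_sizes[j]
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(size > 0, curve.tail_counts[:, j] / max(size, 1), 0.0)
            fdr = np.where(frac > 0, np.minimum(1.0, p_at / frac), 1.0)
        rows.append(pd.DataFrame({
            "neglog10_p1": curve.grid, "stratum": c,
            "fdr": fdr, "tdr": 1.0 - fdr,
        }))
    return pd.concat(rows, ignore_index=True)


def excluded_region_rerun(pair, region: GenomicRegion, ld: LdTable,
                          window: int = 1_000_000, r2_thresh: float = 0.2,
                          strata=DEFAULT_STRATA, grid: np.ndarray | None = None):
    """Recompute fold enrichment after removing a region and its LD partners.

    Deletes SNPs inside ``region``, within ``window`` of its boundary, and
    in LD (r^2 > ``r2_thresh``) with any deleted SNP, then rebuilds the
    enrichment curve on the filtered pair.  Returns ``(curve, removal
    report)``; an empty filtered pair is a hard error.
    """
    filtered, report = exclude_region_ld(pair, region, ld, window=window, r2_thresh=r2_thresh)
    if len(filtered) == 0:
        raise ValueError("region exclusion removed every SNP")
    return fold_enrichment(filtered, strata=strata, grid=grid), report
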