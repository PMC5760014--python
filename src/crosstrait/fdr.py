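"""Conditional and conjunction FDR estimation from paired summary statistics.

The conditional FDR of a SNP for the primary trait given the secondary trait
is estimated empirically, with a conservative null proportion pi0 = 1, as

    condFDR(p1 | p2)  =  min(1, p1 / Fhat(p1 | p2)),

where ``Fhat(p1 | p2)`` is the empirical cumulative fraction of primary-trait
p-values at or below p1 among SNPs whose secondary-trait p-value is at or
below p2 (a cumulative secondary-trait stratum).  The conjunction FDR — the
posterior probability that a SNP is null for either trait or both, given
both p-values are at least as extreme as observed — is estimated as the
maximum of the two conditional FDRs taken in both orientations.

``cond_fdr_direct`` is the brute-force per-query estimator;
``build_lookup`` precomputes the same estimator on a binned 2-D grid over
(-log10 p1, -log10 p2) with optional monotonization, and evaluates per-SNP
values by clamped bilinear interpolation.  At bin-edge query points with
monotonization disabled the lookup agrees with the direct estimator exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

__all__ = ["FdrLookup", "ConjResult", "cond_fdr_direct", "build_lookup", "conj_fdr"]

#: p-values are floored here before the -log10 transform, capping the grid
#: at -log10 p = 20 and avoiding infinities.
P_FLOOR = 1e-20


def cond_fdr_direct(p1: float, p2: float, pair, return_cdf: bool = False):
    """Brute-force conditional FDR of the primary trait at query (p1, p2).

    Counts over the full pair: ``Fhat = #(pval1 <= p1 and pval2 <= p2) /
    #(pval2 <= p2)``; returns ``min(1, p1 / Fhat)`` with pi0 = 1.  An empty
    stratum (no SNP with pval2 <= p2) yields 1.  With ``return_cdf`` the
    empirical conditional cdf ``Fhat`` is returned alongside.
    """
    if not (0 < p1 <= 1 and 0 < p2 <= 1):
        raise ValueError("query p-values must lie in (0, 1]")
    t = pair.table
    stratum = t["pval2"].to_numpy() <= p2
    n_stratum = int(stratum.sum())
    if n_stratum == 0:
        return (1.0, 0.0) if return_cdf else 1.0
    n_joint = int((stratum & (t["pval1"].to_numpy() <= p1)).sum())
    cdf = n_joint / n_stratum
    fdr = 1.0 if n_joint == 0 else min(1.0, p1 / cdf)
    return (fdr, cdf) if return_cdf else fdr


@dataclass
class FdrLookup:
    """Binned 2-D conditional-FDR grid over (-log10 p1, -log10 p2).

    ``fdr[i, j]`` holds condFDR evaluated at primary-axis edge ``edges[i]``
    within the cumulative secondary stratum ``-log10 p2 >= edges[j]``;
    ``cdf`` holds the corresponding empirical conditional cdf and
    ``occupancy`` the per-bin SNP counts.  After monotonization the values
    are non-increasing along increasing significance on both axes.
    """

    edges: np.ndarray
    fdr: np.ndarray
    cdf: np.ndarray
    occupancy: np.ndarray
    monotonized: bool
    trait1: str = "trait1"
    trait2: str = "trait2"
    _interp: RegularGridInterpolator | None = field(default=None, repr=False)
    _interp_cdf: RegularGridInterpolator | None = field(default=None, repr=False)

    def _neglog(self, p) -> np.ndarray:
        x = -np.log10(np.clip(np.asarray(p, dtype=float), P_FLOOR, 1.0))
        return np.clip(x, self.edges[0], self.edges[-1])

    def evaluate(self, p1, p2) -> np.ndarray:
        """Clamped bilinear interpolation of condFDR at per-SNP (p1, p2)."""
        if self._interp is None:
            self._interp = RegularGridInterpolator(
                (self.edges, self.edges), self.fdr, method="linear")
        pts = np.column_stack([self._neglog(p1), self._neglog(p2)])
        return self._interp(pts)

    def evaluate_cdf(self, p1, p2) -> np.ndarray:
        """Interpolated empirical conditional cdf Fhat(p1 | p2) (calibration aid)."""
        if self._interp_cdf is None:
            self._interp_cdf = RegularGridInterpolator(
                (self.edges, self.edges), self.cdf, method="linear")
        pts = np.column_stack([self._neglog(p1), self._neglog(p2)])
        return self._interp_cdf(pts)


def build_lookup(pair, n_bins: int = 200, monotonize: bool = True,
                 p_floor: float = P_FLOOR, min_snps: int = 1000) -> FdrLookup:
    """Precompute the conditional-FDR estimator on a binned 2-D grid.

    Both axes are binned on -log10 p over [0, -log10 p_floor] with
    ``n_bins`` equal-width bins.  For every cumulative secondary-trait
    stratum (one per edge) the empirical cdf of primary p-values is
    evaluated at the primary-axis edges and the direct estimator is filled
    in at all edge pairs.  Monotonization applies a running minimum along
    each axis in the direction of increasing significance, so lookup values
    can only decrease as either p-value becomes more extreme.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(pair) < min_snps:
        warnings.warn(f"building FDR lookup from only {len(pair)} variants "
                      f"(<{min_snps}); estimates will be noisy", stacklevel=2)
    t = pair.table
    hi = -np.log10(p_floor)
    edges = np.linspace(0.0, hi, n_bins + 1)
    x1 = np.clip(-np.log10(np.clip(t["pval1"].to_numpy(), p_floor, 1.0)), 0, hi)
    x2 = np.clip(-np.log10(np.clip(t["pval2"].to_numpy(), p_floor, 1.0)), 0, hi)

    occupancy, _, _ = np.histogram2d(x1, x2, bins=[edges, edges])

    # tail counts at every edge pair: N[i, j] = #(x1 >= edges[i], x2 >= edges[j]);
    # suffix-sum the histogram (the final edge row/column is the empty tail)
    n_edges = n_bins + 1
    tail = np.zeros((n_edges, n_edges))
    tail[:n_bins, :n_bins] = occupancy[::-1, ::-1].cumsum(axis=0).cumsum(axis=1)[::-1, ::-1]

    stratum_sizes = tail[0, :]  # #(x2 >= edges[j]) since every x1 >= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        cdf = np.where(stratum_sizes > 0, tail / stratum_sizes, 0.0)
        p_at_edges = 10.0 ** (-edges)
        fdr = np.where(cdf > 0, np.minimum(1.0, p_at_edges[:, None] / cdf), 1.0)

    if monotonize:
        fdr = np.minimum.accumulate(fdr, axis=0)   # increasing -log10 p1
        fdr = np.minimum.accumulate(fdr, axis=1)   # increasing stratum stringency

    return FdrLookup(edges=edges, fdr=fdr, cdf=cdf, occupancy=occupancy,
                     monotonized=monotonize, trait1=pair.trait1, trait2=pair.trait2)


@dataclass
class ConjResult:
    """Per-SNP conditional and conjunction FDR values with a selection flag.

    ``table`` columns: ``snp, chrom, pos, pval1, pval2, cond_fdr_1g2,
    cond_fdr_2g1, conj_fdr, selected``.
    """

    table: pd.DataFrame
    threshold: float
    trait1: str
    trait2: str

    def selected(self) -> pd.DataFrame:
        return self.table[self.table["selected"]].reset_index(drop=True)


def conj_fdr(pair, lookup_1g2: FdrLookup, lookup_2g1: FdrLookup,
             threshold: float = 0.05) -> ConjResult:
    """Conjunction FDR per SNP: the maximum of the two conditional FDRs.

    ``lookup_1g2`` conditions trait 1 on trait 2 (built from ``pair``);
    ``lookup_2g1`` the reverse (built from ``pair.swap()``).  SNPs with
    conjunction FDR strictly below ``threshold`` are flagged as selected.
    """
    t = pair.table
    c12 = lookup_1g2.evaluate(t["pval1"], t["pval2"])
    c21 = lookup_2g1.evaluate(t["pval2"], t["pval1"])
    conj = np.maximum(c12, c21)
    out = pd.DataFrame({
        "snp": t["snp"], "chrom": t["chrom"], "pos": t["pos"],
        "pval1": t["pval1"], "pval2": t["pval2"],
        "cond_fdr_1g2": c12, "cond_fdr_2g1": c21,
        "conj_fdr": conj, "selected": conj < threshold,
    })
    return ConjResult(out, threshold, pair.trait1, pair.trait2)
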