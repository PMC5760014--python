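"""Functional follow-up of pleiotropic loci in expression data.

Three stages: additive-model ANCOVA cis-eQTL tests (linear regression of
expression on genotype dosage plus optional covariates, variants paired to
genes within 1 Mb of the transcription start site, gated at a conservative
Bonferroni threshold), pooled-region two-group differential expression
(Welch's t-test across brain regions combined for power), and cell-type
assignment of genes to the brain cell class in which each is most highly
expressed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .loci import GeneAnnotation
from .simulate import ExpressionMatrix  # noqa: F401  (re-exported container)

__all__ = [
    "EqtlResult", "cis_pairs", "ancova_additive", "bonferroni_gate",
    "differential_expression", "cell_type_assignment",
    "BONFERRONI_ALPHA", "CANONICAL_CELL_TYPES",
]

#: Conservative Bonferroni threshold used to declare a cis-eQTL significant.
BONFERRONI_ALPHA = 3.9e-5

#: Surveyed brain cell classes, in canonical (tie-breaking) order.
CANONICAL_CELL_TYPES = (
    "neurons",
    "fetal astrocytes",
    "mature astrocytes",
    "oligodendrocyte precursor cells",
    "newly formed oligodendrocytes",
    "myelinating oligodendrocytes",
    "microglia/macrophages",
    "endothelial cells",
    "pericytes",
)

_TINY_P = float(np.finfo(float).tiny)


@dataclass
class EqtlResult:
    """One (variant, gene) additive-model association."""

    variant: str
    gene: str
    slope: float
    tstat: float
    pval: float
    error: str | None = None

    def passes(self, alpha: float = BONFERRONI_ALPHA) -> bool:
        return self.error is None and self.pval < alpha


def cis_pairs(variants: pd.DataFrame, genes: GeneAnnotation,
              window: int = 1_000_000) -> pd.DataFrame:
    """All (variant, gene) pairs within ``window`` of the gene's TSS.

    ``variants`` needs ``snp, chrom, pos`` columns.  The transcription start
    site is the interval start on the + strand and the interval end on the -
    strand (start when no strand column is present).  The window is
    inclusive: |pos - TSS| <= window.
    """
    iv = genes.intervals
    if "strand" in iv.columns:
        tss = np.where(iv["strand"] == "-", iv["end"], iv["start"])
    else:
        tss = iv["start"].to_numpy()
    gene_tab = pd.DataFrame({"gene": iv["name"], "gchrom": iv["chrom"].astype(str), "tss": tss})

    rows = []
    for chrom, vsub in variants.groupby(variants["chrom"].astype(str)):
        gsub = gene_tab[gene_tab["gchrom"] == chrom]
        if len(gsub) == 0:
            continue
        dist = np.abs(vsub["pos"].to_numpy()[:, None] - gsub["tss"].to_numpy()[None, :])
        vi, gi = np.nonzero(dist <= window)
        rows.append(pd.DataFrame({
            "snp": vsub["snp"].to_numpy()[vi],
            "gene": gsub["gene"].to_numpy()[gi],
            "distance": dist[vi, gi].astype(np.int64),
        }))
    if not rows:
        return pd.DataFrame(columns=["snp", "gene", "distance"])
    return pd.concat(rows, ignore_index=True).sort_values(["snp", "gene"]).reset_index(drop=True)


def ancova_additive(expr, dosage, covariates=None,
                    variant: str = "", gene: str = "") -> EqtlResult:
    """Additive-model genotype-expression association with covariates.

    Fits ``expression ~ dosage + covariates`` by ordinary least squares and
    reports the dosage slope with its t statistic and two-sided p-value.  A
    constant dosage vector or too few samples is flagged per pair (the
    ``error`` field) rather than raised.  A numerically perfect fit reports
    the smallest positive p-value instead of zero.
    """
    y = np.asarray(expr, dtype=float)
    d = np.asarray(dosage, dtype=float)
    if covariates is None:
        X = d[:, None]
        names = ["dosage"]
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        X = np.column_stack([d, C])
        names = ["dosage"] + [f"cov{i}" for i in range(C.shape[1])]
    if np.ptp(d) == 0:
        return EqtlResult(variant, gene, np.nan, np.nan, np.nan, error="constant dosage")
    if len(y) <= X.shape[1] + 2:
        return EqtlResult(variant, gene, np.nan, np.nan, np.nan, error="too few samples")

    Xd = pd.DataFrame(X, columns=names)
    fit = sm.OLS(y, sm.add_constant(Xd)).fit()
    slope = float(fit.params["dosage"])
    tstat = float(fit.tvalues["dosage"])
    pval = float(fit.pvalues["dosage"])
    if not np.isfinite(pval) or pval <= 0:
        pval = _TINY_P
        tstat = np.inf * np.sign(slope) if not np.isfinite(tstat) else tstat
    return EqtlResult(variant, gene, slope, tstat, pval)


def bonferroni_gate(results, alpha: float = BONFERRONI_ALPHA):
    """Flag results passing a strict Bonferroni-style cutoff (p < alpha).

    Accepts a list of :class:`EqtlResult` (returns a DataFrame) or any
    DataFrame with a ``pval`` column (returns a copy with a ``pass`` column).
    """
    if isinstance(results, pd.DataFrame):
        out = results.copy()
        out["pass"] = (out["pval"] < alpha).fillna(False)
        return out
    rows = [{
        "variant": r.variant, "gene": r.gene, "slope": r.slope,
        "tstat": r.tstat, "pval": r.pval, "error": r.error,
        "pass": r.passes(alpha),
    } for r in results]
    return pd.DataFrame(rows)


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    res = stats.ttest_ind(a, b, equal_var=False)
    stat, p = float(res.statistic), float(res.pvalue)
    if not np.isfinite(stat):
        # zero within-group variance: maximal p for equal means, minimal otherwise
        diff = float(np.mean(a) - np.mean(b))
        if diff == 0:
            return 0.0, 1.0
        return np.sign(diff) * np.inf, _TINY_P
    return stat, p


def differential_expression(mat: ExpressionMatrix, group_a: str, group_b: str,
                            genes=None, alpha: float = 0.05) -> pd.DataFrame:
    """Per-gene two-group comparison with brain regions pooled.

    Samples from all regions are combined to maximize power and compared
    between the two groups with Welch's two-sided t-test.  Returns a table
    with ``gene, stat, pval, significant, available``; genes requested but
    absent from the matrix are recorded as not available (the N/A case)
    rather than dropped.  Significance is marked at ``pval <= alpha``.
    """
    ga = mat.samples.index[mat.samples["group"] == group_a]
    gb = mat.samples.index[mat.samples["group"] == group_b]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("both groups need >= 2 samples after pooling regions")
    if genes is None:
        genes = list(mat.values.index)

    rows = []
    for g in genes:
        if g not in mat.values.index:
            rows.append({"gene": g, "stat": np.nan, "pval": np.nan,
                         "significant": False, "available": False})
            continue
        stat, p = _welch(mat.values.loc[g, ga].to_numpy(),
                         mat.values.loc[g, gb].to_numpy())
        rows.append({"gene": g, "stat": stat, "pval": p,
                     "significant": bool(p <= alpha), "available": True})
    return pd.DataFrame(rows)


def cell_type_assignment(profile: pd.DataFrame, genes=None):
    """Assign each gene to the cell class in which it is most highly expressed.

    ``profile`` is a genes x cell-types table of mean expression
    (transcript-abundance units, values >= 0).  Ties are broken by the
    canonical cell-type order; requested genes absent from the profile are
    marked ``"not found"``.  Returns ``(assignments, counts)`` where
    ``assignments`` maps gene -> cell type and ``counts`` aggregates genes
    per assigned type (bar-plot-ready).
    """
    if profile.shape[1] < 1:
        raise ValueError("profile needs at least one cell type")
    if (profile.to_numpy() < 0).any():
        raise ValueError("expression values must be >= 0")
    order = [c for c in CANONICAL_CELL_TYPES if c in profile.columns]
    order += sorted(c for c in profile.columns if c not in CANONICAL_CELL_TYPES)
    prof = profile[order]

    if genes is None:
        genes = list(profile.index)
    assigned = {}
    for g in genes:
        if g not in prof.index:
            assigned[g] = "not found"
        else:
            assigned[g] = prof.columns[int(np.argmax(prof.loc[g].to_numpy()))]
    assignments = pd.Series(assigned, name="cell_type")
    counts = assignments.value_counts()
    return assignments, counts
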