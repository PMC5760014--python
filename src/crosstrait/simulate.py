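"""Synthetic data with the statistical structure the pleiotropy analysis assumes.

``simulate_pair`` draws paired GWAS summary statistics from a four-component
mixture of causal status (null / trait-1-only / trait-2-only / pleiotropic)
over exchangeable-correlation LD blocks: within a block, z-scores are
multivariate normal with correlation ``r_within`` around block-smeared means
sqrt(n_t) * (R @ beta_t), where R is the block's LD (correlation) matrix.
This keeps the generator analytically checkable while producing LD-smeared
signal for pruning tests.  ``simulate_expression`` produces a small
gene-by-sample matrix with planted cis-eQTL slopes and group shifts for the
expression follow-up stages.

``load_ftd_immune_loci`` returns the packaged worked-example locus table:
21 SNPs reported as jointly associated with frontotemporal dementia and one
or more immune-mediated diseases at conjunction FDR < 0.05, with the single
known LD fact for that table (rs204989-rs204991, D' = 1, r^2 = 1) exposed by
``ftd_immune_ld``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .loci import LdTable
from .sumstats import P_MIN, PairedStats, SumStats

__all__ = [
    "SimParams", "SimTruth", "ExpressionMatrix",
    "simulate_pair", "simulate_expression",
    "load_ftd_immune_loci", "ftd_immune_ld",
    "CAUSAL_CLASSES", "block_region",
]

#: Causal-status labels: null, trait-1-only, trait-2-only, pleiotropic.
CAUSAL_CLASSES = ("00", "10", "01", "11")

_SNP_SPACING = 10_000  # bp between adjacent simulated SNPs on a chromosome
_N_CHROMS = 22


@dataclass
class SimParams:
    """Generator settings for one paired-GWAS simulation.

    Defaults emulate the scale of the case-control studies the analysis is
    designed for: a modest primary trait (effective n ~ 6,000) against a
    well-powered secondary trait (n ~ 25,000), polygenic pleiotropy at 0.2%
    of SNPs with strongly correlated effect sizes, and LD blocks of 10 SNPs
    at within-block z correlation 0.8.
    """

    m_snps: int = 20_000
    block_size: int = 10
    r_within: float = 0.8
    mixture: tuple[float, float, float, float] = (0.988, 0.005, 0.005, 0.002)
    sigma_beta: float = 0.05
    rho_effect: float = 0.8
    n1: int = 6_000
    n2: int = 25_000
    lambda_inflate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.mixture) - 1.0) > 1e-12:
            raise ValueError(f"mixture must sum to 1, got {sum(self.mixture)}")
        if not (0 <= self.r_within < 1):
            raise ValueError("r_within must be in [0, 1)")
        if not (-1 <= self.rho_effect <= 1):
            raise ValueError("rho_effect must be in [-1, 1]")
        if self.lambda_inflate < 1:
            raise ValueError("lambda_inflate must be >= 1")
        if self.m_snps < 1 or self.block_size < 1:
            raise ValueError("m_snps and block_size must be positive")


@dataclass
class SimTruth:
    """Ground truth of a simulated pair: per-variant causal class and effects.

    ``table`` columns: ``snp, chrom, pos, block, causal_class, beta1, beta2``.
    """

    table: pd.DataFrame
    params: SimParams = field(repr=False, default=None)

    def class_mask(self, cls: str) -> np.ndarray:
        return (self.table["causal_class"] == cls).to_numpy()

    def blocks_with_class(self, cls: str) -> np.ndarray:
        """Sorted block ids containing at least one variant of causal class ``cls``."""
        t = self.table
        return np.unique(t.loc[t["causal_class"] == cls, "block"].to_numpy())


def block_region(truth: SimTruth, block: int):
    """(chrom, start, end) spanned by one simulated LD block."""
    from .loci import GenomicRegion

    rows = truth.table[truth.table["block"] == block]
    if len(rows) == 0:
        raise ValueError(f"no such block: {block}")
    return GenomicRegion(str(rows["chrom"].iloc[0]), int(rows["pos"].min()),
                         int(rows["pos"].max()), name=f"block{block}")


def _block_layout(m: int, block_size: int):
    """Assign blocks round-robin to chromosomes 1..22, sequential positions."""
    block = np.arange(m) // block_size
    chrom = (block % _N_CHROMS) + 1
    # position: per chromosome, consecutive SNPs spaced _SNP_SPACING apart
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, _N_CHROMS + 1):
        mask = chrom == c
        pos[mask] = 1_000_000 + np.arange(mask.sum(), dtype=np.int64) * _SNP_SPACING
    return chrom.astype(str), pos, block


def simulate_pair(params: SimParams, classes: np.ndarray | None = None,
                  with_ld: bool = True):
    """Draw one paired summary-statistics dataset.

    Returns ``(sumstats1, sumstats2, truth, ld_table)``; ``ld_table`` is
    ``None`` when ``with_ld=False``.  Passing an explicit per-variant
    ``classes`` array (values 0..3 indexing :data:`CAUSAL_CLASSES`) overrides
    the mixture draw, e.g. to plant all pleiotropic variants in one block.
    Fully reproducible from ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    m, bs, r = params.m_snps, params.block_size, params.r_within

    if classes is None:
        classes = rng.choice(4, size=m, p=params.mixture)
    else:
        classes = np.asarray(classes)
        if classes.shape != (m,):
            raise ValueError("classes must have shape (m_snps,)")

    causal1 = (classes == 1) | (classes == 3)
    causal2 = (classes == 2) | (classes == 3)

    beta1 = np.zeros(m)
    beta2 = np.zeros(m)
    beta1[causal1] = params.sigma_beta * rng.standard_normal(causal1.sum())
    # trait-2 effects: independent for trait-2-only variants, correlated with
    # beta1 (correlation rho_effect) for pleiotropic ones
    only2 = classes == 2
    both = classes == 3
    beta2[only2] = params.sigma_beta * rng.standard_normal(only2.sum())
    rho = params.rho_effect
    beta2[both] = rho * beta1[both] + np.sqrt(1 - rho**2) * params.sigma_beta * rng.standard_normal(both.sum())

    block = np.arange(m) // bs
    n_blocks = block[-1] + 1
    chrom, pos, _ = _block_layout(m, bs)

    def _z(beta: np.ndarray, n_eff: int) -> np.ndarray:
        # R @ beta per block for exchangeable R: (1-r)*beta_i + r*sum_block(beta)
        bsum = np.bincount(block, weights=beta, minlength=n_blocks)
        mean = np.sqrt(n_eff) * ((1 - r) * beta + r * bsum[block])
        shared = rng.standard_normal(n_blocks)
        noise = np.sqrt(r) * shared[block] + np.sqrt(1 - r) * rng.standard_normal(m)
        return np.sqrt(params.lambda_inflate) * (mean + noise)

    z1 = _z(beta1, params.n1)
    z2 = _z(beta2, params.n2)
    p1 = np.maximum(2 * stats.norm.sf(np.abs(z1)), P_MIN)
    p2 = np.maximum(2 * stats.norm.sf(np.abs(z2)), P_MIN)

    snp = np.array([f"rs{i + 1}" for i in range(m)])
    base = {
        "snp": snp, "chrom": chrom, "pos": pos,
        "allele_effect": np.repeat("A", m), "allele_other": np.repeat("G", m),
    }
    s1 = SumStats(pd.DataFrame({**base, "pval": p1, "effect": z1 / np.sqrt(params.n1)}),
                  trait_name="trait1")
    s2 = SumStats(pd.DataFrame({**base, "pval": p2, "effect": z2 / np.sqrt(params.n2)}),
                  trait_name="trait2")

    truth = SimTruth(pd.DataFrame({
        "snp": snp, "chrom": chrom, "pos": pos, "block": block,
        "causal_class": np.array(CAUSAL_CLASSES)[classes],
        "beta1": beta1, "beta2": beta2,
    }), params=params)

    ld = None
    if with_ld:
        ld = LdTable.from_blocks(
            (snp[block == b] for b in range(n_blocks)), r2=r**2)
    return s1, s2, truth, ld


def paired_from_simulation(s1: SumStats, s2: SumStats) -> PairedStats:
    """Shortcut pairing for simulated traits (identical allele coding by design)."""
    from .sumstats import harmonize_pair

    return harmonize_pair(s1, s2, drop_palindromic=False)


# ---------------------------------------------------------------------------
# expression fixtures


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (log-scale assumed) with sample labels.

    ``samples`` is indexed by sample id with at least ``group`` and
    ``region`` columns; extra columns are treated as covariates.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self):
        if self.values.index.duplicated().any():
            raise ValueError("gene identifiers must be unique")
        if self.samples["group"].isna().any():
            raise ValueError("missing group labels")
        if not self.values.columns.equals(self.samples.index):
            raise ValueError("sample columns and annotation index must match")


REGIONS = ("frontal_cortex", "hippocampus", "cerebellum")


def simulate_expression(n_samples: int = 20, n_genes: int = 100,
                        eqtl_slope: float = 1.0, de_shift: float = 1.0,
                        noise_sd: float = 1.0, maf: float = 0.3,
                        seed: int = 0):
    """Two-group expression matrix with planted eQTL slopes and group shifts.

    Each gene has its own biallelic variant with dosages ~ Binomial(2, maf)
    and expression ``baseline + eqtl_slope * dosage + de_shift * case
    indicator (true-DE genes only) + N(0, noise_sd)``.  Half of the genes
    (alternating) are true differentially expressed genes; brain-region
    labels are assigned round-robin over three regions.  Returns
    ``(ExpressionMatrix, dosages DataFrame, truth DataFrame)``.
    """
    if n_samples < 2 or n_genes < 2:
        raise ValueError("n_samples and n_genes must be >= 2")
    rng = np.random.default_rng(seed)
    n_total = 2 * n_samples
    sample_ids = [f"s{i + 1}" for i in range(n_total)]
    group = np.repeat(["control", "case"], n_samples)
    region = np.array([REGIONS[i % 3] for i in range(n_total)])
    genes = [f"gene{g + 1}" for g in range(n_genes)]
    is_de = np.arange(n_genes) % 2 == 0

    dosage = rng.binomial(2, maf, size=(n_genes, n_total)).astype(float)
    baseline = rng.normal(5.0, 1.0, size=n_genes)
    expr = (baseline[:, None]
            + eqtl_slope * dosage
            + de_shift * is_de[:, None] * (group == "case")[None, :]
            + noise_sd * rng.standard_normal((n_genes, n_total)))

    mat = ExpressionMatrix(
        values=pd.DataFrame(expr, index=genes, columns=sample_ids),
        samples=pd.DataFrame({"group": group, "region": region}, index=sample_ids),
    )
    dosages = pd.DataFrame(dosage, index=genes, columns=sample_ids)
    truth = pd.DataFrame({"gene": genes, "is_de": is_de,
                          "eqtl_slope": eqtl_slope,
                          "de_shift": np.where(is_de, de_shift, 0.0)})
    return mat, dosages, truth


# ---------------------------------------------------------------------------
# packaged worked-example locus table


def load_ftd_immune_loci() -> pd.DataFrame:
    """The packaged 21-row FTD-immune pleiotropic locus table.

    Columns: ``snp, chrom, nearest_gene, immune_trait, immune_p,
    min_conj_fdr, ftd_p, direction, in_hla_region`` plus parsed numeric sign
    columns ``sign1``/``sign2`` (FTD / immune direction of allelic effect).
    Values are stored exactly as printed in the source report and parsed to
    floats on load.
    """
    with resources.files("crosstrait.data").joinpath("ftd_immune_loci.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype={"chrom": str})
    signs = df["direction"].str.split("/", expand=True)
    df["sign1"] = np.where(signs[0] == "+", 1.0, -1.0)
    df["sign2"] = np.where(signs[1] == "+", 1.0, -1.0)
    return df


def ftd_immune_ld() -> LdTable:
    """LD facts published alongside the worked-example table.

    Only one pair in the table is reported as the same signal:
    rs204989-rs204991 with D' = 1 and r^2 = 1.  All other pairs are treated
    as unlinked.
    """
    t = LdTable()
    t.set("rs204989", "rs204991", r2=1.0, dprime=1.0)
    return t


def locus_records_from_table(df: pd.DataFrame) -> pd.DataFrame:
    """Map the worked-example table onto the standard locus-record columns
    used by clumping and the locus-filter report."""
    return pd.DataFrame({
        "snp": df["snp"],
        "chrom": df["chrom"].astype(str),
        "conj_fdr": df["min_conj_fdr"].astype(float),
        "pval1": df["ftd_p"].astype(float),
        "sign1": df["sign1"],
        "sign2": df["sign2"],
        "in_region": df["in_hla_region"].astype(bool),
        "nearest_gene": df["nearest_gene"],
    })
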