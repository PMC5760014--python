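import numpy as np
import pandas as pd
import pytest

from crosstrait.sumstats import PairedStats, SumStats


def make_sumstats(pvals, effects=None, snps=None, chrom="1", trait="t",
                  a1="A", a2="G", pos=None):
    """Hand-built SumStats for small deterministic tests."""
    n = len(pvals)
    if effects is None:
        effects = np.full(n, 0.1)
    if snps is None:
        snps = [f"rs{i + 1}" for i in range(n)]
    if pos is None:
        pos = np.arange(1, n + 1) * 1000
    df = pd.DataFrame({
        "snp": snps,
        "chrom": np.repeat(str(chrom), n) if np.isscalar(chrom) else [str(c) for c in chrom],
        "pos": np.asarray(pos, dtype=np.int64),
        "allele_effect": np.repeat(a1, n),
        "allele_other": np.repeat(a2, n),
        "pval": np.asarray(pvals, dtype=float),
        "effect": np.asarray(effects, dtype=float),
    })
    return SumStats(df, trait_name=trait)


def make_pair(p1, p2, effect1=None, effect2=None, snps=None, chrom="1", pos=None):
    """Hand-built PairedStats bypassing harmonization (already aligned)."""
    n = len(p1)
    if effect1 is None:
        effect1 = np.full(n, 0.1)
    if effect2 is None:
        effect2 = np.full(n, 0.1)
    if snps is None:
        snps = [f"rs{i + 1}" for i in range(n)]
    if pos is None:
        pos = np.arange(1, n + 1) * 1000
    df = pd.DataFrame({
        "snp": snps,
        "chrom": np.repeat(str(chrom), n) if np.isscalar(chrom) else [str(c) for c in chrom],
        "pos": np.asarray(pos, dtype=np.int64),
        "allele_effect": np.repeat("A", n),
        "allele_other": np.repeat("G", n),
        "pval1": np.asarray(p1, dtype=float),
        "pval2": np.asarray(p2, dtype=float),
        "effect1": np.asarray(effect1, dtype=float),
        "effect2": np.asarray(effect2, dtype=float),
    })
    return PairedStats(df, "t1", "t2", n_intersected=n)


@pytest.fixture
def null_pair():
    """Independent uniform p-values for both traits, m = 5,000."""
    rng = np.random.default_rng(42)
    return make_pair(rng.uniform(size=5000), rng.uniform(size=5000))


@pytest.fixture
def fixture_records():
    """Worked-example locus table mapped to standard locus records."""
    from crosstrait.simulate import load_ftd_immune_loci, locus_records_from_table

    return locus_records_from_table(load_ftd_immune_loci())
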