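"""GWAS summary statistics: reading, validation, allele harmonization, genomic control.

A :class:`SumStats` holds one trait's per-variant association records (rsID,
chromosome, position, effect/other allele, p-value, signed effect on the
log-odds scale).  Two traits are combined into a :class:`PairedStats` whose
effect signs are directly comparable because the second trait's effects are
re-expressed relative to the first trait's effect allele.  Test-statistic
inflation is handled by standard genomic control (median chi-square method).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Median of a central 1-df chi-square distribution, the genomic-control
#: null reference (~0.4549).
CHI2_NULL_MEDIAN: float = float(stats.chi2.ppf(0.5, df=1))

#: Smallest p-value carried through corrections (guards against underflow to 0).
P_MIN: float = 1e-300

#: Canonical on-disk column names for the tab-delimited sumstats dialect.
CANONICAL_DIALECT: dict[str, str] = {
    "snp": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "allele_effect": "A1",
    "allele_other": "A2",
    "pval": "P",
    "effect": "BETA",
}

_PALINDROMIC = ({"A", "T"}, {"C", "G"})

_INTERNAL_COLUMNS = ["snp", "chrom", "pos", "allele_effect", "allele_other", "pval", "effect"]


@dataclass
class LoadReport:
    """Bookkeeping of rows dropped while validating a summary-statistics file."""

    n_rows: int = 0
    n_kept: int = 0
    n_bad_pval: int = 0
    n_bad_effect: int = 0
    n_bad_alleles: int = 0
    n_duplicate: int = 0

    @property
    def n_dropped(self) -> int:
        return self.n_rows - self.n_kept

    def to_dict(self) -> dict:
        return {
            "n_rows": self.n_rows,
            "n_kept": self.n_kept,
            "n_dropped": self.n_dropped,
            "n_bad_pval": self.n_bad_pval,
            "n_bad_effect": self.n_bad_effect,
            "n_bad_alleles": self.n_bad_alleles,
            "n_duplicate": self.n_duplicate,
        }


@dataclass
class SumStats:
    """One trait's validated per-variant association records.

    ``table`` columns: ``snp, chrom, pos, allele_effect, allele_other, pval,
    effect`` with ``pval`` in (0, 1], unique rsIDs, 1-based positions and the
    effect on the log-odds scale.  ``gc_lambda`` records an applied
    genomic-control inflation factor (``None`` if never estimated).
    """

    table: pd.DataFrame
    trait_name: str = "trait"
    gc_lambda: float | None = None
    load_report: LoadReport | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.table)

    def copy(self) -> "SumStats":
        return SumStats(self.table.copy(), self.trait_name, self.gc_lambda, self.load_report)


@dataclass
class PairedStats:
    """Two traits harmonized to a common variant set with comparable effect signs.

    ``table`` columns: ``snp, chrom, pos, allele_effect, allele_other,
    pval1, pval2, effect1, effect2``.  Both effects are expressed relative to
    ``allele_effect``, so a sign comparison is a direction-of-effect
    comparison.
    """

    table: pd.DataFrame
    trait1: str
    trait2: str
    n_intersected: int
    n_dropped_unresolvable: int = 0
    n_dropped_palindromic: int = 0

    def __len__(self) -> int:
        return len(self.table)

    def swap(self) -> "PairedStats":
        """Exchange which trait is primary; only permutes columns."""
        t = self.table.rename(
            columns={"pval1": "pval2", "pval2": "pval1", "effect1": "effect2", "effect2": "effect1"}
        )
        t = t[self.table.columns]
        return PairedStats(
            t, self.trait2, self.trait1, self.n_intersected,
            self.n_dropped_unresolvable, self.n_dropped_palindromic,
        )

    def as_sumstats(self, which: int = 1) -> SumStats:
        """View one side of the pair as a :class:`SumStats`."""
        if which not in (1, 2):
            raise ValueError("which must be 1 or 2")
        t = self.table[["snp", "chrom", "pos", "allele_effect", "allele_other",
                        f"pval{which}", f"effect{which}"]].copy()
        t.columns = _INTERNAL_COLUMNS
        return SumStats(t.reset_index(drop=True), self.trait1 if which == 1 else self.trait2)

    def subset(self, mask) -> "PairedStats":
        """Row subset preserving provenance counts."""
        return PairedStats(
            self.table.loc[mask].reset_index(drop=True), self.trait1, self.trait2,
            self.n_intersected, self.n_dropped_unresolvable, self.n_dropped_palindromic,
        )


def read_sumstats(
    path,
    dialect: dict[str, str] | None = None,
    trait_name: str | None = None,
    sep: str = "\t",
    report_sidecar: bool = False,
) -> SumStats:
    """Read a delimited summary-statistics file into a validated :class:`SumStats`.

    ``dialect`` maps internal field names (``snp, chrom, pos, allele_effect,
    allele_other, pval`` and either ``effect`` or ``odds_ratio``) to the
    file's column names; by default the canonical ``SNP/CHR/BP/A1/A2/P/BETA``
    header is expected, with ``OR`` accepted in place of ``BETA`` and
    log-transformed on read.  Rows failing validation (p outside (0, 1],
    identical alleles, non-finite effect, duplicate rsID) are dropped and
    counted in the attached :class:`LoadReport`.
    """
    if dialect is None:
        dialect = dict(CANONICAL_DIALECT)
    raw = pd.read_csv(path, sep=sep)

    # resolve the effect column: a signed log-odds (BETA-style) column wins,
    # otherwise an odds-ratio column is log-transformed
    colmap = {}
    for internal in ["snp", "chrom", "pos", "allele_effect", "allele_other", "pval"]:
        col = dialect.get(internal)
        if col is None or col not in raw.columns:
            raise ValueError(f"required column {internal!r} (file column {col!r}) not found in {path}")
        colmap[internal] = col

    effect_col = dialect.get("effect")
    or_col = dialect.get("odds_ratio", "OR" if "OR" in raw.columns else None)
    if effect_col is not None and effect_col in raw.columns:
        effect = pd.to_numeric(raw[effect_col], errors="coerce")
    elif or_col is not None and or_col in raw.columns:
        orv = pd.to_numeric(raw[or_col], errors="coerce")
        with np.errstate(divide="ignore", invalid="ignore"):
            effect = np.log(orv.where(orv > 0))
    else:
        raise ValueError(f"required column 'effect' (BETA) or 'odds_ratio' (OR) not found in {path}")

    df = pd.DataFrame(
        {
            "snp": raw[colmap["snp"]].astype(str),
            "chrom": raw[colmap["chrom"]].astype(str),
            "pos": pd.to_numeric(raw[colmap["pos"]], errors="coerce"),
            "allele_effect": raw[colmap["allele_effect"]].astype(str).str.upper(),
            "allele_other": raw[colmap["allele_other"]].astype(str).str.upper(),
            "pval": pd.to_numeric(raw[colmap["pval"]], errors="coerce"),
            "effect": np.asarray(effect, dtype=float),
        }
    )

    report = LoadReport(n_rows=len(df))
    ok_p = (df["pval"] > 0) & (df["pval"] <= 1)
    report.n_bad_pval = int((~ok_p).sum())
    df = df[ok_p]

    ok_eff = np.isfinite(df["effect"]) & np.isfinite(df["pos"])
    report.n_bad_effect = int((~ok_eff).sum())
    df = df[ok_eff]

    ok_al = df["allele_effect"] != df["allele_other"]
    report.n_bad_alleles = int((~ok_al).sum())
    df = df[ok_al]

    dup = df.duplicated(subset="snp", keep="first")
    report.n_duplicate = int(dup.sum())
    df = df[~dup]

    df = df.assign(pos=df["pos"].astype(np.int64)).reset_index(drop=True)
    report.n_kept = len(df)
    if report.n_kept == 0:
        raise ValueError(f"no valid rows in {path}")
    if report.n_dropped:
        logger.info("read_sumstats(%s): dropped %d/%d rows (%s)",
                    path, report.n_dropped, report.n_rows, report.to_dict())
    if report_sidecar:
        with open(f"{path}.report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)

    name = trait_name if trait_name is not None else str(path)
    return SumStats(df, trait_name=name, load_report=report)


def write_sumstats(s: SumStats, path, sep: str = "\t") -> None:
    """Write in the canonical dialect; ``read_sumstats`` round-trips the table."""
    out = s.table[_INTERNAL_COLUMNS].copy()
    out.columns = [CANONICAL_DIALECT[c] for c in _INTERNAL_COLUMNS]
    out.to_csv(path, sep=sep, index=False)


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | \
           ((a1 == "C") & (a2 == "G")) | ((a1 == "G") & (a2 == "C"))


def harmonize_pair(s1: SumStats, s2: SumStats, drop_palindromic: bool = True) -> PairedStats:
    """Intersect two traits by rsID and align trait-2 effects to trait-1 alleles.

    Variants whose alleles in the second trait are the swap of the first
    trait's have ``effect2`` negated; variants whose allele pairs cannot be
    reconciled are dropped and counted.  Strand-ambiguous (A/T, C/G) variants
    are dropped by default because strand cannot be resolved without allele
    frequencies.  Harmonizing an already-harmonized pair is a no-op.
    """
    m = s1.table.merge(s2.table, on="snp", suffixes=("1", "2"), how="inner")
    if len(m) == 0:
        raise ValueError("empty variant intersection between traits "
                         f"{s1.trait_name!r} and {s2.trait_name!r}")

    same = (m["allele_effect1"] == m["allele_effect2"]) & (m["allele_other1"] == m["allele_other2"])
    swapped = (m["allele_effect1"] == m["allele_other2"]) & (m["allele_other1"] == m["allele_effect2"])

    effect2 = np.where(swapped, -m["effect2"], m["effect2"])
    resolvable = same | swapped
    n_unresolvable = int((~resolvable).sum())

    pal = _is_palindromic(m["allele_effect1"], m["allele_other1"])
    keep = resolvable
    n_palindromic = 0
    if drop_palindromic:
        n_palindromic = int((resolvable & pal).sum())
        keep = resolvable & ~pal

    out = pd.DataFrame(
        {
            "snp": m["snp"],
            "chrom": m["chrom1"],
            "pos": m["pos1"],
            "allele_effect": m["allele_effect1"],
            "allele_other": m["allele_other1"],
            "pval1": m["pval1"],
            "pval2": m["pval2"],
            "effect1": m["effect1"],
            "effect2": effect2,
        }
    )[keep].reset_index(drop=True)

    if len(out) == 0:
        raise ValueError("no variants survive allele harmonization")
    return PairedStats(
        out, s1.trait_name, s2.trait_name,
        n_intersected=len(m),
        n_dropped_unresolvable=n_unresolvable,
        n_dropped_palindromic=n_palindromic,
    )


def genomic_correction(s: SumStats, min_snps: int = 100) -> SumStats:
    """Apply genomic control: deflate chi-squares by lambda when lambda > 1.

    lambda is the median of the 1-df chi-square statistics implied by the
    p-values divided by the null median (:data:`CHI2_NULL_MEDIAN`).  When
    lambda <= 1 the p-values are returned unchanged; when the input holds
    fewer than ``min_snps`` variants the estimate is unreliable and lambda is
    forced to 1 with a warning.  Rank order of p-values is preserved exactly.
    """
    pvals = s.table["pval"].to_numpy()
    chi2 = stats.chi2.isf(pvals, df=1)
    if len(pvals) < min_snps:
        warnings.warn(
            f"genomic_correction: only {len(pvals)} variants (<{min_snps}); "
            "lambda forced to 1", stacklevel=2)
        lam = 1.0
    else:
        lam = float(np.median(chi2) / CHI2_NULL_MEDIAN)

    out = s.copy()
    if lam > 1:
        new_p = stats.chi2.sf(chi2 / lam, df=1)
        out.table["pval"] = np.maximum(new_p, P_MIN)
    out.gc_lambda = lam
    return out
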