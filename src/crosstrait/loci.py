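"""LD-aware locus post-processing.

Greedy clumping of conjunction-FDR-ranked SNPs, exclusion of a named genomic
region (e.g. the extended MHC/HLA interval on chromosome 6) together with
everything in LD with it, direction-of-effect concordance classification,
nearest-gene annotation against user-supplied interval files, and the
summary locus-filter report (input loci -> discordant removed -> LD
duplicates removed -> surviving loci).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomicRegion", "HLA_REGION", "LdTable", "GeneAnnotation",
    "ld_clump", "exclude_region_ld", "direction_concordance",
    "nearest_gene", "locus_filter_report", "read_bed", "read_ld", "write_ld",
]


@dataclass(frozen=True)
class GenomicRegion:
    """1-based inclusive genomic interval on a single chromosome."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"malformed region: start {self.start} > end {self.end}")

    def contains(self, chrom, pos) -> bool:
        return str(chrom) == self.chrom and self.start <= pos <= self.end


#: Default named HLA region: the extended MHC on chromosome 6 (GRCh37
#: convention, chr6:25-35 Mb).  Configurable wherever it is used.
HLA_REGION = GenomicRegion("6", 25_000_000, 35_000_000, name="HLA")


class LdTable:
    """Sparse symmetric map of pairwise LD: (rsID, rsID) -> r^2 (optionally D').

    Self-pairs have implicit r^2 = 1; absent pairs are treated as unlinked
    (r^2 = 0).
    """

    def __init__(self):
        self._adj: dict[str, dict[str, float]] = {}
        self._dprime: dict[tuple[str, str], float] = {}

    def __len__(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float, dprime: float | None = None) -> None:
        if a == b:
            return
        if not (0 <= r2 <= 1):
            raise ValueError(f"r2 must be in [0, 1], got {r2}")
        self._adj.setdefault(a, {})[b] = float(r2)
        self._adj.setdefault(b, {})[a] = float(r2)
        if dprime is not None:
            self._dprime[self._key(a, b)] = float(dprime)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def dprime(self, a: str, b: str) -> float | None:
        if a == b:
            return 1.0
        return self._dprime.get(self._key(a, b))

    def neighbors(self, a: str) -> dict[str, float]:
        return self._adj.get(a, {})

    def pairs(self):
        """Iterate unique (a, b, r2) with a < b."""
        for a, nbrs in self._adj.items():
            for b, r2 in nbrs.items():
                if a < b:
                    yield a, b, r2

    @classmethod
    def from_pairs(cls, pairs) -> "LdTable":
        """Build from an iterable of (id_a, id_b, r2) or (id_a, id_b, r2, dprime)."""
        t = cls()
        for rec in pairs:
            t.set(*rec)
        return t

    @classmethod
    def from_blocks(cls, blocks, r2: float, dprime: float | None = None) -> "LdTable":
        """All within-block pairs share one r^2 (exchangeable-LD blocks)."""
        t = cls()
        for ids in blocks:
            ids = list(ids)
            for i in range(len(ids)):
                for j in range(i + 1, len(ids)):
                    t.set(ids[i], ids[j], r2, dprime)
        return t


def read_ld(path, sep: str = "\t") -> LdTable:
    """Read a 3- or 4-column LD text table (id_a, id_b, r2[, dprime])."""
    df = pd.read_csv(path, sep=sep)
    cols = list(df.columns)
    has_dp = len(cols) >= 4
    t = LdTable()
    for rec in df.itertuples(index=False):
        t.set(str(rec[0]), str(rec[1]), float(rec[2]), float(rec[3]) if has_dp else None)
    return t


def write_ld(ld: LdTable, path, sep: str = "\t") -> None:
    rows = [{"id_a": a, "id_b": b, "r2": r2} for a, b, r2 in sorted(ld.pairs())]
    pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(path, sep=sep, index=False)


@dataclass
class GeneAnnotation:
    """Gene/region intervals, 1-based inclusive.

    ``intervals`` columns: ``chrom, start, end, name`` and optionally
    ``strand`` ('+'/'-').  Named regions (e.g. an HLA interval) live in
    ``regions``.
    """

    intervals: pd.DataFrame
    regions: dict[str, GenomicRegion] = field(default_factory=dict)

    def __post_init__(self):
        if (self.intervals["start"] > self.intervals["end"]).any():
            raise ValueError("annotation has interval with start > end")
        if self.intervals["name"].duplicated().any():
            raise ValueError("annotation names must be unique")

    def on_chrom(self, chrom) -> pd.DataFrame:
        return self.intervals[self.intervals["chrom"] == str(chrom)]


def read_bed(path, sep: str = "\t") -> GeneAnnotation:
    """Read a BED-style file (0-based half-open) into 1-based inclusive intervals."""
    df = pd.read_csv(path, sep=sep, header=None, comment="#")
    df = df.rename(columns={0: "chrom", 1: "start", 2: "end", 3: "name", 5: "strand"})
    keep = [c for c in ["chrom", "start", "end", "name", "strand"] if c in df.columns]
    df = df[keep].copy()
    df["chrom"] = df["chrom"].astype(str).str.removeprefix("chr")
    df["start"] = df["start"].astype(int) + 1  # to 1-based inclusive
    df["end"] = df["end"].astype(int)
    if "name" not in df.columns:
        df["name"] = [f"interval_{i}" for i in range(len(df))]
    return GeneAnnotation(df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# clumping and filtering


def _rank_records(records: pd.DataFrame) -> pd.DataFrame:
    """Total rank order: conjunction FDR ascending, ties by primary-trait p
    then lexicographic rsID.  Makes clumping independent of input order."""
    return records.sort_values(["conj_fdr", "pval1", "snp"], kind="mergesort").reset_index(drop=True)


def ld_clump(records: pd.DataFrame, ld: LdTable, r2_thresh: float = 0.2) -> pd.DataFrame:
    """Greedy LD clumping of ranked locus records.

    Records are scanned in rank order (conjunction FDR ascending, ties by
    primary p then rsID); a record is pruned iff its r^2 with any retained
    higher-ranked record exceeds ``r2_thresh``.  Returns the ranked table
    with boolean ``lead`` and ``pruned`` columns.
    """
    out = _rank_records(records)
    kept: set[str] = set()
    lead = np.zeros(len(out), dtype=bool)
    for i, snp in enumerate(out["snp"]):
        nbrs = ld.neighbors(snp)
        pruned = any(other in kept and r2 > r2_thresh for other, r2 in nbrs.items())
        if not pruned:
            kept.add(snp)
            lead[i] = True
    out["lead"] = lead
    out["pruned"] = ~lead
    return out


def exclude_region_ld(pair, region: GenomicRegion, ld: LdTable,
                      window: int = 1_000_000, r2_thresh: float = 0.2):
    """Remove a region, its flanks, and everything in LD with the removed SNPs.

    Removes (a) SNPs inside ``region``, (b) SNPs within ``window`` of the
    region boundary, and (c) SNPs anywhere with r^2 > ``r2_thresh`` to any
    SNP removed by (a) or (b).  Returns ``(filtered_pair, report_dict)``.
    """
    t = pair.table
    chrom_match = t["chrom"].astype(str) == region.chrom
    inside = chrom_match & (t["pos"] >= region.start) & (t["pos"] <= region.end)
    near = chrom_match & (t["pos"] >= region.start - window) & (t["pos"] <= region.end + window)

    seeds = set(t.loc[near, "snp"])
    linked = {
        other
        for snp in seeds
        for other, r2 in ld.neighbors(snp).items()
        if r2 > r2_thresh
    } - seeds
    removed = seeds | linked

    keep_mask = ~t["snp"].isin(removed)
    report = {
        "region": region.name or f"{region.chrom}:{region.start}-{region.end}",
        "n_inside": int(inside.sum()),
        "n_window": int((near & ~inside).sum()),
        "n_ld_linked": int(t["snp"].isin(linked).sum()),
        "n_removed": int((~keep_mask).sum()),
        "n_remaining": int(keep_mask.sum()),
    }
    return pair.subset(keep_mask.to_numpy()), report


def direction_concordance(sign1: float, sign2: float) -> str:
    """Classify a sign pair as ``"concordant"`` or ``"discordant"``.

    Discordant iff the signs differ; a zero effect is classified concordant
    with a warning (direction is undefined).
    """
    if sign1 == 0 or sign2 == 0:
        warnings.warn("zero effect: direction undefined, classified concordant", stacklevel=2)
        return "concordant"
    return "discordant" if sign1 * sign2 < 0 else "concordant"


def nearest_gene(chrom, pos: int, ann: GeneAnnotation) -> str:
    """Name of the gene interval closest to (chrom, pos); distance 0 if inside.

    Ties are broken by smaller interval start, then name.  Returns
    ``"none"`` when the chromosome has no annotated genes.
    """
    genes = ann.on_chrom(chrom)
    if len(genes) == 0:
        return "none"
    start = genes["start"].to_numpy()
    end = genes["end"].to_numpy()
    dist = np.where((start <= pos) & (pos <= end), 0,
                    np.minimum(np.abs(pos - start), np.abs(pos - end)))
    order = np.lexsort((genes["name"].to_numpy(), start, dist))
    return str(genes["name"].to_numpy()[order[0]])


def locus_filter_report(records: pd.DataFrame, ld: LdTable,
                        region: GenomicRegion = HLA_REGION,
                        r2_thresh: float = 0.2,
                        discordant_first: bool = True) -> dict:
    """Filter conjunction-FDR-selected loci and report the counts.

    ``records`` must carry ``snp, chrom, conj_fdr, pval1, sign1, sign2`` and
    may carry ``pos`` and/or a precomputed boolean ``in_region`` column.
    Direction-discordant records are removed, LD duplicates are clumped away
    (discordant removal first by default), and the report counts input,
    discordant, pruned and surviving loci plus how many survivors fall on
    the named region's chromosome and inside the region itself.
    """
    records = records.reset_index(drop=True)
    discordant = (records["sign1"] * records["sign2"]) < 0

    if discordant_first:
        concordant = records[~discordant]
        clumped = ld_clump(concordant, ld, r2_thresh=r2_thresh)
        n_pruned = int(clumped["pruned"].sum())
        survivors = clumped[clumped["lead"]].reset_index(drop=True)
        n_discordant = int(discordant.sum())
    else:
        clumped = ld_clump(records, ld, r2_thresh=r2_thresh)
        n_pruned = int(clumped["pruned"].sum())
        leads = clumped[clumped["lead"]]
        disc_leads = (leads["sign1"] * leads["sign2"]) < 0
        n_discordant = int(disc_leads.sum())
        survivors = leads[~disc_leads].reset_index(drop=True)

    on_chrom = survivors["chrom"].astype(str) == region.chrom
    if "in_region" in survivors.columns:
        in_region = survivors["in_region"].astype(bool)
    elif "pos" in survivors.columns and survivors["pos"].notna().all():
        in_region = on_chrom & (survivors["pos"] >= region.start) & (survivors["pos"] <= region.end)
    else:
        in_region = pd.Series(False, index=survivors.index)

    return {
        "n_input": len(records),
        "n_discordant": n_discordant,
        "n_pruned": n_pruned,
        "n_surviving": len(survivors),
        "n_surviving_on_region_chrom": int(on_chrom.sum()),
        "n_surviving_in_region": int(in_region.sum()),
        "survivors": survivors,
    }
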