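"""End-to-end pipeline: read -> correct -> harmonize -> enrich -> conjunction
FDR -> clump -> locus report, with an optional region-exclusion rerun.

Every run directory carries a manifest (config hash, seed, package version)
and rerunning the same configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrich import DEFAULT_STRATA, excluded_region_rerun, fold_enrichment
from .fdr import build_lookup, conj_fdr
from .loci import GenomicRegion, HLA_REGION, LdTable, locus_filter_report, read_ld
from .simulate import SimParams, simulate_pair
from .sumstats import genomic_correction, harmonize_pair, read_sumstats

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Single-file configuration for one pipeline run.

    Either both ``trait1_path``/``trait2_path`` (plus optionally
    ``ld_path``) are set, or ``simulate`` carries generator parameters and
    the inputs are drawn synthetically.
    """

    trait1_path: str | None = None
    trait2_path: str | None = None
    ld_path: str | None = None
    dialect: dict | None = None
    simulate: dict | None = None
    strata: tuple = DEFAULT_STRATA
    grid_points: int = 301
    fdr_threshold: float = 0.05
    n_bins: int = 200
    clump_r2: float = 0.2
    exclusion_window: int = 1_000_000
    region: dict | None = field(
        default_factory=lambda: {"chrom": HLA_REGION.chrom, "start": HLA_REGION.start,
                                 "end": HLA_REGION.end, "name": HLA_REGION.name})
    exclude_region_rerun: bool = False
    discordant_first: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.fdr_threshold < 1):
            raise ValueError("fdr_threshold must be in (0, 1)")
        if not (0 <= self.clump_r2 <= 1):
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.exclusion_window < 0:
            raise ValueError("exclusion_window must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["strata"] = list(d["strata"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "strata" in raw:
            raw["strata"] = tuple(raw["strata"])
        return cls(**raw)

    def named_region(self) -> GenomicRegion | None:
        if self.region is None:
            return None
        return GenomicRegion(str(self.region["chrom"]), int(self.region["start"]),
                             int(self.region["end"]), self.region.get("name", ""))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write result tables, logs and a manifest.

    Returns a summary dict with the locus report counts and paths of the
    written outputs.  Any stage's hard error propagates with the stage name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # --- inputs
    truth = None
    if config.simulate is not None:
        params = SimParams(**{**config.simulate, "seed": config.seed})
        s1, s2, truth, ld = _stage("simulate", simulate_pair, params)
    else:
        if config.trait1_path is None or config.trait2_path is None:
            raise RuntimeError("pipeline stage 'read' failed: no input paths and no simulate block")
        s1 = _stage("read", read_sumstats, config.trait1_path, dialect=config.dialect)
        s2 = _stage("read", read_sumstats, config.trait2_path, dialect=config.dialect)
        ld = _stage("read_ld", read_ld, config.ld_path) if config.ld_path else LdTable()

    # --- genomic control and harmonization
    s1 = _stage("genomic_correction", genomic_correction, s1)
    s2 = _stage("genomic_correction", genomic_correction, s2)
    pair = _stage("harmonize", harmonize_pair, s1, s2,
                  **({"drop_palindromic": False} if config.simulate is not None else {}))

    # --- stratified fold enrichment
    grid = np.linspace(0.0, 7.3, config.grid_points)
    curve = _stage("enrich", fold_enrichment, pair, strata=config.strata, grid=grid)
    _write_tsv(curve.to_frame(), outdir / "enrichment.tsv")
    outputs["enrichment"] = "enrichment.tsv"

    # --- conditional/conjunction FDR
    lookup12 = _stage("fdr", build_lookup, pair, n_bins=config.n_bins)
    lookup21 = _stage("fdr", build_lookup, pair.swap(), n_bins=config.n_bins)
    conj = _stage("fdr", conj_fdr, pair, lookup12, lookup21, threshold=config.fdr_threshold)
    _write_tsv(conj.table, outdir / "conjfdr.tsv")
    outputs["conjfdr"] = "conjfdr.tsv"

    # --- locus records at threshold, concordance + clumping
    sel = conj.selected()
    eff = pair.table.set_index("snp")
    records = pd.DataFrame({
        "snp": sel["snp"], "chrom": sel["chrom"].astype(str), "pos": sel["pos"],
        "conj_fdr": sel["conj_fdr"], "pval1": sel["pval1"],
        "sign1": np.sign(eff.loc[sel["snp"], "effect1"].to_numpy()),
        "sign2": np.sign(eff.loc[sel["snp"], "effect2"].to_numpy()),
    })
    region = config.named_region() or HLA_REGION
    report = _stage("report", locus_filter_report, records, ld, region=region,
                    r2_thresh=config.clump_r2, discordant_first=config.discordant_first)
    survivors = report.pop("survivors")
    _write_tsv(survivors, outdir / "loci.tsv")
    outputs["loci"] = "loci.tsv"

    manhattan = survivors.assign(
        neglog10_conj_fdr=-np.log10(survivors["conj_fdr"]),
        trait_pair=f"{pair.trait1}|{pair.trait2}", lead=True,
    )[["chrom", "pos", "neglog10_conj_fdr", "trait_pair", "lead", "snp"]]
    _write_tsv(manhattan, outdir / "manhattan.tsv")
    outputs["manhattan"] = "manhattan.tsv"

    # --- optional region-exclusion rerun of the enrichment analysis
    if config.exclude_region_rerun and region is not None:
        curve_excl, excl_report = _stage(
            "exclude_region", excluded_region_rerun, pair, region, ld,
            window=config.exclusion_window, r2_thresh=config.clump_r2,
            strata=config.strata, grid=grid)
        _write_tsv(curve_excl.to_frame(), outdir / "enrichment_excluded.tsv")
        outputs["enrichment_excluded"] = "enrichment_excluded.tsv"
        report["region_exclusion"] = excl_report

    # --- manifest and report
    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "crosstrait_version": __version__,
        "gc_lambda": {"trait1": s1.gc_lambda, "trait2": s2.gc_lambda},
        "outputs": outputs,  # file names relative to the run directory
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump({k: v for k, v in report.items()}, fh, indent=2, sort_keys=True)

    summary = dict(report)
    summary["outputs"] = outputs
    summary["gc_lambda"] = manifest["gc_lambda"]
    if truth is not None:
        summary["truth_available"] = True
    return summary
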