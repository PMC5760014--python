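# crosstrait

Cross-trait pleiotropy analysis of GWAS summary statistics.

`crosstrait` is for statistical geneticists who have *summary statistics*
(p-values and odds ratios / log-odds) from two genome-wide association
studies and want to ask whether the two traits share risk variants — for
example whether variants associated with frontotemporal dementia are also
associated with immune-mediated diseases. It implements:

- **Stratified fold enrichment** — for primary threshold t and cumulative
  secondary stratum c,
  `FE(t, c) = P(−log10 p₁ ≥ t | −log10 p₂ ≥ c) / P(−log10 p₁ ≥ t)`,
  restricted to sub-genome-wide signal (−log10 p₁ < 7.3) and readable as a
  stratified true discovery rate (TDR = 1 − FDR).
- **Conditional and conjunction FDR** — the empirical-Bayes estimator
  `condFDR(p₁|p₂) = min(1, p₁ / F̂(p₁|p₂))` with π₀ = 1, where `F̂` is the
  empirical cdf of p₁ among SNPs with secondary p-value ≤ p₂, computed on a
  binned 2-D lookup with a brute-force oracle; the conjunction FDR
  `conjFDR = max(condFDR₁|₂, condFDR₂|₁)` pinpoints SNPs jointly associated
  with both traits.
- **LD-aware locus reporting** — allele harmonization, genomic control,
  greedy r² > 0.2 clumping of conjFDR-ranked SNPs, direction-of-effect
  concordance, nearest-gene annotation, and exclusion of a named region
  (e.g. the extended MHC/HLA interval) together with everything in LD
  with it.
- **Expression follow-up** — additive-model ANCOVA cis-eQTL tests (1-Mb TSS
  window, Bonferroni p < 3.9×10⁻⁵), pooled-region two-group differential
  expression (Welch), and argmax cell-type assignment across brain cell
  classes.
- **A synthetic-data generator** with known ground truth (four-component
  null / trait-specific / pleiotropic causal mixture over
  exchangeable-correlation LD blocks), used by the test suite and usable
  for power studies.

See `docs/methods.md` for the model, estimators, defaults and limitations.

## Worked example

The package ships a published worked-example table of 21 SNPs jointly
associated with frontotemporal dementia and one or more immune-mediated
diseases at conjunction FDR < 0.05, plus the one published LD fact for that
table (rs204989–rs204991, r² = 1):

```python
from crosstrait import locus_filter_report, HLA_REGION
from crosstrait.simulate import (load_ftd_immune_loci, ftd_immune_ld,
                                 locus_records_from_table)

records = locus_records_from_table(load_ftd_immune_loci())
report = locus_filter_report(records, ftd_immune_ld(), region=HLA_REGION)
survivors = report.pop("survivors")
print(report)
print(survivors[["snp", "chrom", "nearest_gene", "conj_fdr"]].head(4).to_string(index=False))
```

prints

```
{'n_input': 21, 'n_discordant': 5, 'n_pruned': 1, 'n_surviving': 15,
 'n_surviving_on_region_chrom': 8, 'n_surviving_in_region': 7}
      snp chrom nearest_gene     conj_fdr
rs9268852     6      HLA-DRA 1.250000e-07
rs3129890     6      HLA-DRA 5.540000e-05
rs3117097     6        BTNL2 8.210000e-05
rs3135353     6      HLA-DRA 3.580000e-03
```

Reading: of the 21 selected SNPs, 5 have opposite directions of allelic
effect in the two traits and are removed, the rs204991/rs204989 pair
(r² = 1) collapses to one locus, and 15 loci survive — 8 of them on
chromosome 6, 7 inside the strict extended-MHC interval (the published
chromosome-6 count includes a 6p12 locus outside it). The most significant
surviving loci sit in the HLA region.

The same stages run end-to-end on files or synthetic data from the command
line:

```bash
crosstrait simulate --m-snps 20000 --seed 1 --out sim/
crosstrait enrich  --trait1 sim/trait1.tsv --trait2 sim/trait2.tsv --out enrich.tsv
crosstrait conjfdr --trait1 sim/trait1.tsv --trait2 sim/trait2.tsv --out conj.tsv
crosstrait run --config pipeline.yaml --out run/   # full pipeline + manifest
```

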