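# Methods

## The analysis

`crosstrait` implements a cross-trait pleiotropy analysis for paired GWAS
summary statistics, of the kind used to ask whether variants associated with
one disorder (the *primary* trait, e.g. frontotemporal dementia) are
systematically shared with a second disorder (the *secondary* trait, e.g. an
immune-mediated disease), using only per-variant p-values and signed effect
estimates from the two studies.

The stages are:

1. **Harmonization** (`sumstats`). Variants are intersected by rsID and the
   secondary trait's effects are re-expressed relative to the primary
   trait's effect allele (swapped allele pairs negate the log-odds;
   irreconcilable pairs are dropped; strand-ambiguous A/T and C/G variants
   are dropped by default because strand cannot be resolved without allele
   frequencies). After this, a sign comparison between the two effects is a
   direction-of-allelic-effect comparison.
2. **Genomic control** (`sumstats.genomic_correction`). The inflation factor
   is the median of the 1-df chi-square statistics implied by the p-values
   divided by the central chi-square median (`scipy.stats.chi2.ppf(0.5, 1)`
   ≈ 0.4549). Statistics are deflated only when λ > 1. Rank order of
   p-values is preserved exactly; fewer than 100 variants forces λ = 1 with
   a warning because the median estimate is unreliable.
3. **Stratified fold enrichment** (`enrich`). For threshold t on
   −log10 p₁ and cumulative secondary stratum c (−log10 p₂ ≥ c),

       FE(t, c) = P(−log10 p₁ ≥ t | stratum c) / P(−log10 p₁ ≥ t),

   so the all-SNP baseline (c = 0) is identically 1 and upward deflection
   with increasing c is evidence of shared signal. The grid is 301 equally
   spaced points on [0, 7.3] — capped below the genome-wide significance
   boundary (p = 5×10⁻⁸) to focus on sub-threshold polygenic signal. The
   surface reads as a stratified Bayes true discovery rate via
   FDR(t, c) = p(t) / P(p₁ ≤ p(t) | stratum c), TDR = 1 − FDR.
4. **Conditional and conjunction FDR** (`fdr`). The conditional FDR is the
   empirical-Bayes estimator condFDR(p₁|p₂) = min(1, p₁ / F̂(p₁|p₂)) with
   F̂ the empirical cdf of p₁ among SNPs with p-value for the secondary
   trait at or below p₂, and a conservative null proportion π₀ = 1. The
   conjunction FDR — the posterior probability that a SNP is null for
   either or both traits — is the maximum of the two conditional FDRs taken
   in both orientations. A 200-bin-per-axis lookup over −log10 p ∈ [0, 20]
   (p floored at 1e−20) precomputes the estimator at bin edges; per-SNP
   values are clamped bilinear interpolations. Monotonization (running
   minimum toward increasing significance on both axes) is on by default;
   with it off, the lookup equals the direct estimator exactly at bin-edge
   queries, which is how the lookup is validated against the brute-force
   oracle.
5. **Locus post-processing** (`loci`). SNPs at conjunction FDR < 0.05 are
   ranked (conjFDR ascending, ties by primary p then rsID) and greedily
   clumped: a SNP is pruned iff r² > 0.2 with a retained higher-ranked SNP.
   Direction-discordant SNPs (sign₁·sign₂ < 0) are removed before LD dedup
   by default (configurable, since the order of the two filters is a
   reporting convention). Region exclusion removes a named interval (the
   default HLA region is the extended MHC, chr6:25–35 Mb, GRCh37
   convention), a 1-Mb flank, and every SNP with r² > 0.2 to a removed SNP,
   then the enrichment analysis can be rerun on the remainder.
6. **Expression follow-up** (`expression`). cis-eQTL candidate pairs are
   variants within 1 Mb (inclusive) of a gene's transcription start site
   (interval start on +, end on − strand). The association test is an
   additive-model ANCOVA: OLS of expression on dosage (0/1/2) plus optional
   covariates, gated at a strict Bonferroni threshold p < 3.9×10⁻⁵.
   Differential expression pools samples across brain regions (samples
   treated as independent; a region covariate is available behind a flag)
   and applies Welch's two-sided t-test per gene, marking p ≤ 0.05; the test
   is injectable because two-group microarray comparisons at this scale are
   also often run with moderated statistics. Cell-type assignment is the
   argmax of a gene's mean expression across the surveyed brain cell
   classes, ties broken by a fixed canonical order (neurons first,
   pericytes last), with genes absent from the profile reported as
   "not found".

## The synthetic-data generator

`simulate.simulate_pair` draws paired z-scores from a four-component causal
mixture (null / trait-1-only / trait-2-only / pleiotropic) over
exchangeable-correlation LD blocks: within a block, z ~ MVN with unit
variances, correlation `r_within`, and mean √n_t · (R·β_t) where R is the
block correlation matrix — so causal signal is smeared onto LD partners the
way clumping assumes. Pleiotropic effect pairs are bivariate normal with
correlation `rho_effect`. Two-sided normal-tail p-values; an optional
variance inflation ≥ 1 emulates genomic inflation.

Defaults, frozen as the package's study conditions: m = 20,000 SNPs in
blocks of 10 at z-correlation 0.8; mixture (0.988, 0.005, 0.005, 0.002);
per-trait causal effect sd 0.05 on the log-odds scale (OR ≈ 1.05, the
common-variant scale); effect correlation 0.8; effective sample sizes
n₁ = 6,000 and n₂ = 25,000, the scale of a modest clinical-cohort GWAS
against a well-powered immune-disease GWAS. Blocks are laid out round-robin
over 22 chromosomes at 10-kb SNP spacing.

What the generator does *not* emulate: realistic MAF spectra, genotype-level
sampling, variable LD (blocks are exchangeable with a single r), population
structure, or overlapping control samples between studies. Tests passing on
this generator show the estimators behave as designed under their own
assumptions; they do not certify behaviour under real LD or stratification.

`simulate_expression` plants per-gene eQTL slopes (dosage ~ Binomial(2, maf))
and a group shift on half the genes, with round-robin region labels, for
exercising the expression stages with known truth.

A packaged worked-example table (`load_ftd_immune_loci`) carries 21
published FTD–immune pleiotropic SNPs (conjunction FDR < 0.05) with their
chromosome, nearest gene, reference immune disease, p-values, minimum
conjunction FDR and direction-of-effect pair, stored exactly as printed and
parsed to floats on load; the only published LD fact for the table
(rs204989–rs204991, D′ = 1, r² = 1) ships as `ftd_immune_ld()`. Running the
locus filter on it reproduces the published counts: 21 selected → 5
discordant removed → 1 LD duplicate pruned → 15 loci, 8 on chromosome 6.
The report exposes both "on the region's chromosome" (8; the published
count includes a 6p12 locus outside the strict MHC interval) and "inside
the named region" (7).

## Numerical choices and edge cases

- Duplicate rsIDs keep the first occurrence; coordinates are 1-based
  internally (BED input converted on read).
- p-values are validated into (0, 1]; corrected p-values are floored at
  1e−300 to avoid underflow to zero; binning floors p at 1e−20.
- Empty strata: fold-enrichment columns are flagged NaN, not an error;
  empty conditional-FDR strata return 1 (maximally conservative).
- Clump ties (equal conjFDR and equal primary p) resolve lexicographically
  by rsID, making clumping a pure function of the record set.
- Zero effects classify as concordant with a warning (direction undefined).
- A constant dosage vector in the eQTL test is flagged per pair, not fatal;
  a numerically perfect fit reports the smallest positive p-value.
- Degenerate equal-value groups in differential expression report p = 1.

## Experiment designs used by the acceptance checks

Problem sizes were chosen so each check completes in minutes on one core
while leaving Monte-Carlo noise well inside the asserted bands:
null-calibration uses 50 replicates of m = 20,000 independent null pairs
(with r_within = 0 so the Kolmogorov–Smirnov and cdf-calibration statistics
apply to independent draws); the discovery experiment uses 100 replicates of
m = 50,000 at the default mixture; λ-recovery uses m = 100,000 independent
SNPs with a planted inflation of 2 (independence keeps the sampling sd of
the median-based estimate ≈ 0.02, well inside the ±0.1 band).

## Known limitations

- **Locus-level FDP after clumping is not controlled at the nominal
  conjunction-FDR threshold.** Measured on the default generator: among
  SNPs flagged at conjFDR < 0.05 the proportion whose LD block contains no
  truly pleiotropic variant is ≈ 0.16, but after clumping to one SNP per
  block it rises to ≈ 0.31. The mechanism is structural: each true
  pleiotropic block contributes many flagged SNPs that collapse into a
  single lead, while chance coincidences (a SNP with moderate p in both
  traits riding the stratum enrichment created by genuine pleiotropic
  blocks, or a trait-specific block with a chance p in the other trait)
  each occupy their own block and survive clumping untouched. The nominal
  threshold therefore describes SNP-tail FDR, not post-dedup locus FDP;
  users who need locus-level control should threshold more stringently.
- π₀ = 1 is conservative when either trait has substantial polygenic
  signal; no local-fdr density estimation is attempted.
- The empirical conditional cdf is noisy in extreme, sparsely populated
  secondary strata; monotonization regularizes but does not remove this.
- Genomic control assumes the median chi-square is null-dominated; under
  heavy polygenicity it overcorrects.
- Effect-direction concordance assumes both studies report effects on a
  comparable log-odds scale after allele alignment.
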