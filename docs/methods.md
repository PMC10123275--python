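# Methods

## Sex-dimorphism screen

The screen compares per-SNP effect estimates from sex-stratified GWAS
strata. Because the female and male strata are disjoint samples, their
estimation errors are independent and the difference statistic

z = (β_f − β_m) / √(SE_f² + SE_m²)

is standard normal under the null of equal effects. The two-sided p-value
2·(1 − Φ(|z|)) is used throughout: the published score/p pairs
(3.196 → 0.0014, 4.27 → 0.00002, 0.38 → 0.70) are all consistent with the
two-sided convention and not with the one-sided one. A SNP is called
sex-dimorphic at |z| ≥ 3 (inclusive) and trait-associated at a strict
p < 5×10⁻⁸.

Harmonization runs in a fixed order: allele-consistency reconciliation
between the sex strata (merge when assignments match; negate the male β
when tested/other are swapped; exclude when irreconcilable), then
palindromic exclusion, then direction harmonization, then scoring.

* **Region bounds** are closed intervals on 1-based GRCh37 coordinates;
  boundary SNPs are included. The two default regions are the *CKB* gene
  ± 500 kb (chr14:103,486,004–104,489,167) and the merged
  *CKMT1B*/*GATM* interval (chr15:43,385,055–46,194,425), where the merged
  core keeps the two gene bodies separate so core-versus-flank tagging
  does not claim the gap between the genes.
* **Palindromic filter**: A/T or C/G allele pairs are strand-ambiguous;
  they are dropped only when the minor-allele frequency of the tested
  allele lies in the closed window [0.48, 0.52], where the strand cannot
  be inferred from frequency. Both bounds are configurable.
* **Direction harmonization** re-expresses records tested for the major
  allele (freq > 0.5): alleles swapped, both betas negated, frequency
  complemented. Frequency exactly 0.5 is left untouched (the tested
  allele is not strictly major); the operation is idempotent and never
  changes |z|, hence never the dimorphism call.
* **Frequency-free mode**: datasets without an allele-frequency column
  (some consortium downloads omit it) cannot be harmonized; by default
  the screen then only flags per-SNP GWAS p-values and computes no
  z-scores. A force flag scores anyway, with a logged warning that signs
  are not strand-safe.
* **Missing fields**: a record missing any of the four score inputs is
  excluded with a logged reason rather than imputed.

## Variant statistics

* **Hardy–Weinberg**: the exact conditional test — enumerate all
  heterozygote counts of the observed parity compatible with the allele
  counts, and sum the probabilities of configurations no likelier than
  the observed one. This is the only valid choice at the minor-allele
  counts of a rare-variant screen (2 carriers in 192); a χ² variant is
  available for large samples. Computation uses log-gamma weights with a
  relative tie tolerance of 1e-12.
* **Test selection policy**: the 2×3 genotype Pearson χ² (df = 2, no
  continuity correction) for common variants; the carrier-collapsed
  two-sided Fisher exact test when any expected cell is below 5. Both are
  always callable explicitly. Fisher two-sidedness follows the
  sum-of-smaller-probabilities rule (every table with hypergeometric
  point probability ≤ the observed one), not tail doubling.
* **Allele-based Fisher** accepts raw (alt, ref) allele counts, the form
  in which frequency-database control cohorts arrive.
* **TDT**: χ² = (b − c)²/(b + c) on 1 df, asymptotic p; an exact
  two-sided binomial p at p₀ = 0.5 is reported alongside because
  informative counts in candidate-gene studies are small. Transmission
  tallying from trio genotypes (0/1/2 minor-allele dosage) resolves each
  heterozygous parent against the child given the other parent; the
  double-heterozygous parents with a heterozygous child are individually
  ambiguous and contribute one transmission and one non-transmission in
  aggregate (standard TDT accounting), while being left out of the
  maternal/paternal split. Mendelian-inconsistent trios are excluded and
  counted, never repaired.
* No multiple-testing correction is applied across variants: the
  candidate-gene screen reports nominal p-values with a 0.05 threshold.

## Expression statistics

* **Pearson correlations** use pairwise-complete deletion per pair, so a
  phenotype measured in a small subset shrinks only its own n — this is
  what produces the per-pair sample sizes varying from the full cohort
  down to a few dozen. At least 3 complete pairs and non-zero variance
  are required. The 0.95 confidence interval comes from the Fisher z
  transform; the p-value from the t transform.
* **Hommel adjustment** (closure principle with Simes local tests, via
  statsmodels) is applied over one family per screen invocation — all
  pairs shown together for a depot — matching how per-panel significance
  is displayed. The family membership is configurable by simply calling
  the screen on the family wanted. Note the exchangeable edge case: m
  identical p-values adjust to p₀, not m·p₀, because the Simes statistic
  of k equal p-values is k·p₀/k.
* **Group comparisons**: Kruskal–Wallis H with tie correction;
  epsilon-squared effect size H/((n² − 1)/(n + 1)) = H/(n − 1); Dunn
  pairwise z with the standard tie-sum variance term, two-sided p-values,
  Hommel-adjusted as one family per gene.
* **Covariate adjustment**: per-gene least-squares residualization on sex
  (binary) plus age (linear by default, binned optionally), with the
  gene mean added back. This is the simplest model consistent with
  "adjusted for sex and age"; whether published correlations were
  computed before or after adjustment is not documented, so both paths
  are exposed and the synthetic tests pin the post-adjustment contract.
* **Menopause subset**: a generic age ≤ 50 sample filter; it can be
  applied to all samples or combined with a sex filter, both supported,
  default none.

## Synthetic data

The generators define the study conditions under which the pipeline is
validated; they are deterministic given the seed and always return a
truth table next to the data.

* **Summary statistics**: true per-sex effects plus independent normal
  noise at the per-sex SE (independence justified by the disjoint sex
  strata). Default 10,000 SNPs in the *CKB* ± 500 kb region with SE
  scale ≈ 0.0035, the order of magnitude implied by strata of ~4×10⁵
  individuals at common allele frequencies; 5% palindromic records with
  MAF in [0.48, 0.5]; half the records emitted with the major allele
  tested, to exercise harmonization. p-values are computed from
  beta/SE, so the file is internally consistent.
* **Trios**: parental genotypes Hardy–Weinberg at the configured
  frequency; each heterozygous parent transmits the minor allele with
  probability τ; children are assembled from the transmitted alleles and
  are therefore always Mendelian-consistent. Defaults: 781 trios,
  τ = 0.5, frequency 0.005 (the rare-variant regime of a confirmation
  cohort). Calibration scenarios that need ≥500 informative
  transmissions raise the frequency to 0.3, which yields ~650
  informative meioses at 781 trios.
* **Case-control**: controls Hardy–Weinberg at f; cases Hardy–Weinberg
  at the frequency implied by the allelic odds-ratio model
  odds_case = OR · f/(1−f). Defaults 192/192 at f = 0.39, the
  screening-cohort shape.
* **Expression**: per depot, gene vectors are multivariate normal with
  the target correlation matrices (VAT: +0.43/+0.12/+0.21; SAT:
  −0.26/−0.37/+0.12 for the three gene pairs), checked for positive
  semi-definiteness. Depot and obesity-group mean offsets and additive
  sex/age effects are applied after the correlated draw, so the planted
  correlations refer to the covariate-adjusted signal: recovery is
  asserted after residualization, mirroring the analysis pipeline, and
  the raw-scale correlations are attenuated by the shared covariate
  variance exactly as in real data. 1,479 subjects (31 non-obese) with
  paired VAT/SAT samples; phenotypes are noisy linear functions of an
  anchor gene's latent signal with configured target correlation and
  missingness (e.g. ~97% missing for the fatty-acid panel, reproducing
  small per-pair n).

What the generators do not emulate: linkage disequilibrium between SNPs,
non-normal expression marginals (the upstream variance-stabilizing
transformation is out of scope), genotyping error, population
stratification, and pedigrees beyond independent trios. Passing
calibration therefore validates the statistical machinery under the
stated models, not robustness to those real-data features.

## Pipeline

Stages run in the declared order from a YAML config; every output
directory receives exactly one `manifest.json` with input SHA-256
digests, the config snapshot, the seed, the package version and
per-stage row counts. Failures abort with a typed error and still write
the manifest recording partial progress. Exit codes: 0 success, 2
configuration error, 3 data-format error, 4 statistical precondition
violation. Tables are tab-delimited UTF-8 with one header row; floats at
full precision (rounding is display-only, in the report command).

## Problem sizes

The test suite and the acceptance script run at the study-condition
sizes — 10,000 SNPs for null calibration, 781 trios, 1,479 expression
donors — and complete in well under a minute; Monte-Carlo loops
(coverage, type-I error, null calibration) use 100–1,000 replicates,
enough to pin the checked rates to the tolerances asserted.

## Known limitations

* The dimorphism screen takes summary statistics at face value: no
  genomic control, no liftover between genome builds, no LD clumping.
* The exact HWE test is conditional on observed allele counts; for very
  large totals (>10⁵) the enumeration is linear in the minor-allele
  count and still fast, but the χ² variant is preferable there anyway.
* Covariate adjustment is linear; non-linear age effects would leak into
  residuals.
* The published expression-cohort correlation values and
  frequency-database comparison p-values depend on non-public data;
  the package validates those code paths on synthetic data only.
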