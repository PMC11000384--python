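# Methods

## Scope and data model

The package analyses a cohort of `n` sequenced subjects with quantitative
trait measurements, organised as four tables: a genotype matrix
(subjects × biallelic variants with per-call GT/AD/GQ/DP), a variant
annotation table (database evidence), a subject table (subpopulation,
sex, age, PC1–PC4, traits) and a gene-panel table (panel membership,
inheritance mode, coding length). Multi-allelic VCF records are
decomposed at load into one biallelic variant per alternate allele, the
per-sample genotype recoded as the count of that allele (other alternates
count as reference for that row). Missing genotypes are excluded from
allele numbers — `AN = 2·n_called` — following the convention of the
large reference databases; the upstream study of this design did not
state its convention, so this one is declared, not inferred.

## Variant classification

A variant is a *known P/LP* when all of the following hold:

* maximum allele frequency < 1% in every provided global database
  (columns `af_*`; a variant absent from a database contributes 0);
* consequence ∈ {missense, nonsense, frameshift, splice_site} or an
  explicit non-coding-pathogenic flag (the package trusts the upstream
  consequence annotation; "splice_site" means the canonical ±1/±2
  dinucleotides as annotated);
* HGMD class DM or DM?; and a ClinVar record that is currently
  Pathogenic/Likely-pathogenic (category 1 at ≥ 2 review stars, else
  category 2), currently Conflicting/VUS (category 3), or currently
  Benign/Likely-benign with a prior-P/LP flag (category 4).

Category 3 does not require the prior-P/LP flag: a conflicting/VUS record
intersected with HGMD DM is taken as evidence of a past pathogenic
assertion, whereas a benign record needs the explicit flag to qualify.
ClinVar review status is consumed as an integer star count; the mapping
from review-status strings is the documented loader table
`CLINVAR_REVIEW_STARS`. Summary statistics restrict to categories 1–2 by
default (configurable); categories 3–4 stay in the catalogue flagged.

*Novel candidates* are panel-gene variants that are globally rare
(< 1%), deleterious in silico (CADD > 20, GERP > 3), carried by at least
3 cohort homozygotes, never classified benign, and not already known
P/LP. The homozygote minimum is a config knob (`min_hom`): the source
material for this design used 3 in its procedure text but 2 in a figure
legend; 3 is the default and the discrepancy is surfaced rather than
resolved.

*Loss-of-function* means nonsense/splice-site/frameshift with global
AF < 1%. Gene-level P/LP counts are length-adjusted as count per kb of
coding sequence — the adjustment was stated without a formula upstream,
and a per-kb rate is the natural reading; the display threshold
(adjusted > 0.3) is a config knob, not a hard-coded rule.

## Carrier burden and subpopulation summaries

A subject *carries* a variant when het or hom-alt. Per subject the
package counts distinct P/LP variants carried, homozygous P/LP genotypes
in recessive-condition genes and heterozygous P/LP genotypes in
dominant-condition genes ("both" genes contribute to both tallies). The
subpopulation summary reports carrier percentages over group size, but
homozygote/heterozygote percentages over the group's **carrier count** —
that denominator is the only one consistent with the published
summary-table arithmetic this surface reproduces (e.g. 25/794 = 3.15%),
and fold enrichments are ratios of those carrier-normalised rates to a
reference group (the admixed group by default). Rounding to one decimal
happens only at report time; `pct()` is the presentation helper.

Homozygote enrichment between groups is tested with the two-sided
Wilcoxon rank-sum on per-subject homozygote counts: exact enumeration
when both groups have ≤ 12 observations without ties, otherwise the
tie-corrected normal approximation with continuity correction
(scipy's implementation). Both PAR-vs-reference and PAR-vs-rest
comparisons are exposed, since either reading of the original contrast is
defensible.

## Gene carrier frequency

Per variant, `CF = (AC − Hom) / (0.5·AN)` with `Hom` the number of
homozygous individuals — algebraically the fraction of called subjects
carrying ≥ 1 alternate allele, which pins down the parenthesisation of
the formula as printed upstream. GCF is the sum of CFs over a gene's
category-1/2 P/LP variants within a subpopulation, computed over subjects
not flagged related (relatedness is an input column; kinship inference is
out of scope). Tier boundaries are half-open with the upper endpoint on
the lower tier, matching the strict ">" of the published category
definitions: cat1 > 1/50, cat2 ∈ (1/100, 1/50], cat3 ∈ (1/150, 1/100],
cat4 ∈ (1/200, 1/150]. GCF may exceed 1 for pathological variant sets; it
is reported uncapped with a warning. Subpopulations below `min_subpop_n`
(default 50) are flagged low-confidence, since sums of carrier
frequencies are upward-biased at small n.

## Population screens

* **Founder alleles**: within-subpopulation AF > 1% while the maximum
  global AF < 1%; hits absent from every database are flagged separately.
* **Common P/LP**: maximum within-cohort subpopulation AF ≥ 2%; above 5%
  the variant is additionally flagged as a benign-reclassification
  candidate.
* **AF correlation**: squared Pearson correlation between cohort AF and a
  global database AF over variants rare (< 1%) in both; the database is a
  parameter, defaulting to the per-variant maximum across those provided.
* **Depleted homozygosity**: for globally rare variants, expected
  homozygotes `E = n_called·q²` with `q` the pooled cohort AF — the
  random-mating (F = 0) expectation, deliberately, so that in a
  consanguineous cohort the screen under-predicts homozygotes and is
  conservative. A hit requires `E ≥ 3` and zero observed homozygotes; a
  per-subpopulation variant of the screen sits behind a flag.
* **Knockouts**: per-subject counts of rare LoF variants (all genes and
  panel genes separately), LoF variants with ≥ 1 homozygote with carrier
  IDs, and per-subpopulation mean/variance of homozygous-LoF counts.

## Extreme-trait screen

Percentiles are nearest-rank order statistics (index `ceil(p·n)` of the
sorted non-missing vector): no interpolation convention can shift a flag
near the boundary. The default decision rule requires **all** non-missing
homozygote values beyond the same tail threshold, matching the worked
examples that motivated the design (5/5 homozygotes extreme); a majority
rule is available. Traits are used raw — the screen's percentile language
refers to measured values, not transformed ones. No multiple-testing
correction is applied: the screen generates hypotheses for literature
triage. Under the null, a variant with k homozygotes is flagged with
probability ≈ 2·(0.05)^k per trait, which the tests verify empirically.

## Rare-variant burden scan

Per-call filters: heterozygote allele balance in (0.2, 0.8) — the
published phrasing "> 0.2 or < 0.8" is read as this retention band, the
only non-vacuous reading — homozygote AB > 0.80, GQ > 10; failing calls
become missing, and calls lacking AD/GQ fail closed. Per-variant filters:
call rate > 90% after call filtering, Hardy-Weinberg exact-test
p ≥ 1e-6, cohort and all global AFs < 1%. Singletons (AC = 1) are
dropped; doubletons (AC = 2) are kept only when every carrier call has
depth ≥ 10 — "excluding doubletons with allele depth ≥ 10 and singletons"
is read as *exempting* good-depth doubletons from exclusion; the opposite
literal reading survives behind `doubleton_keep_high_depth=False`.

The HWE test is the exact conditional test: given `n` diploids and the
observed alternate-allele count, the probability of each possible
heterozygote count (same parity) is computed in log space and the
p-value sums outcomes no more probable than the observed one. Tightening
the call-level thresholds is monotone at the call level but not provably
monotone for the qualifying *variant* set (removing alt carrier calls can
pull a variant's AF under the frequency cutoff); the tests assert
monotonicity where it genuinely holds (variant-level thresholds, and
retained call counts under GQ tightening).

Gene collapsing is the unweighted sum of 0/1/2 allele counts over the
gene's qualifying variants (missing = 0), with aggregated RR|RA|AA class
counts. Association is ordinary least squares of the trait on the burden
plus age, sex and PC1–PC4 over complete cases — a fixed-effects
approximation of a mixed model: without a kinship matrix the PCs absorb
population structure, so betas are comparable to, not identical with, a
kinship-aware fit; a GLS extension can hook in a precomputed kinship.
The reported statistic is the squared Wald ratio with its 1-df chi-square
tail; the genome-wide threshold is a fixed p < 1e-8 with no further
correction. A rank inverse-normal trait transform is available but off by
default.

## Synthetic cohort generator

The generator emulates, per subpopulation `s` with inbreeding
coefficient `F_s` and per-variant frequency `q`, genotypes drawn
independently across subjects and variants from

    P(hom-alt) = q² + F·q(1−q),  P(het) = 2q(1−q)(1−F)

with per-variant base frequencies log10-uniform (default 10⁻⁴–10⁻¹·³)
and per-(variant, subpopulation) lognormal divergence multipliers
(σ = 0.5). Consanguinity is modelled by this single F per group rather
than explicit pedigrees: one parameter reproduces the key observable
(homozygote enrichment) without simulating mating structure. Default
subpopulation sizes follow the motivating cohort (GAR 2311, WEP 1372,
ADM 1180, PAR 1052, AFR 92, SAS 38); the per-group F values
(PAR 0.030, GAR 0.015, WEP/AFR/SAS 0.010–0.015, ADM 0.005) are
illustrative, chosen to bracket the offspring-of-first-cousin value
(0.0625) times realistic consanguinity prevalence, since group-level F
was not published.

Traits follow `y = μ + σ·(0.2·z_age + 0.3·(male−m̄) + 0.1·Σz_PC +
Σ effect·g* + ε)`, `ε ~ N(0,1)`: effect sizes are expressed in units of
the trait's manifest SD (= the residual noise SD), with `g* = 1[gt=2]`
for recessive spikes and the allele count for additive ones. Trait
missingness is 2% uniform; per-call DP ~ Poisson(35), allele depths
binomial around AB 0.5 (het) / 0.98 (hom-alt), GQ ~ N(65, 20) clipped to
[0, 99], call missingness 0.5%. Founder-spiked variants always receive
rare global database AFs — a founder allele is, by definition, rare
outside the cohort. All randomness flows from one seeded generator;
identical config and seed give bit-identical cohorts.

What the generator does **not** emulate: linkage disequilibrium,
haplotype/IBD sharing, explicit pedigrees, sequence context, genotyping
error correlated with genotype, or trait-trait correlation beyond shared
covariates. Tests passing on this generator therefore validate the
statistical machinery and its calibration under the stated model, not
robustness to real-data artefacts such as batch effects or cryptic
relatedness.

## Simulation sizes and operating characteristics

The operating-characteristic checks run at the following sizes, chosen to
make each property measurable with modest Monte-Carlo error:

* generator law: n = 50 000 subjects, F = 0.0625, q = 0.1 (hom-alt
  fraction vs 0.015625 within 3 binomial SE); HWE null calibration at
  n = 1500 × 800 common variants (the exact test's discreteness makes it
  conservative, so the observed rejection rate sits at or slightly below
  the nominal 5%);
* carrier-frequency exactness: 1000 random genotype fixtures, exact
  float equality against a brute-force carrier tally;
* HWE total mass: every configuration with AN ≤ 60, by exact rational
  enumeration;
* burden scan: type-I error over 1000 null gene–trait pairs at
  n = 10 000 (common-enough rare variants, AF 10⁻³–10⁻²·¹, so per-gene
  burdens have tens of carriers and the Wald test is well calibrated);
  power at 0.5 trait-SD per allele with ~30 carriers over 10 seeds;
* extreme screen: 100 replicates of a −2 SD recessive spike at ~5
  homozygotes (n = 3000), plus a −4 SD companion where recovery is
  expected;
* depletion screen: n = 6000 × 800 outbred variants with cohort AF
  0.022–0.3, so expected homozygote counts span the ≥ 3 region.

Two of these characteristics are power-limited by arithmetic, not
implementation. For the burden scan at 0.5 trait-SD per allele and ~30
carriers, the Wald statistic is ~N(0.5·√30, 1) ≈ N(2.74, 1), so
p < 1e-4 is reached in only ~12% of replicates; near-certain detection at
that threshold requires ~1 residual-SD per allele. For the extreme-trait
screen at −2 SD, each homozygote lands below the cohort 5th percentile
with probability at most Φ(2 − 1.645) ≈ 0.64, so all five do so in only
~10% of replicates; at −4 SD the per-homozygote probability is ≈ 0.98 and
the screen recovers the spike almost always. The corresponding checks
state the stronger requirements as specified and report the measured
rates; the power arithmetic above explains the gap.

## Known limitations

* No compound-heterozygote phasing: GCF treats variants independently.
* The burden scan's OLS ignores residual relatedness beyond the PCs.
* Consequence, ClinVar and HGMD fields are consumed, never re-derived;
  garbage annotation in means garbage catalogue out.
* The AF-correlation statistic depends on the variant set and database
  pooling; it is reported for the data at hand, not as a reproducible
  constant.
* Subpopulations with few subjects yield upward-biased GCFs; the
  low-confidence flag marks, but does not correct, this.
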