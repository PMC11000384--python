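# mendelburden

Mendelian-disease carrier-burden analysis for population biobank cohorts
with strong genetic substructure and consanguinity.

Large sequenced biobanks from endogamous populations carry a distinctive
burden of recessive disease: most participants are healthy carriers of at
least one pathogenic allele, homozygotes concentrate in the most inbred
ancestry groups, and founder alleles reach frequencies far above anything
seen in global reference databases. `mendelburden` implements the full
analysis a genetics team runs on such a cohort:

1. **P/LP cataloguing** — select known pathogenic/likely-pathogenic
   variants by intersecting ClinVar and HGMD evidence (rare globally,
   coding or flagged non-coding, ClinVar P/LP × HGMD DM/DM?), classify
   them into four review-status categories, and flag novel candidates
   (CADD > 20, GERP > 3, ≥ 3 cohort homozygotes, never benign).
2. **Carrier burden** — per-subject allele counts and per-subpopulation
   summaries (carrier %, homozygote/heterozygote shares, fold enrichments
   against a reference group, Wilcoxon rank-sum homozygote test).
3. **Gene carrier frequency (GCF)** — per variant the carrier frequency
   `CF = (AC − Hom) / (0.5·AN)`, summed over a gene's pathogenic variants
   per subpopulation, tiered by the carrier-screening cutoffs
   (cat1 > 1/50 … cat4 > 1/200).
4. **Population screens** — founder alleles (common in one subpopulation,
   rare globally), exceedingly common P/LP (≥ 2%, reclassification flag
   above 5%), allele-frequency correlation with global databases,
   homozygosity depletion (0 observed where random mating expects ≥ 3
   homozygotes, `E = n·q²`), and a human-knockout catalogue of rare
   loss-of-function variants.
5. **Extreme-trait screen** — flag candidate variants whose homozygotes
   all sit beyond the cohort 5th/95th trait percentiles.
6. **Rare-variant burden scan** — stringent per-call QC (allele balance,
   GQ), per-variant QC (call rate, exact Hardy-Weinberg test, AF < 1%,
   singleton/doubleton rules), unweighted per-gene collapsing, and OLS of
   each quantitative trait on the burden adjusting for age, sex and
   PC1–PC4, reporting the 1-df Wald chi-square.

Because real cohorts of this kind are access-controlled, the package
ships a first-class **synthetic cohort generator**: subpopulations of
unequal size with distinct inbreeding coefficients *F* (genotypes drawn
from `P(hom-alt) = q² + Fq(1−q)`, `P(het) = 2q(1−q)(1−F)`), database-style
variant annotations, founder-allele spikes, and covariate-structured
quantitative traits with optional large-effect variant spikes. Every
analysis stage is tested against this generator's ground truth.

## Worked example

```python
from mendelburden import (SimulationConfig, SubpopSpec, FounderSpike,
                          simulate_cohort, classify_cohort, subject_burdens,
                          subpop_summary, gene_gcf, genes_above_threshold)

cfg = SimulationConfig(
    seed=11,
    subpops=[SubpopSpec("PAR", 1052, 0.030), SubpopSpec("ADM", 1180, 0.005)],
    n_genes=40, n_variants=150, af_log10_min=-3.0, af_log10_max=-1.0,
    founder_spikes=[FounderSpike(0, "PAR", 0.017)],
    n_known_plp=40, n_novel_candidates=4, n_benign_common=4,
)
cohort, truth = simulate_cohort(cfg)
classified = classify_cohort(cohort)
burdens = subject_burdens(cohort, classified, categories=(1, 2))
print(subpop_summary(burdens, cohort.subjects, ref_label="ADM"))
print(genes_above_threshold(gene_gcf(cohort, classified)).head(3))
```

prints (seed 11):

```
label  n_subjects  n_carriers  pct_carriers  pct_hom_recessive  fold_hom_vs_ref
  ADM        1180         919         77.88               3.05             1.00
  PAR        1052         730         69.39               3.70             1.21

    gene subpopulation    gcf tier
GENE0013           ADM 0.2379 cat1
GENE0037           PAR 0.1501 cat1
GENE0001           ADM 0.1397 cat1
```

Reading: 78% of the outbred reference group carry at least one
category-1/2 pathogenic allele (this toy cohort uses deliberately common
pathogenic AFs so every statistic is exercised at n ≈ 2200); the inbred
PAR-like group shows a 1.2-fold homozygote enrichment relative to the
reference; the top gene's cumulative carrier frequency of 0.24 lands in
tier cat1 (> 1/50), the range that motivates newborn-screening panels.

The same stages are available from the shell:

```sh
mendelburden simulate --out-dir sim --seed 3
mendelburden catalog --vcf sim/cohort.vcf --annotations sim/annotations.tsv \
    --subjects sim/subjects.tsv --panels sim/panels.tsv --out-dir results
mendelburden run-all --config run.yaml     # full pipeline + manifest
```

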