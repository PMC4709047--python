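# founderscan

A tested pipeline for **case-case genome-wide association with founder
alleles**: does a germline variant predispose cancer patients to developing
metastatic disease? The design compares patients whose tumours metastasised
(stage IV) against patients whose tumours did not (stage I/II) — cancer-free
controls only calibrate allele frequencies — and targets founder populations,
where a recently-arisen risk allele rides on a long conserved haplotype that
is itself detectable.

The pipeline covers the full arc of such a study on synthetic cohorts with a
planted founder risk haplotype, so every stage has a known ground truth:

1. **Simulation** (`founderscan.simulate`) — cohorts of stage IV / stage I/II
   cases with a biallelic index SNP whose minor allele A1 segregates on a
   founder haplotype at frequency `f0` in stage I/II and `f4` in stage IV,
   with `f4/(1−f4) = OR · f0/(1−f0)`; stage IV copies conserve a longer
   flanking tract than the "older" stage I/II copies.
2. **QC** (`founderscan.qc`) — MAF ≥ 0.01, missingness ≤ 2%, exact
   Hardy–Weinberg test, 98% sample call rate, and cmdscale (classical MDS)
   stratification axes from allele-sharing distances.
3. **Association** (`founderscan.association`) — per-SNP log-additive
   logistic regression (0/1/2 dosage) adjusted for age, sex and MDS axes;
   Wald z, 95% CI = exp(β ± 1.96·se).
4. **Replication design** (`founderscan.replication`) — winner's-curse
   shrinkage to the 50% lower confidence limit, `exp(ln OR − 0.6745·SE)`;
   exact allelic-test power; two Bonferroni tiers (up to 9 SNPs at 0.04/9,
   up to 8 at 0.01/8, overall α = 0.05) plus unadjusted D′ = 1 companions;
   replication requires p below the tier threshold *and* a concordant
   direction.
5. **Haplotype span** (`founderscan.ld`, `founderscan.spantest`) — two-locus
   haplotype frequencies by EM, D′ = D/Dmax, and the span statistic: the
   number of region SNPs in complete LD (|D′| = 1) with the index, compared
   between groups by a label-permutation test reporting both the combined-SD
   z form (SD = √(V₁+V₂)) and a calibrated empirical tail p.
6. **Meta-analysis** (`founderscan.meta`) — inverse-variance fixed effects,
   DerSimonian–Laird random effects (τ² = max(0, (Q−df)/(Σw−Σw²/Σw))),
   Cochran's Q, and the sample-size-weighted z combination.

See `docs/methods.md` for models, parameter defaults and numerical
conventions.

## Worked example

The numbered drivers under `analysis/` run the whole study on three
simulated cohorts (discovery 89 vs 234 at planted allelic OR 2.63;
validations 89 vs 373 at OR 1.9 and 86 vs 257 at OR 1.31, all sharing one
variant panel and a 20-SNP founder span):

```bash
python analysis/01_simulate.py --seed 2016
python analysis/02_qc.py
python analysis/03_assoc_scan.py
python analysis/04_replication.py
python analysis/05_ld_span.py
python analysis/06_span_permutation.py
python analysis/07_meta.py
```

Output from that seed:

```
discovery: kept 449 samples (13 failed call rate) and 60 variants (0 removed)
discovery: scanned 60 SNPs; top hit snp00031 OR 2.48 (1.67, 3.70), p 7.42e-06
plan: 1 tier-1 SNPs at alpha 0.0400, 0 tier-2 at 0.00000
validation 1: 1 of 1 planned SNPs replicated
discovery: |D'|=1 span around snp00021: 19 SNPs in stage IV vs 7 in stage I/II
validation1: |D'|=1 span around snp00021: 20 SNPs in stage IV vs 6 in stage I/II
discovery: span 19 (stage IV) vs 7 (stage I/II), difference 12 +/- 2.36,
           one-sided normal p 1.85e-07, empirical p 2.00e-04
published inputs: fixed OR 1.94 (1.51, 2.50), random OR 1.93 (1.27, 2.91),
                  Q 5.30 (df 2, p 0.071)
simulated cohorts: fixed OR 1.99 (1.61, 2.47), random OR 1.99 (1.61, 2.47)
```

Reading this: the scan's top hit is a flanking SNP statistically tied with
the planted index (correlated hits inside one LD block are expected); the
replication plan spends its 0.04 budget on the one SNP with ≥ 80% shrunken-OR
power, and that SNP replicates in the first validation cohort. The
founder-haplotype representative (`snp00021`, the planted index, chosen as
the longest-span candidate among the significant region SNPs) shows complete
LD across 19–20 flanking SNPs in the metastatic group against 6–7 in the
non-metastatic group — the planted difference is 13 — and the permutation
test rejects exchangeability decisively. Pooling the three simulated
per-cohort index-SNP estimates recovers an overall OR of 1.99 (1.61, 2.47);
the `published inputs` line pools the three odds ratios of the motivating
study design (2.83 [1.81–4.44], 1.89 [1.27–2.80], 1.31 [0.81–2.12]) and
shows the fixed/random-effects split under mild heterogeneity (Q = 5.30,
df = 2).

Tables land under `results/` (`assoc/*.tsv`, `replication/plan.json`,
`ld/*.d_prime.tsv`, `spantest/span_test.tsv`, `meta/meta.json`).

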