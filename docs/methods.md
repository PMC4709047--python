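# Methods

`founderscan` implements a two-stage case-case GWAS for a founder
metastasis-susceptibility allele: a cohort simulator with a planted founder
risk haplotype, marker and sample QC, covariate-adjusted log-additive
association, power-guided replication design, two-locus EM linkage
disequilibrium with the D′-span permutation test, and odds-ratio
meta-analysis. This note records the models, the parameters that matter, the
numerical conventions, and what the synthetic data do and do not establish.

## The case-case contrast

All association fits compare metastatic (stage IV) colon cancers against
non-metastatic (stage I/II) colon cancers; cancer-free controls, when
simulated, serve only as an allele-frequency reference and never enter a
regression. Sampling is retrospective: group sizes are fixed by design and
allele frequencies differ by group. Under this design a logistic regression
of group on allele dosage is linear in dosage with slope ln(allelic OR)
whenever genotypes are in Hardy–Weinberg proportions within each group, so
the log-additive (trend) model is exactly correct for the simulated data.

## Synthetic cohorts (`simulate`)

Each sample draws two haplotypes over an `n_snps`-SNP panel on one synthetic
chromosome (uniform 5 kb spacing; the candidate LD region occupies the first
`region_snps` columns with the index SNP at its centre). Background alleles
are independent Bernoulli draws at per-SNP frequencies uniform on
`background_maf_range` — linkage equilibrium, which makes founder-free
cohorts exactly exchangeable between groups and gives the null calibration
tests a clean target.

The founder model:

- A haplotype belongs to the founder lineage with probability `f0 =
  index_maf` in stage I/II (and controls) and `f4` in stage IV, where
  `f4/(1−f4) = allelic_or · f0/(1−f0)`. The index minor allele (A1)
  segregates only on founder-lineage haplotypes, so the index MAF equals the
  founder frequency and the planted per-allele odds ratio is exact.
- The founder haplotype's flanking alleles are themselves one draw from the
  background pool. Founder copies conserve that pattern over a central core
  (the fraction `1 − span_erosion` of `founder_span`, default one third,
  nearest the index) on every copy; stage IV copies are always intact over
  the full span; stage I/II and control copies are intact with probability
  `nonmetastatic_intact_prob` (default 0.5), the remainder carrying fresh
  background draws on the distal flanks — "older" copies broken by
  historical recombination.

One recombinant A1 copy in a sample group is enough to create the missing
two-locus haplotype class at an outer-span SNP, so |D′| = 1 to the index
holds across the full span in stage IV but only across the core in stage
I/II: the metastatic group carries the longer conserved haplotype, which is
the signature the span statistic detects. With `founder_span = 0` the groups
are exchangeable and the signature vanishes.

Two parameter choices deserve a note. Drawing the founder flank pattern at
background frequencies (rather than 50/50) reflects that a founder haplotype
is a population sample, and it keeps outer-span markers from systematically
out-ranking the index SNP in the scan — a flank marker can only beat the
index when the founder happens to carry a low-frequency allele there, which
is correspondingly rare. The intact probability 0.5 gives the non-metastatic
group enough recombinant copies (~30 among ~65 A1 haplotypes at the
discovery design) that label permutations essentially never produce a
pseudo-group free of them; with values near 1 the permutation distribution
of the span difference becomes bimodal (a small pseudo-group occasionally
contains no recombinant and jumps to the full span) and the test loses most
of its power. Ages are N(71.2, 10.3²) years truncated at 20, sex is
Bernoulli(0.52) male, and neither carries any effect by default.

Cohorts sharing a `panel_seed` share background frequencies and the founder
pattern — the same genome sampled by different studies — which is what makes
cross-cohort replication and meta-analysis of a given variant meaningful.

What the simulator does **not** emulate: background LD (real panels are
correlated even off the founder haplotype), allele-frequency drift between
cohorts beyond the index SNP, genotyping batch effects, population
admixture, and LD decay with genetic distance (conservation is a sharp
tract, not a decaying function). Passing tests therefore show that each
statistical component behaves correctly under its stated model, not that the
pipeline is robust to every artefact of real array data.

## QC (`qc`)

Variant filters, applied in a fixed order with first-trigger reasons: MAF <
`maf_min` (default 0.01), missingness > `miss_max` (default 0.02), exact HWE
p < `hwe_alpha`. HWE is tested in the stage I/II reference group (a case-case
design has no controls to test in) with the conventional GWAS default α =
1e−6; both the group and the threshold are configurable because published
pipelines rarely state them. The exact test is the standard conditional
sum-of-smaller-probabilities definition (no mid-p), computed in log-space and
verified against exact rational enumeration for every table with ≤ 50
samples. Sample filter: call rate ≥ 0.98. Sex-mismatch, duplicate and
relatedness checks are out of scope (no X-chromosome or IBD machinery);
`QCReport` reserves fields for them.

Stratification axes are classical metric scaling (cmdscale) of the
allele-sharing distance (mean |dosage difference|/2 over pairwise-complete
loci): eigen-decomposition of the doubly centred squared-distance matrix,
axes scaled by √eigenvalue, ordered by decreasing eigenvalue, sign fixed by
making each axis's largest-magnitude loading positive. One caution learned
from the simulated panel: on a short panel dominated by one LD block, axes
computed over all SNPs encode founder-carrier status, and adjusting for them
reverses the index association. The analysis drivers therefore compute axes
from off-region SNPs only; with genome-wide data this is immaterial.

## Association (`association`)

Per-SNP maximum-likelihood logistic regression of group (stage IV = 1) on
0/1/2 A1 dosage plus covariates, Newton/IRLS with relative log-likelihood
tolerance 1e−10 and at most 100 iterations, listwise deletion of missing
dosages, Wald z and two-sided p, 95% CI as exp(β ± 1.96·se) with 1.96 exact
(matching two-decimal published intervals). Separation or non-convergence is
reported (`converged=False`) rather than silently estimated — no Firth
fallback, consistent with published ORs like 8.87 with very wide intervals.
Scans never abort on a per-variant failure; failed variants become flagged
rows. Verified against a nested grid search of the binomial likelihood
(1e−4 agreement), null type-I error 0.040–0.060 over 2000 simulations, and
93–97% CI coverage of the planted lnOR at the discovery design.

## Replication design (`replication`)

Winner's-curse shrinkage: the replication effect size is the lower bound of
a 50% CI, `exp(ln OR − 0.6745·SE)` with SE reconstructed from the 95% CI.
Replication power is, by default, the exact power of the two-sided Woolf
allelic z-test: the two allele counts are independent binomials at the
frequencies implied by (reference MAF, shrunken OR), so the rejection
probability is a finite sum over their joint pmf (empty cells get the
conventional 0.5 inside the statistic). The classical closed form
Φ(|lnOR*|/SE* − z_crit) + Φ(−|lnOR*|/SE* − z_crit) is available as
`method="normal"`; it overstates power by up to ~0.025 at strong effects
with low MAF because the Wald statistic's variance exceeds 1 at moderate
counts, which is why enumeration is the default.

Plans fill two Bonferroni-budgeted tiers from the most significant SNPs
whose shrunken-OR power reaches the floor (default 0.80): up to 9 SNPs
sharing 0.04 and up to 8 more sharing 0.01, overall type-I error 0.05.
Companion SNPs in complete LD (D′ = 1) with a tier-1 member are appended
with no statistical adjustment. Ties in p break by higher power, then
variant id, so plans are deterministic. A SNP replicates iff its validation
p is strictly below its tier alpha *and* its effect direction matches
discovery — a sign-flipped effect at small p is not replication.

## LD and the haplotype span (`ld`, `spantest`)

Two-locus haplotype frequencies come from EM over the double-heterozygote
phase ambiguity: linkage-equilibrium start, expected haplotype counts
iterated to Δ log-likelihood < 1e−12 (≤ 1000 iterations), monotonicity
asserted per iteration in the instrumented single-pair path. D = p_AB −
p_A·p_B; D′ = D/Dmax with Dmax = min(p_A·p_b, p_a·p_B) for D > 0 and
min(p_A·p_B, p_a·p_b) for D < 0; |D′| is used throughout (the sign
convention of published D′ profiles). "D′ = 1" means |D′| ≥ 1 − 1e−6: EM
reaches the simplex boundary only in the limit, so the tolerance is part of
the statistic's definition and is exposed in the API. The span count for a
group is the number of region SNPs at |D′| = 1 with the index, the index
excluded from its own count, monomorphic SNPs skipped and logged. A batch
implementation (one EM across all index/SNP tables, and across all
permutations via a single one-hot matrix product) is tested for agreement
with the instrumented path.

The permutation test re-partitions the case labels into pseudo-groups of the
original sizes; V1 and V2 are the variances of the size-n₄ and size-n₁₂
pseudo-group counts over `n_perm` permutations (default 10 000), the
combined SD is √(V1+V2), z = (count_IV − count_I/II)/SD, and the one-sided
normal p of z is reported. Two facts about this combination, measured on
founder-free simulations: the two pseudo-group counts are *not* independent,
and with unequal group sizes the smaller group attains |D′| = 1 more easily,
so the null expectation of the difference is positive — the z-based p is
strongly anticonservative (~45% rejection at nominal 5%). The empirical
permutation tail p, `(1 + #{permuted diff ≥ observed})/(n_perm + 1)`, is
calibrated by construction under exchangeability (measured 5.7% at nominal
5% over 300 null replicates) and is the value to use for inference; the
z-form is retained for comparability with the published table layout. Span
counts being integers, the empirical tail resolves a 5% level only when the
counts take enough distinct values; the null-calibration study therefore
uses a 60-SNP region rich in low-frequency SNPs (MAF 0.01–0.25), where
single-copy haplotype classes flicker in and out of samples and spread the
count distribution. Power at the discovery design (founder span 20, allelic
OR 2.6, 89 vs 234, 199 permutations) is ≈ 0.99.

## Meta-analysis (`meta`)

Log-scale SEs are reconstructed from 95% CIs as (ln hi − ln lo)/(2·1.96) —
the printed CIs are log-symmetric to within 2%, validating the
reconstruction. Fixed effects: inverse-variance weights. Heterogeneity:
Cochran's Q against χ²(k−1). Random effects: DerSimonian–Laird, τ² =
max(0, (Q − df)/(Σw − Σw²/Σw)), floored at zero. The METAL-style
sample-size-weighted combination (z_i from signed p/2 quantiles, weights
√n_i) is implemented alongside, since published pooled ORs/CIs match
inverse-variance pooling while the named software defaults to the
z-combination; both are reported so the discrepancy is inspectable. Pooling
CI-rounded inputs cannot reproduce a printed p exactly; tolerances in the
tests reflect input rounding, not implementation slack.

## Problem sizes

Default simulated panels are 60 SNPs (41-SNP region, 20-SNP founder span) at
the published cohort sizes (89/234, 89/373, 86/257). Calibration studies
use 2000 null scans, 500 coverage cohorts, 300 null and 100 alternative
span-test replicates at 199 permutations each, 50 EM grid-search fixtures,
and the complete enumeration of HWE tables with ≤ 50 samples; the full suite
runs in a few minutes on one CPU. These sizes give binomial standard errors
comfortably inside the asserted calibration bands.

## Known limitations

- The simulator's linkage-equilibrium background makes span counts smaller
  and cleaner than in real LD-saturated regions; absolute counts are not
  comparable to published ones, only the group contrast and its calibration.
- The span permutation scheme (full-label re-partition) is one defensible
  reading of "variances estimated from the permutation distribution"; the
  original resampling details are not public, so the z-form's printed
  p-values are not a reproduction target.
- The exact-power enumeration assumes the allelic test's binomial sampling
  model; it does not model covariate adjustment in the validation fit.
- Reading VCF/PED re-designates A1 as the minor allele per file; across
  cohorts a site near MAF 0.5 can flip designation, and the replication
  driver re-harmonises directions by allele identity before verdicts.
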