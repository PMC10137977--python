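# Methods

This note documents the statistical model behind each pipeline stage, the
parameters that matter, what the synthetic cohort does and does not
emulate, and the design choices made where the design was genuinely open.

## Study design being modelled

A targeted capture screen of the ~8 Mb 22q11.2 region in 19 sporadic
patients with comorbid microtia and congenital heart defect plus one
nuclear family (both parents healthy; the affected child carries the
classic LCR22-A–D deletion), compared against a 103-sample Han Chinese
(CHB) population panel for gene-level burden, with a 64-case / 96-control
qPCR validation set. All coordinates are 0-based half-open internally;
BED conventions on disk; 1-based only at the VCF boundary.

## Variant prioritization

Hard filters follow GATK hard-filtering conventions with separate SNP and
indel rule sets (SNP: QD < 2.0, FS > 60.0, SOR > 4.0, MQ < 40.0,
MQRankSum < −12.5, ReadPosRankSum < −8.0; indel: QD < 2.0, FS > 200.0,
SOR > 10.0, InbreedingCoeff < −0.8, ReadPosRankSum < −20.0). All
comparisons are strict, so a value exactly at a threshold passes. A
missing site annotation never violates a rule: hard filters act only on
evidence present, which is the GATK convention for absent rank-sum
annotations.

Novelty/rarity: novel = absent from both dbSNP and 1000G; otherwise rare
iff every *available* East-Asian frequency (1000G EAS, ExAC EAS) is
≤ 0.01 — "not exceeding 1%" is read inclusively. A catalogued variant
with no frequency record in either panel is classed rare (absence of
frequency evidence is not evidence of commonness) and flagged
`af_assumed_zero` in the output for transparency.

Consequence: LoF = stop-gain, frameshift or splice; missense is damaging
with ≥ 2 of 8 predictor votes. A missing predictor verdict never counts
as a vote and the threshold stays 2 regardless of how many predictors
reported — with few reporting predictors the rule is conservative by
construction.

Trio parent-absence requires the child to carry ≥ 1 alternate allele with
both parents observed homozygous reference; a missing parent genotype
defeats the flag (no de-novo claim without parental evidence). The
cascade is a pure per-site funnel, so permuting the input permutes the
output; multi-allelic sites are split into bi-allelic records by the VCF
reader before the cascade runs.

## Gene burden

The statistic is the qualifying-allele count: het contributes 1, hom-alt
2, missing genotypes 0. The frequency ratio divides the case allele
frequency by the control allele frequency with allele denominators
2·n_case = 38 and 2·n_ctrl = 206; it is reported with half-up two-decimal
rounding. This 2N-denominator form reproduces all ten reference
gene-table ratios exactly (e.g. (20/38)/(5/206) = 21.68,
(22/38)/(16/206) = 7.45, (8/38)/(38/206) = 1.14), which is why it was
adopted as the definition.

Significance is a one-sided label permutation: case/control labels are
permuted preserving group sizes, leaving each sample's within-gene
genotype vector intact (this preserves gene-internal correlation, the
standard choice for burden tests). The sampled estimator is
+1-corrected, `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, so p is never 0;
when `C(n, n_case) ≤ n_perm` the null is enumerated exhaustively and the
exact p returned instead. Default `n_perm = 10,000`. Raw p-values are the
primary output (mirroring a per-gene report over a small region); a
Benjamini–Hochberg `q_bh` column is emitted as a clearly-labelled
extension. Because the statistic is discrete and the estimator
conservative, p-values are super-uniform under the null; uniformity is
therefore checked per cohort (KS on the per-gene p-values) rather than by
pooling across hundreds of cohorts, where the conservative bias, not
sampling noise, would dominate the KS statistic.

## CNV recurrence

Call-level QC retains p < 0.01 AND size > 1 kb AND q0 ≤ 0.5 (strict /
strict / inclusive, as stated). Concordance between two same-type calls
is reciprocal overlap — `min(overlap/len(a), overlap/len(b))` — strictly
greater than 0.5, so exactly-half overlap is *not* concordant.
Concordance is not transitive; the merge therefore takes connected
components of the pairwise concordance graph and merges each component to
its outermost bounds `[min start, max end)`, which guarantees every
member call is covered by its merged CNV and makes the merge idempotent.

Recurrence keeps merged CNVs supported by strictly more than `threshold`
of the cases and not concordant (same-type, > 50% reciprocal overlap
against the *merged* interval) with any parent call. The published
description states a > 60% recurrence rule, yet the validated candidate
appears in 11/19 = 57.9% of cases; the threshold is therefore an exposed
parameter with default 0.5, and both readings are available via
`--recurrence`.

Rarity against a DGV-style track: a CNV is rare iff ≤ 50% of its length
is covered by the *union* of track regions at > 1% population frequency —
the union, not the sum, so overlapping catalogue records are not double
counted. Exactly 50% coverage is rare (inclusive rule).

### Depth-based deletion scan

Depths per 100 bp bin are normalized by the profile median, smoothed with
a centered 51-bin rolling median, and maximal runs below 0.7× spanning
≥ 500 kb are reported. A ~3 Mb deletion inside an 8 Mb target occupies
~37% of the profile, which drags the global median below the diploid
level and would bias the normalized depth inside the deletion upward
(≈ 0.57 instead of 0.5); the scanner therefore re-estimates the baseline
once from the bins outside the first-pass runs and repeats the scan
against the refined baseline. The defaults (cutoff 0.7, window 51,
min 500 kb) separate a 0.5× heterozygous loss from negative-binomial
coverage noise at 80× with ~1-bin breakpoint error; all three are
configurable. A profile that is uniformly reduced has no within-sample
contrast — normalization makes it flat — and yields no calls; this is an
inherent limit of single-sample depth normalization, and only a zero
median is treated as an error.

## qPCR and clinical summaries

ΔCt is the arithmetic mean of the three target-probe Ct replicates minus
the mean of the three reference-probe replicates (the aggregation is not
dictated by the ΔΔCt method itself; the mean is the conventional choice).
ΔΔCt subtracts the designated diploid calibrator's ΔCt, and the relative
copy number is anchored at two copies: `rel_CN = 2·2^−ΔΔCt`, so the
calibrator is exactly 2 and duplication/deletion thresholds are
interpretable. Group differences are assessed by OLS of rel_CN on a
case indicator plus age and sex (M = 1), with a two-sided t-test on the
group coefficient; a constant outcome or rank-deficient design raises
rather than returning a degenerate fit.

Cohort summaries use the sporadic-patient denominator (n = 19; the
familial child is excluded) and half-up two-decimal percentages — the
convention that reproduces the reference figures 57.89 / 31.58 / 73.68 /
26.32 / 21.05. Multi-lesion patients count once per lesion, so cardiac
percentages need not sum to 100; sex, degree and laterality do (up to
rounding). The mean age is emitted unrounded (12.47 for the reference
table).

## Synthetic cohort: what it emulates and what it does not

Allele frequencies follow Beta(0.2, 20) (mass concentrated well below
1%), with a 12% fraction of common sites drawn uniformly from
(1.1%, 30%) so the rarity exclusion is exercised. Genotypes are
Hardy–Weinberg draws; enrichment multiplies the per-allele carrier *odds*
in cases only, so a multiplier of 1 is exactly the null. The trio child
is generated by Mendelian transmission with a 2% de-novo rate. Predictor
verdicts are conditionally independent given a latent truly-deleterious
flag (sensitivity 0.8, false-positive rate 0.05 per predictor, 5%
missing), which gives the ≥ 2-of-8 consensus rule tunable operating
characteristics. Site QC metrics are drawn in passing ranges with a 5%
fraction forced to violate exactly one rule. Per-bin depth is negative
binomial with cv 0.15 at the 80× sample mean (Poisson at 80 reads would
be cv 0.11; capture coverage is overdispersed), dispersion held fixed
inside the deletion. CNV carrier status is Bernoulli per case at
probability 0.65 with ±2 kb boundary jitter (calls remain mutually
concordant); noise calls have a log-normal length spectrum with median
9 kb, and one in five deliberately fails a QC rule. The default 4,000
variant sites (100 per gene over 40 genes) are a deliberate scale-down of
the real screen's 37,659 sites: they exercise every rule of the cascade
while keeping a full pipeline run in seconds; the burden-calibration
checks use 480 sites/gene, closer to the real density, because p-value
uniformity is an asymptotic property of the discrete permutation
statistic.

Not emulated: read-level data (no FASTQ/BAM), linkage disequilibrium and
haplotype structure, per-gene mutation-rate variation, and segmental
duplication architecture. Passing tests on this generator demonstrate the
correctness and calibration of the downstream algebra and tests, not
robustness to alignment artefacts, batch effects or population
stratification in real capture data.

## Numerical and reproducibility choices

Every generator draws from a purpose-bound child stream of the single
run seed, so stages can be regenerated independently and a fixed
config + seed gives byte-identical output files. VCF INFO floats are
rounded to three decimals on write and read (htslib stores 32-bit floats
and prints six significant digits), and tab-separated floats are written
in shortest-repr form and parsed in round-trip mode, so every on-disk
format round-trips losslessly. Burden-scan permutations come from
per-gene child seeds of the scan seed, making the table independent of
gene evaluation order. Ties in the merge output are ordered by
(start, type, end); the funnel preserves input order.

## Known limitations

* The burden test carries no covariate or population-structure
  adjustment; with a public-panel control group, stratification would
  inflate real-data significance in ways the synthetic null cannot show.
* At the study's sample sizes the permutation p-value floor is
  1/(1+n_perm); per-gene power depends strongly on the number and
  frequency of qualifying variants, as the power simulations make
  explicit.
* Recurrence detection presumes the recurrent event is boundary-stable
  (jitter within the reciprocal-overlap tolerance); dispersed or nested
  rearrangements would fragment across clusters.
* The deletion scanner assumes a predominantly diploid baseline; losses
  covering half or more of the target would defeat median normalization
  even with the two-pass baseline.
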