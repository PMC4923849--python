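# Methods

## Smoothed DMR calling

Each sample's profile is smoothed independently of the group labels.
At CpG *i* the half-width is `h = max(min_window_bp/2, distance to the
min_window_cpgs-th nearest CpG)`; within `|pos − pos_i| ≤ h` a
second-degree polynomial in position is fitted to the raw proportions
M/N by weighted least squares with weights `N · K(d/h)`, `K` the
tricube kernel, and the fitted value at the CpG itself (clipped to
[0, 1]) is the smoothed methylation. Read depth enters only through
the weights, so sparse CpGs borrow strength from covered neighbours; a
window whose total weight is zero falls back to a whole-chromosome fit,
and a chromosome with no reads at all is an error naming the
chromosome. The defaults (≥2 kb, ≥70 CpGs) suit genome-scale CpG
spacing.

The per-CpG statistic divides the smoothed group difference
`d_i = mean_high − mean_low` by the equal-variance pooled two-sample
standard error, floored at a genome-wide quantile of the raw standard
errors (default 0.75). The floor is essential with few replicates:
empirical variances with 8 degrees of freedom occasionally collapse
toward zero and would otherwise manufacture arbitrarily large
statistics at uninformative CpGs. DMRs are maximal runs of CpGs with
`|t| > t_cutoff` (default 4.5) of constant sign, neighbours at most
`max_gap_bp` apart (default 300 bp — "consecutive CpGs" needs an
operational adjacency rule, and 3 mean inter-CpG gaps is a natural
one), kept when they contain ≥3 CpGs and their mean difference exceeds
0.10 in absolute value. The difference filter uses the smoothed `d_i`
by default; `call_dmrs(..., use_raw_diff=True)` switches it to the
unsmoothed group difference for users who prefer the filter on raw
scale. DMR bounds are `[first member CpG, last member CpG + 1)` in
0-based half-open coordinates; direction is the sign of high-stress
minus low-stress.

**FDR.** Smoothing is label-free, so it is computed once; every
balanced relabeling of the samples (mirror pairs deduplicated, identity
excluded; 125 exist for 5 vs 5, subsampled without replacement when
`n_perms` is smaller) reruns only the statistic and the run scan. The
estimate is `mean(null count) / observed count`, defined as 1.0 when
nothing is observed; it is a ratio of expectations, so with very few
observed regions it is noisy and should be read qualitatively.

### The dense-grid profile

The synthetic toy genomes place CpGs at ~100 bp mean spacing, so the
genome-scale window (≥70 CpGs ≈ 7 kb here) would span many multiples
of a 5–10 CpG feature and average it away regardless of effect size.
`DENSE_SMOOTH_PARAMS` (≥600 bp, ≥19 CpGs) matches the window to the
0.5–1 kb feature scale, and `DENSE_FLOOR_QUANTILE = 0.5` places the
variance floor at the median raw standard error: with 5 samples per
group the 75th-percentile floor would replace the denominator at three
quarters of all CpGs and suppress genuine signal, while the median
still guards the lower tail. Both values were fixed by truth-recovery
calibration on simulated data across ten generator seeds (maximizing
mean sensitivity subject to precision staying at 1.0) and are used by
every toy-scale analysis in the package; they are a configuration of
the method for dense grids, not new defaults.

## meQTL classification

Regional methylation per sample is the coverage-weighted mean ΣM/ΣN
over the DMR's CpGs — raw counts, not smoothed values, because the
smoothing window extends beyond the DMR boundary and would leak
genotype effects across regions (a smoothed-mean alternative is a
flag). The SNP window is ±5 kb with inclusive bounds (a SNP exactly
5 000 bp away is tested). The default test is Pearson correlation with
the t-distribution p-value at per-SNP α = 0.05 and no multiple-testing
correction: over-calling gDMRs is the conservative direction when the
goal is an ngDMR set free of genetic influence. A Benjamini–Hochberg
mode and, for very small n where the t approximation is fragile, an
exact permutation test (n ≤ 8) are provided. Constant dosages, constant
methylation, or fewer than 3 complete pairs make a SNP untestable —
never significant — and a DMR with no (testable) SNP in its window
counts as ngDMR, so the labels always partition the DMR set.

## Shuffle-null enrichment

The overlap statistic is the number of DMRs hitting the track by ≥1 bp,
each DMR counted once — counting regions, not bases, and invariant to
splitting or merging track intervals on the same covered bases. The
null repositions every DMR uniformly on its own chromosome, preserving
its length, independently of the others (mutual overlaps allowed), with
rejection sampling against an optional exclusion mask; genome-wide
placement (chromosomes weighted by available slots) is a flag. z
standardizes the observed count by the null moments; with fewer than 30
shuffles or a degenerate null (SD = 0, e.g. a saturating or empty
track) z is reported as NaN with a flag while the add-one empirical
p-value `(1 + #{null ≥ obs}) / (B + 1)` — never exactly zero — remains
valid. Flags mark z-scores beyond the standard-normal 5% and 10% upper
tails; they are reporting aids, not computation changes.

Array overlap counts DMRs containing ≥1 catalog CpG (point positions as
single-base intervals) and reports the fraction, undefined (NaN) with
zero DMRs. Gene assignment maps a DMR to every gene whose body ±
`flank_bp` (default 0: body only) it overlaps; gene-set enrichment is
the one-sided hypergeometric tail on the overlap between DMR genes and
each set, both intersected with a user-supplied universe, BH-adjusted
across sets. Gene sets arrive as a GMT file; no network access is ever
attempted.

## Cohort statistics

The PSQ total score is the **mean** of the 20 item scores (each 1–4),
giving a score in [1, 4]; an instrument summary with minimum 1.00 and
maximum 3.55 is only consistent with this per-item scale, so the
sum-of-items reading is not used. Quartile cutpoints use the
linear-interpolation quantile convention (nearest-rank is a flag);
"low" is strictly below Q1 and "high" strictly above Q3, so scores tied
with a cutpoint fall into "medium" and the low/high groups are each at
most half the cohort — with heavily tied scores the three groups need
not be n/4, n/2, n/4.

Raw odds ratios come from the 2×2 table, `OR = (a·d)/(b·c)`, with Wald
95% intervals `exp(ln OR ± 1.96·SE)`, `SE = √(1/a+1/b+1/c+1/d)`; a zero
cell is an error pointing at the optional 0.5 continuity correction.
Adjusted ORs are `exp(β̂)` from maximum-likelihood logistic regression
(statsmodels Newton IRLS; covariance from the observed information;
non-convergence and separation are explicit errors), with categorical
covariates dummy-coded against their first level; with no covariates
the logistic estimate reproduces the 2×2 odds ratio exactly. Mean
ratios are `exp(β̂)` from OLS on the log-transformed outcome — the
ratio of geometric means — invariant to multiplicative rescaling of the
outcome and affine rescaling of continuous covariates; non-positive
outcomes are an error listing the offending subjects.
Representativeness is the Pearson chi-square on the category × cohort
table, with a warning (not an error) when an expected count falls
below 1. Wald intervals are used throughout for determinism; intervals
computed by other methods can differ in the second decimal,
so interval bounds should not be compared across implementations.

## What the generators emulate — and what they do not

`simulate_methylome` draws CpG positions with geometric gaps (mean
100 bp), a latent baseline from a mean-reverting logit-scale AR(1)
(stationary SD 0.5, so baselines mostly lie in 0.25–0.75), truncated-
Poisson coverage (≥1 read) and beta-binomial counts with intra-class
correlation 0.05 — WGBS replicates are overdispersed, and a pure
binomial generator would make the variance floor look unnecessary.
Planted regions (default 50 of 5–10 CpGs, disjoint with a 10-CpG
buffer) shift the two groups by ±Δ/2 (default Δ = 0.3) with balanced
randomized signs, clipped to [0, 1]. The defaults mirror the study
design the pipeline targets: 5 mother–child pairs per stress group at
~15× coverage. `simulate_genotypes` adds background SNPs (≈2 expected
per ±5 kb test window) with Binomial(2, maf) dosages and, per selected
region, one cis SNP whose dosage shifts the region's latent methylation
by `beta` per allele, redrawing those counts in place.
`simulate_annotations` centres a chosen fraction of intervals on
planted regions (round-robin, so fraction 1 covers every region) and
scatters the rest uniformly. `simulate_cohort` gives each of 443
subjects a latent stress propensity, 20 noisy items rounded to 1–4,
quartile categories, a logistic wheeze model with planted category
odds ratios (defaults 2.44 high, 1.39 medium vs low, ~9% baseline
risk) plus independent binary confounders with modest effects, and a
log-normal biomarker with a planted geometric-mean ratio (default 1.5)
in the high-stress group.

Not emulated: read-level data and bisulfite-conversion error, linkage
disequilibrium and haplotype structure, cell-composition heterogeneity,
CpG-density structure (islands/shores), confounders correlated with the
exposure, and missing questionnaire data. Passing tests therefore
demonstrate that the estimators recover the effects this model plants
at these sample sizes — not that the pipeline is robust to artefacts
real WGBS or questionnaire data may carry.

## Verification design

Oracle checks compare each core operation against an independent
implementation on small inputs: the smoother against a directly coded
weighted polynomial fit (agreement to 1e-10), the run scan against an
exhaustive enumeration of maximal runs, interval overlap against a
quadratic double loop, the shuffle null against exact placement
enumeration on a 100 bp toy, the hypergeometric p against direct tail
summation, and the exact-permutation correlation p against full
enumeration. Stochastic recovery checks pool a small number of
fixed-seed replicate simulations, sized so the check's tolerance is at
least twice the standard deviation of the pooled estimate (spread
measured across ten seeds during development): three replicates for
planted-DMR recovery, five for odds-ratio recovery at n = 50 000 per
replicate; the meQTL recovery experiment simulates with the exposure
effect disabled (Δ = 0) and a flat 0.3 baseline so the correlation test
sees only the genetic signal and the [0, 1] clip stays inactive. The
problem sizes (200 kb genome, ~2 000 CpGs, 10 samples, 20 permutations,
50 000-subject cohorts) keep the full suite and the acceptance script
in the minutes range on one CPU.

## Known limitations

* The FDR ratio estimator is unstable when the observed DMR count is
  small; the 1.0 convention at zero observed count is a definition, not
  an inference.
* Pearson p-values at n = 10 rest on normality of regional methylation;
  the exact-permutation option is limited to n ≤ 8 by factorial cost.
* The shuffle null ignores chromatin-driven placement biases of real
  DMRs; an exclusion mask mitigates but does not remove this.
* Logistic odds ratios are non-collapsible: marginal (2×2) and
  covariate-conditional estimates differ slightly even with independent
  confounders, so raw and adjusted ORs are not expected to coincide.
* With heavy ties in stress scores, quartile group sizes can deviate
  substantially from n/4; cutpoint ties are deliberately assigned to
  the medium group.
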