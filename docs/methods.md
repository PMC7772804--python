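# Methods

## The score

The COX-IS contrasts two COX-2-regulated inflammatory programs. For sample
*i* with log2 expression *e*, matched cancer-promoting genes CP (nominal 9)
and cancer-inhibitory genes CI (nominal 15):

    COX-IS_i = mean_{g in CP} e_gi  /  mean_{g in CI} e_gi

Low values are favorable. Three decisions the formula leaves open are fixed
as follows.

*Missing genes.* After case-insensitive matching and one alias hop
(IL8→CXCL8 and a handful of legacy symbols), the matched gene counts
replace the nominal list sizes, so each side of the ratio remains a mean.
Scoring refuses to run if fewer than 50% of either list matches
(configurable floor), and the genes actually used are recorded in the score
table's metadata.

*Input scale.* The ratio is defined on non-negative log2 expression —
log2(CPM+1), log2(RSEM+1) or similar. A per-sample mean CI expression at or
below 1e-8 raises an error naming the sample; silent clamping would distort
the ranking of exactly the extreme samples the stratification cares about.

*Z-scored variant.* On per-gene Z-scores the set means can be zero or
negative and the printed ratio is undefined, so the Z variant is the
difference mean(CP z) − mean(CI z). It preserves the same "CP up, CI down"
ordering; its ranking is invariant to any positive per-gene affine rescaling
of the raw matrix. This is an interpretation of an under-specified
definition and is flagged as such here.

## Preprocessing

Counts matrices go through CPM scaling (v → v/colsum × 1e6), low-expression
filtering, then log2(CPM+1). A gene survives filtering iff its CPM reaches
0.25 in at least ceil(0.10 × n_samples) samples; both comparisons are
inclusive (the common edgeR-style reading — the thresholds are stated
without strictness). The filter returns counts so the chain recomputes CPM
on the surviving genes; it is idempotent because removing genes only raises
the CPM of those that remain. Z-scoring uses the n−1 denominator (fixed
here for reproducibility; nothing in the source analyses pins it down) and
maps zero-variance genes to all-zero rows with a warning.

Duplicate gene rows collapse by element-wise maximum (conservative for
signal genes; mean available by flag). Missing expression values are a load
error — the target matrices are dense, and explicitness beats silent
imputation. Clinical stage labels coerce to numeric 1–4 by major stage
("Stage IIIA" → 3), with the ambiguous "Stage I/II NOS" annotation mapped
to 1 and anything unrecognized becoming missing with a warning rather than
an error.

## Survival analysis

Two-group stratification labels a sample "high" iff its score is strictly
greater than the cutoff quantile (type-7 / linear interpolation); ties go
to "low". Both choices are arbitrary but deterministic, which matters more
for reproducibility than which side the ties land on. k-quantile
stratification orders samples by score (stable sort, so ties break by input
order) and splits into k groups whose sizes differ by at most one.

The "optimal" cutoff scans the 25%, 50% and 75% quantiles and keeps the
split with the lowest Mantel–Cox log-rank p. This procedure is a form of
multiple testing, so the result always carries the complete per-candidate p
table — the chosen minimum should never be quoted alone. Ties in p go to
the lower quantile; candidates with no events in either arm are skipped
with a warning.

Kaplan–Meier estimation, the log-rank test (two-group and k-group,
chi-square with k−1 df) and Cox proportional-hazards regression delegate to
lifelines, with Efron handling of tied event times. Survival time is years
throughout; loaders convert days/months on request. Cox fits drop and count
rows with missing covariates, expand categorical covariates to drop-first
indicators, reject rank-deficient designs before fitting, and warn below 10
events. The per-variable hazard ratio is exp(coef) with a 95% Wald CI.

## Response analysis

RECIST categories pool to a binary responder flag under two published
conventions: SD with the non-responders ({PD,SD}→0, {PR,CR}→1; the
renal/bladder convention) or SD with the responders (the melanoma/gastric
convention). NE samples are dropped and counted; on-treatment biopsies are
excluded before pooling.

ROC AUC is P(score of a random responder beats a random non-responder),
ties counting one half — numerically identical to the Mann–Whitney U
statistic over all pairs. Orientation is explicit: the COX-IS is scored
low-favorable (scores negated before the AUC), comparator inflammation
signatures high-favorable.

Logistic models are plain maximum-likelihood binomial GLMs with intercept
(statsmodels). PD-L1 IC level enters as unordered indicator columns by
default (an ordinal encoding is available), TMB untransformed with a log10
option. Separation and non-convergence raise hard errors rather than
falling back to penalized fits, because the nested chi-square test
(deviance(small) − deviance(large) against chi-square with df = added
columns) and the deviance-explained summary (1 − residual/null deviance)
are only meaningful for plain MLE fits. Tiny negative deviance differences
(numerical noise, < 1e-6) clamp to zero; anything larger means the pair was
not a valid nested fit and raises.

The R-vs-NR two-sample comparison defaults to the Mann–Whitney test
(two-sided, no continuity correction so identical groups give p = 1; the
exact null is used when sizes permit and no ties are present), with Welch's
t available.

## The synthetic cohort generator

Each sample carries two latent activities: cancer-promoting a ~ N(0,1) and
cancer-inhibitory b = ρ·a + √(1−ρ²)·ε, with ρ = −0.6 by default — strong
antagonism between the programs. CP genes (and the PTGS2-like anchor) shift
their log2 relative abundance by a per-gene loading (mean 1.0, sd 0.2, in
log2 units per SD of latent) times a; CI genes likewise with b; 475
background genes (log2 abundance uniform on [0, 8]) load on neither.
Relative abundances are renormalized per sample, scaled by a log-normal
library size (median 2e6, log-sd 0.3), and counts drawn negative-binomial
via the gamma–Poisson mixture with dispersion 0.3 (var = μ + 0.3 μ²) —
typical bulk RNA-seq overdispersion, chosen to stress the CPM/log2 path.

The *true* score is the COX-IS computed on the noise-free expected
log2(CPM+1) values; its standardized version z drives the outcomes:

- survival: exponential event times with hazard 0.23·exp(β·z) per year
  (β = ln 2 by default, i.e. hazard doubling per SD; baseline chosen for a
  ~3-year median), censored by an independent Uniform(0, c) time with c
  solved by bisection so the expected censoring fraction hits the target
  (0.30);
- response: Bernoulli with logit −0.85 + γ·std(b − a) + 0.5·std(log10
  TMB+1) + 0.3·(PD-L1 IC level), γ = 1.0; responders are assigned CR/PR and
  non-responders SD/PD so both pooling conventions can be tested against
  the planted truth. TMB is log-normal (median 5, log-sd 1); PD-L1 levels
  IC0/IC1/IC2+ have probabilities 0.45/0.35/0.20. The defaults give a
  response rate near 30%, typical of ICB trial cohorts.

All randomness flows from one seed through a single generator with a fixed
draw order, so identical config + seed is bit-identical. The truth record
(latents, true score, hazards, response probabilities, per-gene loadings)
always accompanies the cohort: parameter-recovery tests must never
re-derive planted values from the data.

What the generator does *not* emulate: tumor-type-specific marginal
distributions, batch effects, GC/length biases, non-proportional hazards,
or single-cell structure. Passing tests therefore demonstrate that the
statistical machinery is correct and well calibrated under the model's own
assumptions, not that the signature will reproduce its behavior on any
particular real cohort.

## Calibration and validation experiments

The test suite validates each statistic against an independent route:
hand product-limit arithmetic for Kaplan–Meier, brute-force all-pairs
counting for the AUC, exhaustive enumeration for the exact Mann–Whitney
null, a vectorized label-permutation reference for the log-rank test, and
planted-effect simulations for Cox and logistic recovery (per-SD log-HR
ln 2 at n = 500 recovered within ±0.15 on average over 20 seeds; the small
downward bias is the expected attenuation from scoring noisy counts, the
observed score correlating ~0.97 with the planted one). Null cohorts
calibrate the median-split log-rank rejection rate (nominal 0.05) and the
uniformity of nested-GLM null p-values.

One known limit: at n ≤ 14 the chi-square p of the log-rank test differs
from the exact permutation p by ~0.01–0.04 — the asymptotic reference, not
an implementation artifact (the statistic itself matches the permutation
oracle's to 1e-12, and the gap closes to ≤0.01 by n = 60). Exact inference
at such sizes requires a permutation test, which the oracle in the test
suite effectively provides.

Problem sizes in the default experiments (cohorts of 200–500 samples, 500
genes, 20–1000 replicates depending on the experiment) were chosen so the
whole suite runs in about a minute on one core while keeping Monte-Carlo
error well below each assertion's margin.
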