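# coxis

Scoring and downstream analysis of the **COX-2-associated inflammatory
signature (COX-IS)** in bulk tumor transcriptomes.

Prostaglandin-driven (COX-2/PTGS2) inflammation splits into two antagonistic
transcriptional programs in tumors: a *cancer-promoting* (CP) program of 9
genes (VEGFA, CCL2, IL8/CXCL8, CXCL1, CXCL2, CSF3, IL6, IL1B, IL1A) and a
*cancer-inhibitory* (CI) program of 15 type-1 immunity genes (CCL5, CXCL9,
CXCL10, CXCL11, IL12A, IL12B, IFNG, CD8A, CD8B, GZMA, GZMB, EOMES, PRF1,
STAT1, TBX21). The COX-IS summarizes the balance per sample as a ratio of
means over log2 expression *e*:

```
COX-IS_i = ( 1/n_p · Σ_{g ∈ CP} e_gi ) / ( 1/n_n · Σ_{g ∈ CI} e_gi )
```

A **low** COX-IS (CI-skewed inflammation) is the favorable end: it marks
tumors with better overall survival and a higher probability of responding
to immune-checkpoint blockade (ICB). The package is aimed at computational
oncologists who want to score the signature on their own cohorts and rerun
the analyses it supports:

- CPM normalization, low-expression filtering (0.25 CPM in ≥10% of
  samples), log2(CPM+1) and per-gene Z-scoring;
- signature scoring (ratio, Z-difference, plain marker means) with
  alias-aware gene resolution (legacy IL8 → CXCL8);
- Pearson correlation profiling of signature genes against *PTGS2*;
- survival stratification (median/quartile/k-quantile cutoffs, and the
  lowest-log-rank-p "optimal" cutoff with full disclosure of all candidate
  p-values), Kaplan–Meier curves, Mantel–Cox log-rank tests, and Cox
  proportional-hazards models;
- ICB responder analysis: RECIST pooling under both published conventions,
  ROC AUC with explicit orientation, and nested binomial GLMs (deviance
  explained, chi-square model comparison) against TMB and PD-L1 covariates;
- a synthetic cohort generator that plants the assumed structure
  (anti-correlated CP/CI programs, hazard increasing with the score,
  response probability decreasing with it) with a full ground-truth record.

## Worked example

```python
from coxis import (SimulationConfig, simulate_cohort, normalize_counts,
                   coxis_score, stratify, logrank_test, cox_fit,
                   pool_responses, exclude_on_treatment, roc_auc)

cohort = simulate_cohort(SimulationConfig(), seed=7)      # 200 tumors
log2m  = normalize_counts(cohort.expression)              # CPM -> filter -> log2
scores = coxis_score(log2m).scores["COX-IS"]

strat = stratify(scores, mode="median")
lr = logrank_test(cohort.clinical.times, cohort.clinical.events,
                  strat.labels.to_numpy())

z = (scores - scores.mean()) / scores.std(ddof=1)
fit = cox_fit(cohort.clinical, scores=z, score_name="coxis_z",
              covariates=("age", "sex", "stage"))

pooled = pool_responses(exclude_on_treatment(cohort.response),
                        "sd_nonresponder")
auc = roc_auc(scores.loc[pooled.responder.index], pooled.responder,
              low_score_is_positive=True)
```

prints, via the obvious format calls:

```
scores head:
S0000    1.076
S0001    0.948
S0002    0.934
log-rank chi2 = 34.54, p = 4.18e-09
HR per SD = 1.96 (95% CI 1.64-2.34), p = 1.2e-13
ICB response AUC (low COX-IS = responder) = 0.658
```

The cohort was generated with a hazard doubling per SD of the true score
(HR 2.0), so the fitted HR per SD of 1.96 is the planted effect recovered
through the whole normalize → score → regress chain; the AUC of 0.658
reflects that response in this generator is driven by the program balance
plus partially informative TMB/PD-L1 terms.

The same run is available from the shell:

```
coxis run --simulate --seed 7 --out results/demo
coxis score --expression expr.tsv --scale counts --out scores.tsv
coxis survival --scores scores.tsv --clinical clinical.tsv --mode optimal --out fit.json
```

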