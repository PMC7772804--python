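"""Survival stratification, Kaplan-Meier, log-rank and Cox PH analysis.

Patients are split into score-high vs score-low groups at a quantile cutoff
(25%, 50% or 75%, or k near-equal quantile groups), compared by the
Mantel-Cox log-rank test, and the score's hazard ratio is estimated by Cox
proportional-hazards regression, univariate or adjusted for age, sex,
numeric stage and any further covariates.  The "optimal" cutoff is the
candidate quantile with the lowest log-rank p; the full per-candidate p
table is always reported so cutoff selection stays visible.

Model fitting delegates to lifelines (Efron handling of tied event times);
time is in years throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

from .datatypes import ClinicalTable, CoxisError

__all__ = [
    "StratificationResult",
    "SurvivalFit",
    "LogrankResult",
    "KMCurve",
    "stratify",
    "optimal_cutoff",
    "km_estimate",
    "logrank_test",
    "cox_fit",
]

_QUANTILE_MODES = {"q25": 0.25, "median": 0.50, "q75": 0.75}


@dataclass
class StratificationResult:
    cutoff_type: str
    labels: pd.Series  # per sample: 'high'/'low' or 'q1'..'qk'
    cutoffs: list[float]
    group_sizes: dict[str, int] = field(default_factory=dict)
    candidate_pvalues: dict[float, float] | None = None  # filled by optimal_cutoff

    def __post_init__(self) -> None:
        self.group_sizes = {str(k): int(v)
                            for k, v in self.labels.value_counts().items()}
        if sum(self.group_sizes.values()) != len(self.labels):
            raise CoxisError("stratification labels do not cover all samples")


def stratify(scores: pd.Series, mode: str = "median",
             k_quantiles: int | None = None) -> StratificationResult:
    """Split samples by a score quantile.

    Two-group modes ('q25', 'median', 'q75'): label 'high' iff score is
    strictly greater than the cutoff quantile (type-7 / linear
    interpolation); ties at the cutoff go to 'low'.  ``k_quantiles=k``
    instead produces k ordered groups 'q1' (lowest scores) .. 'qk' of
    near-equal size (difference at most 1), ties broken by stable input
    order.
    """
    n = len(scores)
    vals = scores.to_numpy(dtype=float)
    if k_quantiles is not None:
        k = int(k_quantiles)
        if k < 2:
            raise CoxisError("k_quantiles must be >= 2")
        if n < 2 * k:
            raise CoxisError(f"need at least {2 * k} samples for {k} quantile groups")
        order = np.argsort(vals, kind="stable")
        labels = np.empty(n, dtype=object)
        # earlier groups take the extra sample when n % k != 0
        for g, chunk in enumerate(np.array_split(order, k), start=1):
            labels[chunk] = f"q{g}"
        cutpoints = list(np.quantile(vals, [i / k for i in range(1, k)]))
        return StratificationResult(cutoff_type=f"quantiles_{k}",
                                    labels=pd.Series(labels, index=scores.index, name="group"),
                                    cutoffs=cutpoints)
    if mode not in _QUANTILE_MODES:
        raise CoxisError(f"unknown mode {mode!r}; expected one of {sorted(_QUANTILE_MODES)}")
    if n < 4:
        raise CoxisError("need at least 4 samples for a two-group split")
    q = _QUANTILE_MODES[mode]
    cutoff = float(np.quantile(vals, q, method="linear"))
    labels = np.where(vals > cutoff, "high", "low")
    return StratificationResult(cutoff_type=mode,
                                labels=pd.Series(labels, index=scores.index, name="group"),
                                cutoffs=[cutoff])


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float


def logrank_test(times, events, labels) -> LogrankResult:
    """Mantel-Cox log-rank test across k >= 2 groups (chi-square, df = k-1)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(labels)
    groups, counts = np.unique(g, return_counts=True)
    if len(groups) < 2:
        raise CoxisError("log-rank test needs at least 2 non-empty groups")
    if e.sum() == 0:
        raise CoxisError("log-rank test needs at least one event")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(statistic=float(res.test_statistic),
                         df=len(groups) - 1,
                         p_value=float(res.p_value))


def optimal_cutoff(
    scores: pd.Series,
    clinical: ClinicalTable,
    candidates: tuple[float, ...] = (0.25, 0.50, 0.75),
) -> StratificationResult:
    """Pick the candidate quantile split with the lowest log-rank p.

    The result carries the complete per-candidate p table: optimal-cutoff
    selection is a multiple-testing procedure and the evidence for the
    chosen split should never be read off the minimum p alone.  Ties in p
    go to the lower quantile; a candidate whose two arms both contain zero
    events is skipped with a warning.
    """
    common = scores.index.intersection(clinical.data.index)
    if len(common) < 4:
        raise CoxisError("too few samples shared between scores and clinical table")
    s = scores.loc[common]
    t = clinical.data.loc[common, ClinicalTable.TIME].to_numpy(dtype=float)
    e = clinical.data.loc[common, ClinicalTable.EVENT].to_numpy(dtype=int)
    mode_of = {0.25: "q25", 0.50: "median", 0.75: "q75"}
    pvals: dict[float, float] = {}
    strata: dict[float, StratificationResult] = {}
    for q in candidates:
        mode = mode_of.get(q)
        if mode is None:
            raise CoxisError(f"unsupported candidate quantile {q}")
        res = stratify(s, mode=mode)
        lab = res.labels.to_numpy()
        events_per_arm = [e[lab == arm].sum() for arm in np.unique(lab)]
        if len(np.unique(lab)) < 2 or all(v == 0 for v in events_per_arm):
            warnings.warn(f"candidate q={q}: no events in either arm; skipped",
                          stacklevel=2)
            continue
        lr = logrank_test(t, e, lab)
        pvals[q] = lr.p_value
        strata[q] = res
    if not pvals:
        raise CoxisError("no candidate cutoff was evaluable")
    if min(pvals.values()) > 0.999:
        warnings.warn("all candidate cutoffs give log-rank p ~ 1; "
                      "score appears uninformative", stacklevel=2)
    best_q = min(sorted(pvals), key=lambda q: (pvals[q], q))
    best = strata[best_q]
    best.candidate_pvalues = dict(sorted(pvals.items()))
    return best


@dataclass
class KMCurve:
    """Product-limit survival curve: S(0) = 1, non-increasing steps."""

    times: np.ndarray
    survival: np.ndarray
    median: float  # NaN when S never reaches 0.5

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator with median survival time."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise CoxisError("km_estimate needs at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    med = float(kmf.median_survival_time_)
    if np.isinf(med):
        med = float("nan")
    return KMCurve(times=sf.index.to_numpy(dtype=float),
                   survival=sf.iloc[:, 0].to_numpy(dtype=float),
                   median=med)


@dataclass
class SurvivalFit:
    """Cox PH fit summary: per-variable HR with 95% CI and Wald p."""

    table: pd.DataFrame  # index variable; columns coef, hr, hr_low, hr_high, p
    log_likelihood: float
    n: int
    n_events: int
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        hr = self.table["hr"].to_numpy()
        if (hr <= 0).any():
            raise CoxisError("hazard ratios must be positive")
        if ((self.table["hr_low"] > hr) | (self.table["hr_high"] < hr)).any():
            raise CoxisError("HR outside its confidence interval")

    def hr(self, variable: str) -> float:
        return float(self.table.loc[variable, "hr"])


def cox_fit(
    clinical: ClinicalTable,
    scores: pd.Series | None = None,
    score_name: str = "score",
    covariates: tuple[str, ...] = (),
    warn_events_below: int = 10,
) -> SurvivalFit:
    """Cox proportional-hazards regression of overall survival on a score.

    Univariate when ``covariates`` is empty; multivariate adds the named
    clinical columns (categorical columns are expanded to indicators).
    Rows with missing values in any used column are dropped and counted.
    Efron approximation for tied event times.
    """
    df = clinical.data.copy()
    cols = [ClinicalTable.TIME, ClinicalTable.EVENT]
    if scores is not None:
        df[score_name] = scores.reindex(df.index)
        cols.append(score_name)
    for c in covariates:
        if c not in df.columns:
            raise CoxisError(f"covariate {c!r} not in clinical table")
        cols.append(c)
    sub = df[cols]
    n_before = len(sub)
    sub = sub.dropna()
    n_dropped = n_before - len(sub)
    design = pd.get_dummies(sub, drop_first=True, dtype=float)
    predictors = [c for c in design.columns
                  if c not in (ClinicalTable.TIME, ClinicalTable.EVENT)]
    if not predictors:
        raise CoxisError("cox_fit needs at least one predictor")
    X = design[predictors].to_numpy(dtype=float)
    if np.linalg.matrix_rank(np.column_stack([X, np.ones(len(X))])) < len(predictors) + 1:
        raise CoxisError("design matrix is rank-deficient (collinear predictors); "
                         "model is non-identifiable")
    n_events = int(design[ClinicalTable.EVENT].sum())
    if n_events < warn_events_below:
        warnings.warn(f"only {n_events} events; Cox estimates will be unstable",
                      stacklevel=2)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col=ClinicalTable.TIME,
                    event_col=ClinicalTable.EVENT)
    except ConvergenceError as err:
        raise CoxisError(f"Cox model failed to converge: {err}") from err
    summ = cph.summary
    table = pd.DataFrame({
        "coef": summ["coef"],
        "hr": summ["exp(coef)"],
        "hr_low": np.exp(summ["coef lower 95%"]),
        "hr_high": np.exp(summ["coef upper 95%"]),
        "p": summ["p"],
    })
    table.index.name = "variable"
    return SurvivalFit(table=table,
                       log_likelihood=float(cph.log_likelihood_),
                       n=len(design), n_events=n_events,
                       n_dropped_missing=n_dropped)
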