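"""Immunotherapy-response analysis: responder pooling, ROC AUC, nested GLMs.

Best-overall-response categories are pooled to a binary responder flag
under one of two published conventions (stable disease counted with the
non-responders, or with the responders), the score's discrimination is
summarized as ROC AUC with an explicit orientation (for the COX-IS a LOW
score marks the likely responder), and the added value of a score over
clinical covariates (TMB, PD-L1 immune-cell level) is quantified by nested
binomial GLMs compared with the chi-square deviance test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .association import GroupComparison, group_compare
from .datatypes import CoxisError, ResponseCategory, ResponseTable
from .scoring import ScoreTable

__all__ = [
    "BinaryResponse",
    "GlmFit",
    "pool_responses",
    "roc_auc",
    "pd_vs_cr_subset",
    "logistic_fit",
    "nested_model_test",
    "deviance_explained",
    "signature_benchmark",
]

_CONVENTIONS = {
    # SD pooled with non-responders (renal / bladder convention)
    "sd_nonresponder": {"PD": 0, "SD": 0, "PR": 1, "CR": 1},
    # SD pooled with responders (melanoma / gastric convention)
    "sd_responder": {"PD": 0, "SD": 1, "PR": 1, "CR": 1},
}


@dataclass
class BinaryResponse:
    """Binary responder flags derived from RECIST-like categories."""

    responder: pd.Series  # 0/1, indexed by sample id
    convention: str
    source_category: pd.Series
    n_ne_dropped: int = 0


def pool_responses(r: ResponseTable, convention: str = "sd_nonresponder") -> BinaryResponse:
    """Pool CR/PR/SD/PD to responder (1) vs non-responder (0).

    Not-evaluable (NE) samples are dropped and counted.  The table should
    be baseline-only (apply :func:`coxis.io.exclude_on_treatment` first).
    """
    if convention not in _CONVENTIONS:
        raise CoxisError(f"unknown convention {convention!r}; "
                         f"expected one of {sorted(_CONVENTIONS)}")
    mapping = _CONVENTIONS[convention]
    cats = r.data["category"].astype(str)
    ne_mask = cats == ResponseCategory.NE.value
    kept = cats[~ne_mask]
    unknown = set(kept) - set(mapping)
    if unknown:
        raise CoxisError(f"cannot pool unknown categories: {sorted(unknown)}")
    responder = kept.map(mapping).astype(int)
    responder.name = "responder"
    return BinaryResponse(responder=responder, convention=convention,
                          source_category=kept, n_ne_dropped=int(ne_mask.sum()))


def roc_auc(scores, labels, low_score_is_positive: bool = False) -> float:
    """ROC AUC: P(score of a random positive beats a random negative),
    ties counting one half.

    With ``low_score_is_positive`` the scores are negated first, the right
    orientation for the COX-IS where responders sit at the low end.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    classes = np.unique(y)
    if len(classes) != 2:
        raise CoxisError("roc_auc needs both classes present")
    if low_score_is_positive:
        s = -s
    return float(roc_auc_score(y, s))


def pd_vs_cr_subset(r: ResponseTable) -> tuple[ResponseTable, dict[str, int]]:
    """Restrict to the clear-cut extremes: progressive disease vs complete
    response (CR is the positive class).  Returns the subset and counts."""
    cats = r.data["category"].astype(str)
    keep = cats.isin([ResponseCategory.PD.value, ResponseCategory.CR.value])
    counts = {
        "PD": int((cats == "PD").sum()),
        "CR": int((cats == "CR").sum()),
        "dropped": int((~keep).sum()),
    }
    if counts["PD"] == 0 or counts["CR"] == 0:
        raise CoxisError(f"pd_vs_cr_subset needs both classes; counts: {counts}")
    return ResponseTable(data=r.data.loc[keep].copy()), counts


@dataclass
class GlmFit:
    """A fitted binomial GLM with the deviances nested tests need."""

    predictors: tuple[str, ...]       # conceptual predictors, pre-expansion
    design_columns: tuple[str, ...]   # expanded columns incl. indicators
    params: pd.Series
    null_deviance: float
    deviance: float
    n: int
    llf: float

    def __post_init__(self) -> None:
        if self.deviance > self.null_deviance + 1e-8 and self.predictors:
            raise CoxisError("residual deviance exceeds null deviance in an "
                             "intercept-containing model")


def _build_design(predictors: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical/object columns to drop-first indicator columns."""
    return pd.get_dummies(predictors, drop_first=True, dtype=float)


def logistic_fit(response: pd.Series, predictors: pd.DataFrame | None = None) -> GlmFit:
    """Maximum-likelihood binomial GLM (logit link) with intercept.

    Categorical predictors (e.g. PD-L1 IC level) expand to indicator
    columns.  Perfect separation and non-convergence raise rather than
    returning a silently penalized fit, since downstream deviance tests
    assume plain maximum likelihood.
    """
    y = pd.Series(response).astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise CoxisError("response must be binary 0/1")
    if predictors is None or predictors.shape[1] == 0:
        design = pd.DataFrame(index=y.index)
        names: tuple[str, ...] = ()
    else:
        predictors = predictors.loc[y.index]
        design = _build_design(predictors)
        names = tuple(predictors.columns)
    if len(y) <= design.shape[1] + 1:
        raise CoxisError("need n > number of predictors + 1")
    X = sm.add_constant(design.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CoxisError("collinear predictors; logistic model non-identifiable")
    model = sm.GLM(y.to_numpy(dtype=float), X, family=sm.families.Binomial())
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            # divergence is detected below on the fitted params
            _warnings.simplefilter("ignore")
            res = model.fit(maxiter=200, tol=1e-10)
    except Exception as err:  # statsmodels raises PerfectSeparationError etc.
        raise CoxisError(f"logistic fit failed: {err}") from err
    if not np.all(np.isfinite(res.params)) or np.max(np.abs(res.params)) > 50:
        raise CoxisError("logistic fit diverged (likely complete separation)")
    params = pd.Series(res.params, index=["const", *design.columns])
    return GlmFit(predictors=names,
                  design_columns=tuple(design.columns),
                  params=params,
                  null_deviance=float(res.null_deviance),
                  deviance=float(res.deviance),
                  n=int(res.nobs),
                  llf=float(res.llf))


def nested_model_test(small: GlmFit, large: GlmFit) -> tuple[float, int, float]:
    """Chi-square deviance test of a nested GLM pair.

    Returns (statistic, df, p) with statistic = deviance(small) −
    deviance(large) and df the number of added design columns.
    """
    if not set(small.predictors) <= set(large.predictors):
        raise CoxisError("models are not nested: small has predictors the "
                         "large model lacks")
    if small.n != large.n:
        raise CoxisError("nested models must be fitted on the same samples")
    df = len(large.design_columns) - len(small.design_columns)
    if df < 0:
        raise CoxisError("large model has fewer design columns than small")
    stat = small.deviance - large.deviance
    if stat < 0:
        if stat < -1e-6:
            raise CoxisError(f"negative deviance difference ({stat:g}); "
                             "models are not a valid nested MLE pair")
        stat = 0.0
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return float(stat), df, p


def deviance_explained(fit: GlmFit) -> float:
    """Fraction of null deviance explained: 1 − residual/null deviance."""
    if fit.null_deviance == 0:
        raise CoxisError("null deviance is zero; explained fraction undefined")
    frac = 1.0 - fit.deviance / fit.null_deviance
    return float(min(max(frac, 0.0), 1.0))


def signature_benchmark(
    score_table: ScoreTable,
    responder: pd.Series,
    signatures: list[str] | None = None,
    low_favorable: dict[str, bool] | None = None,
    test: str = "mann_whitney",
) -> pd.DataFrame:
    """Responder-vs-non-responder comparison for each scored signature.

    One row per signature with the two-sample p, −log10 p and the ROC AUC
    computed in each signature's favorable orientation (the COX-IS is
    low-favorable; comparator inflammation signatures are high-favorable).
    """
    if signatures is None:
        signatures = list(score_table.scores.columns)
    if low_favorable is None:
        low_favorable = {}
    common = score_table.scores.index.intersection(responder.index)
    if len(common) < 4:
        raise CoxisError("too few samples shared between scores and responses")
    y = responder.loc[common].astype(int)
    rows = []
    for name in signatures:
        if name not in score_table.scores.columns:
            raise CoxisError(f"signature {name!r} not in score table")
        s = score_table.scores.loc[common, name]
        low_fav = low_favorable.get(name, name.upper().startswith("COX"))
        cmp = group_compare(s.to_numpy(), y.to_numpy(), test=test)
        auc = roc_auc(s.to_numpy(), y.to_numpy(), low_score_is_positive=low_fav)
        rows.append({
            "signature": name,
            "p": cmp.p_value,
            "neg_log10_p": -np.log10(cmp.p_value) if cmp.p_value > 0 else np.inf,
            "auc": auc,
            "direction": cmp.direction,
            "orientation": "low_favorable" if low_fav else "high_favorable",
            "n_responders": int(y.sum()),
            "n_nonresponders": int((1 - y).sum()),
        })
    return pd.DataFrame(rows).set_index("signature")
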