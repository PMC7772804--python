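"""Correlation profiling against an anchor gene and extreme-group comparisons.

The characteristic signature structure is visible as the sign pattern of
Pearson correlations of each signature gene with the COX-2 gene (PTGS2):
positive for the cancer-promoting program, negative for the
cancer-inhibitory one.  Extreme-group utilities (top/bottom quartile
stratification and two-sample comparison) support marker-high vs marker-low
contrasts and responder vs non-responder comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CoxisError, ExpressionMatrix, Scale
from .signatures import resolve_genes

__all__ = [
    "CorrelationProfile",
    "pearson_profile",
    "correlation_heatmap_matrix",
    "stratify_extremes",
    "group_compare",
    "GroupComparison",
]


@dataclass
class CorrelationProfile:
    """Pearson r (and two-sided p) of each target gene with an anchor gene."""

    anchor_gene: str
    table: pd.DataFrame  # index = target genes; columns r, p, n

    def __post_init__(self) -> None:
        r = self.table["r"].to_numpy(dtype=float)
        finite = np.isfinite(r)
        if (np.abs(r[finite]) > 1 + 1e-12).any():
            raise CoxisError("correlation coefficients outside [-1, 1]")

    def with_bh_adjustment(self) -> "CorrelationProfile":
        """Optional Benjamini-Hochberg adjusted p column."""
        from statsmodels.stats.multitest import multipletests

        out = self.table.copy()
        ok = np.isfinite(out["p"].to_numpy(dtype=float))
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok] = multipletests(out["p"].to_numpy()[ok], method="fdr_bh")[1]
        out["p_bh"] = adj
        return CorrelationProfile(anchor_gene=self.anchor_gene, table=out)


def pearson_profile(
    m: ExpressionMatrix,
    anchor: str,
    targets: list[str],
) -> CorrelationProfile:
    """Pearson r of ``anchor`` against each target across samples."""
    if m.n_samples < 3:
        raise CoxisError("pearson_profile needs at least 3 samples")
    anchor_rep = resolve_genes([anchor], m.gene_ids)
    if not anchor_rep.matched:
        raise CoxisError(f"anchor gene {anchor!r} not present in matrix")
    anchor_id = anchor_rep.matched[0]
    target_rep = resolve_genes(targets, m.gene_ids)
    if not target_rep.matched:
        raise CoxisError("no target genes present in matrix")
    x = m.values.loc[anchor_id].to_numpy(dtype=float)
    if np.std(x) == 0:
        raise CoxisError(f"anchor gene {anchor!r} has zero variance")
    rows = {}
    matched_iter = iter(target_rep.matched)
    for requested in target_rep.requested:
        if requested in target_rep.unmatched:
            continue
        gid = next(matched_iter)
        y = m.values.loc[gid].to_numpy(dtype=float)
        if np.std(y) == 0:
            warnings.warn(f"target {gid} has zero variance; r reported as missing",
                          stacklevel=2)
            rows[requested] = (np.nan, np.nan, len(y))
            continue
        r, p = stats.pearsonr(x, y)
        rows[requested] = (r, p, len(y))
    table = pd.DataFrame.from_dict(rows, orient="index", columns=["r", "p", "n"])
    table.index.name = "gene"
    return CorrelationProfile(anchor_gene=anchor_id, table=table)


def correlation_heatmap_matrix(m: ExpressionMatrix, genes: list[str]) -> pd.DataFrame:
    """Square symmetric Pearson correlation matrix over ``genes``.

    Row/column order follows the input order; the diagonal is exactly 1.
    """
    if m.n_samples < 3:
        raise CoxisError("correlation matrix needs at least 3 samples")
    rep = resolve_genes(genes, m.gene_ids)
    if len(rep.matched) < 2:
        raise CoxisError(f"need >=2 genes present; missing: {rep.unmatched}")
    sub = m.values.loc[rep.matched].to_numpy(dtype=float)
    if (sub.std(axis=1) == 0).any():
        warnings.warn("zero-variance genes yield NaN correlations", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(sub)
    corr = (corr + corr.T) / 2.0
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=rep.matched, columns=rep.matched)


def stratify_extremes(scores: pd.Series, top_frac: float = 0.25) -> pd.Series:
    """Label the top and bottom ``top_frac`` of samples 'high'/'low', rest 'mid'.

    Group sizes are both floor(top_frac * n).  Ties at a boundary are broken
    by stable input order: among equal scores, earlier samples enter the low
    group and later samples the high group.
    """
    n = len(scores)
    if n < 4:
        raise CoxisError("stratify_extremes needs at least 4 samples")
    if not (0 < top_frac <= 0.5):
        raise CoxisError("top_frac must be in (0, 0.5]")
    m = int(np.floor(top_frac * n))
    vals = scores.to_numpy(dtype=float)
    if np.all(vals == vals[0]):
        warnings.warn("all scores equal; extreme groups determined by input order",
                      stacklevel=2)
    order = np.argsort(vals, kind="stable")
    labels = np.array(["mid"] * n, dtype=object)
    labels[order[:m]] = "low"
    labels[order[n - m:]] = "high"
    return pd.Series(labels, index=scores.index, name="group")


@dataclass
class GroupComparison:
    statistic: float
    p_value: float
    direction: int  # sign of (mean of group 1) - (mean of group 0)
    test: str
    n0: int = 0
    n1: int = 0


def group_compare(values: pd.Series | np.ndarray,
                  labels: pd.Series | np.ndarray,
                  test: str = "mann_whitney") -> GroupComparison:
    """Two-sided two-sample comparison between the label-1 and label-0 groups.

    ``mann_whitney`` uses the exact null when sample sizes permit and no
    ties are present, matching a full label-permutation reference; with
    ties it falls back to the tie-corrected normal approximation (no
    continuity correction, so identical groups give p = 1).
    """
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    uniq = np.unique(lab)
    if len(uniq) != 2:
        raise CoxisError(f"need exactly 2 groups, got {len(uniq)}")
    g0 = v[lab == uniq[0]]
    g1 = v[lab == uniq[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise CoxisError("each group needs at least 2 values")
    direction = int(np.sign(g1.mean() - g0.mean()))
    if test == "welch_t":
        res = stats.ttest_ind(g1, g0, equal_var=False)
        return GroupComparison(float(res.statistic), float(res.pvalue), direction,
                               test, len(g0), len(g1))
    if test == "mann_whitney":
        res = stats.mannwhitneyu(g1, g0, alternative="two-sided",
                                 use_continuity=False, method="auto")
        return GroupComparison(float(res.statistic), float(min(res.pvalue, 1.0)),
                               direction, test, len(g0), len(g1))
    raise ValueError(f"unknown test {test!r}")
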