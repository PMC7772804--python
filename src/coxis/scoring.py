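"""Signature scores and the COX-IS ratio.

Per-sample signature scores are means over the matched signature genes, on
log2 or Z-scored expression.  The COX-IS itself is the ratio

    COX-IS_i = mean over CP genes of e_gi / mean over CI genes of e_gi

on non-negative log2 expression; lower values indicate a tumor whose
inflammatory milieu leans cancer-inhibitory and are the favorable end.
On Z-scored input the ratio is ill-defined (set means can be zero or
negative), so the Z variant is the difference of set means, which preserves
the same "CP up, CI down" ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CoxisError, ExpressionMatrix, GeneSet, Scale, SignaturePair
from .signatures import ResolutionReport, resolve_genes

__all__ = [
    "ScoreTable",
    "mean_signature_score",
    "coxis_score",
    "coxis_score_zdiff",
    "DEFAULT_RESOLUTION_FLOOR",
    "DENOMINATOR_EPSILON",
]

DEFAULT_RESOLUTION_FLOOR = 0.5
DENOMINATOR_EPSILON = 1e-8


@dataclass
class ScoreTable:
    """Per-sample scores for one or more signatures.

    ``scores`` has one row per sample of the scored matrix and one column
    per signature; ``metadata`` records, per column, the scoring method and
    the genes actually used after alias resolution.
    """

    scores: pd.DataFrame
    metadata: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            raise CoxisError("score table contains non-finite values")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    def column(self, name: str) -> pd.Series:
        return self.scores[name]

    def add(self, name: str, values: pd.Series, meta: dict) -> None:
        self.scores[name] = values
        self.metadata[name] = meta


def _resolve_or_fail(genes, m: ExpressionMatrix, floor: float, what: str) -> ResolutionReport:
    rep = resolve_genes(genes, m.gene_ids)
    if rep.fraction_matched < floor:
        raise CoxisError(
            f"{what}: only {len(rep.matched)}/{len(rep.requested)} genes present "
            f"(floor {floor:.0%}); missing: {rep.unmatched}"
        )
    return rep


def mean_signature_score(
    m: ExpressionMatrix,
    s: GeneSet,
    method: str = "mean_log2",
    min_fraction: float = DEFAULT_RESOLUTION_FLOOR,
) -> ScoreTable:
    """Mean expression of the matched signature genes, per sample.

    ``method="mean_log2"`` expects a (non-Z-scored) log2 matrix;
    ``method="mean_zscore"`` expects a Z-scored one.
    """
    if method not in ("mean_log2", "mean_zscore"):
        raise ValueError(f"unknown method {method!r}")
    if m.scale is not Scale.LOG2:
        raise CoxisError("mean_signature_score requires a log2-scale matrix")
    if method == "mean_zscore" and not m.zscored:
        raise CoxisError("method 'mean_zscore' requires a Z-scored matrix")
    if method == "mean_log2" and m.zscored:
        raise CoxisError("method 'mean_log2' requires a non-Z-scored log2 matrix")
    rep = _resolve_or_fail(s.genes, m, min_fraction, f"signature {s.name!r}")
    vals = m.values.loc[rep.matched].mean(axis=0)
    scores = pd.DataFrame({s.name: vals})
    scores.index.name = "sample_id"
    meta = {
        "method": method,
        "genes_used": list(rep.matched),
        "n_matched": len(rep.matched),
        "unmatched": list(rep.unmatched),
        "alias_substitutions": dict(rep.alias_substitutions),
    }
    return ScoreTable(scores=scores, metadata={s.name: meta})


def coxis_score(
    m: ExpressionMatrix,
    pair: SignaturePair | None = None,
    min_fraction: float = DEFAULT_RESOLUTION_FLOOR,
    epsilon: float = DENOMINATOR_EPSILON,
    column: str = "COX-IS",
) -> ScoreTable:
    """The COX-IS ratio: mean CP expression over mean CI expression.

    The matched gene counts after aliasing replace the nominal list sizes,
    so each side stays a mean.  A denominator mean at or below ``epsilon``
    is a hard error naming the sample — clamping would silently distort the
    ranking of extreme samples.
    """
    if pair is None:
        from .signatures import builtin_coxis

        pair = builtin_coxis()
    if m.scale is not Scale.LOG2 or m.zscored:
        raise CoxisError(
            "coxis_score requires non-negative log2 expression; "
            "use coxis_score_zdiff for Z-scored input"
        )
    if (m.values.to_numpy() < 0).any():
        raise CoxisError("coxis_score requires non-negative expression values")
    pos_rep = _resolve_or_fail(pair.pos_genes, m, min_fraction, f"{pair.name} pos")
    neg_rep = _resolve_or_fail(pair.neg_genes, m, min_fraction, f"{pair.name} neg")
    pos_mean = m.values.loc[pos_rep.matched].mean(axis=0)
    neg_mean = m.values.loc[neg_rep.matched].mean(axis=0)
    tiny = neg_mean <= epsilon
    if tiny.any():
        bad = list(neg_mean.index[tiny])[:5]
        raise CoxisError(
            f"denominator (mean CI expression) <= {epsilon:g} for sample(s) {bad}; "
            "refusing to divide"
        )
    scores = pd.DataFrame({column: pos_mean / neg_mean})
    scores.index.name = "sample_id"
    meta = {
        "method": "ratio",
        "pos_genes_used": list(pos_rep.matched),
        "neg_genes_used": list(neg_rep.matched),
        "n_pos": len(pos_rep.matched),
        "n_neg": len(neg_rep.matched),
        "alias_substitutions": {**pos_rep.alias_substitutions, **neg_rep.alias_substitutions},
        "unmatched": pos_rep.unmatched + neg_rep.unmatched,
    }
    return ScoreTable(scores=scores, metadata={column: meta})


def coxis_score_zdiff(
    m: ExpressionMatrix,
    pair: SignaturePair | None = None,
    min_fraction: float = DEFAULT_RESOLUTION_FLOOR,
    column: str = "COX-IS_zdiff",
) -> ScoreTable:
    """Z-score variant of the COX-IS: mean CP z minus mean CI z."""
    if pair is None:
        from .signatures import builtin_coxis

        pair = builtin_coxis()
    if m.scale is not Scale.LOG2 or not m.zscored:
        raise CoxisError("coxis_score_zdiff requires a Z-scored log2 matrix")
    pos_rep = _resolve_or_fail(pair.pos_genes, m, min_fraction, f"{pair.name} pos")
    neg_rep = _resolve_or_fail(pair.neg_genes, m, min_fraction, f"{pair.name} neg")
    diff = m.values.loc[pos_rep.matched].mean(axis=0) - m.values.loc[neg_rep.matched].mean(axis=0)
    scores = pd.DataFrame({column: diff})
    scores.index.name = "sample_id"
    meta = {
        "method": "zdiff",
        "pos_genes_used": list(pos_rep.matched),
        "neg_genes_used": list(neg_rep.matched),
        "n_pos": len(pos_rep.matched),
        "n_neg": len(neg_rep.matched),
        "alias_substitutions": {**pos_rep.alias_substitutions, **neg_rep.alias_substitutions},
    }
    return ScoreTable(scores=scores, metadata={column: meta})
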