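"""Expression normalization: CPM, low-expression filtering, log2, Z-scores.

The canonical bulk RNA-seq preprocessing chain for signature scoring is
counts -> CPM -> filter genes below 0.25 CPM in 10% of samples -> log2(CPM+1),
optionally followed by per-gene Z-scoring for scale-free signature means.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd

from .datatypes import CoxisError, ExpressionMatrix, Scale

log = logging.getLogger(__name__)

__all__ = [
    "cpm_normalize",
    "filter_low_expression",
    "log2_plus1",
    "zscore_genes",
    "normalize_counts",
]


def _require_scale(m: ExpressionMatrix, scale: Scale, op: str) -> None:
    if m.scale is not scale:
        raise CoxisError(f"{op} requires a {scale.value}-scale matrix, got {m.scale.value}")


def cpm_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Counts-per-million scaling: v_gs -> v_gs / colsum_s * 1e6."""
    _require_scale(m, Scale.COUNTS, "cpm_normalize")
    colsums = m.values.sum(axis=0)
    zero = colsums[colsums <= 0]
    if len(zero):
        raise CoxisError(f"zero total counts for sample(s): {list(zero.index)[:5]}")
    cpm = m.values.div(colsums, axis=1) * 1e6
    return ExpressionMatrix(values=cpm, scale=Scale.LINEAR)


def filter_low_expression(
    m: ExpressionMatrix,
    cpm_threshold: float = 0.25,
    sample_fraction: float = 0.10,
) -> ExpressionMatrix:
    """Drop genes not reaching ``cpm_threshold`` CPM in enough samples.

    A gene survives iff its CPM is >= ``cpm_threshold`` (inclusive) in at
    least ceil(``sample_fraction`` * n_samples) samples.  The returned
    matrix contains the raw counts of the surviving genes; the CPM values
    are recomputed internally from the unfiltered library sizes.
    """
    _require_scale(m, Scale.COUNTS, "filter_low_expression")
    cpm = cpm_normalize(m).values
    min_samples = math.ceil(sample_fraction * m.n_samples)
    n_passing = (cpm >= cpm_threshold).sum(axis=1)
    keep = n_passing >= min_samples
    n_dropped = int((~keep).sum())
    if n_dropped:
        log.info("filter_low_expression dropped %d/%d genes", n_dropped, m.n_genes)
    return ExpressionMatrix(values=m.values.loc[keep], scale=Scale.COUNTS)


def log2_plus1(m: ExpressionMatrix) -> ExpressionMatrix:
    """log2(value + 1) transform of a linear-scale matrix."""
    _require_scale(m, Scale.LINEAR, "log2_plus1")
    arr = m.values.to_numpy()
    if arr.size and (arr < 0).any():
        raise CoxisError("log2_plus1 requires non-negative values")
    out = pd.DataFrame(np.log2(arr + 1.0), index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=out, scale=Scale.LOG2)


def zscore_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene Z-score across samples (n-1 denominator).

    Zero-variance genes become all-zero rows with a warning — they carry no
    ranking information and would otherwise divide by zero.
    """
    _require_scale(m, Scale.LOG2, "zscore_genes")
    if m.n_samples < 2:
        raise CoxisError("zscore_genes needs at least 2 samples")
    arr = m.values.to_numpy(dtype=float)
    mu = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance genes set to all-zero rows: "
            f"{list(m.values.index[flat][:5])}",
            stacklevel=2,
        )
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (arr - mu) / sd_safe
    z[flat, :] = 0.0
    out = pd.DataFrame(z, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(values=out, scale=Scale.LOG2, zscored=True)


def normalize_counts(
    m: ExpressionMatrix,
    cpm_threshold: float = 0.25,
    sample_fraction: float = 0.10,
    do_filter: bool = True,
) -> ExpressionMatrix:
    """Full counts -> filtered log2(CPM+1) chain."""
    if do_filter:
        m = filter_low_expression(m, cpm_threshold=cpm_threshold,
                                  sample_fraction=sample_fraction)
    return log2_plus1(cpm_normalize(m))
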