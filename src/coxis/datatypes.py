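"""Core in-memory containers for expression, clinical and response data.

All tabular data is held in pandas objects; the thin dataclass wrappers add
the metadata the analysis needs to stay honest about units and scale (raw
counts vs linear-normalized vs log2, survival time in years, RECIST
categories) and enforce the structural invariants the downstream statistics
assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Scale",
    "Timepoint",
    "ResponseCategory",
    "ExpressionMatrix",
    "ClinicalTable",
    "ResponseTable",
    "GeneSet",
    "SignaturePair",
    "CoxisError",
    "ValidationError",
]


class CoxisError(Exception):
    """Base class for package errors."""


class ValidationError(CoxisError):
    """Raised when an input violates a documented structural invariant."""


class Scale(str, Enum):
    """Declared scale of an expression matrix.

    Never guessed from the data: the loader requires an explicit declaration
    because counts, linear-normalized (RSEM/FPKM/TPM-like) and log2 values
    are numerically indistinguishable in pathological cases.
    """

    COUNTS = "counts"
    LINEAR = "linear"
    LOG2 = "log2"


class Timepoint(str, Enum):
    BASELINE = "baseline"
    ON_TREATMENT = "on_treatment"


class ResponseCategory(str, Enum):
    """RECIST-like best-overall-response categories."""

    CR = "CR"
    PR = "PR"
    SD = "SD"
    PD = "PD"
    NE = "NE"


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = pd.Index(ids)
    if seen.has_duplicates:
        dups = seen[seen.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups[:5]}")


@dataclass
class ExpressionMatrix:
    """A genes x samples expression grid with an explicit scale tag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique gene symbols, columns by unique sample ids.
        Values must be finite; NaN is rejected at construction (dense
        matrices only — explicitness beats silent imputation).
    scale : Scale
        Declared scale of the values.
    zscored : bool
        True only for per-gene Z-score-normalized log2 matrices, which are
        the single case where negative log2 values are legal.
    """

    values: pd.DataFrame
    scale: Scale
    zscored: bool = False

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        if arr.size and not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                "non-finite expression value at gene "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        if self.scale is Scale.COUNTS and arr.size and (arr < 0).any():
            raise ValidationError("counts-scale matrix contains negative values")
        if self.scale is Scale.LOG2 and not self.zscored and arr.size and (arr < 0).any():
            raise ValidationError(
                "log2-scale matrix contains negative values but is not flagged z-scored"
            )
        if self.zscored and self.scale is not Scale.LOG2:
            raise ValidationError("zscored flag is only meaningful on log2-scale matrices")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: pd.DataFrame, scale: Scale | None = None,
                    zscored: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=values,
            scale=self.scale if scale is None else scale,
            zscored=self.zscored if zscored is None else zscored,
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        z = ", zscored" if self.zscored else ""
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples, {self.scale.value}{z})"


@dataclass
class ClinicalTable:
    """Per-sample survival endpoints and covariates.

    ``data`` is indexed by unique sample id and must carry ``os_time``
    (overall survival, years, strictly positive) and ``os_event``
    (1 = death observed, 0 = censored).  Any further columns (age, sex,
    numeric stage, ...) ride along as covariates.
    """

    data: pd.DataFrame

    TIME = "os_time"
    EVENT = "os_event"

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        for col in (self.TIME, self.EVENT):
            if col not in self.data.columns:
                raise ValidationError(f"clinical table missing required column {col!r}")
        t = self.data[self.TIME].to_numpy(dtype=float)
        if not np.isfinite(t).all() or (t <= 0).any():
            raise ValidationError("os_time must be finite and > 0 for every sample")
        ev = self.data[self.EVENT].to_numpy()
        if not np.isin(ev, [0, 1]).all():
            raise ValidationError("os_event must be 0 (censored) or 1 (event)")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def times(self) -> np.ndarray:
        return self.data[self.TIME].to_numpy(dtype=float)

    @property
    def events(self) -> np.ndarray:
        return self.data[self.EVENT].to_numpy(dtype=int)


@dataclass
class ResponseTable:
    """Per-sample immune-checkpoint-blockade annotations.

    ``data`` is indexed by unique sample id with columns ``category``
    (CR/PR/SD/PD/NE), optional ``tmb`` (mutations, non-negative or NaN),
    optional ``pdl1_ic`` (ordered categories such as IC0/IC1/IC2+), and
    ``timepoint`` (baseline / on_treatment).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        if "category" not in self.data.columns:
            raise ValidationError("response table missing required column 'category'")
        cats = set(self.data["category"].astype(str))
        legal = {c.value for c in ResponseCategory}
        unknown = cats - legal
        if unknown:
            raise ValidationError(f"unknown response categories: {sorted(unknown)}")
        if "timepoint" not in self.data.columns:
            self.data = self.data.assign(timepoint=Timepoint.BASELINE.value)
        tps = set(self.data["timepoint"].astype(str))
        bad = tps - {t.value for t in Timepoint}
        if bad:
            raise ValidationError(f"unknown timepoints: {sorted(bad)}")
        if "tmb" in self.data.columns:
            tmb = self.data["tmb"].to_numpy(dtype=float)
            if np.nanmin(tmb, initial=0.0) < 0:
                raise ValidationError("tmb must be non-negative or missing")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)


@dataclass(frozen=True)
class GeneSet:
    """A named, non-empty list of unique gene symbols."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.name!r} is empty")
        _check_unique(self.genes, f"genes in set {self.name!r}")
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class SignaturePair:
    """A two-sided signature: cancer-promoting (pos) vs cancer-inhibitory (neg).

    ``n_pos`` and ``n_neg`` are the nominal list sizes; scoring uses the
    matched counts after alias resolution so the score stays a mean.
    """

    name: str
    pos_genes: tuple[str, ...]
    neg_genes: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "pos_genes", tuple(self.pos_genes))
        object.__setattr__(self, "neg_genes", tuple(self.neg_genes))
        if not self.pos_genes or not self.neg_genes:
            raise ValidationError("both sides of a signature pair must be non-empty")
        _check_unique(self.pos_genes, "pos genes")
        _check_unique(self.neg_genes, "neg genes")
        overlap = set(self.pos_genes) & set(self.neg_genes)
        if overlap:
            raise ValidationError(f"pos and neg gene lists overlap: {sorted(overlap)}")

    @property
    def n_pos(self) -> int:
        return len(self.pos_genes)

    @property
    def n_neg(self) -> int:
        return len(self.neg_genes)

    def swapped(self) -> "SignaturePair":
        """The pair with pos and neg exchanged (score reciprocal)."""
        return SignaturePair(name=f"{self.name}_swapped",
                             pos_genes=self.neg_genes, neg_genes=self.pos_genes)
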