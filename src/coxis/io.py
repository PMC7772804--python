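"""Readers and writers for the plain-text formats the pipeline consumes.

Expression matrices are tab-separated text with one header row and one id
column; gene sets use the standard GMT dialect (name, description, then one
gene per tab-separated field).  Clinical and response tables are TSV with a
documented required-column schema; column renaming is handled via the
``column_map`` argument rather than by guessing.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    CoxisError,
    ExpressionMatrix,
    GeneSet,
    ResponseTable,
    Scale,
    Timepoint,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "LoadReport",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "read_response",
    "coerce_stage",
    "exclude_on_treatment",
]


@dataclass
class LoadReport:
    """Bookkeeping for an expression load: what was collapsed or dropped."""

    path: str = ""
    n_genes: int = 0
    n_samples: int = 0
    duplicate_genes_collapsed: dict[str, int] = field(default_factory=dict)

    @property
    def n_duplicates(self) -> int:
        return sum(self.duplicate_genes_collapsed.values())


def read_expression(
    path: str | Path,
    orientation: str = "genes_in_rows",
    scale: Scale | str = Scale.COUNTS,
    duplicate_policy: str = "max",
    report: LoadReport | None = None,
) -> ExpressionMatrix:
    """Load a delimited expression matrix into genes x samples orientation.

    Duplicate gene rows are collapsed (default: element-wise maximum, the
    conservative choice for signal genes; ``duplicate_policy="mean"``
    selects the mean instead) and recorded in ``report``.  Gene symbols are
    uppercased so human/mouse-cased inputs match the built-in signatures.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if duplicate_policy not in ("max", "mean"):
        raise ValueError(f"unknown duplicate_policy {duplicate_policy!r}")
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, skip_blank_lines=True)
    header = raw.iloc[0, 1:].tolist()
    row_ids = raw.iloc[1:, 0].tolist()
    body = raw.iloc[1:, 1:]
    # float() round-trips shortest-repr doubles exactly; pandas' fast
    # parser does not, so convert cell-wise and localize any bad cell
    values = np.empty(body.shape, dtype=float)
    for j in range(body.shape[1]):
        col = body.iloc[:, j].to_numpy()
        for i, cell in enumerate(col):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError):
                raise CoxisError(
                    f"non-numeric cell at row {row_ids[i]!r}, "
                    f"column {header[j]!r}: {cell!r}"
                ) from None
    if np.isnan(values).any():
        raise CoxisError(f"missing values in expression file {path}")
    num = pd.DataFrame(values, index=row_ids, columns=header)
    if orientation == "samples_in_rows":
        num = num.T
    if num.columns.has_duplicates:
        dups = num.columns[num.columns.duplicated()].unique().tolist()
        raise CoxisError(f"duplicate sample ids in {path}: {dups[:5]}")
    num.index = num.index.astype(str).str.upper()
    num.columns = num.columns.astype(str)
    if num.index.has_duplicates:
        counts = num.index.value_counts()
        dup_counts = {g: int(c - 1) for g, c in counts.items() if c > 1}
        agg = "max" if duplicate_policy == "max" else "mean"
        num = num.groupby(level=0, sort=False).agg(agg)
        if report is not None:
            report.duplicate_genes_collapsed.update(dup_counts)
        log.info("collapsed %d duplicate gene rows by %s",
                 sum(dup_counts.values()), duplicate_policy)
    if report is not None:
        report.path = str(path)
        report.n_genes, report.n_samples = num.shape
    num.index.name = "gene"
    return ExpressionMatrix(values=num, scale=Scale(scale))


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the same dialect ``read_expression`` accepts."""
    out = m.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: list[GeneSet] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise CoxisError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name, _desc, *genes = fields
        genes = [g.strip().upper() for g in genes if g.strip()]
        sets.append(GeneSet(name=name, genes=tuple(dict.fromkeys(genes))))
    return sets


def write_gmt(sets: list[GeneSet], path: str | Path, description: str = "na") -> None:
    lines = ["\t".join([s.name, description, *s.genes]) for s in sets]
    Path(path).write_text("\n".join(lines) + "\n")


_CLINICAL_REQUIRED = ("os_time", "os_event")


def read_clinical(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    time_unit: str = "years",
    stage_column: str | None = None,
) -> ClinicalTable:
    """Read a clinical TSV.

    Required columns (after ``column_map`` renaming): ``sample_id``,
    ``os_time``, ``os_event``.  ``time_unit`` in {years, months, days}
    converts to years, the unit used throughout.  If ``stage_column`` is
    given, its labels are coerced to numeric 1-4 via :func:`coerce_stage`
    into a ``stage`` column.
    """
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    if "sample_id" not in df.columns:
        raise CoxisError(f"{path}: missing 'sample_id' column")
    for col in _CLINICAL_REQUIRED:
        if col not in df.columns:
            raise CoxisError(f"{path}: missing required column {col!r}")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    divisor = {"years": 1.0, "months": 12.0, "days": 365.25}.get(time_unit)
    if divisor is None:
        raise CoxisError(f"unknown time_unit {time_unit!r}")
    df["os_time"] = pd.to_numeric(df["os_time"]) / divisor
    if stage_column is not None:
        df["stage"] = [coerce_stage(s) for s in df[stage_column].astype(str)]
    return ClinicalTable(data=df)


def read_response(path: str | Path, column_map: dict[str, str] | None = None) -> ResponseTable:
    """Read an ICB response TSV with columns sample_id, category,
    and optionally tmb, pdl1_ic, timepoint."""
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=column_map)
    if "sample_id" not in df.columns:
        raise CoxisError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    df.index = df.index.astype(str)
    return ResponseTable(data=df)


_STAGE_NOS = re.compile(r"stage\s*i\s*/\s*ii\s*nos", re.IGNORECASE)
_STAGE_ROMAN = re.compile(r"(?:stage)?\s*(IV|III|II|I)\s*[ABC]?\s*$", re.IGNORECASE)
_STAGE_ARABIC = re.compile(r"(?:stage)?\s*([1-4])\s*[ABC]?\s*$", re.IGNORECASE)
_ROMAN = {"I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0}


def coerce_stage(label: object) -> float:
    """Coerce a free-text tumor stage label to a number in {1, 2, 3, 4}.

    Sub-stages collapse to their major stage ("Stage IIIA" -> 3); the
    ambiguous "Stage I/II NOS" annotation maps to 1; anything unrecognized
    returns NaN with a warning rather than failing.
    """
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return float("nan")
    text = str(label).strip()
    if not text:
        return float("nan")
    if _STAGE_NOS.search(text):
        return 1.0
    m = _STAGE_ROMAN.match(text)
    if m:
        return _ROMAN[m.group(1).upper()]
    m = _STAGE_ARABIC.match(text)
    if m:
        return float(m.group(1))
    warnings.warn(f"unrecognized stage label {label!r}; treated as missing", stacklevel=2)
    return float("nan")


def exclude_on_treatment(r: ResponseTable) -> ResponseTable:
    """Drop on-treatment samples, keeping baseline biopsies only."""
    mask = r.data["timepoint"].astype(str) == Timepoint.BASELINE.value
    n_dropped = int((~mask).sum())
    if n_dropped:
        log.info("excluded %d on-treatment samples", n_dropped)
    kept = r.data.loc[mask]
    if kept.empty:
        warnings.warn("all samples were on-treatment; result is empty", stacklevel=2)
    return ResponseTable(data=kept.copy())
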