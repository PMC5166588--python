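"""Case-series domain types and CSV input/output.

A case series is one surgeon's consecutive run of operations, ordered by
case volume (1-based order of operation).  Each record carries the binary
healing-abnormality outcome (mesh erosion / rejection / infection /
exposure within follow-up), the covariates used by the risk model, and the
pre- and postoperative POP-Q exams used for anatomic staging.

The CSV schema is a flat table with one row per patient.  Canonical column
names are listed in :data:`CANONICAL_COLUMNS`; a ``schema_map`` translates
foreign headers (such as the terse names of the deposited study table:
``op ordinal``, ``erosion``, ``0Ba`` …) into canonical ones.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

__all__ = [
    "PopqExam",
    "CaseRecord",
    "CaseSeries",
    "read_case_series",
    "write_case_series",
    "DATASET_SCHEMA_MAP",
    "CANONICAL_COLUMNS",
]

# POP-Q point names in the order they appear in the standard exam grid.
_POPQ_POINTS = ("Aa", "Ba", "C", "D", "Ap", "Bp")
_POPQ_LENGTHS = ("TVL", "GH", "PB")


def _is_missing(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip() == "":
        return True
    return False


@dataclass(frozen=True)
class PopqExam:
    """One POP-Q exam: six point positions plus three lengths, in cm.

    Point positions are signed distances from the hymen (negative = above
    the hymen, the supported position); TVL/GH/PB are positive lengths.
    ``timing`` tags the exam as preoperative or the 12-month follow-up.
    """

    Aa: float | None = None
    Ba: float | None = None
    C: float | None = None
    D: float | None = None
    Ap: float | None = None
    Bp: float | None = None
    TVL: float | None = None
    GH: float | None = None
    PB: float | None = None
    timing: str = "preoperative"

    def __post_init__(self):
        if self.timing not in ("preoperative", "12-month"):
            raise ValidationError(
                f"timing must be 'preoperative' or '12-month', got {self.timing!r}"
            )
        for name in _POPQ_LENGTHS:
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        upper = self.TVL if self.TVL is not None else math.inf
        for name in _POPQ_POINTS:
            v = getattr(self, name)
            if v is None:
                continue
            hi = min(upper, 3.0) if name in ("Aa", "Ap") else upper
            if not (-3.0 <= v <= hi):
                raise ValidationError(
                    f"POP-Q point {name}={v} outside [-3, {hi}] cm"
                )

    def is_empty(self) -> bool:
        return all(
            getattr(self, name) is None for name in _POPQ_POINTS + _POPQ_LENGTHS
        )


@dataclass(frozen=True)
class CaseRecord:
    """One operated patient, keyed by 1-based order of operation."""

    case_index: int
    outcome: int
    age: float | None = None
    bmi: float | None = None
    parity: int | None = None
    operation_time: float | None = None
    popq_pre: PopqExam | None = None
    popq_post: PopqExam | None = None
    followup_complete: bool = True
    reoperation: int | None = None
    bladder_perforation: int | None = None
    sui: int | None = None
    frequency: int | None = None

    def __post_init__(self):
        if self.case_index < 1:
            raise ValidationError(f"case_index must be >= 1, got {self.case_index}")
        if self.outcome not in (0, 1):
            raise ValidationError(f"outcome must be 0 or 1, got {self.outcome!r}")
        for name in ("age", "bmi", "operation_time"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValidationError(f"{name} must be positive, got {v}")
        if self.parity is not None and self.parity < 0:
            raise ValidationError(f"parity must be >= 0, got {self.parity}")
        for name in ("reoperation", "bladder_perforation", "sui", "frequency"):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValidationError(f"{name} must be 0/1 if present, got {v!r}")


class CaseSeries:
    """An ordered, duplicate-free collection of :class:`CaseRecord`.

    Records are stored sorted by ``case_index``; the binary outcome vector in
    case order is available as :attr:`outcomes`.
    """

    def __init__(self, records: Iterable[CaseRecord]):
        recs = sorted(records, key=lambda r: r.case_index)
        seen: set[int] = set()
        for r in recs:
            if r.case_index in seen:
                raise ValidationError(f"duplicate case_index {r.case_index}")
            seen.add(r.case_index)
        self._records: tuple[CaseRecord, ...] = tuple(recs)

    @property
    def records(self) -> tuple[CaseRecord, ...]:
        return self._records

    @property
    def outcomes(self) -> np.ndarray:
        return np.array([r.outcome for r in self._records], dtype=int)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self._records)

    def __getitem__(self, i: int) -> CaseRecord:
        return self._records[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, CaseSeries):
            return NotImplemented
        return self._records == other._records

    def __repr__(self) -> str:
        return f"CaseSeries(n={len(self)}, events={int(self.outcomes.sum())})"

    def complete(self) -> "CaseSeries":
        """Sub-series of follow-up-complete cases (original indices kept)."""
        return CaseSeries(r for r in self if r.followup_complete)

    def to_frame(self) -> pd.DataFrame:
        """Flat canonical-schema DataFrame (one row per case)."""
        rows = [_record_to_row(r) for r in self]
        return pd.DataFrame(rows, columns=CANONICAL_COLUMNS)


# ---------------------------------------------------------------------------
# CSV schema


def _popq_cols(prefix: str) -> list[str]:
    return [f"{prefix}_{p}" for p in _POPQ_POINTS + _POPQ_LENGTHS]


CANONICAL_COLUMNS: tuple[str, ...] = tuple(
    ["case_index", "outcome", "age", "bmi", "parity", "operation_time",
     "followup_complete", "reoperation", "bladder_perforation", "sui",
     "frequency"]
    + _popq_cols("pre")
    + _popq_cols("post")
)

#: Default header translation for the deposited study table.  The study's
#: legend prefixes preoperative POP-Q columns with ``0`` and 12-month
#: follow-up columns with ``1``; ``erosion`` is taken as the binary
#: healing-abnormality flag (the published outcome counts five abnormalities,
#: matching the erosion column rather than the broader ``any cx``).
DATASET_SCHEMA_MAP: dict[str, str] = {
    "op ordinal": "case_index",
    "erosion": "outcome",
    "age": "age",
    "BMI": "bmi",
    "para": "parity",
    "optime": "operation_time",
    "reop": "reoperation",
    "bladder perfo": "bladder_perforation",
    "SUI": "sui",
    "frequency": "frequency",
    **{f"0{p}": f"pre_{p}" for p in _POPQ_POINTS + _POPQ_LENGTHS},
    **{f"1{p}": f"post_{p}" for p in _POPQ_POINTS + _POPQ_LENGTHS},
}

_REQUIRED = ("case_index", "outcome")


def _record_to_row(r: CaseRecord) -> dict:
    row: dict = {
        "case_index": r.case_index,
        "outcome": r.outcome,
        "age": r.age,
        "bmi": r.bmi,
        "parity": r.parity,
        "operation_time": r.operation_time,
        "followup_complete": int(r.followup_complete),
        "reoperation": r.reoperation,
        "bladder_perforation": r.bladder_perforation,
        "sui": r.sui,
        "frequency": r.frequency,
    }
    for prefix, exam in (("pre", r.popq_pre), ("post", r.popq_post)):
        for name in _POPQ_POINTS + _POPQ_LENGTHS:
            row[f"{prefix}_{name}"] = None if exam is None else getattr(exam, name)
    return row


def _float_or_none(value) -> float | None:
    if _is_missing(value):
        return None
    return float(value)


def _int_or_none(value) -> int | None:
    if _is_missing(value):
        return None
    f = float(value)
    if f != int(f):
        raise ValidationError(f"expected an integer, got {value!r}")
    return int(f)


def _row_to_record(row: Mapping[str, object]) -> CaseRecord:
    def exam(prefix: str, timing: str) -> PopqExam | None:
        vals = {
            name: _float_or_none(row.get(f"{prefix}_{name}"))
            for name in _POPQ_POINTS + _POPQ_LENGTHS
        }
        e = PopqExam(timing=timing, **vals)
        return None if e.is_empty() else e

    fu = row.get("followup_complete")
    popq_post = exam("post", "12-month")
    if _is_missing(fu):
        # Absent column: infer completion from the presence of a follow-up exam.
        followup = popq_post is not None
    else:
        followup = bool(_int_or_none(fu))
    return CaseRecord(
        case_index=_int_or_none(row.get("case_index")),
        outcome=_int_or_none(row.get("outcome")),
        age=_float_or_none(row.get("age")),
        bmi=_float_or_none(row.get("bmi")),
        parity=_int_or_none(row.get("parity")),
        operation_time=_float_or_none(row.get("operation_time")),
        popq_pre=exam("pre", "preoperative"),
        popq_post=popq_post,
        followup_complete=followup,
        reoperation=_int_or_none(row.get("reoperation")),
        bladder_perforation=_int_or_none(row.get("bladder_perforation")),
        sui=_int_or_none(row.get("sui")),
        frequency=_int_or_none(row.get("frequency")),
    )


def read_case_series(
    path: str | Path,
    schema_map: Mapping[str, str] | None = None,
) -> CaseSeries:
    """Read a case series from a headered CSV file.

    Parameters
    ----------
    path
        CSV file with one row per case.
    schema_map
        Optional mapping from the file's column names to canonical names
        (see :data:`CANONICAL_COLUMNS`).  Pass :data:`DATASET_SCHEMA_MAP`
        for the deposited study table.  Unmapped/unknown columns are ignored.

    Returns
    -------
    CaseSeries
        Validated and sorted by case order.  Missing optional cells are
        carried as absent — never imputed.

    Raises
    ------
    SchemaError
        If a required column (case order, outcome) is missing after mapping.
    ValidationError
        If any row violates a record invariant; the message carries the
        offending row numbers (1-based, excluding the header).
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if schema_map:
        df = df.rename(columns=dict(schema_map))
    for col in _REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} not found in {path}")
    records: list[CaseRecord] = []
    problems: list[str] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            records.append(_row_to_record(row))
        except ValidationError as exc:
            problems.append(f"row {pos}: {exc}")
    if problems:
        raise ValidationError(
            "invalid rows in case-series CSV:\n" + "\n".join(problems)
        )
    return CaseSeries(records)


def write_case_series(series: CaseSeries, path: str | Path) -> None:
    """Write a case series as a canonical-schema CSV (absent fields → empty
    cells).  ``read_case_series(write_case_series(s))`` round-trips exactly."""
    df = series.to_frame()
    df.to_csv(path, index=False)
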