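"""Canonical cohort table schema and delimited-text round trip.

One row per patient, one column per questionnaire/examination field.  The
on-disk format is plain CSV with a header row; an empty cell encodes a
missing value.  Booleans are stored as 0/1, categorical fields as their
level labels.  ``read_cohort`` validates every cell against the schema and
returns the table together with a :class:`LoadReport` listing the cells it
flagged as missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ColumnSpec",
    "LoadReport",
    "COLUMNS",
    "COLUMN_ORDER",
    "RMDQ_HOUSE_ITEM",
    "STARTBACK_ITEM9_LEVELS",
    "DERIVED_COLUMNS",
    "validate_cohort",
    "write_cohort",
    "read_cohort",
]


class SchemaError(ValueError):
    """A cohort table violates the documented column schema."""


@dataclass(frozen=True)
class ColumnSpec:
    """Declarative description of one cohort column."""

    name: str
    kind: str  # "int" | "bool" | "category" | "id"
    lo: int | None = None
    hi: int | None = None
    levels: tuple[str, ...] | None = None


# Roland-Morris item 21 is the "heavy jobs around the house" item used for
# the impact characteristic in patients not in work.
RMDQ_HOUSE_ITEM = "rmdq_21"

STARTBACK_ITEM9_LEVELS = (
    "not at all",
    "slightly",
    "moderately",
    "very much",
    "extremely",
)

DURATION_LEVELS = ("<6 weeks", "6 weeks-3 months", ">3 months")
REFLEX_LEVELS = ("normal", "slightly reduced", "absent", "significantly reduced")
PINPRICK_LEVELS = ("normal", "reduced", "loss")
SEX_LEVELS = ("female", "male")


def _nrs(name: str) -> ColumnSpec:
    return ColumnSpec(name, "int", 0, 10)


def _bool(name: str) -> ColumnSpec:
    return ColumnSpec(name, "bool")


_COLUMNS: list[ColumnSpec] = [
    ColumnSpec("patient_id", "id"),
    ColumnSpec("age", "int", 18, 100),
    ColumnSpec("sex", "category", levels=SEX_LEVELS),
    _nrs("leg_pain_current"),
    _nrs("leg_pain_usual"),
    _nrs("back_pain_current"),
    _nrs("back_pain_usual"),
    _bool("pain_below_knee"),
    _bool("in_work"),
    _nrs("work_interference"),
    *[_bool(f"rmdq_{i:02d}") for i in range(1, 25)],
    *[ColumnSpec(f"startback_{i}", "int", 0, 1) for i in range(1, 9)],
    ColumnSpec("startback_9", "category", levels=STARTBACK_ITEM9_LEVELS),
    ColumnSpec("both_leg_pain", "int", 0, 6),
    ColumnSpec("both_paraesthesia", "int", 0, 6),
    ColumnSpec("both_weakness", "int", 0, 6),
    ColumnSpec("both_sitting", "int", 0, 6),
    ColumnSpec("pain_self_efficacy", "int", 0, 60),
    ColumnSpec("illness_identity", "int", 0, 10),
    _bool("leg_worse_than_back"),
    _bool("tingling_numbness"),
    _bool("cough_sneeze_positive"),
    ColumnSpec("duration_category", "category", levels=DURATION_LEVELS),
    _bool("myotomal_weakness"),
    ColumnSpec("reflex_status", "category", levels=REFLEX_LEVELS),
    ColumnSpec("pinprick_sensation", "category", levels=PINPRICK_LEVELS),
    _bool("neural_tension_positive"),
    ColumnSpec("diagnostic_confidence", "int", 0, 100),
    _bool("referred"),
]

COLUMNS: dict[str, ColumnSpec] = {c.name: c for c in _COLUMNS}
COLUMN_ORDER: tuple[str, ...] = tuple(c.name for c in _COLUMNS)

# Columns appended by the scoring/derivation modules; accepted on read so a
# scored cohort file can be re-loaded, but never required.
DERIVED_COLUMNS: dict[str, ColumnSpec] = {
    c.name: c
    for c in [
        ColumnSpec("startback_total", "int", 0, 9),
        ColumnSpec("startback_psych", "int", 0, 5),
        ColumnSpec("startback_risk", "category", levels=("low", "medium", "high")),
        _bool("c_impact"),
        _bool("c_leg_pain"),
        _bool("c_sensory"),
        _bool("c_below_knee"),
        ColumnSpec("char_count", "int", 0, 4),
        ColumnSpec("group", "int", 1, 3),
        ColumnSpec("both_composite", "int", 0, 24),
    ]
}


@dataclass
class LoadReport:
    """Summary of a cohort file load: rows read and cells flagged missing."""

    n_rows: int = 0
    missing_cells: dict[str, int] = field(default_factory=dict)
    flagged: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_missing(self) -> int:
        return sum(self.missing_cells.values())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [f"{self.n_rows} rows read, {self.n_missing} missing cells"]
        for col, n in sorted(self.missing_cells.items()):
            lines.append(f"  {col}: {n}")
        return "\n".join(lines)


def _spec_for(name: str) -> ColumnSpec:
    spec = COLUMNS.get(name) or DERIVED_COLUMNS.get(name)
    if spec is None:
        raise SchemaError(f"unknown column {name!r}")
    return spec


def _first_bad(mask: pd.Series) -> int:
    return int(np.flatnonzero(mask.to_numpy())[0])


def validate_cohort(df: pd.DataFrame, *, allow_derived: bool = True) -> None:
    """Raise :class:`SchemaError` naming the first offending row/column.

    Missing values (pandas NA) are always allowed; range and level checks
    apply to present values only.
    """
    for name in df.columns:
        if name not in COLUMNS and not (allow_derived and name in DERIVED_COLUMNS):
            raise SchemaError(f"unknown column {name!r}")
        spec = _spec_for(name)
        col = df[name]
        present = col.notna()
        if spec.kind in ("int", "bool"):
            vals = pd.to_numeric(col[present], errors="coerce")
            bad = vals.isna() | (vals != np.floor(vals))
            if spec.kind == "bool":
                bad |= ~vals.isin([0, 1])
            else:
                if spec.lo is not None:
                    bad |= vals < spec.lo
                if spec.hi is not None:
                    bad |= vals > spec.hi
            if bad.any():
                row = bad.index[bad.to_numpy()][0]
                raise SchemaError(
                    f"out-of-range value {col[row]!r} in column {name!r}, row {row}"
                )
        elif spec.kind == "category":
            bad = ~col[present].astype(str).isin(spec.levels)
            if bad.any():
                row = bad.index[bad.to_numpy()][0]
                raise SchemaError(
                    f"invalid level {col[row]!r} in column {name!r}, row {row}; "
                    f"expected one of {spec.levels}"
                )


def _coerce_dtypes(df: pd.DataFrame) -> pd.DataFrame:
    """Cast columns to nullable schema dtypes (Int64 / boolean / string)."""
    out = {}
    for name in df.columns:
        spec = _spec_for(name)
        col = df[name]
        if spec.kind == "int":
            out[name] = pd.to_numeric(col, errors="raise").astype("Int64")
        elif spec.kind == "bool":
            out[name] = pd.to_numeric(col, errors="raise").astype("Int64").astype("boolean")
        else:
            out[name] = col.astype("string")
    return pd.DataFrame(out, index=df.index)


def write_cohort(df: pd.DataFrame, destination: str | Path) -> None:
    """Write a cohort table as CSV; missing values become empty cells."""
    validate_cohort(df)
    enc = df.copy()
    for name in enc.columns:
        spec = _spec_for(name)
        if spec.kind == "bool":
            enc[name] = enc[name].astype("boolean").astype("Int64")
    enc.to_csv(destination, index=False, na_rep="")


def read_cohort(source: str | Path) -> tuple[pd.DataFrame, LoadReport]:
    """Load and validate a cohort CSV.

    Returns the table (nullable dtypes; NA for empty cells) and a
    :class:`LoadReport` counting every flagged (empty) cell per column.
    Schema violations raise :class:`SchemaError` naming row and column.
    """
    raw = pd.read_csv(source, dtype=str, keep_default_na=False)
    raw = raw.replace({"": pd.NA})
    for name in raw.columns:
        _spec_for(name)  # unknown column check, before any cell parsing

    report = LoadReport(n_rows=len(raw))
    for name in raw.columns:
        n_na = int(raw[name].isna().sum())
        if n_na:
            report.missing_cells[name] = n_na
            for row in raw.index[raw[name].isna()]:
                report.flagged.append((int(row), name))

    parsed = {}
    for name in raw.columns:
        spec = _spec_for(name)
        col = raw[name]
        if spec.kind in ("int", "bool"):
            if spec.kind == "bool":
                col = col.replace(
                    {"True": "1", "False": "0", "true": "1", "false": "0"}
                )
            vals = pd.to_numeric(col, errors="coerce")
            malformed = col.notna() & vals.isna()
            if malformed.any():
                row = _first_bad(malformed)
                raise SchemaError(
                    f"malformed value {col[row]!r} in column {name!r}, row {row}"
                )
            parsed[name] = vals
        else:
            parsed[name] = col
    df = pd.DataFrame(parsed)
    validate_cohort(df)
    return _coerce_dtypes(df), report


def coerce_cohort(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and cast a raw cohort table to schema (nullable) dtypes."""
    validate_cohort(df)
    return _coerce_dtypes(df)


def cohort_frame(records: Iterable[dict]) -> pd.DataFrame:
    """Build a schema-typed cohort table from per-patient dictionaries."""
    return coerce_cohort(pd.DataFrame(list(records)))
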