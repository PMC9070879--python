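"""Reading, validating and writing cohort performance data.

The canonical on-disk layout is a long CSV with one row per
subject x trial x measure::

    subject_id,sex,trial,measure,value,absolute_load_kg
    S01,male,T1,1RM,100.0,
    S01,male,T1,RTF90,4,90.0
    ...

Measures are the one-repetition maximum (``1RM``, kg) and repetitions
to failure at 90/80/70 % of the current 1-RM (``RTF90``/``RTF80``/
``RTF70``, integer counts).  Trials are the baseline test ``T1`` and
the retest ``T2``.  A best-effort converter ingests the wide
supplementary-spreadsheet layout via an explicit column mapping.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "TRIALS",
    "ParseError",
    "ValidationError",
    "PerformanceRecord",
    "PerformanceDataset",
    "LoadRepPoint",
    "S1ColumnMapping",
    "load_dataset",
    "write_dataset",
    "to_model_table",
]

MEASURES = ("1RM", "RTF90", "RTF80", "RTF70")
TRIALS = ("T1", "T2")
SEXES = ("male", "female", "unspecified")

#: smallest load increment used for absolute-load consistency checks (kg)
LOAD_INCREMENT_KG = 2.5

_MEASURE_ALIASES = {"1RM": "1RM", "ONE_RM": "1RM", "RTF90": "RTF90", "RTF80": "RTF80", "RTF70": "RTF70"}

_COLUMNS = ["subject_id", "sex", "trial", "measure", "value", "absolute_load_kg"]


class ParseError(ValueError):
    """The file cannot be read as the declared dialect."""


class ValidationError(ValueError):
    """The parsed rows violate a dataset invariant."""


@dataclass(frozen=True)
class PerformanceRecord:
    subject_id: str
    sex: str
    trial: str
    measure: str
    value: float
    absolute_load_kg: float | None = None


@dataclass(frozen=True)
class LoadRepPoint:
    """One (relative load, RTF) observation for the strength-endurance models."""

    relative_load: float
    rtf: float
    trial: str


@dataclass
class PerformanceDataset:
    """Validated long-format test-retest performance records for a cohort.

    ``table`` holds one row per (subject, trial, measure); ``metadata``
    carries free-form provenance notes; ``incomplete_subjects`` flags
    subjects with missing T2 records.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    incomplete_subjects: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.table = _validate_table(self.table)
        missing_t2 = []
        for sid, grp in self.table.groupby("subject_id", sort=False):
            if "T2" not in set(grp["trial"]):
                missing_t2.append(str(sid))
        self.incomplete_subjects = tuple(missing_t2)

    # -- convenience accessors -------------------------------------------------
    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.table["subject_id"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def records(self) -> list[PerformanceRecord]:
        out = []
        for row in self.table.itertuples(index=False):
            abs_load = None if pd.isna(row.absolute_load_kg) else float(row.absolute_load_kg)
            out.append(
                PerformanceRecord(
                    str(row.subject_id), str(row.sex), str(row.trial), str(row.measure), float(row.value), abs_load
                )
            )
        return out

    def values(self, measure: str, trial: str) -> pd.Series:
        """Measure values for one trial, indexed by subject."""
        measure = _MEASURE_ALIASES.get(measure.upper(), measure)
        sel = self.table[(self.table["measure"] == measure) & (self.table["trial"] == trial)]
        return sel.set_index("subject_id")["value"]

    def paired_values(self, measure: str) -> pd.DataFrame:
        """T1/T2 values side by side (columns ``T1``, ``T2``), one row per subject."""
        t1 = self.values(measure, "T1")
        t2 = self.values(measure, "T2")
        return pd.DataFrame({"T1": t1, "T2": t2})

    def equals(self, other: "PerformanceDataset") -> bool:
        a = self.table.sort_values(_COLUMNS[:4]).reset_index(drop=True)
        b = other.table.sort_values(_COLUMNS[:4]).reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        same_vals = np.allclose(a["value"], b["value"], rtol=0, atol=1e-9)
        la, lb = a["absolute_load_kg"], b["absolute_load_kg"]
        same_loads = bool(((la.isna() & lb.isna()) | (np.isclose(la, lb, rtol=0, atol=1e-9))).all())
        same_labels = all((a[c] == b[c]).all() for c in ("subject_id", "sex", "trial", "measure"))
        return bool(same_vals and same_loads and same_labels)


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _COLUMNS if c not in df.columns and c != "absolute_load_kg"]
    if missing:
        raise ParseError(f"missing required columns: {missing}")
    df = df.copy()
    if "absolute_load_kg" not in df.columns:
        df["absolute_load_kg"] = np.nan
    df = df[_COLUMNS]
    df["subject_id"] = df["subject_id"].astype(str)

    for i, row in enumerate(df.itertuples(index=False)):
        rowname = f"row {i} (subject {row.subject_id}, {row.trial}, {row.measure})"
        if row.trial not in TRIALS:
            raise ValidationError(f"{rowname}: trial must be one of {TRIALS}")
        if row.measure not in MEASURES:
            raise ValidationError(f"{rowname}: measure must be one of {MEASURES}")
        if row.sex not in SEXES:
            raise ValidationError(f"{rowname}: sex must be one of {SEXES}")
        v = float(row.value)
        if not np.isfinite(v):
            raise ValidationError(f"{rowname}: non-finite value")
        if row.measure == "1RM":
            if v <= 0:
                raise ValidationError(f"{rowname}: 1RM must be > 0")
        else:
            if v < 1 or v != int(v):
                raise ValidationError(f"{rowname}: RTF must be an integer >= 1, got {row.value}")

    dup = df.duplicated(subset=["subject_id", "trial", "measure"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            f"duplicate record for (subject {first['subject_id']}, {first['trial']}, {first['measure']})"
        )

    # every subject must appear at T1
    t1_subjects = set(df.loc[df["trial"] == "T1", "subject_id"])
    only_t2 = sorted(set(df["subject_id"]) - t1_subjects)
    if only_t2:
        raise ValidationError(f"subjects present at T2 but missing the T1 baseline: {only_t2}")

    # absolute RTF loads, when given, must agree with that subject-and-trial's 1-RM
    one_rm = df[df["measure"] == "1RM"].set_index(["subject_id", "trial"])["value"]
    for i, row in enumerate(df.itertuples(index=False)):
        if row.measure == "1RM" or pd.isna(row.absolute_load_kg):
            continue
        key = (row.subject_id, row.trial)
        if key not in one_rm.index:
            continue
        pct = float(row.measure[3:]) / 100.0
        expected = pct * float(one_rm.loc[key])
        if abs(float(row.absolute_load_kg) - expected) > LOAD_INCREMENT_KG:
            raise ValidationError(
                f"row {i}: absolute load {row.absolute_load_kg} kg deviates from "
                f"{row.measure} of the {row.trial} 1-RM ({expected:.1f} kg) by more than "
                f"{LOAD_INCREMENT_KG} kg"
            )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# reading / writing


@dataclass(frozen=True)
class S1ColumnMapping:
    """Column mapping for the wide supplementary-spreadsheet layout.

    Defaults assume one row per subject with columns ``<measure>_<trial>``
    (e.g. ``1RM_T1``, ``RTF90_T2``); adjust ``columns`` when the actual
    sheet differs.
    """

    subject: str = "subject"
    sex: str | None = "sex"
    columns: dict = field(
        default_factory=lambda: {(m, t): f"{m}_{t}" for m in MEASURES for t in TRIALS}
    )
    sheet: int | str = 0


def load_dataset(path, dialect: str = "canonical_csv", mapping: S1ColumnMapping | None = None) -> PerformanceDataset:
    """Read a :class:`PerformanceDataset` from ``path``.

    ``dialect`` is ``"canonical_csv"`` (long format) or ``"s1_xlsx"``
    (wide spreadsheet, converted through ``mapping``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "canonical_csv":
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError as exc:
            raise ParseError(f"{path}: empty file") from exc
        if df.empty:
            raise ParseError(f"{path}: no data rows")
        return PerformanceDataset(df, metadata={"source": str(path), "dialect": dialect})
    if dialect == "s1_xlsx":
        mapping = mapping or S1ColumnMapping()
        try:
            wide = pd.read_excel(path, sheet_name=mapping.sheet)
        except Exception as exc:  # openpyxl raises several corruption types
            raise ParseError(f"{path}: cannot read spreadsheet ({exc})") from exc
        if mapping.subject not in wide.columns:
            raise ParseError(f"{path}: subject column {mapping.subject!r} not found")
        rows = []
        for _, r in wide.iterrows():
            sex = str(r[mapping.sex]) if mapping.sex and mapping.sex in wide.columns else "unspecified"
            for (measure, trial), col in mapping.columns.items():
                if col not in wide.columns or pd.isna(r[col]):
                    continue
                rows.append(
                    {
                        "subject_id": str(r[mapping.subject]),
                        "sex": sex,
                        "trial": trial,
                        "measure": measure,
                        "value": float(r[col]),
                        "absolute_load_kg": np.nan,
                    }
                )
        if not rows:
            raise ParseError(f"{path}: no mapped cells found")
        return PerformanceDataset(pd.DataFrame(rows), metadata={"source": str(path), "dialect": dialect})
    raise ValueError(f"unknown dialect {dialect!r}")


def write_dataset(ds: PerformanceDataset, path) -> None:
    """Write the canonical long CSV (UTF-8, '.' decimal separator)."""
    out = ds.table.copy()
    # keep RTF counts as integers in the file
    is_rtf = out["measure"] != "1RM"
    out["value"] = out["value"].astype(object)
    out.loc[is_rtf, "value"] = out.loc[is_rtf, "value"].astype(int)
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# marshalling into strength-endurance model tables


def to_model_table(ds: PerformanceDataset, include_one_rm_point: bool = True) -> dict[str, list[LoadRepPoint]]:
    """Per-subject (relative load, RTF) points for curve fitting.

    Each subject-trial contributes (90, RTF90), (80, RTF80), (70, RTF70)
    and, when ``include_one_rm_point`` is set, the 1-RM expressed as the
    point (100, 1).  Subjects with no RTF measures at all are excluded
    with a warning.
    """
    table: dict[str, list[LoadRepPoint]] = {}
    for sid in ds.subjects:
        pts: list[LoadRepPoint] = []
        for trial in TRIALS:
            sub = ds.table[(ds.table["subject_id"] == sid) & (ds.table["trial"] == trial)]
            if sub.empty:
                continue
            by_measure = sub.set_index("measure")["value"]
            if include_one_rm_point and "1RM" in by_measure.index:
                pts.append(LoadRepPoint(100.0, 1.0, trial))
            for m, pct in (("RTF90", 90.0), ("RTF80", 80.0), ("RTF70", 70.0)):
                if m in by_measure.index:
                    pts.append(LoadRepPoint(pct, float(by_measure.loc[m]), trial))
        if any(p.relative_load < 100 for p in pts):
            table[sid] = pts
        else:
            warnings.warn(f"subject {sid} has no RTF measures and was excluded from the model table")
    return table
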