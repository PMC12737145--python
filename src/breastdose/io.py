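"""Cohort and parameter file I/O.

Cohort CSV dialect: comma-separated, UTF-8, '.' decimal separator, header
required. Columns: patient_id, weight_kg, height_m, age_years,
breast_thickness_mm, total_dlp_mgycm, plus an optional ir_mgy label column.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .dose_model import DoseModelParams, InvalidPatientError, LabelledCohort, PatientRecord

__all__ = ["COHORT_COLUMNS", "CohortSchemaError", "read_cohort", "write_cohort",
           "write_labelled_cohort", "read_params", "write_params"]

COHORT_COLUMNS = (
    "patient_id",
    "weight_kg",
    "height_m",
    "age_years",
    "breast_thickness_mm",
    "total_dlp_mgycm",
)
IR_COLUMN = "ir_mgy"


class CohortSchemaError(ValueError):
    """The cohort CSV violates the documented schema."""


def read_cohort(path: str | Path) -> tuple[list[PatientRecord], list[float] | None]:
    """Read and validate a cohort CSV; returns (patients, ir-or-None).

    Errors name the offending row (1-based, excluding the header) and
    column.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortSchemaError(f"{path}: missing column(s) {missing}")
    numeric = [c for c in df.columns if c != "patient_id"]
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any() or df[col].isna().any():
            row = int((bad | df[col].isna()).idxmax()) + 1
            raise CohortSchemaError(f"{path}: row {row}, column {col!r}: non-numeric or missing value")
        df[col] = vals

    patients = []
    for i, rec in df.iterrows():
        try:
            patients.append(
                PatientRecord(
                    patient_id=str(rec["patient_id"]),
                    weight=float(rec["weight_kg"]),
                    height=float(rec["height_m"]),
                    age=float(rec["age_years"]),
                    breast_thickness=float(rec["breast_thickness_mm"]),
                    total_dlp=float(rec["total_dlp_mgycm"]),
                )
            )
        except InvalidPatientError as exc:
            raise CohortSchemaError(f"{path}: row {int(i) + 1}: {exc}") from exc
    ir = None
    if IR_COLUMN in df.columns:
        ir = [float(v) for v in df[IR_COLUMN]]
        neg = [j for j, v in enumerate(ir) if not v >= 0]
        if neg:
            raise CohortSchemaError(f"{path}: row {neg[0] + 1}, column {IR_COLUMN!r}: negative dose")
    return patients, ir


def _frame(patients: Sequence[PatientRecord], ir: Sequence[float] | None) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "weight_kg": [p.weight for p in patients],
            "height_m": [p.height for p in patients],
            "age_years": [p.age for p in patients],
            "breast_thickness_mm": [p.breast_thickness for p in patients],
            "total_dlp_mgycm": [p.total_dlp for p in patients],
        }
    )
    if ir is not None:
        df[IR_COLUMN] = list(ir)
    return df


def write_cohort(path: str | Path, patients: Sequence[PatientRecord],
                 ir: Sequence[float] | None = None) -> None:
    # %.17g keeps doubles bit-exact through the CSV round trip
    _frame(patients, ir).to_csv(path, index=False, float_format="%.17g")


def write_labelled_cohort(path: str | Path, cohort: LabelledCohort) -> None:
    write_cohort(path, cohort.patients, cohort.ir)


def write_params(path: str | Path, params: DoseModelParams) -> None:
    Path(path).write_text(params.to_json() + "\n", encoding="utf-8")


def read_params(path: str | Path) -> DoseModelParams:
    return DoseModelParams.from_json(Path(path).read_text(encoding="utf-8"))
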