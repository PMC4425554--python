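"""Cohort CSV reading and writing.

Schema (UTF-8, comma-separated, dot decimal, one admission per row)::

    patient_id, arm, drg_code, drg_group, age, sex, los_days,
    iv_treated, iv_nursing_minutes, ab_cost_eur, n_consults, readmitted

``arm`` is ``intervention`` or ``control``; ``sex`` is ``M``/``F``;
``iv_treated``/``readmitted`` accept 0/1 or true/false.  Validation errors
name the offending CSV row (1-based, header = row 1) and field.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .calibration import PatientRecord
from .errors import ValidationError

__all__ = ["COHORT_COLUMNS", "read_cohort_csv", "write_cohort_csv"]

COHORT_COLUMNS = (
    "patient_id", "arm", "drg_code", "drg_group", "age", "sex", "los_days",
    "iv_treated", "iv_nursing_minutes", "ab_cost_eur", "n_consults",
    "readmitted",
)

_TRUE = {"1", "true", "t", "yes", "y"}
_FALSE = {"0", "false", "f", "no", "n"}


def _as_bool(value, row: int, field: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(f"cannot interpret {value!r} as a flag",
                          row=row, field=field)


def _as_float(value, row: int, field: str, allow_nan: bool = False) -> float:
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"cannot interpret {value!r} as a number",
                              row=row, field=field)
    if math.isnan(out) and not allow_nan:
        raise ValidationError("value is missing", row=row, field=field)
    return out


def _as_int(value, row: int, field: str) -> int:
    out = _as_float(value, row, field)
    if out != int(out):
        raise ValidationError(f"expected an integer, got {value!r}",
                              row=row, field=field)
    return int(out)


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV into :class:`PatientRecord` objects."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")

    records: list[PatientRecord] = []
    for i, raw in enumerate(frame.to_dict("records")):
        row = i + 2  # 1-based CSV line number incl. header
        try:
            records.append(PatientRecord(
                patient_id=str(raw["patient_id"]).strip(),
                arm=str(raw["arm"]).strip().lower(),
                drg_code=str(raw["drg_code"]).strip(),
                drg_group=_as_int(raw["drg_group"], row, "drg_group"),
                age=_as_float(raw["age"] or "nan", row, "age", allow_nan=True),
                sex=str(raw["sex"]).strip().upper(),
                los_days=_as_float(raw["los_days"], row, "los_days"),
                iv_treated=_as_bool(raw["iv_treated"], row, "iv_treated"),
                iv_nursing_minutes=_as_float(raw["iv_nursing_minutes"], row,
                                             "iv_nursing_minutes"),
                ab_cost=_as_float(raw["ab_cost_eur"] or "nan", row,
                                  "ab_cost_eur", allow_nan=True),
                n_consults=_as_int(raw["n_consults"], row, "n_consults"),
                readmitted=_as_bool(raw["readmitted"], row, "readmitted"),
            ))
        except ValidationError as err:
            if err.row is None:
                raise ValidationError(str(err), row=row) from err
            raise
    return records


def write_cohort_csv(records: Sequence[PatientRecord], path: str | Path) -> None:
    """Write records in the cohort CSV schema (floats at full precision)."""
    frame = pd.DataFrame([{
        "patient_id": r.patient_id,
        "arm": r.arm,
        "drg_code": r.drg_code,
        "drg_group": r.drg_group,
        "age": repr(r.age) if not math.isnan(r.age) else "",
        "sex": r.sex,
        "los_days": repr(r.los_days),
        "iv_treated": int(r.iv_treated),
        "iv_nursing_minutes": repr(r.iv_nursing_minutes),
        "ab_cost_eur": repr(r.ab_cost) if not math.isnan(r.ab_cost) else "",
        "n_consults": r.n_consults,
        "readmitted": int(r.readmitted),
    } for r in records], columns=list(COHORT_COLUMNS))
    frame.to_csv(path, index=False)
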