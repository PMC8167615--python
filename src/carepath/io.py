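"""Readers and writers for the record / profile / intervention formats.

CSV (UTF-8, comma, header required) and JSONL (one object per line) are
supported symmetrically; the format is chosen by file extension.  Dates are
ISO-8601.  Invalid rows are rejected with their line numbers.  Unknown
columns on records are preserved into the record's value map.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from datetime import date, datetime
from pathlib import Path
from typing import Any, Sequence, Union

import pandas as pd
import yaml

from .models import (
    Disease,
    Education,
    InterventionRecord,
    PatientProfile,
    SelfMonitoringRecord,
    Sex,
    ValidationError,
)

PathLike = Union[str, Path]

_RECORD_FIXED = ("record_id", "patient_id", "timestamp", "kind")
_BOOL_VALUE_KEYS = {"ketone", "acute_exacerbation", "hospitalization"}


def _to_bool(x: Any) -> bool:
    if isinstance(x, bool):
        return x
    return str(x).strip().lower() in ("true", "1", "yes")


def _rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)


def _read_rows(path: PathLike) -> list[dict]:
    p = Path(path)
    if p.suffix == ".jsonl":
        rows = []
        with open(p) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        return rows
    df = pd.read_csv(p)
    return [
        {k: v for k, v in row.items() if not pd.isna(v)}
        for row in df.to_dict(orient="records")
    ]


def _write_rows(rows: list[dict], path: PathLike) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    if p.suffix == ".jsonl":
        with open(p, "w") as fh:
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    else:
        _rows_to_frame(rows).to_csv(p, index=False)


# -- records -----------------------------------------------------------------

def write_records(records: Sequence[SelfMonitoringRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        row: dict[str, Any] = {
            "record_id": r.record_id,
            "patient_id": r.patient_id,
            "timestamp": r.timestamp.isoformat(),
            "kind": r.kind.value,
        }
        row.update(r.values)
        rows.append(row)
    _write_rows(rows, path)


def read_records(path: PathLike) -> list[SelfMonitoringRecord]:
    """Parse self-monitoring records, validating every row; raises a
    ValidationError naming the offending line numbers."""
    out: list[SelfMonitoringRecord] = []
    errors: list[str] = []
    for lineno, row in enumerate(_read_rows(path), start=2):  # line 1 = header
        try:
            values = {
                k: (_to_bool(v) if k in _BOOL_VALUE_KEYS else v)
                for k, v in row.items()
                if k not in _RECORD_FIXED
            }
            out.append(
                SelfMonitoringRecord(
                    patient_id=str(row["patient_id"]),
                    timestamp=datetime.fromisoformat(str(row["timestamp"])),
                    kind=row["kind"],
                    values=values,
                    record_id=(str(row["record_id"]) if row.get("record_id") else None),
                )
            )
        except (KeyError, ValueError, ValidationError) as e:
            errors.append(f"line {lineno}: {e}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid rows: " + "; ".join(errors[:10]))
    return out


# -- profiles ----------------------------------------------------------------

def write_profiles(profiles: Sequence[PatientProfile], path: PathLike) -> None:
    rows = []
    for p in profiles:
        rows.append(
            {
                "patient_id": p.patient_id,
                "age": p.age,
                "sex": p.sex.value,
                "education": p.education.value,
                "diseases": "|".join(sorted(d.value for d in p.diseases)),
                "enrollment_date": p.enrollment_date.isoformat(),
                "bp_target_sbp": p.bp_target[0],
                "bp_target_dbp": p.bp_target[1],
                "bg_target_fbg": p.bg_target[0],
                "bg_target_pbg": p.bg_target[1],
                "pef_personal_best": p.pef_personal_best,
                "current_levels": "|".join(
                    f"{d.value}={lvl}" for d, lvl in sorted(
                        p.current_levels.items(), key=lambda kv: kv[0].value
                    )
                ),
                "smoker": p.smoker,
                "obese": p.obese,
                "organ_damage": p.organ_damage,
                "comorbidity": p.comorbidity,
            }
        )
    _write_rows(rows, path)


def read_profiles(path: PathLike) -> list[PatientProfile]:
    out: list[PatientProfile] = []
    errors: list[str] = []
    for lineno, row in enumerate(_read_rows(path), start=2):
        try:
            pef = row.get("pef_personal_best")
            out.append(
                PatientProfile(
                    patient_id=str(row["patient_id"]),
                    age=float(row["age"]),
                    sex=Sex(row["sex"]),
                    education=Education(row.get("education", "unknown")),
                    diseases=frozenset(
                        Disease(d) for d in str(row["diseases"]).split("|")
                    ),
                    enrollment_date=date.fromisoformat(str(row["enrollment_date"])),
                    bp_target=(
                        float(row.get("bp_target_sbp", 140.0)),
                        float(row.get("bp_target_dbp", 90.0)),
                    ),
                    bg_target=(
                        float(row.get("bg_target_fbg", 7.0)),
                        float(row.get("bg_target_pbg", 10.0)),
                    ),
                    pef_personal_best=float(pef) if pef not in (None, "") else None,
                    current_levels={
                        Disease(part.split("=")[0]): part.split("=")[1]
                        for part in str(row.get("current_levels") or "").split("|")
                        if part
                    },
                    smoker=_to_bool(row.get("smoker", False)),
                    obese=_to_bool(row.get("obese", False)),
                    organ_damage=_to_bool(row.get("organ_damage", False)),
                    comorbidity=_to_bool(row.get("comorbidity", False)),
                )
            )
        except (KeyError, ValueError, ValidationError) as e:
            errors.append(f"line {lineno}: {e}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid rows: " + "; ".join(errors[:10]))
    return out


# -- interventions -----------------------------------------------------------

def write_interventions(ivs: Sequence[InterventionRecord], path: PathLike) -> None:
    rows = [
        {
            "provider_id": iv.provider_id,
            "patient_id": iv.patient_id,
            "kind": iv.kind.value,
            "requested_at": iv.requested_at.isoformat(),
            "completed_at": iv.completed_at.isoformat(),
            "notes": iv.notes,
        }
        for iv in ivs
    ]
    _write_rows(rows, path)


def read_interventions(path: PathLike) -> list[InterventionRecord]:
    out: list[InterventionRecord] = []
    errors: list[str] = []
    for lineno, row in enumerate(_read_rows(path), start=2):
        try:
            out.append(
                InterventionRecord(
                    provider_id=str(row["provider_id"]),
                    patient_id=str(row["patient_id"]),
                    kind=row["kind"],
                    requested_at=date.fromisoformat(str(row["requested_at"])),
                    completed_at=date.fromisoformat(str(row["completed_at"])),
                    notes=str(row.get("notes", "") or ""),
                )
            )
        except (KeyError, ValueError, ValidationError) as e:
            errors.append(f"line {lineno}: {e}")
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid rows: " + "; ".join(errors[:10]))
    return out


# -- event log and config ----------------------------------------------------

def write_event_log(events: Sequence[dict], path: PathLike) -> None:
    _write_rows(list(events), Path(path))


def load_run_config(path: PathLike) -> dict:
    """YAML run configuration: engine thresholds, simulator settings,
    evaluation settings, seed, output directory."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: run config must be a YAML mapping")
    return cfg


def write_json(obj: Any, path: PathLike) -> None:
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    with open(p, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o: Any) -> Any:
    if isinstance(o, (date, datetime)):
        return o.isoformat()
    if hasattr(o, "__dataclass_fields__"):
        return asdict(o)
    if isinstance(o, (set, frozenset)):
        return sorted(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
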