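"""File formats: appointment-log CSV, ledger CSV, config YAML/JSON, event logs.

The appointment log is a flat CSV with one row per appointment and a
fixed header (see :data:`APPOINTMENT_COLUMNS`). Malformed rows are never
silently dropped: the loader returns them in a rejects report with the
line number and reason, and accepted + rejected always equals input.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml

from .domain import AppointmentRecord, MonthlyLedger, PatientProfile, validate_ledger
from .errors import FormatError
from .simulate import ExperimentConfig

__all__ = [
    "APPOINTMENT_COLUMNS",
    "LoadResult",
    "load_appointment_log",
    "write_appointment_log",
    "appointment_row",
    "load_config",
    "write_ledgers_csv",
    "read_ledgers_csv",
    "write_events_jsonl",
]

APPOINTMENT_COLUMNS = [
    "patient_id",
    "age",
    "gender",
    "district",
    "channel",
    "booking_time",
    "slot_time",
    "role",
    "status",
    "cancel_lead_min",
    "travel_time_min",
    "physician_id",
    "branch_id",
]

_TS = "%Y-%m-%dT%H:%M:%S"


@dataclass
class LoadResult:
    """Typed records, patient profiles, and the rejects report."""

    records: list[AppointmentRecord] = field(default_factory=list)
    profiles: dict[str, PatientProfile] = field(default_factory=dict)
    rejects: list[dict] = field(default_factory=list)
    statuses: list[str] = field(default_factory=list)

    @property
    def n_input(self) -> int:
        return len(self.records) + len(self.rejects)


def _parse_row(row: dict) -> tuple[AppointmentRecord, PatientProfile]:
    lead = row.get("cancel_lead_min", "")
    travel = row.get("travel_time_min", "")
    rec = AppointmentRecord(
        patient_id=row["patient_id"],
        slot_time=datetime.strptime(row["slot_time"], _TS),
        booking_time=datetime.strptime(row["booking_time"], _TS),
        channel=row["channel"],
        role=row["role"],
        status=row["status"],
        cancel_lead_min=float(lead) if lead not in ("", None) else None,
        physician_id=row["physician_id"],
        branch_id=row["branch_id"],
    )
    prof = PatientProfile(
        patient_id=row["patient_id"],
        age_years=int(row["age"]),
        gender=row["gender"],
        district=row["district"],
        travel_time_min=float(travel) if travel not in ("", None) else None,
    )
    return rec, prof


def load_appointment_log(path: Union[str, Path]) -> LoadResult:
    """Read an appointment-log CSV into typed records.

    Raises :class:`FormatError` naming the first missing required
    column; per-row problems go to ``rejects`` with a reason instead of
    raising.
    """
    path = Path(path)
    result = LoadResult()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for col in APPOINTMENT_COLUMNS:
            if col not in header:
                raise FormatError(f"appointment log {path} is missing column {col!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                rec, prof = _parse_row(row)
            except (KeyError, ValueError) as exc:
                result.rejects.append({"line": lineno, "reason": str(exc), "row": dict(row)})
                continue
            result.records.append(rec)
            result.profiles.setdefault(rec.patient_id, prof)
            result.statuses.append(rec.status.value)
    return result


def appointment_row(rec: AppointmentRecord, profile: Optional[PatientProfile] = None) -> dict:
    """Flatten a record (plus optional profile) into a CSV row dict."""
    return {
        "patient_id": rec.patient_id,
        "age": profile.age_years if profile else "",
        "gender": profile.gender if profile else "",
        "district": profile.district if profile else "",
        "channel": rec.channel.value,
        "booking_time": rec.booking_time.strftime(_TS),
        "slot_time": rec.slot_time.strftime(_TS),
        "role": rec.role.value,
        "status": rec.status.value,
        "cancel_lead_min": "" if rec.cancel_lead_min is None else repr(rec.cancel_lead_min),
        "travel_time_min": (
            "" if not profile or profile.travel_time_min is None
            else repr(profile.travel_time_min)
        ),
        "physician_id": rec.physician_id,
        "branch_id": rec.branch_id,
    }


def write_appointment_log(path: Union[str, Path], rows: Iterable[dict]) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=APPOINTMENT_COLUMNS)
        writer.writeheader()
        for row in rows:
            writer.writerow(row)


def load_config(path: Union[str, Path]) -> ExperimentConfig:
    """Load a scenario config from YAML or JSON (YAML is a superset)."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"config {path} must be a mapping at top level")
    return ExperimentConfig.model_validate(data)


_LEDGER_COLUMNS = [
    "month_label",
    "n_total",
    "n_realized_web",
    "n_canceled",
    "n_noshow",
    "n_standby_realized",
]


def write_ledgers_csv(path: Union[str, Path], ledgers: Sequence[MonthlyLedger]) -> None:
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_LEDGER_COLUMNS)
        for led in ledgers:
            writer.writerow(
                [
                    led.month_label,
                    led.n_total,
                    led.n_realized_web,
                    led.n_canceled,
                    led.n_noshow,
                    led.n_standby_realized,
                ]
            )


def read_ledgers_csv(path: Union[str, Path]) -> list[MonthlyLedger]:
    ledgers = []
    with Path(path).open(newline="") as fh:
        reader = csv.DictReader(fh)
        for col in _LEDGER_COLUMNS:
            if col not in (reader.fieldnames or []):
                raise FormatError(f"ledger CSV {path} is missing column {col!r}")
        for row in reader:
            ledgers.append(
                validate_ledger(
                    MonthlyLedger(
                        month_label=row["month_label"],
                        n_total=int(row["n_total"]),
                        n_realized_web=int(row["n_realized_web"]),
                        n_canceled=int(row["n_canceled"]),
                        n_noshow=int(row["n_noshow"]),
                        n_standby_realized=int(row["n_standby_realized"]),
                    )
                )
            )
    return ledgers


def write_events_jsonl(path: Union[str, Path], events: Iterable[dict]) -> None:
    """Newline-delimited JSON event log (replayable by tests)."""
    with Path(path).open("w") as fh:
        for e in events:
            fh.write(json.dumps(e, sort_keys=True) + "\n")
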