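"""Canonical visit-log data model and CSV I/O.

A facility visit log has one row per patient visit with four timestamps:

* ``scheduled_time`` — appointment slot (for walk-in visits this equals the
  arrival time: with no real schedule, arrival is the standard proxy),
* ``arrival_time`` — when the patient checked in,
* ``begin_time`` / ``end_time`` — when the exam started and finished.

The prediction target is the *delay* ``begin − scheduled`` at scheduled and
hybrid facilities (negative when a patient is seen early) and the *wait*
``begin − arrival`` at walk-in facilities (nonnegative by construction).
All durations are integer minutes; timestamps are stored at minute
resolution in ISO 8601 local facility time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ParseError, SchemaError, ValidationError

__all__ = [
    "FacilityType",
    "VisitRecord",
    "EventLog",
    "LOG_COLUMNS",
    "read_log",
    "write_log",
    "compute_target",
]

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"

LOG_COLUMNS = [
    "visit_id",
    "facility_id",
    "exam_code",
    "exam_category",
    "contrast_flag",
    "scheduled_time",
    "arrival_time",
    "begin_time",
    "end_time",
    "resource_id",
    "patient_age",
    "is_outpatient",
    "addon_time",
]

EXAM_CATEGORIES = (
    "MSK",
    "cardiac",
    "vascular",
    "abdominal",
    "neuro",
    "pediatric",
    "thoracic",
    "other",
    "combined",
)

CONTRAST_FLAGS = ("none", "with", "with_and_without")


class FacilityType(str, enum.Enum):
    SCHEDULED = "scheduled"
    HYBRID = "hybrid"
    WALKIN = "walkin"

    @classmethod
    def coerce(cls, value: Union[str, "FacilityType"]) -> "FacilityType":
        return value if isinstance(value, cls) else cls(str(value))


@dataclass(frozen=True)
class VisitRecord:
    """One patient visit. Optional fields are ``None`` when absent."""

    visit_id: str
    facility_id: str
    exam_code: str
    scheduled_time: pd.Timestamp
    arrival_time: pd.Timestamp
    begin_time: pd.Timestamp
    end_time: pd.Timestamp
    resource_id: str
    exam_category: Optional[str] = None
    contrast_flag: Optional[str] = None
    patient_age: Optional[float] = None
    is_outpatient: bool = True
    addon_time: Optional[pd.Timestamp] = None

    def validate(self) -> None:
        if not self.arrival_time <= self.begin_time <= self.end_time:
            raise ValidationError(
                f"visit {self.visit_id!r}: requires arrival <= begin <= end, got "
                f"arrival={self.arrival_time}, begin={self.begin_time}, end={self.end_time}"
            )
        if self.exam_category is not None and self.exam_category not in EXAM_CATEGORIES:
            raise ValidationError(
                f"visit {self.visit_id!r}: unknown exam_category {self.exam_category!r}"
            )
        if self.contrast_flag is not None and self.contrast_flag not in CONTRAST_FLAGS:
            raise ValidationError(
                f"visit {self.visit_id!r}: unknown contrast_flag {self.contrast_flag!r}"
            )

    @property
    def wait_minutes(self) -> int:
        return int((self.begin_time - self.arrival_time).total_seconds() // 60)


class EventLog:
    """An ordered, validated sequence of :class:`VisitRecord` for one facility.

    Records are kept sorted by arrival time (ties broken by visit id) and all
    share the log's ``facility_id``. At walk-in facilities the scheduled time
    of every record is forced to its arrival time (the schedule proxy).
    """

    def __init__(
        self,
        records: Sequence[VisitRecord],
        facility_id: str,
        facility_type: Union[str, FacilityType],
    ) -> None:
        self.facility_id = facility_id
        self.facility_type = FacilityType.coerce(facility_type)
        records = list(records)
        seen: set = set()
        fixed = []
        for rec in records:
            if rec.facility_id != facility_id:
                raise ValidationError(
                    f"visit {rec.visit_id!r} belongs to facility {rec.facility_id!r}, "
                    f"log is for {facility_id!r}"
                )
            if rec.visit_id in seen:
                raise ValidationError(f"duplicate visit_id {rec.visit_id!r}")
            seen.add(rec.visit_id)
            if self.facility_type is FacilityType.WALKIN and rec.scheduled_time != rec.arrival_time:
                rec = replace(rec, scheduled_time=rec.arrival_time)
            rec.validate()
            fixed.append(rec)
        fixed.sort(key=lambda r: (r.arrival_time, r.visit_id))
        self._records: list[VisitRecord] = fixed
        self._by_id = {r.visit_id: r for r in fixed}

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[VisitRecord]:
        return iter(self._records)

    def __getitem__(self, visit_id: str) -> VisitRecord:
        return self._by_id[visit_id]

    def __contains__(self, visit_id: str) -> bool:
        return visit_id in self._by_id

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, EventLog)
            and self.facility_id == other.facility_id
            and self.facility_type == other.facility_type
            and self._records == other._records
        )

    @property
    def records(self) -> list[VisitRecord]:
        return list(self._records)

    @property
    def span(self) -> tuple[pd.Timestamp, pd.Timestamp]:
        if not self._records:
            raise EmptyInputError("empty log has no span")
        return self._records[0].arrival_time, self._records[-1].arrival_time

    def to_frame(self) -> pd.DataFrame:
        """Tabular view with one column per log field, rows in log order."""
        rows = []
        for r in self._records:
            rows.append(
                {
                    "visit_id": r.visit_id,
                    "facility_id": r.facility_id,
                    "exam_code": r.exam_code,
                    "exam_category": r.exam_category,
                    "contrast_flag": r.contrast_flag,
                    "scheduled_time": r.scheduled_time,
                    "arrival_time": r.arrival_time,
                    "begin_time": r.begin_time,
                    "end_time": r.end_time,
                    "resource_id": r.resource_id,
                    "patient_age": r.patient_age,
                    "is_outpatient": r.is_outpatient,
                    "addon_time": r.addon_time,
                }
            )
        return pd.DataFrame(rows, columns=LOG_COLUMNS)


def _parse_ts(value: str, column: str, row: int) -> pd.Timestamp:
    try:
        return pd.Timestamp(pd.to_datetime(value, format=TIMESTAMP_FORMAT))
    except (ValueError, TypeError) as exc:
        raise ParseError(
            f"row {row}: cannot parse {column}={value!r} as YYYY-MM-DDTHH:MM"
        ) from exc


def read_log(path, facility_type: Union[str, FacilityType]) -> EventLog:
    """Read a visit-log CSV into a validated :class:`EventLog`.

    Empty strings encode absent optional fields. Raises :class:`SchemaError`
    on a missing column, :class:`ParseError` on a bad timestamp and
    :class:`ValidationError` (naming the row) on an invariant violation.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    facility_type = FacilityType.coerce(facility_type)
    records = []
    facility_id = None
    for i, row in enumerate(df.itertuples(index=False)):
        facility_id = facility_id or row.facility_id
        sched = row.scheduled_time
        arrival = _parse_ts(row.arrival_time, "arrival_time", i)
        if sched == "":
            # walk-in rows (pure walk-in logs or walk-ins inside a hybrid log)
            # carry no appointment; arrival time is the standard proxy.
            sched_ts = arrival
        else:
            sched_ts = _parse_ts(sched, "scheduled_time", i)
        rec = VisitRecord(
            visit_id=row.visit_id,
            facility_id=row.facility_id,
            exam_code=row.exam_code,
            exam_category=row.exam_category or None,
            contrast_flag=row.contrast_flag or None,
            scheduled_time=sched_ts,
            arrival_time=arrival,
            begin_time=_parse_ts(row.begin_time, "begin_time", i),
            end_time=_parse_ts(row.end_time, "end_time", i),
            resource_id=row.resource_id,
            patient_age=float(row.patient_age) if row.patient_age != "" else None,
            is_outpatient=row.is_outpatient.lower() != "false",
            addon_time=_parse_ts(row.addon_time, "addon_time", i)
            if row.addon_time != ""
            else None,
        )
        records.append(rec)
    return EventLog(records, facility_id or "", facility_type)


def _fmt_ts(ts: Optional[pd.Timestamp]) -> str:
    return "" if ts is None else ts.strftime(TIMESTAMP_FORMAT)


def write_log(log: EventLog, path) -> None:
    """Write an :class:`EventLog` as CSV with the fixed column order and
    ISO 8601 minute-precision timestamps. Deterministic byte-for-byte."""
    rows = []
    for r in log:
        age = ""
        if r.patient_age is not None:
            age = "%g" % r.patient_age
        rows.append(
            {
                "visit_id": r.visit_id,
                "facility_id": r.facility_id,
                "exam_code": r.exam_code,
                "exam_category": r.exam_category or "",
                "contrast_flag": r.contrast_flag or "",
                "scheduled_time": _fmt_ts(r.scheduled_time),
                "arrival_time": _fmt_ts(r.arrival_time),
                "begin_time": _fmt_ts(r.begin_time),
                "end_time": _fmt_ts(r.end_time),
                "resource_id": r.resource_id,
                "patient_age": age,
                "is_outpatient": "true" if r.is_outpatient else "false",
                "addon_time": _fmt_ts(r.addon_time),
            }
        )
    pd.DataFrame(rows, columns=LOG_COLUMNS).to_csv(path, index=False)


def compute_target(
    visit: VisitRecord, facility_type: Union[str, FacilityType]
) -> int:
    """Prediction target in minutes for one visit.

    Scheduled/hybrid: signed delay ``begin − scheduled`` (negative when the
    exam starts before its slot). Walk-in: wait ``begin − arrival``, which is
    nonnegative because the data model enforces arrival ≤ begin.
    """
    facility_type = FacilityType.coerce(facility_type)
    if facility_type is FacilityType.WALKIN:
        return int((visit.begin_time - visit.arrival_time).total_seconds() // 60)
    if visit.scheduled_time is None:
        raise ValidationError(
            f"visit {visit.visit_id!r}: scheduled facility requires scheduled_time"
        )
    return int((visit.begin_time - visit.scheduled_time).total_seconds() // 60)


def minutes_since_epoch(ts) -> np.ndarray:
    """Vector of int64 minutes since the Unix epoch for a timestamp sequence."""
    return np.asarray(pd.DatetimeIndex(ts).asi8 // 60_000_000_000, dtype=np.int64)
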