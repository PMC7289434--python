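"""Discrete-event simulator of outpatient imaging workflows.

The simulator emulates the operational patterns of four common facility
archetypes — fully scheduled (MRI- and ultrasound-like), hybrid
scheduled-plus-walk-in (CT-like), and pure walk-in FIFO (X-ray-like) — and
emits visit logs in the canonical CSV dialect together with the latent
ground truth (service durations, begin order, per-server busy intervals),
so queue-reconstruction code can be tested against known dynamics.

Model, per operating day (weekdays only):

* scheduled patients are booked on a fixed slot grid, ``Binomial(n_servers,
  booking_prob)`` per slot; a booked patient no-shows with ``noshow_prob``
  and is dropped from the log entirely;
* add-on patients are inserted during the day with a schedule timestamp
  equal to their insertion time and are flagged via ``addon_time``;
* walk-ins arrive as a Poisson process at ``walkin_rate`` per hour; their
  scheduled time is their arrival time (schedule proxy);
* arrival earliness: ``arrival = scheduled + Normal(earliness_mean,
  earliness_sd)`` minutes (default mean −20: patients arrive early),
  clamped into the operating day;
* service durations are log-normal per exam code (configured mean in
  minutes, dispersion = sd of the log), rounded to whole minutes ≥ 1;
* service discipline: the next free server takes the *arrived* waiting
  patient with the earliest scheduled time, and never starts an exam before
  its scheduled time. Because walk-ins carry arrival as their scheduled
  time, this single rule yields schedule-order (non-FIFO w.r.t. arrival)
  service at scheduled facilities and FIFO service at walk-in facilities.

The clock advances in whole minutes; every quantity of interest is
denominated in minutes.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, EmptyInputError
from .events import EventLog, FacilityType, VisitRecord, compute_target

__all__ = [
    "ExamSpec",
    "FacilityConfig",
    "SimulationGroundTruth",
    "generate_log",
    "summarize_log",
    "facility_archetype",
    "ARCHETYPES",
]


@dataclass(frozen=True)
class ExamSpec:
    """One entry of a facility's exam mix."""

    probability: float
    mean_minutes: float
    dispersion: float  # sd of log service time (log-normal shape)
    category: Optional[str] = None
    contrast: Optional[str] = None


@dataclass
class FacilityConfig:
    facility_id: str
    facility_type: Union[str, FacilityType]
    exam_mix: dict[str, ExamSpec]
    n_servers: int = 1
    open_time: str = "08:00"
    close_time: str = "18:00"
    slot_minutes: int = 30
    booking_prob: float = 0.0  # per server-slot fill probability (scheduled/hybrid)
    earliness_mean: float = -20.0  # minutes, arrival − scheduled
    earliness_sd: float = 12.0
    walkin_rate: float = 0.0  # arrivals/hour (walk-in and hybrid only)
    noshow_prob: float = 0.0
    addon_prob: float = 0.0  # per-slot probability of an inserted add-on
    n_days: int = 120  # operating (week)days
    start_date: str = "2018-01-01"
    seed: int = 0

    def __post_init__(self) -> None:
        self.facility_type = FacilityType.coerce(self.facility_type)
        self.exam_mix = {
            code: spec if isinstance(spec, ExamSpec) else ExamSpec(**spec)
            for code, spec in self.exam_mix.items()
        }
        self.validate()

    @property
    def open_minute(self) -> int:
        h, m = map(int, self.open_time.split(":"))
        return h * 60 + m

    @property
    def close_minute(self) -> int:
        h, m = map(int, self.close_time.split(":"))
        return h * 60 + m

    def validate(self) -> None:
        if self.n_days <= 0:
            raise ConfigError(f"n_days must be positive, got {self.n_days}")
        if self.n_servers < 1:
            raise ConfigError(f"n_servers must be >= 1, got {self.n_servers}")
        if self.slot_minutes <= 0:
            raise ConfigError("slot_minutes must be positive")
        window = self.close_minute - self.open_minute
        if window <= 0:
            raise ConfigError("close_time must be after open_time")
        if window % self.slot_minutes != 0:
            raise ConfigError(
                f"slot_minutes={self.slot_minutes} must divide the "
                f"{window}-minute operating window"
            )
        if self.exam_mix:
            total = sum(s.probability for s in self.exam_mix.values())
            if not math.isclose(total, 1.0, abs_tol=1e-6):
                raise ConfigError(f"exam_mix probabilities sum to {total}, expected 1")
            for code, spec in self.exam_mix.items():
                if spec.mean_minutes <= 0 or spec.dispersion < 0:
                    raise ConfigError(f"exam {code!r}: invalid service parameters")
        for p, name in [
            (self.noshow_prob, "noshow_prob"),
            (self.addon_prob, "addon_prob"),
            (self.booking_prob, "booking_prob"),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")

    @classmethod
    def from_dict(cls, data: dict) -> "FacilityConfig":
        data = dict(data)
        mix = {
            code: ExamSpec(**spec) if not isinstance(spec, ExamSpec) else spec
            for code, spec in data.pop("exam_mix", {}).items()
        }
        return cls(exam_mix=mix, **data)

    @classmethod
    def from_yaml(cls, path) -> "FacilityConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimulationGroundTruth:
    """Latent simulator state alongside the emitted log."""

    service_minutes: dict[str, int] = field(default_factory=dict)
    queue_order: dict[str, int] = field(default_factory=dict)  # global begin order
    busy_intervals: dict[str, list[tuple[pd.Timestamp, pd.Timestamp]]] = field(
        default_factory=dict
    )


@dataclass
class _Patient:
    seq: int
    scheduled: int  # minutes within day
    arrival: int
    addon: Optional[int]
    exam_code: str
    service: int
    age: float
    outpatient: bool


def _draw_service(rng: np.random.Generator, spec: ExamSpec) -> int:
    mu = math.log(spec.mean_minutes) - 0.5 * spec.dispersion**2
    return max(1, int(round(rng.lognormal(mu, spec.dispersion))))


def _operating_days(start_date: str, n_days: int) -> list[pd.Timestamp]:
    days = []
    day = pd.Timestamp(start_date)
    while len(days) < n_days:
        if day.dayofweek < 5:
            days.append(day)
        day += pd.Timedelta(days=1)
    return days


def run_day_queue(
    patients: list[_Patient], n_servers: int, open_minute: int
) -> dict[int, tuple[int, int, int]]:
    """Minute-clock queue simulation of one day.

    The next free server (lowest index on ties) takes the arrived patient
    with the earliest scheduled time, never before that scheduled time.
    Returns ``{seq: (begin, end, server)}`` in minutes within the day.
    """
    patients = sorted(patients, key=lambda p: (p.arrival, p.scheduled, p.seq))
    busy_until = [open_minute] * n_servers
    assignments: dict[int, tuple[int, int, int]] = {}
    waiting: list[tuple[int, int, int]] = []  # heap: (scheduled, arrival, seq)
    by_seq = {p.seq: p for p in patients}
    next_arrival = 0
    now = open_minute
    while len(assignments) < len(patients):
        while next_arrival < len(patients) and patients[next_arrival].arrival <= now:
            p = patients[next_arrival]
            heapq.heappush(waiting, (p.scheduled, p.arrival, p.seq))
            next_arrival += 1
        while waiting and waiting[0][0] <= now:
            server = min(range(n_servers), key=lambda k: (busy_until[k], k))
            if busy_until[server] > now:
                break
            _, _, pseq = heapq.heappop(waiting)
            begin = now
            end = begin + by_seq[pseq].service
            busy_until[server] = end
            assignments[pseq] = (begin, end, server)
        now += 1
    return assignments


def generate_log(config: FacilityConfig) -> tuple[EventLog, SimulationGroundTruth]:
    """Simulate the configured facility and return (log, ground truth).

    Identical config (including seed) yields a byte-identical log. Every
    visit satisfies arrival ≤ begin ≤ end and at most ``n_servers`` exams
    are in progress at any instant.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    codes = sorted(config.exam_mix)
    probs = np.array([config.exam_mix[c].probability for c in codes]) if codes else None
    ft = FacilityType.coerce(config.facility_type)
    open_m, close_m = config.open_minute, config.close_minute
    slots = list(range(open_m, close_m, config.slot_minutes))

    records: list[VisitRecord] = []
    truth = SimulationGroundTruth()
    for k in range(config.n_servers):
        truth.busy_intervals[f"{config.facility_id}-R{k + 1}"] = []
    begin_order: list[tuple[int, str]] = []  # (absolute begin minute, visit_id)

    for day_idx, day in enumerate(_operating_days(config.start_date, config.n_days)):
        patients: list[_Patient] = []
        seq = 0

        def new_patient(scheduled: int, arrival: int, addon: Optional[int]) -> None:
            nonlocal seq
            code = str(rng.choice(codes, p=probs))
            patients.append(
                _Patient(
                    seq=seq,
                    scheduled=scheduled,
                    arrival=arrival,
                    addon=addon,
                    exam_code=code,
                    service=_draw_service(rng, config.exam_mix[code]),
                    age=float(rng.integers(5, 91)),
                    outpatient=bool(rng.random() < 0.9),
                )
            )
            seq += 1

        if ft in (FacilityType.SCHEDULED, FacilityType.HYBRID) and config.booking_prob:
            for slot in slots:
                booked = rng.binomial(config.n_servers, config.booking_prob)
                for _ in range(booked):
                    if rng.random() < config.noshow_prob:
                        continue
                    early = rng.normal(config.earliness_mean, config.earliness_sd)
                    arrival = int(round(slot + early))
                    arrival = min(max(arrival, open_m - 60), close_m)
                    new_patient(slot, arrival, None)
            if config.addon_prob:
                n_add = rng.binomial(len(slots), config.addon_prob)
                for _ in range(n_add):
                    insert = int(rng.integers(open_m, close_m - 30))
                    new_patient(insert, insert, insert)

        if ft in (FacilityType.WALKIN, FacilityType.HYBRID) and config.walkin_rate > 0:
            hours = (close_m - open_m) / 60.0
            n_walk = rng.poisson(config.walkin_rate * hours)
            arrivals = np.sort(rng.integers(open_m, close_m, size=n_walk))
            for a in arrivals:
                new_patient(int(a), int(a), None)  # scheduled := arrival (proxy)

        assignments = run_day_queue(patients, config.n_servers, open_m)

        for p in sorted(patients, key=lambda p: p.seq):
            begin, end, server = assignments[p.seq]
            vid = f"{config.facility_id}-D{day_idx:04d}-{p.seq:03d}"
            spec = config.exam_mix[p.exam_code]
            to_ts = lambda m: day + pd.Timedelta(minutes=m)
            resource = f"{config.facility_id}-R{server + 1}"
            records.append(
                VisitRecord(
                    visit_id=vid,
                    facility_id=config.facility_id,
                    exam_code=p.exam_code,
                    exam_category=spec.category,
                    contrast_flag=spec.contrast,
                    scheduled_time=to_ts(p.scheduled),
                    arrival_time=to_ts(p.arrival),
                    begin_time=to_ts(begin),
                    end_time=to_ts(end),
                    resource_id=resource,
                    patient_age=p.age,
                    is_outpatient=p.outpatient,
                    addon_time=to_ts(p.addon) if p.addon is not None else None,
                )
            )
            truth.service_minutes[vid] = p.service
            truth.busy_intervals[resource].append((to_ts(begin), to_ts(end)))
            begin_order.append((day_idx * 10_000 + begin, vid))

    begin_order.sort()
    truth.queue_order = {vid: i for i, (_, vid) in enumerate(begin_order)}
    return EventLog(records, config.facility_id, ft), truth


def summarize_log(log: EventLog) -> pd.Series:
    """Headline operational statistics of a log: visits/day, mean and max of
    the facility target (delay or wait), mean service minutes, and rough
    server utilization (busy minutes over observed resource-day windows)."""
    if len(log) == 0:
        raise EmptyInputError("cannot summarize an empty log")
    df = log.to_frame()
    days = df["arrival_time"].dt.normalize()
    n_days = days.nunique()
    targets = np.array([compute_target(r, log.facility_type) for r in log])
    service = (df["end_time"] - df["begin_time"]).dt.total_seconds() / 60.0
    n_resources = df["resource_id"].nunique()
    day_span = (
        df.groupby(days)
        .apply(
            lambda g: (g["end_time"].max() - g["arrival_time"].min()).total_seconds()
            / 60.0,
            include_groups=False,
        )
        .sum()
    )
    utilization = float(service.sum() / (n_resources * day_span)) if day_span else float("nan")
    return pd.Series(
        {
            "n_visits": float(len(log)),
            "n_days": float(n_days),
            "visits_per_day": len(log) / n_days,
            "mean_target_minutes": float(targets.mean()),
            "max_target_minutes": float(targets.max()),
            "mean_service_minutes": float(service.mean()),
            "utilization": utilization,
        }
    )


def _mix(entries: dict[str, tuple[float, float, float, Optional[str], Optional[str]]]):
    return {
        code: ExamSpec(p, mean, disp, cat, con)
        for code, (p, mean, disp, cat, con) in entries.items()
    }


# Facility archetypes. Daily volumes span the 25–120 visits/day range typical
# of outpatient imaging; utilizations are chosen so congestion, not the clock,
# drives delays. Values are stated modelling assumptions (see docs/methods.md).
ARCHETYPES: dict[str, dict] = {
    # MRI-like: fully scheduled, long exams, ~25 visits/day, high utilization.
    "mri_scheduled": dict(
        facility_id="MRI1",
        facility_type="scheduled",
        n_servers=2,
        open_time="08:00",
        close_time="18:00",
        slot_minutes=30,
        booking_prob=0.70,
        noshow_prob=0.05,
        addon_prob=0.04,
        exam_mix=_mix(
            {
                "MR_BRAIN": (0.28, 42, 0.35, "neuro", "none"),
                "MR_BRAIN_C": (0.17, 50, 0.35, "neuro", "with"),
                "MR_SPINE": (0.22, 40, 0.35, "MSK", "none"),
                "MR_KNEE": (0.18, 34, 0.30, "MSK", "none"),
                "MR_ABD_WWO": (0.15, 48, 0.40, "abdominal", "with_and_without"),
            }
        ),
    ),
    # Ultrasound-like: fully scheduled, ~60 visits/day across 4 rooms.
    "ultrasound_scheduled": dict(
        facility_id="US1",
        facility_type="scheduled",
        n_servers=4,
        open_time="08:00",
        close_time="18:00",
        slot_minutes=30,
        booking_prob=0.88,
        noshow_prob=0.05,
        addon_prob=0.05,
        exam_mix=_mix(
            {
                "US_ABD": (0.30, 30, 0.40, "abdominal", "none"),
                "US_PELVIS": (0.22, 28, 0.40, "abdominal", "none"),
                "US_VASC": (0.18, 38, 0.40, "vascular", "none"),
                "US_THYROID": (0.15, 22, 0.35, "other", "none"),
                "US_PED": (0.15, 26, 0.40, "pediatric", "none"),
            }
        ),
    ),
    # CT-like hybrid: mostly scheduled with interspersed walk-ins, fast exams.
    "ct_hybrid": dict(
        facility_id="CT1",
        facility_type="hybrid",
        n_servers=2,
        open_time="08:00",
        close_time="20:00",
        slot_minutes=15,
        booking_prob=0.50,
        noshow_prob=0.04,
        addon_prob=0.04,
        walkin_rate=1.0,
        exam_mix=_mix(
            {
                "CT_HEAD": (0.25, 12, 0.40, "neuro", "none"),
                "CT_CHEST": (0.20, 15, 0.40, "thoracic", "none"),
                "CT_CHEST_C": (0.15, 18, 0.40, "thoracic", "with"),
                "CT_ABD_PELV_C": (0.25, 20, 0.45, "abdominal", "with"),
                "CT_CAP": (0.15, 26, 0.45, "combined", "with"),
            }
        ),
    ),
    # X-ray-like: pure walk-in FIFO, ~120 visits/day, very short exams.
    "xray_walkin": dict(
        facility_id="XR1",
        facility_type="walkin",
        n_servers=2,
        open_time="08:00",
        close_time="18:00",
        slot_minutes=30,
        walkin_rate=12.0,
        exam_mix=_mix(
            {
                "XR_CHEST": (0.35, 7, 0.40, "thoracic", "none"),
                "XR_HAND": (0.20, 6, 0.35, "MSK", "none"),
                "XR_FOOT": (0.15, 6, 0.35, "MSK", "none"),
                "XR_SPINE": (0.15, 9, 0.40, "other", "none"),
                "XR_PED": (0.15, 8, 0.40, "pediatric", "none"),
            }
        ),
    ),
}


def facility_archetype(name: str, **overrides) -> FacilityConfig:
    """A ready-made :class:`FacilityConfig` for one of the four archetypes
    (``mri_scheduled``, ``ultrasound_scheduled``, ``ct_hybrid``,
    ``xray_walkin``), with keyword overrides applied on top."""
    if name not in ARCHETYPES:
        raise ConfigError(f"unknown archetype {name!r}; choose from {sorted(ARCHETYPES)}")
    params = dict(ARCHETYPES[name])
    params.update(overrides)
    return FacilityConfig(**params)
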