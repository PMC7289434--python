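"""Leakage-safe as-of computation of the 84-feature vector.

Every feature row is evaluated at the index patient's arrival time ``t``
and may use only

* *events* (arrivals, exam begins, exam ends, add-on insertions) with
  timestamps ≤ t — a visit's delay/wait becomes known at its begin time;
* *schedule entries* (scheduled times and expected exam durations), which
  are known in advance and may therefore lie after ``t``.

Set membership at an instant ``t`` uses half-open boundaries:

=================  =============================
in line            arrival ≤ t < begin
in progress        begin ≤ t < end
completed today    end ≤ t, same day as t
begun today        begin ≤ t, same day as t
=================  =============================

so a visit whose exam begins exactly at ``t`` counts as in progress, not in
line. Trailing windows of width ``w`` are half-open ``(t − w, t]``. The
index visit itself is excluded from every state set and count.

Delay/wait-history features (MostRecent1–5, AvgWaitLast{2,4,8}Customers,
Median5, AvgWaitForDay, Min/MaxTime, DelayCount) are scoped to the current
day; the K-customer statistics zero-pad when fewer than K same-day
predecessors have begun. "Delayed" means a strictly positive delay.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .catalog import FeatureCatalog, build_catalog
from .errors import ConfigError, EmptyInputError
from .events import (
    EventLog,
    FacilityType,
    VisitRecord,
    minutes_since_epoch,
)

__all__ = [
    "QueueSnapshot",
    "DurationStats",
    "estimate_duration_stats",
    "expected_duration",
    "snapshot_state",
    "compute_features",
    "featurize_log",
    "write_matrix",
    "read_matrix",
]

DAY = 1440  # minutes
# A visit is assumed to complete within this many minutes of arrival; line
# and in-progress membership scans look back no further.
MAX_VISIT_SPAN = DAY


@dataclass
class QueueSnapshot:
    """Queue state of a log at an instant ``t`` (visit ids)."""

    t: pd.Timestamp
    in_line: list[str]
    in_progress: list[str]
    completed_today: list[str]
    begun_today: list[str]  # ordered by begin time


@dataclass
class DurationStats:
    """Historical expected (median) service duration per exam code, with a
    facility-wide fallback for unseen codes. Built from a reference period
    that precedes the rows being featurized."""

    durations: dict[str, float]
    fallback: float
    n_servers: int = 1
    reference_end: Optional[pd.Timestamp] = None

    def __post_init__(self) -> None:
        if self.fallback <= 0 or any(v <= 0 for v in self.durations.values()):
            raise ConfigError("expected durations must be positive")


def estimate_duration_stats(log: EventLog, reference_days: int = 90) -> DurationStats:
    """Median observed service duration per exam code over the first
    ``reference_days`` calendar days of the log (the reference period),
    frozen before any modelling. Raises on an empty reference period."""
    if len(log) == 0:
        raise EmptyInputError("cannot estimate durations from an empty log")
    start, _ = log.span
    cutoff = start.normalize() + pd.Timedelta(days=reference_days)
    by_code: dict[str, list[float]] = {}
    all_durs: list[float] = []
    for rec in log:
        if rec.arrival_time >= cutoff:
            continue
        dur = (rec.end_time - rec.begin_time).total_seconds() / 60.0
        if dur <= 0:
            dur = 1.0
        by_code.setdefault(rec.exam_code, []).append(dur)
        all_durs.append(dur)
    if not all_durs:
        raise ConfigError(
            f"no visits inside the {reference_days}-day reference period"
        )
    n_servers = len({rec.resource_id for rec in log})
    return DurationStats(
        durations={c: float(np.median(v)) for c, v in by_code.items()},
        fallback=float(np.median(all_durs)),
        n_servers=max(1, n_servers),
        reference_end=cutoff,
    )


def expected_duration(exam_code: str, stats: DurationStats) -> float:
    """Expected (historical median) service minutes for an exam code, the
    facility fallback median for codes never seen in the reference period."""
    return stats.durations.get(exam_code, stats.fallback)


def snapshot_state(log: EventLog, t: pd.Timestamp) -> QueueSnapshot:
    """Queue state of the whole log at ``t`` (no index-visit exclusion)."""
    t = pd.Timestamp(t)
    day = t.normalize()
    in_line, in_progress, completed, begun = [], [], [], []
    for rec in log:
        if rec.arrival_time <= t < rec.begin_time:
            in_line.append(rec.visit_id)
        if rec.begin_time <= t < rec.end_time:
            in_progress.append(rec.visit_id)
        same_day = rec.begin_time.normalize() == day
        if same_day and rec.end_time <= t:
            completed.append(rec.visit_id)
        if same_day and rec.begin_time <= t:
            begun.append((rec.begin_time, rec.visit_id))
    begun.sort()
    return QueueSnapshot(
        t=t,
        in_line=in_line,
        in_progress=in_progress,
        completed_today=completed,
        begun_today=[v for _, v in begun],
    )


class _AsOfEngine:
    """Vectorized per-row evaluation of the 84 features over one log."""

    def __init__(
        self,
        log: EventLog,
        catalog: FeatureCatalog,
        stats: DurationStats,
        slot_minutes: int = 30,
        n_servers: Optional[int] = None,
    ) -> None:
        if slot_minutes <= 0:
            raise ConfigError("slot_minutes must be positive")
        self.log = log
        self.catalog = catalog
        self.stats = stats
        self.slot = int(slot_minutes)
        self.n_servers = int(n_servers or stats.n_servers or 1)
        recs = log.records
        self._recs = recs
        n = len(recs)
        self.n = n
        self.visit_ids = [r.visit_id for r in recs]
        self.id_pos = {vid: i for i, vid in enumerate(self.visit_ids)}

        self.arr = minutes_since_epoch([r.arrival_time for r in recs])
        self.beg = minutes_since_epoch([r.begin_time for r in recs])
        self.end = minutes_since_epoch([r.end_time for r in recs])
        self.sch = minutes_since_epoch([r.scheduled_time for r in recs])
        self.addon = np.array(
            [
                minutes_since_epoch([r.addon_time])[0] if r.addon_time is not None else -(2**60)
                for r in recs
            ],
            dtype=np.int64,
        )
        self.has_addon = np.array([r.addon_time is not None for r in recs])
        self.age = np.array(
            [r.patient_age if r.patient_age is not None else np.nan for r in recs]
        )
        self.outp = np.array([r.is_outpatient for r in recs])
        self.contrast = np.array([r.contrast_flag or "none" for r in recs])
        self.category = np.array([r.exam_category or "" for r in recs])
        self.code = np.array([r.exam_code for r in recs])
        self.expdur = np.array([expected_duration(c, stats) for c in self.code])
        if log.facility_type is FacilityType.WALKIN:
            self.target = (self.beg - self.arr).astype(float)
        else:
            self.target = (self.beg - self.sch).astype(float)

        # begin-ordered view (stable in arrival order for ties)
        self.order_beg = np.lexsort((np.arange(n), self.beg))
        self.beg_sorted = self.beg[self.order_beg]
        self.pos_in_beg = np.empty(n, dtype=np.int64)
        self.pos_in_beg[self.order_beg] = np.arange(n)
        # end- and schedule-ordered views
        self.order_end = np.argsort(self.end, kind="stable")
        self.end_sorted = self.end[self.order_end]
        self.order_sch = np.argsort(self.sch, kind="stable")
        self.sch_sorted = self.sch[self.order_sch]
        # add-on insertion times, sorted
        addon_times = self.addon[self.has_addon]
        self.addon_sorted = np.sort(addon_times)

    # -- helpers ----------------------------------------------------------
    def _line_segment(self, i: int, t: int):
        """Candidate indices for in-line / in-progress membership at t."""
        lo = np.searchsorted(self.arr, t - MAX_VISIT_SPAN, side="left")
        hi = np.searchsorted(self.arr, t, side="right")
        idx = np.arange(lo, hi)
        return idx[idx != i]

    def _beg_window(self, i: int, lo_t: int, hi_t: int) -> np.ndarray:
        """Original indices of visits with begin in (lo_t, hi_t], index excluded."""
        lo = np.searchsorted(self.beg_sorted, lo_t, side="right")
        hi = np.searchsorted(self.beg_sorted, hi_t, side="right")
        idx = self.order_beg[lo:hi]
        return idx[idx != i]

    def row(self, i: int) -> dict[str, float]:
        arr, beg, end, sch = self.arr, self.beg, self.end, self.sch
        t = int(arr[i])
        day_start = (t // DAY) * DAY
        day_end = day_start + DAY
        slot = self.slot

        seg = self._line_segment(i, t)
        in_line = seg[beg[seg] > t]
        in_prog = seg[(beg[seg] <= t) & (end[seg] > t)]

        f: dict[str, float] = {}
        line_n = len(in_line)
        f["LineCount0"] = line_n
        f["LineCount0Strict"] = float(np.sum(sch[in_line] > t))
        for k, back in enumerate((15, 30, 45, 60), start=1):
            s = t - back
            members = seg[(arr[seg] <= s) & (beg[seg] > s)]
            f[f"LineCount{k}"] = float(len(members))
        f["NoneInLine"] = float(line_n == 0)
        f["SumWaits"] = float(np.sum(t - arr[in_line]))
        f["SumHowEarlyWaiting"] = float(np.sum(sch[in_line] - arr[in_line]))
        f["AvgHowEarlyWaiting"] = f["SumHowEarlyWaiting"] / line_n if line_n else 0.0
        f["SumDelayWaitingInLine"] = float(np.sum(t - sch[in_line]))
        f["DelayedInLine"] = float(np.sum(sch[in_line] < t))

        # flow: begins and ends in trailing windows
        for w in (30, 60):
            f[f"FlowCount{w}"] = float(len(self._beg_window(i, t - w, t)))
        for w in (30, 60, 120):
            lo = np.searchsorted(self.end_sorted, t - w, side="right")
            hi = np.searchsorted(self.end_sorted, t, side="right")
            idx = self.order_end[lo:hi]
            f[f"NumCompletedInLast{w}"] = float(np.sum(idx != i))
        # arrivals in trailing windows: the log is arrival-sorted; the index
        # visit always sits inside (t−w, t] and is excluded.
        for w in (30, 60, 120):
            lo = np.searchsorted(arr, t - w, side="right")
            hi = np.searchsorted(arr, t, side="right")
            f[f"NumCustomersLast{w}"] = float(hi - lo - 1)

        # schedule windows (schedule entries may lie after t)
        def sched_count(lo_t: int, hi_t: int, lo_side="right", hi_side="right"):
            lo = np.searchsorted(self.sch_sorted, lo_t, side=lo_side)
            hi = np.searchsorted(self.sch_sorted, hi_t, side=hi_side)
            idx = self.order_sch[lo:hi]
            return idx[idx != i]

        f["ScheduledFlowCount30"] = float(len(sched_count(t - 30, t)))
        f["ScheduledFlowCount60"] = float(len(sched_count(t - 60, t)))
        f["FutureFlowCount30"] = float(len(sched_count(t, t + 30)))
        f["FutureFlowCount60"] = float(len(sched_count(t, t + 60)))
        f["NumScheduledNext60"] = f["FutureFlowCount60"]
        # next slot: the first full grid slot [g, g+slot) starting at or after t
        g = day_start + -((day_start - t) // slot) * slot  # ceil to grid
        next_slot = sched_count(g, g + slot, lo_side="left", hi_side="left")
        f["NumScheduledNextSlot"] = float(len(next_slot))
        f["SumTimeToCompleteNextSlot"] = float(np.sum(self.expdur[next_slot]))
        next60 = sched_count(t, t + 60)
        f["SumTimeToCompleteNext60"] = float(np.sum(self.expdur[next60]))

        # position of the index visit within today's schedule
        si = int(sch[i])
        s_day_start = (si // DAY) * DAY
        lo_d = np.searchsorted(self.sch_sorted, s_day_start, side="left")
        hi_d = np.searchsorted(self.sch_sorted, s_day_start + DAY, side="left")
        before = np.searchsorted(self.sch_sorted, si, side="left")
        after = np.searchsorted(self.sch_sorted, si, side="right")
        f["AheadCount"] = float(before - lo_d)
        f["IsFirst"] = float(before - lo_d == 0)
        f["IsLast"] = float(hi_d - after == 0)

        # add-ons (an add-on becomes known at its insertion time)
        own = 1 if (self.has_addon[i] and self.addon[i] <= t) else 0
        lo = np.searchsorted(self.addon_sorted, day_start, side="left")
        hi = np.searchsorted(self.addon_sorted, t, side="right")
        f["NumAddOnsToday"] = float(hi - lo - (own if self.addon[i] >= day_start else 0))
        lo = np.searchsorted(self.addon_sorted, t - 60, side="right")
        f["NumAddOnsLast60"] = float(hi - lo - (own if self.addon[i] > t - 60 else 0))

        # in-progress aggregates
        prog_n = len(in_prog)
        f["InProgressSize"] = float(prog_n)
        f["NoneInProgress"] = float(prog_n == 0)
        f["SumInProgress"] = float(np.sum(t - beg[in_prog]))
        remaining = np.maximum(0.0, self.expdur[in_prog] - (t - beg[in_prog]))
        f["SumTimeToCompleteInProgress"] = float(np.sum(remaining))
        f["SumDelayInProgress"] = float(np.sum(beg[in_prog] - sch[in_prog]))

        # completed today
        lo = np.searchsorted(self.end_sorted, day_start, side="left")
        hi = np.searchsorted(self.end_sorted, t, side="right")
        idx = self.order_end[lo:hi]
        completed_today = float(np.sum(idx != i))
        f["NumCompletedToday"] = completed_today
        f["NoneCompleted"] = float(completed_today == 0)

        # day-scoped delay/wait history: visits begun today, begin ≤ t
        begun = self._beg_window(i, day_start - 1, t)
        begun = begun[beg[begun] >= day_start]
        hist = self.target[begun]  # ordered by begin (window preserves order)
        m = len(hist)
        f["AvgWaitForDay"] = float(hist.mean()) if m else 0.0
        f["MinTime"] = float(hist.min()) if m else 0.0
        f["MaxTime"] = float(hist.max()) if m else 0.0
        f["DelayCount"] = float(np.sum(hist > 0))
        hour = self._beg_window(i, t - 60, t)
        f["DelayCountLastHour"] = float(np.sum(self.target[hour] > 0))
        for w in (30, 60, 120):
            win = self.target[self._beg_window(i, t - w, t)]
            f[f"AvgWaitLast{w}"] = float(win.mean()) if len(win) else 0.0
        recent = hist[::-1]  # most recent first
        for k in range(1, 6):
            f[f"MostRecent{k}"] = float(recent[k - 1]) if m >= k else 0.0
        for k in (2, 4, 8):
            f[f"AvgWaitLast{k}Customers"] = float(np.sum(recent[:k]) / k)
        last5 = np.zeros(5)
        last5[: min(5, m)] = recent[:5]
        f["Median5"] = float(np.median(last5))

        # customer / resource / task state
        ages = self.age[in_line]
        ages = ages[~np.isnan(ages)]
        f["AvgAgePeopleWaiting"] = float(ages.mean()) if len(ages) else 0.0
        f["OutpatientWaitingCount"] = float(np.sum(self.outp[in_line]))
        f["NumScannersInUseToday"] = float(
            len(set(self._recs[j].resource_id for j in begun))
        )
        f["WithContrastCountWaiting"] = float(np.sum(self.contrast[in_line] == "with"))
        f["WithandWithoutContrastCountWaiting"] = float(
            np.sum(self.contrast[in_line] == "with_and_without")
        )
        f["WithContrastCountInProgress"] = float(np.sum(self.contrast[in_prog] == "with"))
        f["WithandWithoutContrastCountInProgress"] = float(
            np.sum(self.contrast[in_prog] == "with_and_without")
        )
        same_code = in_line[self.code[in_line] == self.code[i]]
        f["SumDelayWaitingByExamCode"] = float(np.sum(t - sch[same_code]))
        waits_code = t - arr[same_code]
        f["SumWaitByTaskTypeLine"] = float(np.sum(waits_code))
        f["AvgWaitByTaskTypeLine"] = (
            float(waits_code.mean()) if len(waits_code) else 0.0
        )
        for cat, fname in [
            ("MSK", "MSKCount"),
            ("cardiac", "CardiacCount"),
            ("vascular", "VascularCount"),
            ("abdominal", "AbdominalCount"),
            ("neuro", "NeuroCount"),
            ("pediatric", "PediatricCount"),
            ("thoracic", "ThoracicCount"),
        ]:
            f[fname] = float(np.sum(self.category[in_line] == cat))

        # expected delay of the next scheduled exam (index excluded)
        nxt = sched_count(t, day_end, hi_side="left")
        if len(nxt):
            next_sch = float(np.min(sch[nxt]))
            clearance = t + f["SumTimeToCompleteInProgress"] / self.n_servers
            f["ExpectedDelayNextExam"] = max(0.0, clearance - next_sch)
        else:
            f["ExpectedDelayNextExam"] = 0.0

        # clock / calendar features
        ts = self._recs[i].scheduled_time
        f["DayOfYear"] = float(ts.dayofyear)
        f["Month"] = float(ts.month)
        f["DayOfWeek"] = float(ts.dayofweek)
        start = (t - day_start) / 60.0
        f["StartTime"] = start
        f["StartTime2"] = start**2
        f["StartTime3"] = start**3
        f["StartTime4"] = start**4
        before_slot = (t - day_start) % slot
        f["BeforeSlot"] = float(before_slot)
        f["AfterSlot"] = float((slot - before_slot) % slot)

        return {name: f[name] for name in self.catalog.names}


def compute_features(
    log: EventLog,
    index_visit: Union[str, VisitRecord],
    catalog: Optional[FeatureCatalog] = None,
    stats: Optional[DurationStats] = None,
    slot_minutes: int = 30,
    n_servers: Optional[int] = None,
) -> pd.Series:
    """The 84-feature vector for one visit of ``log``, evaluated at that
    visit's arrival time. Raises ``KeyError`` if the visit is not in the log."""
    catalog = catalog or build_catalog(log.facility_type)
    stats = stats or estimate_duration_stats(log, reference_days=36_500)
    vid = index_visit if isinstance(index_visit, str) else index_visit.visit_id
    engine = _AsOfEngine(log, catalog, stats, slot_minutes, n_servers)
    if vid not in engine.id_pos:
        raise KeyError(f"visit {vid!r} is not in the log")
    return pd.Series(engine.row(engine.id_pos[vid]), dtype=float)


def featurize_log(
    log: EventLog,
    catalog: Optional[FeatureCatalog] = None,
    stats: Optional[DurationStats] = None,
    slot_minutes: int = 30,
    n_servers: Optional[int] = None,
    start: Optional[pd.Timestamp] = None,
) -> pd.DataFrame:
    """Feature matrix for a log: one row per visit, 84 feature columns in
    catalog order plus the facility-appropriate ``target`` (minutes).

    ``start`` restricts rows to visits arriving at or after it — used to
    keep the duration-reference period disjoint from the modelling rows.
    """
    if len(log) == 0:
        raise EmptyInputError("cannot featurize an empty log")
    catalog = catalog or build_catalog(log.facility_type)
    stats = stats or estimate_duration_stats(log, reference_days=36_500)
    engine = _AsOfEngine(log, catalog, stats, slot_minutes, n_servers)
    start_m = None
    if start is not None:
        start_m = int(minutes_since_epoch([pd.Timestamp(start)])[0])
    rows, ids, times, targets = [], [], [], []
    for i in range(engine.n):
        if start_m is not None and engine.arr[i] < start_m:
            continue
        rows.append(engine.row(i))
        ids.append(engine.visit_ids[i])
        times.append(engine._recs[i].arrival_time)
        targets.append(engine.target[i])
    matrix = pd.DataFrame(rows, columns=catalog.names)
    matrix.insert(0, "visit_id", ids)
    matrix.insert(1, "prediction_time", pd.DatetimeIndex(times))
    matrix["target"] = np.asarray(targets, dtype=float)
    return matrix


def write_matrix(matrix: pd.DataFrame, path) -> None:
    out = matrix.copy()
    out["prediction_time"] = out["prediction_time"].dt.strftime("%Y-%m-%dT%H:%M")
    out.to_csv(path, index=False)


def read_matrix(path) -> pd.DataFrame:
    matrix = pd.read_csv(path)
    matrix["prediction_time"] = pd.to_datetime(matrix["prediction_time"])
    return matrix
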