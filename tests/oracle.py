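"""Independent brute-force re-implementation of the 84-feature definitions.

Computes every feature for one index visit by naive full scans over the raw
record list — no sorting tricks, no incremental state, no shared code with
the package's vectorized engine — so it can serve as an O(n²) oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from queueflow.events import FacilityType, VisitRecord
from queueflow.features import DurationStats, expected_duration

DAY = 1440


def _m(ts: pd.Timestamp) -> int:
    return int(ts.value // 60_000_000_000)


def _target(rec: VisitRecord, facility_type: FacilityType) -> float:
    if facility_type is FacilityType.WALKIN:
        return float(_m(rec.begin_time) - _m(rec.arrival_time))
    return float(_m(rec.begin_time) - _m(rec.scheduled_time))


def oracle_features(
    records: list[VisitRecord],
    facility_type,
    index: VisitRecord,
    stats: DurationStats,
    slot_minutes: int = 30,
    n_servers: int = 1,
) -> dict[str, float]:
    ft = FacilityType.coerce(facility_type)
    t = _m(index.arrival_time)
    others = [r for r in records if r.visit_id != index.visit_id]
    day_start = (t // DAY) * DAY
    day_end = day_start + DAY
    slot = slot_minutes

    def in_line_at(s):
        return [r for r in others if _m(r.arrival_time) <= s < _m(r.begin_time)]

    line = in_line_at(t)
    prog = [r for r in others if _m(r.begin_time) <= t < _m(r.end_time)]

    f: dict[str, float] = {}
    f["LineCount0"] = len(line)
    f["LineCount0Strict"] = sum(1 for r in line if _m(r.scheduled_time) > t)
    for k, back in enumerate((15, 30, 45, 60), start=1):
        f[f"LineCount{k}"] = len(in_line_at(t - back))
    f["NoneInLine"] = 1.0 if not line else 0.0
    f["SumWaits"] = sum(t - _m(r.arrival_time) for r in line)
    f["SumHowEarlyWaiting"] = sum(
        _m(r.scheduled_time) - _m(r.arrival_time) for r in line
    )
    f["AvgHowEarlyWaiting"] = f["SumHowEarlyWaiting"] / len(line) if line else 0.0
    f["SumDelayWaitingInLine"] = sum(t - _m(r.scheduled_time) for r in line)
    f["DelayedInLine"] = sum(1 for r in line if _m(r.scheduled_time) < t)

    for w in (30, 60):
        f[f"FlowCount{w}"] = sum(1 for r in others if t - w < _m(r.begin_time) <= t)
    for w in (30, 60, 120):
        f[f"NumCompletedInLast{w}"] = sum(
            1 for r in others if t - w < _m(r.end_time) <= t
        )
        f[f"NumCustomersLast{w}"] = sum(
            1 for r in others if t - w < _m(r.arrival_time) <= t
        )

    f["ScheduledFlowCount30"] = sum(1 for r in others if t - 30 < _m(r.scheduled_time) <= t)
    f["ScheduledFlowCount60"] = sum(1 for r in others if t - 60 < _m(r.scheduled_time) <= t)
    f["FutureFlowCount30"] = sum(1 for r in others if t < _m(r.scheduled_time) <= t + 30)
    f["FutureFlowCount60"] = sum(1 for r in others if t < _m(r.scheduled_time) <= t + 60)
    f["NumScheduledNext60"] = f["FutureFlowCount60"]
    g = day_start + ((t - day_start + slot - 1) // slot) * slot
    nxt_slot = [r for r in others if g <= _m(r.scheduled_time) < g + slot]
    f["NumScheduledNextSlot"] = len(nxt_slot)
    f["SumTimeToCompleteNextSlot"] = sum(
        expected_duration(r.exam_code, stats) for r in nxt_slot
    )
    f["SumTimeToCompleteNext60"] = sum(
        expected_duration(r.exam_code, stats)
        for r in others
        if t < _m(r.scheduled_time) <= t + 60
    )

    si = _m(index.scheduled_time)
    s_day = (si // DAY) * DAY
    same_day_sched = [r for r in others if s_day <= _m(r.scheduled_time) < s_day + DAY]
    f["AheadCount"] = sum(1 for r in same_day_sched if _m(r.scheduled_time) < si)
    f["IsFirst"] = 1.0 if f["AheadCount"] == 0 else 0.0
    f["IsLast"] = (
        1.0 if not any(_m(r.scheduled_time) > si for r in same_day_sched) else 0.0
    )

    addons = [r for r in others if r.addon_time is not None]
    f["NumAddOnsToday"] = sum(
        1 for r in addons if day_start <= _m(r.addon_time) <= t
    )
    f["NumAddOnsLast60"] = sum(1 for r in addons if t - 60 < _m(r.addon_time) <= t)

    f["InProgressSize"] = len(prog)
    f["NoneInProgress"] = 1.0 if not prog else 0.0
    f["SumInProgress"] = sum(t - _m(r.begin_time) for r in prog)
    f["SumTimeToCompleteInProgress"] = sum(
        max(0.0, expected_duration(r.exam_code, stats) - (t - _m(r.begin_time)))
        for r in prog
    )
    f["SumDelayInProgress"] = sum(
        _m(r.begin_time) - _m(r.scheduled_time) for r in prog
    )

    completed_today = sum(
        1 for r in others if day_start <= _m(r.end_time) <= t
    )
    f["NumCompletedToday"] = completed_today
    f["NoneCompleted"] = 1.0 if completed_today == 0 else 0.0

    begun = [
        r for r in others if day_start <= _m(r.begin_time) <= t
    ]
    begun.sort(key=lambda r: (_m(r.begin_time), _m(r.arrival_time), r.visit_id))
    hist = [_target(r, ft) for r in begun]
    f["AvgWaitForDay"] = float(np.mean(hist)) if hist else 0.0
    f["MinTime"] = min(hist) if hist else 0.0
    f["MaxTime"] = max(hist) if hist else 0.0
    f["DelayCount"] = sum(1 for v in hist if v > 0)
    f["DelayCountLastHour"] = sum(
        1
        for r in others
        if t - 60 < _m(r.begin_time) <= t and _target(r, ft) > 0
    )
    for w in (30, 60, 120):
        win = [_target(r, ft) for r in others if t - w < _m(r.begin_time) <= t]
        f[f"AvgWaitLast{w}"] = float(np.mean(win)) if win else 0.0
    recent = hist[::-1]
    for k in range(1, 6):
        f[f"MostRecent{k}"] = recent[k - 1] if len(recent) >= k else 0.0
    for k in (2, 4, 8):
        f[f"AvgWaitLast{k}Customers"] = sum(recent[:k]) / k
    last5 = (recent[:5] + [0.0] * 5)[:5]
    f["Median5"] = float(np.median(last5))

    ages = [r.patient_age for r in line if r.patient_age is not None]
    f["AvgAgePeopleWaiting"] = float(np.mean(ages)) if ages else 0.0
    f["OutpatientWaitingCount"] = sum(1 for r in line if r.is_outpatient)
    f["NumScannersInUseToday"] = len({r.resource_id for r in begun})
    f["WithContrastCountWaiting"] = sum(1 for r in line if r.contrast_flag == "with")
    f["WithandWithoutContrastCountWaiting"] = sum(
        1 for r in line if r.contrast_flag == "with_and_without"
    )
    f["WithContrastCountInProgress"] = sum(1 for r in prog if r.contrast_flag == "with")
    f["WithandWithoutContrastCountInProgress"] = sum(
        1 for r in prog if r.contrast_flag == "with_and_without"
    )
    same_code = [r for r in line if r.exam_code == index.exam_code]
    f["SumDelayWaitingByExamCode"] = sum(t - _m(r.scheduled_time) for r in same_code)
    waits_code = [t - _m(r.arrival_time) for r in same_code]
    f["SumWaitByTaskTypeLine"] = sum(waits_code)
    f["AvgWaitByTaskTypeLine"] = float(np.mean(waits_code)) if waits_code else 0.0
    for cat, name in [
        ("MSK", "MSKCount"),
        ("cardiac", "CardiacCount"),
        ("vascular", "VascularCount"),
        ("abdominal", "AbdominalCount"),
        ("neuro", "NeuroCount"),
        ("pediatric", "PediatricCount"),
        ("thoracic", "ThoracicCount"),
    ]:
        f[name] = sum(1 for r in line if r.exam_category == cat)

    future_sched = [
        r for r in others if t < _m(r.scheduled_time) < day_end
    ]
    if future_sched:
        next_sch = min(_m(r.scheduled_time) for r in future_sched)
        clearance = t + f["SumTimeToCompleteInProgress"] / n_servers
        f["ExpectedDelayNextExam"] = max(0.0, clearance - next_sch)
    else:
        f["ExpectedDelayNextExam"] = 0.0

    ts = index.scheduled_time
    f["DayOfYear"] = float(ts.dayofyear)
    f["Month"] = float(ts.month)
    f["DayOfWeek"] = float(ts.dayofweek)
    start = (t - day_start) / 60.0
    f["StartTime"] = start
    f["StartTime2"] = start**2
    f["StartTime3"] = start**3
    f["StartTime4"] = start**4
    f["BeforeSlot"] = float((t - day_start) % slot)
    f["AfterSlot"] = float((slot - (t - day_start) % slot) % slot)
    return {k: float(v) for k, v in f.items()}
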