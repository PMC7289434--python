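"""The operational feature catalog: 84 named predictors in five groups.

Groups
    congestion (57)  system-load state: line counts and their one-hour
                     history, flow counts, in-progress totals, completed
                     counts, and delay/wait history;
    customer (2)     aggregates over the patients currently in line;
    resource (1)     distinct scanners used so far today;
    task (15)        exam-type composition of the line and in-progress set;
    time (9)         calendar and clock attributes of the index visit.

Every feature is evaluated *as of the index patient's arrival time* and is
computable from a typical facility information system's visit log. Two
applicability flags accompany each feature:

``walkin_applicable``
    strict reading — False for every feature whose definition needs a real
    appointment schedule (slot-grid features, scheduled-flow counts,
    earliness sums, first/last-of-day indicators) or a signed delay;
``walkin_proxy_applicable``
    permissive reading — with arrival time standing in for the scheduled
    time, only the delay-defined counters (DelayedInLine, DelayCount,
    DelayCountLastHour) lose their meaning, since a walk-in "delay"
    degenerates to a nonnegative wait and the counters saturate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional, Union

import pandas as pd

from .events import FacilityType

__all__ = ["FeatureDefinition", "FeatureCatalog", "build_catalog", "GROUPS"]

GROUPS = ("congestion", "customer", "resource", "task", "time")


@dataclass(frozen=True)
class FeatureDefinition:
    name: str
    group: str
    description: str
    window_minutes: Optional[int] = None
    walkin_applicable: bool = True
    walkin_proxy_applicable: bool = True


# (name, group, description, window, strict walk-in flag, proxy flag)
_ROWS: list[tuple] = [
    ("LineCount0Strict", "congestion", "Patients in line whose scheduled time is after now", None, False, True),
    ("LineCount0", "congestion", "Patients in line at arrival", None, True, True),
    ("LineCount1", "congestion", "Patients in line 15 minutes before arrival", 15, True, True),
    ("LineCount2", "congestion", "Patients in line 30 minutes before arrival", 30, True, True),
    ("LineCount3", "congestion", "Patients in line 45 minutes before arrival", 45, True, True),
    ("LineCount4", "congestion", "Patients in line 60 minutes before arrival", 60, True, True),
    ("FlowCount30", "congestion", "Exams begun in the last 30 minutes", 30, True, True),
    ("FlowCount60", "congestion", "Exams begun in the last 60 minutes", 60, True, True),
    ("ScheduledFlowCount30", "congestion", "Patients scheduled in the last 30 minutes", 30, False, True),
    ("ScheduledFlowCount60", "congestion", "Patients scheduled in the last 60 minutes", 60, False, True),
    ("FutureFlowCount30", "congestion", "Patients scheduled in the next 30 minutes", 30, False, True),
    ("FutureFlowCount60", "congestion", "Patients scheduled in the next 60 minutes", 60, False, True),
    ("AheadCount", "congestion", "Patients scheduled before this one today", None, True, True),
    ("IsFirst", "congestion", "First scheduled patient of the day", None, False, True),
    ("IsLast", "congestion", "Last scheduled patient of the day", None, False, True),
    ("NoneInLine", "congestion", "No patients in line", None, True, True),
    ("SumWaits", "congestion", "Sum of elapsed waits of patients in line", None, True, True),
    ("NumCustomersLast30", "congestion", "Arrivals in the last 30 minutes", 30, True, True),
    ("NumCustomersLast60", "congestion", "Arrivals in the last 60 minutes", 60, True, True),
    ("NumCustomersLast120", "congestion", "Arrivals in the last 120 minutes", 120, True, True),
    ("NumScheduledNextSlot", "congestion", "Patients scheduled in the next slot", None, False, True),
    ("NumScheduledNext60", "congestion", "Patients scheduled in the next 60 minutes", 60, False, True),
    ("AvgWaitForDay", "congestion", "Mean delay/wait of patients begun today", None, True, True),
    ("NumCompletedInLast30", "congestion", "Exams completed in the last 30 minutes", 30, True, True),
    ("NumCompletedInLast60", "congestion", "Exams completed in the last 60 minutes", 60, True, True),
    ("NumCompletedInLast120", "congestion", "Exams completed in the last 120 minutes", 120, True, True),
    ("NumCompletedToday", "congestion", "Exams completed so far today", None, True, True),
    ("DelayedInLine", "congestion", "Patients in line already past their scheduled time", None, False, False),
    ("MinTime", "congestion", "Minimum delay/wait so far today", None, True, True),
    ("MaxTime", "congestion", "Maximum delay/wait so far today", None, True, True),
    ("DelayCount", "congestion", "Delayed exams so far today", None, False, False),
    ("DelayCountLastHour", "congestion", "Delayed exams in the last hour", 60, False, False),
    ("AvgWaitLast30", "congestion", "Mean delay/wait of exams begun in the last 30 minutes", 30, True, True),
    ("AvgWaitLast60", "congestion", "Mean delay/wait of exams begun in the last 60 minutes", 60, True, True),
    ("AvgWaitLast120", "congestion", "Mean delay/wait of exams begun in the last 120 minutes", 120, True, True),
    ("SumTimeToCompleteNextSlot", "congestion", "Expected service minutes of exams in the next slot", None, False, True),
    ("SumTimeToCompleteNext60", "congestion", "Expected service minutes of exams scheduled in the next hour", 60, False, True),
    ("InProgressSize", "congestion", "Exams in progress", None, True, True),
    ("SumTimeToCompleteInProgress", "congestion", "Remaining expected minutes of exams in progress", None, True, True),
    ("NoneCompleted", "congestion", "No exams completed yet today", None, True, True),
    ("NoneInProgress", "congestion", "No exams in progress", None, True, True),
    ("SumInProgress", "congestion", "Sum of elapsed minutes of exams in progress", None, True, True),
    ("MostRecent1", "congestion", "Delay/wait of the most recent patient", None, True, True),
    ("MostRecent2", "congestion", "Delay/wait of the 2nd most recent patient", None, True, True),
    ("MostRecent3", "congestion", "Delay/wait of the 3rd most recent patient", None, True, True),
    ("MostRecent4", "congestion", "Delay/wait of the 4th most recent patient", None, True, True),
    ("MostRecent5", "congestion", "Delay/wait of the 5th most recent patient", None, True, True),
    ("AvgWaitLast2Customers", "congestion", "Mean delay/wait of the last 2 patients", None, True, True),
    ("AvgWaitLast4Customers", "congestion", "Mean delay/wait of the last 4 patients", None, True, True),
    ("AvgWaitLast8Customers", "congestion", "Mean delay/wait of the last 8 patients", None, True, True),
    ("Median5", "congestion", "Median delay/wait of the 5 most recent patients", None, True, True),
    ("NumAddOnsToday", "congestion", "Patients added to today's schedule so far", None, False, True),
    ("NumAddOnsLast60", "congestion", "Patients added to the schedule in the last 60 minutes", 60, False, True),
    ("SumHowEarlyWaiting", "congestion", "Sum of (scheduled − arrival) over patients in line", None, False, True),
    ("AvgHowEarlyWaiting", "congestion", "Mean of (scheduled − arrival) over patients in line", None, False, True),
    ("SumDelayWaitingInLine", "congestion", "Sum of current delays/waits of patients in line", None, True, True),
    ("SumDelayInProgress", "congestion", "Sum of delays/waits of exams in progress", None, True, True),
    ("AvgAgePeopleWaiting", "customer", "Mean age of patients in line", None, True, True),
    ("OutpatientWaitingCount", "customer", "Outpatients in line", None, True, True),
    ("NumScannersInUseToday", "resource", "Distinct scanners used so far today", None, True, True),
    ("WithContrastCountWaiting", "task", "Patients in line for a with-contrast exam", None, True, True),
    ("WithandWithoutContrastCountWaiting", "task", "Patients in line for a with-and-without-contrast exam", None, True, True),
    ("WithContrastCountInProgress", "task", "With-contrast exams in progress", None, True, True),
    ("WithandWithoutContrastCountInProgress", "task", "With-and-without-contrast exams in progress", None, True, True),
    ("ExpectedDelayNextExam", "task", "Expected delay of the next scheduled exam", None, False, True),
    ("SumDelayWaitingByExamCode", "task", "Sum of current delays of in-line patients with this exam code", None, True, True),
    ("AvgWaitByTaskTypeLine", "task", "Mean elapsed wait of in-line patients with this exam code", None, True, True),
    ("SumWaitByTaskTypeLine", "task", "Sum of elapsed waits of in-line patients with this exam code", None, True, True),
    ("MSKCount", "task", "Patients in line for a musculoskeletal exam", None, True, True),
    ("CardiacCount", "task", "Patients in line for a cardiac exam", None, True, True),
    ("VascularCount", "task", "Patients in line for a vascular exam", None, True, True),
    ("AbdominalCount", "task", "Patients in line for an abdominal exam", None, True, True),
    ("NeuroCount", "task", "Patients in line for a neuro exam", None, True, True),
    ("PediatricCount", "task", "Patients in line for a pediatric exam", None, True, True),
    ("ThoracicCount", "task", "Patients in line for a thoracic exam", None, True, True),
    ("DayOfYear", "time", "Day of year of the scheduled exam", None, True, True),
    ("Month", "time", "Month of the scheduled exam", None, True, True),
    ("DayOfWeek", "time", "Day of week of the scheduled exam (Monday = 0)", None, True, True),
    ("StartTime", "time", "Fractional hour of arrival", None, True, True),
    ("StartTime2", "time", "Squared hour of arrival", None, True, True),
    ("StartTime3", "time", "Cubed hour of arrival", None, True, True),
    ("StartTime4", "time", "4th power of hour of arrival", None, True, True),
    ("BeforeSlot", "time", "Minutes since the previous appointment-grid point", None, False, True),
    ("AfterSlot", "time", "Minutes until the next appointment-grid point", None, False, True),
]


class FeatureCatalog:
    """Ordered collection of the 84 feature definitions."""

    def __init__(self, definitions: list[FeatureDefinition], facility_type=None):
        names = [d.name for d in definitions]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        self._defs = list(definitions)
        self._by_name = {d.name: d for d in definitions}
        self.facility_type = facility_type

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self) -> Iterator[FeatureDefinition]:
        return iter(self._defs)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> FeatureDefinition:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [d.name for d in self._defs]

    def group(self, name: str) -> str:
        return self._by_name[name].group

    def group_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for d in self._defs:
            counts[d.group] = counts.get(d.group, 0) + 1
        return counts

    def order_index(self, name: str) -> int:
        return self.names.index(name)

    def to_frame(self) -> pd.DataFrame:
        """Data-dictionary view (one row per feature)."""
        return pd.DataFrame(
            [
                {
                    "name": d.name,
                    "group": d.group,
                    "description": d.description,
                    "window_minutes": d.window_minutes,
                    "walkin_applicable": d.walkin_applicable,
                    "walkin_proxy_applicable": d.walkin_proxy_applicable,
                }
                for d in self._defs
            ]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_catalog(
    facility_type: Union[str, FacilityType, None] = None
) -> FeatureCatalog:
    """The full expanded catalog (84 features, 5 groups) with walk-in
    applicability flags. ``facility_type`` is recorded on the catalog for
    downstream applicability filtering; the definitions themselves are
    facility-independent."""
    if facility_type is not None:
        facility_type = FacilityType.coerce(facility_type)
    defs = [
        FeatureDefinition(name, group, desc, window, strict, proxy)
        for name, group, desc, window, strict, proxy in _ROWS
    ]
    return FeatureCatalog(defs, facility_type=facility_type)
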