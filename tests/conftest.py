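import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import queueflow as qf

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def ts(s: str) -> pd.Timestamp:
    return pd.Timestamp(s)


def make_visit(
    visit_id,
    arrival,
    begin,
    end,
    scheduled=None,
    facility_id="F",
    exam_code="EX",
    exam_category=None,
    contrast_flag=None,
    resource_id="F-R1",
    patient_age=None,
    is_outpatient=True,
    addon_time=None,
):
    return qf.VisitRecord(
        visit_id=visit_id,
        facility_id=facility_id,
        exam_code=exam_code,
        exam_category=exam_category,
        contrast_flag=contrast_flag,
        scheduled_time=ts(scheduled) if scheduled else ts(arrival),
        arrival_time=ts(arrival),
        begin_time=ts(begin),
        end_time=ts(end),
        resource_id=resource_id,
        patient_age=patient_age,
        is_outpatient=is_outpatient,
        addon_time=ts(addon_time) if addon_time else None,
    )


@pytest.fixture
def toy_log():
    """Three walk-in visits on one morning: A arrives 09:00 (begins 09:20),
    B 09:05 (09:30), C 09:15 (09:40)."""
    records = [
        make_visit("A", "2018-03-05T09:00", "2018-03-05T09:20", "2018-03-05T09:35"),
        make_visit("B", "2018-03-05T09:05", "2018-03-05T09:30", "2018-03-05T09:45"),
        make_visit("C", "2018-03-05T09:15", "2018-03-05T09:40", "2018-03-05T09:50"),
    ]
    return qf.EventLog(records, "F", "walkin")


@pytest.fixture(scope="session")
def small_sched_log():
    config = qf.facility_archetype("mri_scheduled", n_days=10, seed=3)
    log, truth = qf.generate_log(config)
    return log, truth, config


@pytest.fixture(scope="session")
def small_walkin_log():
    config = qf.facility_archetype("xray_walkin", n_days=5, seed=4)
    log, truth = qf.generate_log(config)
    return log, truth, config
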