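"""Workflow simulator: hand-checked dynamics, capacity, determinism."""

import numpy as np
import pandas as pd
import pytest

import queueflow as qf
from queueflow.errors import ConfigError, EmptyInputError
from queueflow.simulate import ExamSpec


def minimal_config(**overrides):
    params = dict(
        facility_id="T",
        facility_type="walkin",
        exam_mix={"EX": ExamSpec(1.0, 10, 0.3)},
        n_servers=1,
        n_days=1,
        seed=0,
    )
    params.update(overrides)
    return qf.FacilityConfig(**params)


class TestConfig:
    @pytest.mark.parametrize("bad", [{"n_days": 0}, {"n_servers": 0}, {"slot_minutes": 7}])
    def test_invalid_configuration_rejected(self, bad):
        with pytest.raises(ConfigError):
            minimal_config(**bad)

    def test_exam_probabilities_must_sum_to_one(self):
        with pytest.raises(ConfigError, match="sum"):
            minimal_config(exam_mix={"A": ExamSpec(0.4, 10, 0.3)})


class TestGenerateLog:
    def test_no_arrivals_yields_empty_log(self):
        log, _ = qf.generate_log(minimal_config(walkin_rate=0.0))
        assert len(log) == 0

    def test_single_scheduled_patient_starts_at_scheduled_time(self, monkeypatch):
        """One patient scheduled 09:00 arriving early must begin exactly at
        09:00: service starts at max(arrival, scheduled)."""
        config = minimal_config(
            facility_type="scheduled", booking_prob=1.0, n_servers=1,
            open_time="09:00", close_time="09:30", slot_minutes=30,
            earliness_mean=-10, earliness_sd=0,
        )
        log, _ = qf.generate_log(config)
        assert len(log) == 1
        rec = log.records[0]
        assert rec.scheduled_time.strftime("%H:%M") == "09:00"
        assert rec.arrival_time < rec.scheduled_time
        assert rec.begin_time == rec.scheduled_time
        assert qf.compute_target(rec, "scheduled") == 0

    def test_two_walkins_single_server_fifo(self):
        """Hand simulation: arrivals 09:00/09:05, services 30/10 -> the
        second begins 09:30 after a 25-minute wait."""
        from queueflow.simulate import _Patient, run_day_queue

        patients = [  # walk-ins carry arrival as scheduled time
            _Patient(0, 540, 540, None, "EX", 30, 40.0, True),
            _Patient(1, 545, 545, None, "EX", 10, 40.0, True),
        ]
        assignments = run_day_queue(patients, n_servers=1, open_minute=540)
        assert assignments[0][0] == 540  # 09:00
        assert assignments[1][0] == 570  # 09:30 -> waited 25 minutes

    def test_scheduled_queue_served_in_schedule_order_not_arrival_order(self):
        from queueflow.simulate import _Patient, run_day_queue

        # B is scheduled earlier (09:10) but arrives later than A (sched 09:30);
        # both are waiting from 09:05 on, and B must be served first.
        patients = [
            _Patient(0, 570, 541, None, "EX", 10, 40.0, True),
            _Patient(1, 550, 545, None, "EX", 10, 40.0, True),
        ]
        assignments = run_day_queue(patients, n_servers=1, open_minute=540)
        assert assignments[1][0] < assignments[0][0]

    def test_walkin_scheduled_equals_arrival(self, small_walkin_log):
        log, _, _ = small_walkin_log
        assert all(r.scheduled_time == r.arrival_time for r in log)

    def test_arrival_begin_end_ordered(self, small_sched_log):
        log, _, _ = small_sched_log
        assert all(r.arrival_time <= r.begin_time <= r.end_time for r in log)

    def test_capacity_never_exceeded(self, small_sched_log):
        log, truth, config = small_sched_log
        # busy intervals on one server never overlap
        for intervals in truth.busy_intervals.values():
            ordered = sorted(intervals)
            for (b1, e1), (b2, e2) in zip(ordered, ordered[1:]):
                assert e1 <= b2
        # at every begin instant at most n_servers exams are in progress
        for rec in log:
            t = rec.begin_time
            in_progress = sum(
                1 for r in log if r.begin_time <= t < r.end_time
            )
            assert in_progress <= config.n_servers

    def test_identical_seed_gives_byte_identical_logs(self, tmp_path):
        config = qf.facility_archetype("ct_hybrid", n_days=3, seed=42)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        qf.write_log(qf.generate_log(config)[0], a)
        config2 = qf.facility_archetype("ct_hybrid", n_days=3, seed=42)
        qf.write_log(qf.generate_log(config2)[0], b)
        assert a.read_bytes() == b.read_bytes()

    def test_ground_truth_service_matches_log(self, small_sched_log):
        log, truth, _ = small_sched_log
        for rec in log:
            dur = int((rec.end_time - rec.begin_time).total_seconds() // 60)
            assert truth.service_minutes[rec.visit_id] == dur


class TestSummarize:
    def test_single_visit_mean_wait(self, toy_log):
        one = qf.EventLog([toy_log.records[2]], "F", "walkin")
        summary = qf.summarize_log(one)
        assert summary["mean_target_minutes"] == 25.0

    def test_visits_per_day_arithmetic(self, small_walkin_log):
        log, _, config = small_walkin_log
        summary = qf.summarize_log(log)
        assert summary["visits_per_day"] == len(log) / summary["n_days"]

    def test_walkin_waits_nonnegative(self, small_walkin_log):
        log, _, _ = small_walkin_log
        assert qf.summarize_log(log)["mean_target_minutes"] >= 0

    def test_empty_log_raises(self):
        with pytest.raises(EmptyInputError):
            qf.summarize_log(qf.EventLog([], "F", "walkin"))


class TestCongestionCausality:
    def test_line_length_at_arrival_predicts_wait(self):
        """In a contended walk-in facility, the queue seen on arrival must
        correlate positively with the realized wait."""
        config = qf.facility_archetype("xray_walkin", n_days=10, seed=9)
        log, _ = qf.generate_log(config)
        matrix = qf.featurize_log(log, slot_minutes=config.slot_minutes,
                                  n_servers=config.n_servers)
        corr = np.corrcoef(matrix["LineCount0"], matrix["target"])[0, 1]
        assert corr > 0.3
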