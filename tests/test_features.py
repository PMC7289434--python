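"""Feature engine: snapshots, hand-computed toy values, duration stats,
consistency identities and a spot oracle comparison."""

import numpy as np
import pandas as pd
import pytest

import queueflow as qf
from queueflow.errors import ConfigError, EmptyInputError
from queueflow.features import DurationStats

from conftest import make_visit, ts
from oracle import oracle_features


def toy_stats():
    return DurationStats(durations={"EX": 15.0}, fallback=15.0, n_servers=1)


class TestSnapshot:
    def test_before_any_arrival_all_sets_empty(self, toy_log):
        snap = qf.snapshot_state(toy_log, ts("2018-03-05T08:00"))
        assert snap.in_line == snap.in_progress == snap.completed_today == []

    def test_toy_log_at_0915(self, toy_log):
        snap = qf.snapshot_state(toy_log, ts("2018-03-05T09:15"))
        assert sorted(snap.in_line) == ["A", "B", "C"]
        assert snap.in_progress == []

    def test_begin_boundary_moves_visit_to_in_progress(self, toy_log):
        snap = qf.snapshot_state(toy_log, ts("2018-03-05T09:20"))
        assert sorted(snap.in_line) == ["B", "C"]
        assert snap.in_progress == ["A"]

    def test_sets_pairwise_disjoint_on_simulated_log(self, small_sched_log):
        log, _, _ = small_sched_log
        for minute in (15, 145, 305):
            t = log.records[0].arrival_time.normalize() + pd.Timedelta(hours=9, minutes=minute)
            snap = qf.snapshot_state(log, t)
            line, prog = set(snap.in_line), set(snap.in_progress)
            comp = set(snap.completed_today)
            assert not (line & prog) and not (line & comp) and not (prog & comp)


class TestDurationStats:
    def test_median_of_three_observations(self):
        recs = [
            make_visit(f"V{i}", "2018-01-01T09:00", "2018-01-01T09:00",
                       f"2018-01-01T{9 + d // 60:02d}:{d % 60:02d}", exam_code="EX")
            for i, d in enumerate([10, 20, 40])
        ]
        # same arrival allowed: ids disambiguate
        log = qf.EventLog(recs, "F", "walkin")
        stats = qf.estimate_duration_stats(log, reference_days=7)
        assert qf.expected_duration("EX", stats) == 20

    def test_single_observation(self):
        rec = make_visit("V", "2018-01-01T09:00", "2018-01-01T09:00", "2018-01-01T09:35")
        stats = qf.estimate_duration_stats(qf.EventLog([rec], "F", "walkin"), 7)
        assert qf.expected_duration("EX", stats) == 35

    def test_unseen_code_falls_back_to_facility_median(self):
        stats = DurationStats(durations={"EX": 20.0}, fallback=30.0)
        assert qf.expected_duration("NEW", stats) == 30

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ConfigError):
            DurationStats(durations={"EX": -5.0}, fallback=10.0)

    def test_empty_reference_period_rejected(self):
        rec = make_visit("V", "2018-06-01T09:00", "2018-06-01T09:00", "2018-06-01T09:35")
        log = qf.EventLog([rec], "F", "walkin")
        with pytest.raises(ConfigError, match="reference"):
            qf.estimate_duration_stats(log, reference_days=0)


class TestComputeFeatures:
    def test_first_visit_of_day_empty_state_defaults(self, toy_log):
        row = qf.compute_features(toy_log, "A", stats=toy_stats())
        assert row["LineCount0"] == 0
        assert row["NoneInLine"] == 1
        assert row["NoneInProgress"] == 1
        assert row["NoneCompleted"] == 1
        assert row["IsFirst"] == 1
        for k in range(1, 6):
            assert row[f"MostRecent{k}"] == 0

    def test_toy_log_index_c_hand_computation(self, toy_log):
        row = qf.compute_features(toy_log, "C", stats=toy_stats())
        assert row["LineCount0"] == 2  # A and B still waiting at 09:15
        assert row["SumWaits"] == 15 + 10
        assert row["InProgressSize"] == 0
        assert row["NumCustomersLast30"] == 2

    def test_row_has_84_named_features(self, toy_log):
        row = qf.compute_features(toy_log, "C", stats=toy_stats())
        assert len(row) == 84
        assert list(row.index) == qf.build_catalog().names
        assert np.isfinite(row.to_numpy()).all()

    def test_unknown_visit_raises(self, toy_log):
        with pytest.raises(KeyError):
            qf.compute_features(toy_log, "nope", stats=toy_stats())

    def test_matches_brute_force_oracle_on_toy_log(self, toy_log):
        stats = toy_stats()
        for rec in toy_log:
            engine_row = qf.compute_features(toy_log, rec.visit_id, stats=stats)
            oracle_row = oracle_features(
                toy_log.records, "walkin", rec, stats, slot_minutes=30, n_servers=1
            )
            for name, value in oracle_row.items():
                assert engine_row[name] == pytest.approx(value), name


class TestFeaturizeLog:
    def test_three_visits_give_three_rows(self, toy_log):
        matrix = qf.featurize_log(toy_log, stats=toy_stats())
        assert matrix.shape[0] == 3
        assert len([c for c in matrix.columns if c not in ("visit_id", "prediction_time", "target")]) == 84

    def test_walkin_targets_nonnegative(self, small_walkin_log):
        log, _, config = small_walkin_log
        matrix = qf.featurize_log(log, slot_minutes=config.slot_minutes)
        assert (matrix["target"] >= 0).all()

    def test_empty_log_raises(self):
        with pytest.raises(EmptyInputError):
            qf.featurize_log(qf.EventLog([], "F", "walkin"))

    def test_consistency_identities_on_simulated_log(self, small_sched_log):
        log, _, config = small_sched_log
        m = qf.featurize_log(log, slot_minutes=config.slot_minutes,
                             n_servers=config.n_servers)
        assert ((m["NoneInLine"] == 1) == (m["LineCount0"] == 0)).all()
        np.testing.assert_allclose(
            m["AvgHowEarlyWaiting"] * m["LineCount0"], m["SumHowEarlyWaiting"]
        )
        body_regions = (
            m["MSKCount"] + m["CardiacCount"] + m["VascularCount"]
            + m["AbdominalCount"] + m["NeuroCount"] + m["PediatricCount"]
            + m["ThoracicCount"]
        )
        assert (body_regions <= m["LineCount0"]).all()

    def test_walkin_proxy_degeneracy(self, small_walkin_log):
        """Under arrival-as-scheduled, nobody's slot is in the future and
        in-line delay equals in-line wait."""
        log, _, config = small_walkin_log
        m = qf.featurize_log(log, slot_minutes=config.slot_minutes)
        assert (m["LineCount0Strict"] == 0).all()
        np.testing.assert_allclose(m["SumDelayWaitingInLine"], m["SumWaits"])

    def test_truncating_future_events_leaves_rows_unchanged(self, small_sched_log):
        """Anti-leakage: shifting every event that happens after a row's
        prediction time (keeping the schedule) must not change that row."""
        log, _, config = small_sched_log
        stats = qf.estimate_duration_stats(log, reference_days=4)
        m = qf.featurize_log(log, stats=stats, slot_minutes=config.slot_minutes,
                             n_servers=config.n_servers)
        feature_names = qf.build_catalog().names
        rng = np.random.default_rng(0)
        for pos in rng.choice(len(m), size=4, replace=False):
            row = m.iloc[int(pos)]
            t = row["prediction_time"]
            shifted = []
            for rec in log:
                changes = {}
                if rec.arrival_time > t:
                    changes = dict(
                        arrival_time=rec.arrival_time + pd.Timedelta(days=400),
                        begin_time=rec.begin_time + pd.Timedelta(days=400),
                        end_time=rec.end_time + pd.Timedelta(days=400),
                    )
                elif rec.begin_time > t:
                    changes = dict(
                        begin_time=rec.begin_time + pd.Timedelta(days=400),
                        end_time=rec.end_time + pd.Timedelta(days=400),
                    )
                elif rec.end_time > t:
                    changes = dict(end_time=rec.end_time + pd.Timedelta(days=400))
                from dataclasses import replace

                shifted.append(replace(rec, **changes) if changes else rec)
            shifted_log = qf.EventLog(shifted, log.facility_id, log.facility_type)
            new_row = qf.compute_features(
                shifted_log, row["visit_id"], stats=stats,
                slot_minutes=config.slot_minutes, n_servers=config.n_servers,
            )
            for name in feature_names:
                assert new_row[name] == pytest.approx(row[name]), name
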