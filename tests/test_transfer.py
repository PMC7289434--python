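"""Feature-set algebra, walk-in applicability, and transfer ratios."""

import numpy as np
import pytest

import queueflow as qf
from queueflow.errors import ConfigError, EmptyInputError
from queueflow.synthetic import planted_linear_matrix
from queueflow.transfer import reference_feature_set


@pytest.fixture(scope="module")
def catalog():
    return qf.build_catalog()


class TestSetAlgebra:
    def test_union_idempotent(self):
        a = qf.FeatureSet("a", ["x", "y"])
        assert qf.union_sets([a, a]).features == ("x", "y")

    def test_union_ordered_by_first_appearance(self):
        a = qf.FeatureSet("a", ["x", "y"])
        b = qf.FeatureSet("b", ["y", "z"])
        assert qf.union_sets([a, b]).features == ("x", "y", "z")

    def test_intersection_of_disjoint_sets_empty(self):
        a = qf.FeatureSet("a", ["x"])
        b = qf.FeatureSet("b", ["y"])
        assert len(qf.intersect_sets(a, b)) == 0

    def test_self_intersection_identity(self):
        a = qf.FeatureSet("a", ["x", "y"])
        assert set(qf.intersect_sets(a, a).features) == {"x", "y"}

    def test_duplicates_dropped_preserving_order(self):
        assert qf.FeatureSet("s", ["b", "a", "b"]).features == ("b", "a")


class TestReferenceSets:
    def test_shipped_unions_have_published_sizes(self):
        assert len(reference_feature_set("lr_union_scheduled")) == 17
        assert len(reference_feature_set("rf_union_scheduled")) == 14
        assert len(reference_feature_set("lr_top10_walkin")) == 10
        assert len(reference_feature_set("rf_top10_walkin")) == 10

    def test_lr_rf_unions_share_exactly_eight_features(self, catalog):
        lr = reference_feature_set("lr_union_scheduled")
        rf = reference_feature_set("rf_union_scheduled")
        common = qf.intersect_sets(lr, rf, catalog)
        assert set(common.features) == {
            "LineCount0Strict",
            "AheadCount",
            "StartTime4",
            "NumCompletedToday",
            "DelayedInLine",
            "SumWaits",
            "SumDelayInProgress",
            "BeforeSlot",
        }

    def test_unresolved_names_reported_not_dropped(self, catalog):
        rf = reference_feature_set("rf_union_scheduled")
        assert rf.unresolved(catalog) == ["AvgWaitLastK3Customers"]


class TestApplicableSubset:
    def test_scheduled_facility_is_noop(self, catalog):
        fs = qf.FeatureSet("s", ["DelayedInLine", "BeforeSlot"])
        assert qf.applicable_subset(fs, "scheduled", catalog) is fs

    def test_empty_set_stays_empty(self, catalog):
        fs = qf.FeatureSet("s", [])
        assert len(qf.applicable_subset(fs, "walkin", catalog)) == 0

    def test_rf_union_proxy_policy_keeps_12(self, catalog):
        rf = reference_feature_set("rf_union_scheduled")
        kept = qf.applicable_subset(rf, "walkin", catalog, policy="proxy")
        assert len(kept) == 12
        assert "DelayedInLine" not in kept.features
        assert "DelayCount" not in kept.features

    def test_lr_union_strict_policy_keeps_8(self, catalog):
        lr = reference_feature_set("lr_union_scheduled")
        kept = qf.applicable_subset(lr, "walkin", catalog, policy="strict")
        assert len(kept) == 8

    def test_unknown_policy_raises(self, catalog):
        with pytest.raises(ConfigError):
            qf.applicable_subset(qf.FeatureSet("s", ["x"]), "walkin", catalog, policy="bad")


def _splits_for(matrix, n, seed=0):
    return qf.make_splits(matrix, n, seed=seed, train_months=2, test_days=7)


@pytest.fixture(scope="module")
def ratio_matrix():
    return planted_linear_matrix(n_rows=4000, n_features=8, noise_sd=0.5, seed=13)


class TestTransferRatio:
    @pytest.fixture
    def matrix(self, ratio_matrix):
        return ratio_matrix

    def test_identical_sets_give_ratio_exactly_one(self, matrix):
        fs = qf.FeatureSet("own", ["f1", "f2"])
        result = qf.transfer_ratio(matrix, fs, fs, splits=_splits_for(matrix, 3))
        assert result.ratio == 1.0

    def test_noise_set_transfers_worse_than_signal_set(self, matrix):
        optimal = qf.FeatureSet("signal", ["f1"])
        noise = qf.FeatureSet("noise", ["f5", "f6"])
        result = qf.transfer_ratio(matrix, noise, optimal, splits=_splits_for(matrix, 5))
        assert result.ratio > 1.0

    def test_empty_filtered_set_raises(self, matrix):
        with pytest.raises(ConfigError):
            qf.transfer_ratio(
                matrix, qf.FeatureSet("e", []), qf.FeatureSet("o", ["f1"]),
                splits=_splits_for(matrix, 2),
            )

    def test_no_splits_raises(self, matrix):
        with pytest.raises(EmptyInputError):
            qf.transfer_ratio(
                matrix, qf.FeatureSet("a", ["f1"]), qf.FeatureSet("b", ["f2"]),
            )

    def test_ci_brackets_mean(self, matrix):
        optimal = qf.FeatureSet("signal", ["f1"])
        noise = qf.FeatureSet("noise", ["f5"])
        result = qf.transfer_ratio(matrix, noise, optimal, splits=_splits_for(matrix, 8))
        assert result.ci_low <= result.ratio <= result.ci_high


@pytest.fixture(scope="module")
def cross_matrix():
    return planted_linear_matrix(n_rows=4000, n_features=6, noise_sd=0.5, seed=17)


class TestCrossModelTransfer:
    @pytest.fixture
    def matrix(self, cross_matrix):
        return cross_matrix

    def test_output_has_four_cells(self, matrix):
        table = qf.cross_model_transfer(
            matrix,
            qf.FeatureSet("lr", ["f1", "f2"]),
            qf.FeatureSet("rf", ["f1", "f3"]),
            splits=_splits_for(matrix, 2),
            rf_params=qf.RFHyperparams(2, 8, 30),
        )
        assert table.shape == (2, 2)
        assert not table.isna().any().any()

    def test_identical_sets_give_equal_columns(self, matrix):
        fs1 = qf.FeatureSet("lr", ["f1", "f2"])
        fs2 = qf.FeatureSet("rf", ["f1", "f2"])
        table = qf.cross_model_transfer(
            matrix, fs1, fs2, splits=_splits_for(matrix, 2),
            rf_params=qf.RFHyperparams(2, 8, 30),
        )
        np.testing.assert_allclose(table["lr"], table["rf"])
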