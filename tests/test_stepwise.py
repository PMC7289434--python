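"""Forward-stepwise selection protocol: splits, paths, error curves,
frequencies, and an independent cross-validation oracle for step 1."""

import numpy as np
import pandas as pd
import pytest

import queueflow as qf
from queueflow.errors import ConfigError, DegenerateInputError, EmptyInputError
from queueflow.synthetic import planted_linear_matrix, time_split


@pytest.fixture(scope="module")
def planted():
    return planted_linear_matrix(n_rows=400, n_features=10, seed=5)


class TestMakeSplits:
    def _matrix(self, n_days):
        times = pd.Timestamp("2018-01-01") + pd.to_timedelta(
            np.arange(n_days) * 1440 + 600, unit="m"
        )
        return pd.DataFrame(
            {"visit_id": [f"V{i}" for i in range(n_days)],
             "prediction_time": times, "f1": 0.0, "target": 0.0}
        )

    def test_single_split_has_adjacent_test_window(self):
        splits = qf.make_splits(self._matrix(370), 1, seed=0)
        (s,) = splits
        assert s.train_end == s.train_start + pd.DateOffset(months=6)
        assert s.test_end == s.train_end + pd.Timedelta(days=14)

    def test_short_span_raises_naming_requirement(self):
        with pytest.raises(ConfigError, match="6 months"):
            qf.make_splits(self._matrix(150), 1, seed=0)

    def test_deterministic_given_seed(self):
        m = self._matrix(370)
        assert qf.make_splits(m, 100, seed=7) == qf.make_splits(m, 100, seed=7)


class TestForwardStepwise:
    def test_single_candidate_is_forced_choice(self, planted):
        train, test = time_split(planted)
        path = qf.forward_stepwise(train, test, features=["f3"], n_max=5)
        assert path.features == ["f3"]

    def test_path_has_exactly_n_max_steps_no_repeats(self, planted):
        train, test = time_split(planted)
        path = qf.forward_stepwise(train, test, n_max=8, folds=10, seed=1)
        assert len(path.features) == 8
        assert len(set(path.features)) == 8

    def test_planted_driver_selected_first(self, planted):
        train, test = time_split(planted)
        path = qf.forward_stepwise(train, test, n_max=3, seed=2)
        assert path.features[0] == "f1"

    def test_train_mse_nonincreasing_along_path(self, planted):
        train, test = time_split(planted)
        path = qf.forward_stepwise(train, test, n_max=10, seed=3)
        diffs = np.diff(path.train_mse)
        assert (diffs <= 1e-9).all()

    def test_constant_target_raises(self, planted):
        train, test = time_split(planted)
        train = train.assign(target=5.0)
        with pytest.raises(DegenerateInputError, match="constant"):
            qf.forward_stepwise(train, test)

    def test_first_step_matches_exhaustive_sklearn_scan(self, planted):
        """Independent oracle: for every single-feature OLS model, compute
        10-fold CV-MSE with scikit-learn on the same fold assignment; the
        stepwise engine must pick the argmin."""
        from sklearn.linear_model import LinearRegression

        train, test = time_split(planted)
        seed = 11
        path = qf.forward_stepwise(train, test, n_max=1, folds=10, seed=seed)

        rng = np.random.default_rng(seed)
        fold_id = rng.permutation(len(train)) % 10
        y = train["target"].to_numpy()
        scores = {}
        for feat in [f"f{j}" for j in range(1, 11)]:
            X = train[[feat]].to_numpy()
            err = 0.0
            for f in range(10):
                tr, te = fold_id != f, fold_id == f
                model = LinearRegression().fit(X[tr], y[tr])
                resid = model.predict(X[te]) - y[te]
                err += float(resid @ resid)
            scores[feat] = err / len(train)
        best = min(scores, key=scores.get)
        assert path.features[0] == best
        assert path.cv_mse[0] == pytest.approx(scores[best], rel=1e-6)


class TestTestingPercentageError:
    def test_intercept_only_is_exactly_100(self, planted):
        train, test = time_split(planted)
        path = qf.forward_stepwise(train, test, n_max=2, seed=0)
        tpe = qf.testing_percentage_error(path)
        assert tpe[0] == 100.0

    def test_exact_model_reaches_zero(self):
        m = planted_linear_matrix(n_rows=200, n_features=3, noise_sd=0.0, seed=1)
        train, test = time_split(m)
        path = qf.forward_stepwise(train, test, n_max=1, seed=0)
        tpe = qf.testing_percentage_error(path)
        assert tpe[1] == pytest.approx(0.0, abs=1e-9)

    def test_planted_signal_beats_intercept(self, planted):
        train, test = time_split(planted)
        path = qf.forward_stepwise(train, test, n_max=1, seed=0)
        assert qf.testing_percentage_error(path)[1] < 100.0


class TestSelectionFrequency:
    def _path(self, names):
        return qf.StepwisePath(
            features=list(names), cv_mse=[0.0] * len(names),
            train_mse=[0.0] * (len(names) + 1), test_mse=[1.0] * (len(names) + 1),
            n_train=10, n_test=5, train_mean=0.0,
        )

    def test_single_path_gives_100_percent(self):
        summary = qf.selection_frequency([self._path(["a", "b"])])
        assert summary.frequency_percent("a") == 100.0

    def test_counting_across_replicates(self):
        paths = [self._path(["a"])] * 73 + [self._path(["b"])] * 27
        summary = qf.selection_frequency(paths)
        assert summary.frequency_percent("a") == 73.0
        assert summary.counts["b"] == 27

    def test_top_k_tie_broken_by_earlier_mean_step(self):
        paths = [self._path(["a", "b"]), self._path(["b", "a"]), self._path(["c", "a", "b"])]
        summary = qf.selection_frequency(paths)
        # a and b both appear 3 times; a's mean step is earlier
        assert summary.top(1) == ["a"]

    def test_empty_input_raises(self):
        with pytest.raises(EmptyInputError):
            qf.selection_frequency([])

    def test_planted_driver_ranked_first_across_replicates(self):
        paths = []
        for r in range(10):
            m = planted_linear_matrix(n_rows=300, n_features=8, seed=100 + r)
            train, test = time_split(m)
            paths.append(qf.forward_stepwise(train, test, n_max=3, seed=r))
        summary = qf.selection_frequency(paths)
        assert summary.frequency_percent("f1") == 100.0
        assert summary.top(1) == ["f1"]


class TestEvaluateFeatureSet:
    def test_perfect_linear_target_gives_zero_mae(self):
        m = planted_linear_matrix(n_rows=200, n_features=3, noise_sd=0.0, seed=2)
        train, test = time_split(m)
        assert qf.evaluate_feature_set(["f1"], train, test) == pytest.approx(0.0, abs=1e-9)

    def test_intercept_only_hand_arithmetic(self):
        train = pd.DataFrame({"f1": [0.0, 0.0], "target": [5.0, 5.0]})
        test = pd.DataFrame({"f1": [0.0, 0.0], "target": [0.0, 10.0]})
        assert qf.evaluate_feature_set([], train, test) == 5.0

    def test_unknown_feature_raises(self, planted):
        train, test = time_split(planted)
        with pytest.raises(KeyError):
            qf.evaluate_feature_set(["nope"], train, test)
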