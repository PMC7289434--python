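"""Repeated forward-stepwise linear-regression feature selection.

Protocol, per replicate: draw a random consecutive six-month training
window and the immediately following two weeks as the test window; starting
from the intercept-only model, repeatedly add the candidate feature whose
augmented ordinary-least-squares model has the lowest 10-fold
cross-validated MSE on the training window, for exactly ``n_max`` steps.
Across replicates, the number of times each feature enters a path is its
selection frequency; the most frequently selected features form the
reduced (top-k) set.

The *testing percentage error* of the size-N model on a split is
``100 × testMSE(N) / testMSE(intercept-only)``; the intercept-only model
predicts the training-set mean target, so its own value is exactly 100%.

Implementation notes: candidate CV scores are evaluated from per-fold Gram
matrices of the (train-standardized) design, which makes the candidate scan
O(k³) per candidate instead of O(n·k²); singular subsets fall back to the
minimum-norm least-squares (pseudoinverse) solution; exact score ties are
broken in catalog (column) order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DegenerateInputError, EmptyInputError

__all__ = [
    "SplitSpec",
    "StepwisePath",
    "SelectionSummary",
    "make_splits",
    "split_frames",
    "forward_stepwise",
    "testing_percentage_error",
    "selection_frequency",
    "evaluate_feature_set",
    "feature_columns",
]

META_COLUMNS = ("visit_id", "prediction_time", "target")


def feature_columns(matrix: pd.DataFrame) -> list[str]:
    """All non-metadata columns of a feature matrix, in column order."""
    return [c for c in matrix.columns if c not in META_COLUMNS]


@dataclass(frozen=True)
class SplitSpec:
    """One replicate's train/test windows: a consecutive training interval
    and the immediately following test interval."""

    replicate: int
    train_start: pd.Timestamp
    train_end: pd.Timestamp  # exclusive; == test start
    test_end: pd.Timestamp  # exclusive
    seed: int


def make_splits(
    matrix: pd.DataFrame,
    n_replicates: int,
    seed: int = 0,
    train_months: int = 6,
    test_days: int = 14,
) -> list[SplitSpec]:
    """Draw ``n_replicates`` train/test windows with the training start
    uniform over admissible days (overlap between replicates is allowed).
    Deterministic given ``seed``."""
    times = pd.DatetimeIndex(matrix["prediction_time"])
    span_start = times.min().normalize()
    span_end = times.max()
    last_start = (span_end - pd.Timedelta(days=test_days)) - pd.DateOffset(
        months=train_months
    )
    n_days = (last_start.normalize() - span_start).days + 1
    if n_days < 1:
        raise ConfigError(
            f"log span {span_start.date()}..{span_end.date()} is shorter than the "
            f"required {train_months} months training + {test_days} days testing"
        )
    rng = np.random.default_rng(seed)
    offsets = rng.integers(0, n_days, size=n_replicates)
    rep_seeds = rng.integers(0, 2**31 - 1, size=n_replicates)
    splits = []
    for r, (off, s) in enumerate(zip(offsets, rep_seeds)):
        start = span_start + pd.Timedelta(days=int(off))
        train_end = start + pd.DateOffset(months=train_months)
        splits.append(
            SplitSpec(
                replicate=r,
                train_start=start,
                train_end=train_end,
                test_end=train_end + pd.Timedelta(days=test_days),
                seed=int(s),
            )
        )
    return splits


def split_frames(
    matrix: pd.DataFrame, spec: SplitSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    times = pd.DatetimeIndex(matrix["prediction_time"])
    train = matrix[(times >= spec.train_start) & (times < spec.train_end)]
    test = matrix[(times >= spec.train_end) & (times < spec.test_end)]
    return train, test


@dataclass
class StepwisePath:
    """One replicate's ordered selection and its error curves.

    ``test_mse[k]`` / ``train_mse[k]`` are for the model of size k
    (index 0 = intercept-only); ``cv_mse[k-1]`` is the winning candidate's
    cross-validated MSE at step k.
    """

    features: list[str]
    cv_mse: list[float]
    train_mse: list[float]
    test_mse: list[float]
    n_train: int
    n_test: int
    train_mean: float


class _GramCV:
    """Per-fold Gram matrices of a standardized design for fast OLS CV."""

    def __init__(self, X: np.ndarray, y: np.ndarray, folds: int, rng: np.random.Generator):
        n, p = X.shape
        self.mean = X.mean(axis=0)
        std = X.std(axis=0)
        std[std == 0] = 1.0
        self.std = std
        Z = np.empty((n, p + 1))
        Z[:, 0] = 1.0
        Z[:, 1:] = (X - self.mean) / std
        self.Z, self.y, self.n = Z, y, n
        fold_id = rng.permutation(n) % folds
        self.G = []  # per fold: (G_f, b_f, syy_f, n_f)
        for fidx in range(folds):
            mask = fold_id == fidx
            Zf, yf = Z[mask], y[mask]
            self.G.append((Zf.T @ Zf, Zf.T @ yf, float(yf @ yf), int(mask.sum())))
        self.G_tot = Z.T @ Z
        self.b_tot = Z.T @ y

    @staticmethod
    def _solve(G: np.ndarray, b: np.ndarray) -> np.ndarray:
        try:
            coef = np.linalg.solve(G, b)
            if not np.all(np.isfinite(coef)):
                raise np.linalg.LinAlgError
            return coef
        except np.linalg.LinAlgError:
            return np.linalg.pinv(G, hermitian=True) @ b

    def cv_mse(self, cols: Sequence[int]) -> float:
        idx = np.asarray(cols)
        ix = np.ix_(idx, idx)
        total = 0.0
        for G_f, b_f, syy_f, n_f in self.G:
            if n_f == 0:
                continue
            coef = self._solve(self.G_tot[ix] - G_f[ix], self.b_tot[idx] - b_f[idx])
            total += syy_f - 2.0 * coef @ b_f[idx] + coef @ G_f[ix] @ coef
        return max(total, 0.0) / self.n

    def fit_full(self, cols: Sequence[int]) -> np.ndarray:
        idx = np.asarray(cols)
        return self._solve(self.G_tot[np.ix_(idx, idx)], self.b_tot[idx])

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = np.empty((X.shape[0], X.shape[1] + 1))
        Z[:, 0] = 1.0
        Z[:, 1:] = (X - self.mean) / self.std
        return Z


def forward_stepwise(
    train: pd.DataFrame,
    test: pd.DataFrame,
    features: Optional[list[str]] = None,
    n_max: int = 20,
    folds: int = 10,
    seed: int = 0,
) -> StepwisePath:
    """Forward stepwise OLS selection on one train/test split.

    At each of exactly ``n_max`` steps the remaining candidate with the
    lowest ``folds``-fold CV-MSE on the training window is appended. Test
    MSE is recorded for every model size including the intercept-only model.
    """
    features = features if features is not None else feature_columns(train)
    if len(train) < folds:
        raise DegenerateInputError(
            f"need at least {folds} training rows, got {len(train)}"
        )
    y = train["target"].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateInputError("training target is constant")
    X = train[features].to_numpy(dtype=float)
    X_test = test[features].to_numpy(dtype=float)
    y_test = test["target"].to_numpy(dtype=float)
    n_max = min(n_max, len(features))

    rng = np.random.default_rng(seed)
    gram = _GramCV(X, y, folds, rng)
    Z_test = gram.transform(X_test)

    selected: list[int] = []  # design column indices (feature j -> j+1)
    path = StepwisePath(
        features=[],
        cv_mse=[],
        train_mse=[],
        test_mse=[],
        n_train=len(train),
        n_test=len(test),
        train_mean=float(y.mean()),
    )

    def record(cols: list[int]) -> None:
        coef = gram.fit_full(cols)
        resid_train = gram.Z[:, cols] @ coef - y
        path.train_mse.append(float(resid_train @ resid_train / len(y)))
        if len(y_test):
            resid = Z_test[:, cols] @ coef - y_test
            path.test_mse.append(float(resid @ resid / len(y_test)))
        else:
            path.test_mse.append(float("nan"))

    record([0])  # intercept-only
    remaining = list(range(1, len(features) + 1))
    for _ in range(n_max):
        best_col, best_score = None, np.inf
        for col in remaining:  # catalog order => first wins exact ties
            score = gram.cv_mse([0] + selected + [col])
            if score < best_score:
                best_col, best_score = col, score
        selected.append(best_col)
        remaining.remove(best_col)
        path.features.append(features[best_col - 1])
        path.cv_mse.append(best_score)
        record([0] + selected)
    return path


def testing_percentage_error(path: StepwisePath) -> np.ndarray:
    """Testing Percentage Error curve of a fitted path: entry N is
    ``100 × testMSE(N) / testMSE(intercept-only)``; entry 0 is exactly 100."""
    base = path.test_mse[0]
    if base == 0:
        raise DegenerateInputError("intercept-only test MSE is zero")
    return (np.asarray(path.test_mse) / base) * 100.0


@dataclass
class SelectionSummary:
    """Cross-replicate selection counts and the derived top-k feature list."""

    counts: dict[str, int]
    mean_step: dict[str, float]
    n_replicates: int

    def frequency_percent(self, name: str) -> float:
        return 100.0 * self.counts.get(name, 0) / self.n_replicates

    def ranked(self) -> list[str]:
        return sorted(
            self.counts,
            key=lambda f: (-self.counts[f], self.mean_step[f], f),
        )

    def top(self, k: int = 10) -> list[str]:
        return self.ranked()[:k]

    def to_frame(self) -> pd.DataFrame:
        names = self.ranked()
        return pd.DataFrame(
            {
                "feature": names,
                "count": [self.counts[f] for f in names],
                "frequency_percent": [self.frequency_percent(f) for f in names],
                "mean_step": [self.mean_step[f] for f in names],
            }
        )


def selection_frequency(paths: Sequence[StepwisePath], k: int = 10) -> SelectionSummary:
    """Count how often each feature appears across replicate paths. Top-k
    ties are broken by mean selection step (earlier is better), then name."""
    if not paths:
        raise EmptyInputError("no stepwise paths given")
    counts: dict[str, int] = {}
    steps: dict[str, list[int]] = {}
    for path in paths:
        for step, name in enumerate(path.features):
            counts[name] = counts.get(name, 0) + 1
            steps.setdefault(name, []).append(step)
    mean_step = {f: float(np.mean(s)) for f, s in steps.items()}
    return SelectionSummary(counts=counts, mean_step=mean_step, n_replicates=len(paths))


def evaluate_feature_set(
    features: Sequence[str],
    train: pd.DataFrame,
    test: pd.DataFrame,
    model: str = "linear",
    seed: int = 0,
    rf_params=None,
) -> float:
    """Fit a model with the given features on the training window and return
    its mean absolute error (minutes) on the test window. An empty feature
    list fits the intercept-only model (train-mean prediction)."""
    unknown = [f for f in features if f not in train.columns]
    if unknown:
        raise KeyError(f"unknown feature name(s): {unknown}")
    y_train = train["target"].to_numpy(dtype=float)
    y_test = test["target"].to_numpy(dtype=float)
    if not list(features):
        pred = np.full(len(y_test), y_train.mean())
        return float(np.abs(pred - y_test).mean())
    X_train = train[list(features)].to_numpy(dtype=float)
    X_test = test[list(features)].to_numpy(dtype=float)
    if model == "linear":
        mean = X_train.mean(axis=0)
        std = X_train.std(axis=0)
        std[std == 0] = 1.0
        Z = np.column_stack([np.ones(len(X_train)), (X_train - mean) / std])
        coef, *_ = np.linalg.lstsq(Z, y_train, rcond=None)
        Zt = np.column_stack([np.ones(len(X_test)), (X_test - mean) / std])
        pred = Zt @ coef
    elif model == "forest":
        from sklearn.ensemble import RandomForestRegressor

        params = dict(n_estimators=200, max_features=max(1, len(features) // 3))
        if rf_params is not None:
            params = {
                "n_estimators": rf_params.n_estimators,
                "max_features": min(rf_params.max_features, len(features)),
                "max_depth": rf_params.max_depth,
            }
        forest = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        forest.fit(X_train, y_train)
        pred = forest.predict(X_test)
    else:
        raise ConfigError(f"unknown model {model!r}; use 'linear' or 'forest'")
    return float(np.abs(pred - y_test).mean())
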