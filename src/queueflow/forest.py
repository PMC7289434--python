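"""Random-forest feature selection by cumulative permutation importance.

Per facility, forest hyperparameters (variables per split, maximum tree
depth, trees per forest) are tuned once by 10-fold cross-validated MSE over
a small grid and reused across replicates. For each replicate train/test
pair a forest is fitted and each feature is scored by *out-of-bag
permutation importance*: for every tree, the MSE on its out-of-bag rows is
compared with the MSE after permuting the feature's column among those
rows, and the increases are averaged over trees (the classic MSE-driven
importance of bagged ensembles). Permutation importance is preferred to
impurity importance, which is biased toward high-cardinality features.
Negative scores are kept as-is — they delimit the noise floor.

Features are ranked by importance summed across replicates (cumulative
importance) and the top-k form the reduced set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .errors import ConfigError, DegenerateInputError, EmptyInputError
from .stepwise import feature_columns

__all__ = [
    "RFHyperparams",
    "ImportanceTable",
    "default_grid",
    "tune_rf",
    "rf_importance",
    "cumulative_ranking",
]


@dataclass(frozen=True)
class RFHyperparams:
    max_features: int  # variables considered per split
    max_depth: Optional[int]  # None = unlimited
    n_estimators: int

    def validate(self, n_features: int) -> None:
        if not 1 <= self.max_features <= n_features:
            raise ConfigError(
                f"max_features={self.max_features} outside [1, {n_features}]"
            )
        if self.n_estimators < 1:
            raise ConfigError("n_estimators must be positive")
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigError("max_depth must be positive or None")


def default_grid(n_features: int, n_estimators: Sequence[int] = (200, 500)) -> list[RFHyperparams]:
    """Default tuning grid: variables/split in {p/3, sqrt(p), p/2}, depth in
    {8, 16, unlimited}, trees in ``n_estimators``."""
    mtry = sorted(
        {
            max(1, n_features // 3),
            max(1, int(np.sqrt(n_features))),
            max(1, n_features // 2),
        }
    )
    return [
        RFHyperparams(m, d, t)
        for m in mtry
        for d in (8, 16, None)
        for t in n_estimators
    ]


def _forest(params: RFHyperparams, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=params.n_estimators,
        max_features=params.max_features,
        max_depth=params.max_depth,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )


def tune_rf(
    train: pd.DataFrame,
    grid: Sequence[RFHyperparams],
    features: Optional[list[str]] = None,
    folds: int = 10,
    seed: int = 0,
) -> RFHyperparams:
    """Grid point with the lowest mean ``folds``-fold CV-MSE on the training
    window; exact ties go to the earlier grid point. Deterministic given seed."""
    if not grid:
        raise ConfigError("hyperparameter grid is empty")
    features = features if features is not None else feature_columns(train)
    X = train[features].to_numpy(dtype=float)
    y = train["target"].to_numpy(dtype=float)
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    best, best_mse = None, np.inf
    for params in grid:
        params.validate(len(features))
        total, count = 0.0, 0
        for tr, te in kf.split(X):
            model = _forest(params, seed).fit(X[tr], y[tr])
            resid = model.predict(X[te]) - y[te]
            total += float(resid @ resid)
            count += len(te)
        mse = total / count
        if mse < best_mse:
            best, best_mse = params, mse
    return best


def rf_importance(
    train: pd.DataFrame,
    params: RFHyperparams,
    features: Optional[list[str]] = None,
    seed: int = 0,
) -> pd.Series:
    """Out-of-bag permutation importance of every feature under one fitted
    forest: mean over trees of (OOB MSE after permuting the feature − OOB
    MSE), in squared minutes. All candidate features are scored."""
    features = features if features is not None else feature_columns(train)
    if len(train) < 2:
        raise DegenerateInputError("need at least 2 rows to fit a forest")
    X = train[features].to_numpy(dtype=float)
    y = train["target"].to_numpy(dtype=float)
    n = len(y)
    forest = _forest(params, seed).fit(X, y)
    rng = np.random.default_rng(seed)
    increases = np.zeros((len(forest.estimators_), len(features)))
    used = np.zeros(len(forest.estimators_), dtype=bool)
    for ti, (tree, samples) in enumerate(
        zip(forest.estimators_, forest.estimators_samples_)
    ):
        oob = np.setdiff1d(np.arange(n), samples)
        if len(oob) == 0:
            continue
        used[ti] = True
        X_oob, y_oob = X[oob], y[oob]
        base_resid = tree.predict(X_oob) - y_oob
        base_mse = float(base_resid @ base_resid) / len(oob)
        X_perm = X_oob.copy()
        for j in range(len(features)):
            perm = rng.permutation(len(oob))
            X_perm[:, j] = X_oob[perm, j]
            resid = tree.predict(X_perm) - y_oob
            increases[ti, j] = float(resid @ resid) / len(oob) - base_mse
            X_perm[:, j] = X_oob[:, j]
    if not used.any():
        raise DegenerateInputError("no out-of-bag samples; cannot score features")
    return pd.Series(increases[used].mean(axis=0), index=features, name="importance")


@dataclass
class ImportanceTable:
    """Per-replicate importances, their cumulative sum, and the ranking."""

    per_replicate: pd.DataFrame  # replicates x features
    cumulative: pd.Series  # summed over replicates
    ranking: list[str]  # all features, best first

    def top(self, k: int = 10) -> list[str]:
        return self.ranking[:k]


def cumulative_ranking(
    tables: Sequence[pd.Series], k: int = 10
) -> ImportanceTable:
    """Rank features by importance summed across replicate forests. All
    replicates must score the same feature set; exact ties keep feature
    (catalog) order."""
    if not tables:
        raise EmptyInputError("no importance tables given")
    first = list(tables[0].index)
    for t in tables[1:]:
        if list(t.index) != first:
            raise ConfigError("replicates scored different feature sets")
    per_rep = pd.DataFrame([t.to_numpy() for t in tables], columns=first)
    cumulative = per_rep.sum(axis=0)
    order = np.argsort(-cumulative.to_numpy(), kind="stable")
    ranking = [first[i] for i in order]
    return ImportanceTable(per_replicate=per_rep, cumulative=cumulative, ranking=ranking)
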