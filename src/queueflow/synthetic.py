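"""Planted-signal benchmark matrices for validating the selection protocols.

These generators build feature matrices whose true predictive structure is
known by construction, so that a selection procedure's output can be graded
exactly: a linear driver planted among independent noise columns must be
found first by forward stepwise selection, and a deep interaction must make
depth-limited forests lose to deeper ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["planted_linear_matrix", "planted_interaction_matrix", "time_split"]


def _wrap(X: np.ndarray, y: np.ndarray, seed: int) -> pd.DataFrame:
    n, p = X.shape
    df = pd.DataFrame(X, columns=[f"f{j + 1}" for j in range(p)])
    df.insert(0, "visit_id", [f"S{seed}-{i:05d}" for i in range(n)])
    # ~40 synthetic rows/day so the matrix spans enough calendar for splits
    times = pd.Timestamp("2018-01-01") + pd.to_timedelta(
        (np.arange(n) // 40) * 1440 + 480 + (np.arange(n) % 40) * 12, unit="m"
    )
    df.insert(1, "prediction_time", times)
    df["target"] = y
    return df


def planted_linear_matrix(
    n_rows: int = 500,
    n_features: int = 10,
    coef: float = 2.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Target = ``coef``·f1 + Normal(0, noise_sd); f2..fp are independent
    standard-normal noise. f1 is the unique true driver."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_rows, n_features))
    y = coef * X[:, 0] + rng.normal(0.0, noise_sd, size=n_rows)
    return _wrap(X, y, seed)


def planted_interaction_matrix(
    n_rows: int = 1200, n_features: int = 6, noise_sd: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Target = f1·f2 + noise: a pure pairwise interaction with no marginal
    main effects, unlearnable by depth-1 trees (a stump can split on only
    one variable) but well captured by deeper trees."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_rows, n_features))
    y = X[:, 0] * X[:, 1] + rng.normal(0.0, noise_sd, size=n_rows)
    return _wrap(X, y, seed)


def time_split(matrix: pd.DataFrame, train_fraction: float = 0.8):
    """Chronological train/test split (the matrix is already time-ordered)."""
    cut = int(len(matrix) * train_fraction)
    return matrix.iloc[:cut], matrix.iloc[cut:]
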