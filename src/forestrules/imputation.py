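"""Column-wise missing-value handling for feature tables.

Random forests (and the rule sets extracted from them) need complete
feature matrices, but clinical tables routinely have gaps.  Missing cells
are replaced per column with the mean, the median, or the most frequent
observed value, so incomplete samples need not be discarded.

The transformer is split into fit/apply so that cross-validation can fit
fill values on the training fold only and apply them to the test fold —
no information leaks from test to train.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.impute import SimpleImputer

__all__ = ["Imputer", "impute", "STRATEGIES", "MISSING_MARKERS"]

STRATEGIES = ("mean", "median", "most_frequent")

#: cell values treated as missing when reading delimited text
MISSING_MARKERS = ("", "NA", "NaN")


class Imputer:
    """Per-column fill-value imputer with train/apply separation.

    ``most_frequent`` ties break toward the smallest value, so results are
    deterministic.  Fitting a column with no observed value is an error —
    there is nothing to learn a fill value from.
    """

    def __init__(self, strategy: str = "mean"):
        if strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
        self.strategy = strategy
        self._imputer: SimpleImputer | None = None
        self._columns: list | None = None

    def fit(self, features) -> "Imputer":
        X, columns = _as_matrix(features)
        all_missing = np.isnan(X).all(axis=0)
        if all_missing.any():
            bad = [str(columns[i]) for i in np.flatnonzero(all_missing)]
            raise ValueError(f"column(s) {bad} have no observed values; cannot impute")
        self._imputer = SimpleImputer(strategy=self.strategy, keep_empty_features=False)
        self._imputer.fit(X)
        self._columns = list(columns)
        return self

    def transform(self, features):
        if self._imputer is None:
            raise RuntimeError("imputer is not fitted")
        X, columns = _as_matrix(features)
        out = self._imputer.transform(X)
        if isinstance(features, pd.DataFrame):
            return pd.DataFrame(out, columns=features.columns, index=features.index)
        return out

    def fit_transform(self, features):
        return self.fit(features).transform(features)

    @property
    def fill_values(self) -> np.ndarray:
        if self._imputer is None:
            raise RuntimeError("imputer is not fitted")
        return self._imputer.statistics_


def _as_matrix(features) -> tuple[np.ndarray, Sequence]:
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.columns)
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"expected a 2-D feature matrix, got shape {X.shape}")
    return X, list(range(X.shape[1]))


def impute(features, strategy: str = "mean"):
    """Fill every missing cell from its own column's observed values.

    Observed cells are untouched, so the operation is idempotent and the
    mean strategy preserves each column's observed mean exactly.
    """
    return Imputer(strategy).fit_transform(features)
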