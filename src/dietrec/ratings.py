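"""Quintile rating construction: intake amounts -> 1-5 preference ratings.

Collaborative filtering needs a rating matrix. Here the "rating" a
participant gives a food group is the quintile of their intake amount
among *consumers* of that group: the lowest-consuming fifth gets 1, the
highest fifth gets 5. Zero intake is not a low rating — it is a missing
cell, the candidate set for recommendation.

The transformer is scikit-learn style: quintile boundaries are learned on
``fit`` (typically the training partition) and frozen, so test users are
rated on the training distribution without leakage; out-of-range test
intakes clamp to ratings 1 and 5.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .catalog import FoodGroupCatalog

__all__ = [
    "QuintileRatingTransformer",
    "quintile_ratings",
    "read_ratings_long",
    "write_ratings_long",
]


class QuintileRatingTransformer(TransformerMixin, BaseEstimator):
    """Per-item consumer-quintile discretization of intake to ratings 1-5.

    For each item independently, ``fit`` records the positive intake
    values of the fitting sample (the item's consumers). ``transform``
    assigns a positive intake ``x`` the mid-rank it would hold among those
    consumers, converts it to a quantile position ``p = (rank - 0.5) / n``
    and bins at 0.2/0.4/0.6/0.8 into ratings 1..5. Zero intake maps to a
    missing cell (NaN).

    This rank-based rule makes ratings deterministic and exchangeable:
    tied intakes always share a rating (ties take the average rank), a
    lone consumer sits at the distribution's midpoint and gets rating 3,
    and with ``n`` distinct consumers each rating class receives
    ``floor(n/5)`` or ``ceil(n/5)`` of them. Intakes outside the fitted
    range clamp to ratings 1 / 5.

    Attributes
    ----------
    feature_names_in_ : ndarray of str
        Item (column) names seen during fit.
    consumer_values_ : dict[str, ndarray]
        Sorted positive intake values per item from the fitting sample.
    n_consumers_ : dict[str, int]
        Number of consumers per item in the fitting sample.
    """

    def fit(self, X: pd.DataFrame, y=None) -> "QuintileRatingTransformer":
        X = self._as_frame(X)
        if len(X) == 0:
            raise ValueError("cannot fit quintile ratings on an empty table")
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.n_features_in_ = X.shape[1]
        self.consumer_values_ = {}
        self.n_consumers_ = {}
        for col in X.columns:
            v = X[col].to_numpy(dtype=float)
            pos = np.sort(v[v > 0])
            self.consumer_values_[col] = pos
            self.n_consumers_[col] = int(pos.size)
            if pos.size == 0:
                warnings.warn(
                    f"item '{col}' has no consumers; its ratings will be all-missing",
                    UserWarning,
                    stacklevel=2,
                )
            elif np.unique(pos).size < 5:
                warnings.warn(
                    f"item '{col}' has fewer than 5 distinct positive intakes; "
                    "quintile ratings degenerate to the tie rule",
                    UserWarning,
                    stacklevel=2,
                )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "consumer_values_")
        X = self._as_frame(X)
        missing = [c for c in self.feature_names_in_ if c not in X.columns]
        if missing:
            raise ValueError(f"columns seen in fit are absent from transform input: {missing}")
        out = pd.DataFrame(
            np.nan, index=X.index, columns=list(self.feature_names_in_), dtype=float
        )
        for col in self.feature_names_in_:
            x = X[col].to_numpy(dtype=float)
            if np.any(x < 0) or not np.all(np.isfinite(x)):
                raise ValueError(f"intake for item '{col}' must be finite and >= 0")
            ref = self.consumer_values_[col]
            n = ref.size
            pos = x > 0
            if n == 0 or not pos.any():
                continue
            # mid-rank of each value among the fitted consumer values
            lt = np.searchsorted(ref, x[pos], side="left")
            le = np.searchsorted(ref, x[pos], side="right")
            midrank = lt + (le - lt + 1) / 2.0
            p = (midrank - 0.5) / n
            ratings = np.floor(5.0 * p).astype(int) + 1
            out.loc[pos, col] = np.clip(ratings, 1, 5)
        return out

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        arr = np.asarray(X, dtype=float)
        if arr.ndim != 2:
            raise ValueError("expected a 2-d table of intake values")
        return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


def quintile_ratings(table: pd.DataFrame, catalog: FoodGroupCatalog) -> pd.DataFrame:
    """Build a rating matrix from an intake table in one shot.

    Fits and applies :class:`QuintileRatingTransformer` on the catalog's
    group columns of ``table``. Returns a users x items DataFrame with
    ratings in {1..5} and NaN exactly where intake was zero.
    """
    cols = [g for g in catalog.groups if g in table.columns]
    missing = [g for g in catalog.groups if g not in table.columns]
    if missing:
        raise ValueError(f"intake table missing catalog groups: {missing}")
    return QuintileRatingTransformer().fit_transform(table[cols])


def write_ratings_long(ratings: pd.DataFrame, path) -> None:
    """Serialize observed cells of a rating matrix to long CSV (user,item,rating)."""
    long = ratings.stack().rename("rating").reset_index()
    long.columns = ["user", "item", "rating"]
    long.to_csv(path, index=False)


def read_ratings_long(path, users=None, items=None) -> pd.DataFrame:
    """Read a long-format rating CSV back into a users x items matrix.

    ``users`` / ``items`` fix the axis order (and reintroduce all-missing
    rows/columns); by default order of first appearance is used.
    """
    long = pd.read_csv(path)
    expected = {"user", "item", "rating"}
    if not expected.issubset(long.columns):
        raise ValueError(f"rating CSV must have columns {sorted(expected)}")
    mat = long.pivot(index="user", columns="item", values="rating")
    if users is None:
        users = pd.unique(long["user"])
    if items is None:
        items = pd.unique(long["item"])
    mat = mat.reindex(index=users, columns=items)
    mat.index.name = None
    mat.columns.name = None
    return mat
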