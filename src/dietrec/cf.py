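"""User-based and item-based k-NN collaborative filtering.

Both predictors estimate the rating a participant would give a food group
they do not consume, from the Pearson-similarity structure of the rating
matrix:

* **UBCF** — find the k most similar users who rated the item and combine
  their ratings after removing each user's own rating-scale bias:
  ``r_hat(u,i) = mean(u) + sum_v sim(u,v) * (r(v,i) - mean(v)) / sum_v |sim(u,v)|``.
* **IBCF** — find the k most similar items the user has rated and take
  the similarity-weighted average of the user's own ratings:
  ``r_hat(u,i) = sum_j sim(i,j) * r(u,j) / sum_j |sim(i,j)|``.

Predictions are clamped to the rating scale [1, 5]. A cell with no usable
neighbor (no defined — or, by default, no positive — similarity to any
rater, or an all-zero weight sum) is flagged *unpredictable* rather than
silently filled. Prediction is fully deterministic: ties in similarity
break toward the lower index.

The estimators follow the scikit-learn protocol (``fit`` stores the
rating matrix and its similarity structure; ``predict`` fills missing
cells of the fitted matrix or of new user rows).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .similarity import SimilarityMatrix, pearson_cross, pearson_similarity

__all__ = [
    "PredictedRatings",
    "NeighborhoodConfig",
    "UserBasedCF",
    "ItemBasedCF",
    "predict_ubcf",
    "predict_ibcf",
]

RATING_MIN, RATING_MAX = 1.0, 5.0

OBSERVED, PREDICTED, UNPREDICTABLE = "observed", "predicted", "unpredictable"


@dataclass(frozen=True)
class NeighborhoodConfig:
    """k-NN neighborhood settings for one CF method."""

    method: str = "UBCF"  # "UBCF" | "IBCF"
    k_neighbors: int = 25
    min_overlap: int = 3
    positive_only: bool = True

    def __post_init__(self) -> None:
        if self.method.upper() not in ("UBCF", "IBCF"):
            raise ValueError(f"method must be UBCF or IBCF, got {self.method!r}")
        object.__setattr__(self, "method", self.method.upper())
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.min_overlap < 2:
            raise ValueError("min_overlap must be >= 2")


@dataclass(frozen=True)
class PredictedRatings:
    """Dense rating estimates with per-cell provenance.

    ``ratings`` carries observed cells unchanged, model estimates for
    originally-missing cells, and NaN where no estimate was possible;
    ``provenance`` labels each cell observed / predicted / unpredictable.
    """

    ratings: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def users(self) -> pd.Index:
        return self.ratings.index

    @property
    def items(self) -> pd.Index:
        return self.ratings.columns

    def mask(self, label: str) -> pd.DataFrame:
        return self.provenance == label

    def to_long(self) -> pd.DataFrame:
        """Long-format export: user, item, predicted_rating, provenance."""
        r = self.ratings.stack(dropna=False).rename("predicted_rating")
        p = self.provenance.stack(dropna=False).rename("provenance")
        out = pd.concat([r, p], axis=1).reset_index()
        out.columns = ["user", "item", "predicted_rating", "provenance"]
        return out


def _order_by_similarity(sims: np.ndarray) -> np.ndarray:
    """Indices of defined similarities, best first; ties -> lower index."""
    idx = np.flatnonzero(np.isfinite(sims))
    if idx.size == 0:
        return idx
    order = np.lexsort((idx, -sims[idx]))
    return idx[order]


def _ubcf_fill(
    Xt: np.ndarray,
    Xs: np.ndarray,
    S: np.ndarray,
    k: int,
    positive_only: bool,
    exclude_diag: bool,
) -> np.ndarray:
    """UBCF estimates for every cell of Xt using neighbors from Xs.

    Xt: (nt, m) ratings of target users; Xs: (ns, m) neighbor pool;
    S: (nt, ns) target-to-pool similarities. Returns a dense (nt, m)
    array of raw (unclamped) estimates, NaN where unpredictable.
    """
    nt, m = Xt.shape
    obs_s = np.isfinite(Xs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # rows with no ratings
        mu_t = np.nanmean(Xt, axis=1)
        mu_s = np.nanmean(np.where(obs_s, Xs, np.nan), axis=1)
    C0 = np.where(obs_s, Xs - mu_s[:, None], 0.0)

    out = np.full((nt, m), np.nan)
    for u in range(nt):
        if not np.isfinite(mu_t[u]):
            continue  # user rated nothing: no baseline, all cells unpredictable
        s = S[u].copy()
        if exclude_diag:
            s[u] = np.nan
        if positive_only:
            s[s <= 0] = np.nan
        ranked = _order_by_similarity(s)
        if ranked.size == 0:
            continue
        w = s[ranked]
        M = obs_s[ranked]  # (n_cand, m)
        within_k = np.cumsum(M, axis=0) <= k
        sel = M & within_k
        den = np.abs(w) @ sel
        num = np.einsum("c,cm->m", w, np.where(sel, C0[ranked], 0.0))
        with np.errstate(invalid="ignore", divide="ignore"):
            est = mu_t[u] + num / den
        est[den <= 0] = np.nan
        out[u] = est
    return out


def _ibcf_fill(Xt: np.ndarray, S_items: np.ndarray, k: int, positive_only: bool) -> np.ndarray:
    """IBCF estimates for every cell of Xt from the user's own rated items."""
    nt, m = Xt.shape
    obs = np.isfinite(Xt)
    X0 = np.where(obs, Xt, 0.0)
    out = np.full((nt, m), np.nan)
    for i in range(m):
        s = S_items[i].copy()
        s[i] = np.nan
        if positive_only:
            s[s <= 0] = np.nan
        ranked = _order_by_similarity(s)
        if ranked.size == 0:
            continue
        w = s[ranked]
        M = obs[:, ranked]  # (nt, n_cand)
        within_k = np.cumsum(M, axis=1) <= k
        sel = M & within_k
        den = sel @ np.abs(w)
        num = np.where(sel, X0[:, ranked], 0.0) @ w
        with np.errstate(invalid="ignore", divide="ignore"):
            est = num / den
        est[den <= 0] = np.nan
        out[:, i] = est
    return out


def _assemble(R: pd.DataFrame, raw: np.ndarray) -> PredictedRatings:
    """Clamp raw estimates, pass observed cells through, flag the rest."""
    X = R.to_numpy(dtype=float)
    obs = np.isfinite(X)
    est = np.clip(raw, RATING_MIN, RATING_MAX)
    values = np.where(obs, X, est)
    prov = np.where(obs, OBSERVED, np.where(np.isfinite(est), PREDICTED, UNPREDICTABLE))
    if (~obs).all(axis=1).any():
        empty = R.index[(~obs).all(axis=1)].tolist()
        warnings.warn(
            f"users with no observed ratings are fully unpredictable: {empty[:5]}",
            UserWarning,
            stacklevel=3,
        )
    return PredictedRatings(
        ratings=pd.DataFrame(values, index=R.index, columns=R.columns),
        provenance=pd.DataFrame(prov, index=R.index, columns=R.columns),
    )


class _BaseCF(BaseEstimator):
    _axis: str  # similarity axis computed at fit time

    def __init__(self, k_neighbors: int = 25, min_overlap: int = 3, positive_only: bool = True):
        self.k_neighbors = k_neighbors
        self.min_overlap = min_overlap
        self.positive_only = positive_only

    def fit(self, X: pd.DataFrame, y=None):
        """Store the rating matrix and compute its similarity structure.

        ``X`` is a users x items DataFrame with NaN marking missing
        (non-consumed, recommendation-candidate) cells.
        """
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        vals = X.to_numpy(dtype=float)
        obs = np.isfinite(vals)
        if not ((vals[obs] >= RATING_MIN) & (vals[obs] <= RATING_MAX)).all():
            raise ValueError("observed ratings must lie in [1, 5]")
        self.ratings_ = X.copy()
        self.similarity_ = pearson_similarity(X, axis=self._axis, min_overlap=self.min_overlap)
        self.n_users_, self.n_items_ = X.shape
        return self

    def predict(self, X: pd.DataFrame | None = None) -> PredictedRatings:
        """Fill missing cells of the fitted matrix, or of new user rows ``X``."""
        check_is_fitted(self, "ratings_")
        if X is None:
            return self._predict_fitted()
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float), columns=self.ratings_.columns)
        if list(X.columns) != list(self.ratings_.columns):
            raise ValueError("new users must be rated on the fitted item columns")
        return self._predict_new(X)


class UserBasedCF(_BaseCF):
    """User-based k-NN collaborative filtering with mean-centering.

    Neighbors are the ``k_neighbors`` most Pearson-similar users who rated
    the target item; aggregation removes each neighbor's mean rating so
    that users who rate systematically high or low are comparable.
    """

    _axis = "user"

    def _predict_fitted(self) -> PredictedRatings:
        R = self.ratings_
        X = R.to_numpy(dtype=float)
        raw = _ubcf_fill(X, X, self.similarity_.sim.to_numpy(), self.k_neighbors,
                         self.positive_only, exclude_diag=True)
        return _assemble(R, raw)

    def _predict_new(self, X: pd.DataFrame) -> PredictedRatings:
        S, _ = pearson_cross(X, self.ratings_, min_overlap=self.min_overlap)
        raw = _ubcf_fill(X.to_numpy(dtype=float), self.ratings_.to_numpy(dtype=float),
                         S.to_numpy(), self.k_neighbors, self.positive_only,
                         exclude_diag=False)
        return _assemble(X, raw)


class ItemBasedCF(_BaseCF):
    """Item-based k-NN collaborative filtering.

    A missing rating is the similarity-weighted average of the user's own
    ratings on the ``k_neighbors`` most similar items (no centering: all
    ratings come from the same user, so there is no scale bias to remove).
    """

    _axis = "item"

    def __init__(self, k_neighbors: int = 30, min_overlap: int = 3, positive_only: bool = True):
        super().__init__(k_neighbors=k_neighbors, min_overlap=min_overlap,
                         positive_only=positive_only)

    def _predict_fitted(self) -> PredictedRatings:
        R = self.ratings_
        raw = _ibcf_fill(R.to_numpy(dtype=float), self.similarity_.sim.to_numpy(),
                         self.k_neighbors, self.positive_only)
        return _assemble(R, raw)

    def _predict_new(self, X: pd.DataFrame) -> PredictedRatings:
        # item similarities come from the fitted base; the user's own
        # rated items supply the ratings, so new rows need no refit
        raw = _ibcf_fill(X.to_numpy(dtype=float), self.similarity_.sim.to_numpy(),
                         self.k_neighbors, self.positive_only)
        return _assemble(X, raw)


def predict_ubcf(
    R: pd.DataFrame,
    S: SimilarityMatrix,
    k_neighbors: int = 25,
    positive_only: bool = True,
) -> PredictedRatings:
    """Functional UBCF: fill missing cells of ``R`` given a user-axis similarity."""
    if S.axis != "user":
        raise ValueError("predict_ubcf requires a user-axis SimilarityMatrix")
    if not S.labels.equals(R.index):
        raise ValueError("similarity matrix users differ from rating matrix users")
    raw = _ubcf_fill(R.to_numpy(dtype=float), R.to_numpy(dtype=float),
                     S.sim.to_numpy(), k_neighbors, positive_only, exclude_diag=True)
    return _assemble(R, raw)


def predict_ibcf(
    R: pd.DataFrame,
    S: SimilarityMatrix,
    k_neighbors: int = 30,
    positive_only: bool = True,
) -> PredictedRatings:
    """Functional IBCF: fill missing cells of ``R`` given an item-axis similarity."""
    if S.axis != "item":
        raise ValueError("predict_ibcf requires an item-axis SimilarityMatrix")
    if not S.labels.equals(R.columns):
        raise ValueError("similarity matrix items differ from rating matrix items")
    raw = _ibcf_fill(R.to_numpy(dtype=float), S.sim.to_numpy(), k_neighbors, positive_only)
    return _assemble(R, raw)
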