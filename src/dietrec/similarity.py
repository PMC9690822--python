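"""Pairwise Pearson similarity over co-observed rating cells.

Similarity between two users (or two items) is the Pearson correlation of
their ratings restricted to the cells both have observed. A pair is
*undefined* (NaN) when the co-observation overlap is below ``min_overlap``
or when either side is constant on the overlap — correlating fewer than a
handful of points, or a flat vector, carries no signal.

Everything is vectorized through masked sum matrices; no installed
library computes pairwise Pearson with per-pair overlap bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SimilarityMatrix", "pearson_similarity", "pearson_cross"]

# Variance-term zero cutoff. The term n*sum(x^2) - sum(x)^2 is integral for
# integer ratings and >= n-1 whenever the overlap is non-constant, so a
# small absolute threshold separates true zeros from matmul round-off.
_VAR_TOL = 1e-6


@dataclass(frozen=True)
class SimilarityMatrix:
    """Symmetric pairwise similarities with co-observation counts.

    ``sim`` holds Pearson coefficients in [-1, 1] with NaN for undefined
    pairs; ``overlap`` the number of co-observed cells per pair. ``axis``
    records whether rows/columns index users or items.
    """

    axis: str
    sim: pd.DataFrame
    overlap: pd.DataFrame
    min_overlap: int

    @property
    def labels(self) -> pd.Index:
        return self.sim.index


def _masked_pearson_sums(A: np.ndarray, B: np.ndarray, min_overlap: int):
    """Pearson between every row of A and every row of B over shared cells."""
    Ma = np.isfinite(A).astype(float)
    Mb = np.isfinite(B).astype(float)
    A0 = np.nan_to_num(A)
    B0 = np.nan_to_num(B)

    n = Ma @ Mb.T
    Sx = A0 @ Mb.T
    Sy = Ma @ B0.T
    Sxx = (A0 * A0) @ Mb.T
    Syy = Ma @ (B0 * B0).T
    Sxy = A0 @ B0.T

    cov = n * Sxy - Sx * Sy
    varx = n * Sxx - Sx * Sx
    vary = n * Syy - Sy * Sy
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = cov / np.sqrt(varx * vary)
    undefined = (n < min_overlap) | (varx <= _VAR_TOL) | (vary <= _VAR_TOL)
    sim[undefined] = np.nan
    np.clip(sim, -1.0, 1.0, out=sim)
    return sim, n.astype(int)


def pearson_similarity(
    R: pd.DataFrame, axis: str = "user", min_overlap: int = 3
) -> SimilarityMatrix:
    """Pairwise Pearson similarity between users or between items.

    Parameters
    ----------
    R
        Rating matrix, users x items, NaN for missing cells.
    axis
        ``"user"`` for user-user similarity (rows), ``"item"`` for
        item-item similarity (columns).
    min_overlap
        Minimum number of co-observed cells for a pair to be defined.

    The diagonal is fixed at 1 for every entity with at least one
    observed rating (an entity is maximally similar to itself even when
    its ratings are constant), NaN for entities with none.
    """
    if axis not in ("user", "item"):
        raise ValueError(f"axis must be 'user' or 'item', got {axis!r}")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    M = R if axis == "user" else R.T
    if M.shape[0] < 2:
        raise ValueError(f"need at least 2 {axis}s to compute pairwise similarity")
    X = M.to_numpy(dtype=float)
    sim, overlap = _masked_pearson_sums(X, X, min_overlap)
    has_rating = np.isfinite(X).any(axis=1)
    diag = np.where(has_rating, 1.0, np.nan)
    np.fill_diagonal(sim, diag)
    labels = M.index
    return SimilarityMatrix(
        axis=axis,
        sim=pd.DataFrame(sim, index=labels, columns=labels),
        overlap=pd.DataFrame(overlap, index=labels, columns=labels),
        min_overlap=int(min_overlap),
    )


def pearson_cross(
    A: pd.DataFrame, B: pd.DataFrame, min_overlap: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson similarity between rows of ``A`` and rows of ``B``.

    Both matrices must share the same item columns. Used to relate new
    users to a fitted user base without refitting.
    """
    if not A.columns.equals(B.columns):
        raise ValueError("rating matrices must share identical item columns")
    sim, overlap = _masked_pearson_sums(
        A.to_numpy(dtype=float), B.to_numpy(dtype=float), min_overlap
    )
    return (
        pd.DataFrame(sim, index=A.index, columns=B.index),
        pd.DataFrame(overlap, index=A.index, columns=B.index),
    )
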