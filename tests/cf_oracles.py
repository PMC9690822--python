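"""Naive loop-based reference implementations used as test oracles.

These deliberately mirror the k-NN aggregation definitions one candidate
at a time, independently of the vectorized code paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def naive_user_means(X: np.ndarray) -> np.ndarray:
    return np.array([
        np.nanmean(row) if np.isfinite(row).any() else np.nan for row in X
    ])


def naive_ubcf(R: pd.DataFrame, S: np.ndarray, k: int, positive_only: bool = True) -> np.ndarray:
    """Mean-centered weighted UBCF, one (user, item) cell at a time."""
    X = R.to_numpy(dtype=float)
    n, m = X.shape
    mu = naive_user_means(X)
    out = np.full((n, m), np.nan)
    for u in range(n):
        if not np.isfinite(mu[u]):
            continue
        for i in range(m):
            cands = []
            for v in range(n):
                if v == u or not np.isfinite(S[u, v]):
                    continue
                if positive_only and S[u, v] <= 0:
                    continue
                if not np.isfinite(X[v, i]):
                    continue
                cands.append((-S[u, v], v))
            cands.sort()
            sel = cands[:k]
            if not sel:
                continue
            den = sum(abs(-negs) for negs, _ in sel)
            if den <= 0:
                continue
            num = sum((-negs) * (X[v, i] - mu[v]) for negs, v in sel)
            out[u, i] = np.clip(mu[u] + num / den, 1.0, 5.0)
    return out


def naive_ibcf(R: pd.DataFrame, S_items: np.ndarray, k: int, positive_only: bool = True) -> np.ndarray:
    """Uncentered weighted-average IBCF, one cell at a time."""
    X = R.to_numpy(dtype=float)
    n, m = X.shape
    out = np.full((n, m), np.nan)
    for u in range(n):
        for i in range(m):
            cands = []
            for j in range(m):
                if j == i or not np.isfinite(S_items[i, j]):
                    continue
                if positive_only and S_items[i, j] <= 0:
                    continue
                if not np.isfinite(X[u, j]):
                    continue
                cands.append((-S_items[i, j], j))
            cands.sort()
            sel = cands[:k]
            if not sel:
                continue
            den = sum(abs(-negs) for negs, _ in sel)
            if den <= 0:
                continue
            num = sum((-negs) * X[u, j] for negs, j in sel)
            out[u, i] = np.clip(num / den, 1.0, 5.0)
    return out


def random_rating_matrix(rng: np.random.Generator, n: int, m: int,
                         p_missing: float = 0.35) -> pd.DataFrame:
    X = rng.integers(1, 6, size=(n, m)).astype(float)
    X[rng.random((n, m)) < p_missing] = np.nan
    return pd.DataFrame(X, index=[f"u{i}" for i in range(n)],
                        columns=[f"g{j}" for j in range(m)])
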