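"""Health-constrained top-N recommendation lists.

Candidates for a user are the food groups they do not currently consume
and for which the model produced a rating estimate. In recommendation
mode the list is restricted to the catalog's guideline-aligned eligible
groups — the groups a user would rate highest are not necessarily the
healthiest, so an unconstrained recommender would happily push soft
drinks. Evaluation mode can switch the constraint off to score the full
candidate universe.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .catalog import FoodGroupCatalog
from .cf import PREDICTED, PredictedRatings

__all__ = ["RecommendationList", "top_n_recommend", "recommendations_to_frame"]

#: Production cap on list length: short lists favor adherence.
DEFAULT_N_MAX = 5


@dataclass(frozen=True)
class RecommendationList:
    """Ordered top-N list for one user: highest predicted rating first."""

    user: object
    entries: tuple[tuple[str, float], ...]
    n_max: int

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def items(self) -> tuple[str, ...]:
        return tuple(item for item, _ in self.entries)

    def truncate(self, n: int) -> "RecommendationList":
        """Prefix of length <= n (top-1 ⊂ top-3 ⊂ top-5 nesting)."""
        return RecommendationList(self.user, self.entries[:n], n)


def top_n_recommend(
    pred: PredictedRatings,
    catalog: FoodGroupCatalog,
    n_max: int = DEFAULT_N_MAX,
    eligible_only: bool = True,
) -> dict:
    """Build per-user top-N recommendation lists from predicted ratings.

    Parameters
    ----------
    pred
        Model output; only cells with provenance ``predicted`` (i.e.
        originally missing and successfully estimated) are candidates.
    catalog
        Supplies the eligibility constraint and the deterministic
        tie-break order for equal predicted ratings.
    n_max
        Maximum list length.
    eligible_only
        Restrict candidates to ``catalog.eligible``.

    Returns an ordered ``{user: RecommendationList}`` mapping; users with
    no candidates get an empty list.
    """
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    eligible = set(catalog.eligible)
    candidate_mask = pred.mask(PREDICTED)
    out: dict = {}
    for user in pred.users:
        row_mask = candidate_mask.loc[user]
        scores = pred.ratings.loc[user]
        cands = [
            (item, float(scores[item]))
            for item in pred.items
            if row_mask[item] and (not eligible_only or item in eligible)
        ]
        cands.sort(key=lambda e: (-e[1], catalog.rank(e[0])))
        out[user] = RecommendationList(user, tuple(cands[:n_max]), n_max)
    return out


def recommendations_to_frame(recs: dict) -> pd.DataFrame:
    """Flatten recommendation lists to ``user,rank,item,predicted_rating``."""
    rows = [
        (rl.user, rank, item, score)
        for rl in recs.values()
        for rank, (item, score) in enumerate(rl.entries, start=1)
    ]
    return pd.DataFrame(rows, columns=["user", "rank", "item", "predicted_rating"])
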