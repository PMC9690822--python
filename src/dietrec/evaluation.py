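"""Withheld-item evaluation of the recommenders.

Protocol: participants are split at random into a training set (70%) and
a test set (30%). Each test user keeps exactly ``given`` observed ratings
visible; the remainder are withheld. Models are fitted on the training
users together with the visible test ratings, then asked to estimate the
withheld cells. Two views of performance follow:

* **rating errors** — RMSE / MSE / MAE between estimates and withheld
  true ratings;
* **top-N retrieval** — recommendation lists of increasing length are
  scored against the withheld items: a recommended item the user in fact
  consumes is a true positive. Per-user mean TP/FP/FN/TN counts and the
  derived precision / recall / TPR / FPR form one confusion row per list
  size; the rows traced across list sizes are the ROC and
  precision-recall curves.

The candidate universe of a test user is every item except their
``given`` visible ones (21 - 10 = 11 items under the defaults), so
TP+FP+FN+TN = 11 in every row — the arithmetic signature of top-N
evaluation over a fixed candidate pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error

from .catalog import FoodGroupCatalog
from .cf import (
    OBSERVED,
    ItemBasedCF,
    NeighborhoodConfig,
    PredictedRatings,
    UserBasedCF,
)
from .recommend import RecommendationList, top_n_recommend

__all__ = [
    "EvaluationScheme",
    "SplitResult",
    "ErrorMetrics",
    "TopNConfusion",
    "split_scheme",
    "rating_error_metrics",
    "topn_confusion",
    "confusion_from_counts",
    "random_ranking_base_rate",
    "evaluate_sweep",
    "plot_curves",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EvaluationScheme:
    """Parameters of the given-x withheld-item protocol.

    train_fraction : share of users assigned to training (default 0.70).
    given : observed ratings kept visible per test user (default 10).
    good_rating : relevance threshold on withheld ratings; the default 1
        counts any consumed item as relevant.
    seed : random-state initializer for the user split and withholding.
    list_sizes : recommendation-list lengths to sweep.
    """

    train_fraction: float = 0.70
    given: int = 10
    good_rating: float = 1.0
    seed: int = 0
    list_sizes: tuple[int, ...] = (1, 3, 5, 10)

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")
        if self.given < 1:
            raise ValueError("given must be >= 1")
        sizes = tuple(int(n) for n in self.list_sizes)
        if not sizes or any(n < 1 for n in sizes) or list(sizes) != sorted(sizes):
            raise ValueError("list_sizes must be positive and sorted ascending")
        object.__setattr__(self, "list_sizes", sizes)

    def to_dict(self) -> dict:
        return {
            "train_fraction": self.train_fraction,
            "given": self.given,
            "good_rating": self.good_rating,
            "seed": self.seed,
            "list_sizes": list(self.list_sizes),
        }


class SplitResult(NamedTuple):
    train: pd.DataFrame
    test_given: pd.DataFrame
    test_withheld: pd.DataFrame


def split_scheme(
    R: pd.DataFrame,
    scheme: EvaluationScheme,
    train_users: Sequence | None = None,
) -> SplitResult:
    """Split a rating matrix into train / test-given / test-withheld parts.

    Users are split at random by ``scheme.train_fraction`` (or by an
    explicit ``train_users`` list, e.g. when quintile boundaries were
    already learned on a predetermined training partition). For each test
    user, exactly ``scheme.given`` observed cells chosen uniformly at
    random stay visible; the rest are withheld. Test users with too few
    observed ratings (<= given) are dropped with a warning. The three
    parts are disjoint and partition the observed cells of the retained
    users.
    """
    rng = np.random.default_rng(scheme.seed)
    users = R.index
    if train_users is None:
        n_train = int(round(scheme.train_fraction * len(users)))
        perm = rng.permutation(len(users))
        train_idx = np.sort(perm[:n_train])
        train_users = users[train_idx]
    else:
        train_users = pd.Index(train_users)
        unknown = train_users.difference(users)
        if not unknown.empty:
            raise ValueError(f"train_users not in rating matrix: {list(unknown)[:5]}")
    test_users = users.difference(pd.Index(train_users), sort=False)

    obs_counts = R.loc[test_users].notna().sum(axis=1)
    too_few = obs_counts[obs_counts <= scheme.given].index
    if len(too_few) > 0:
        warnings.warn(
            f"dropping {len(too_few)} test users with <= given={scheme.given} "
            "observed ratings",
            UserWarning,
            stacklevel=2,
        )
        test_users = test_users.difference(too_few, sort=False)

    train = R.loc[train_users]
    given = pd.DataFrame(np.nan, index=test_users, columns=R.columns)
    withheld = pd.DataFrame(np.nan, index=test_users, columns=R.columns)
    for user in test_users:
        row = R.loc[user]
        observed = row.index[row.notna()].to_numpy()
        keep = rng.choice(observed, size=scheme.given, replace=False)
        keep_set = set(keep)
        hold = [c for c in observed if c not in keep_set]
        given.loc[user, list(keep)] = row[list(keep)]
        withheld.loc[user, hold] = row[hold]
    return SplitResult(train, given, withheld)


@dataclass(frozen=True)
class ErrorMetrics:
    """Rating-prediction errors over (estimate, withheld truth) pairs."""

    rmse: float
    mse: float
    mae: float
    n_pairs: int
    n_unpredictable: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "mse": self.mse,
            "mae": self.mae,
            "n_pairs": self.n_pairs,
            "n_unpredictable": self.n_unpredictable,
        }


def rating_error_metrics(P: PredictedRatings, truth: pd.DataFrame) -> ErrorMetrics:
    """RMSE / MSE / MAE of predictions against withheld true ratings.

    Truth cells must have been hidden from the model (provenance
    ``predicted`` or ``unpredictable``, never ``observed``).
    Unpredictable cells are excluded from the averages; their count is
    reported so abstention stays visible.
    """
    truth_aligned = truth.reindex(index=P.users, columns=P.items)
    truth_mask = truth_aligned.notna().to_numpy()
    prov = P.provenance.to_numpy()
    if (truth_mask & (prov == OBSERVED)).any():
        raise ValueError("withheld truth cells overlap observed model input")
    pred = P.ratings.to_numpy(dtype=float)
    usable = truth_mask & np.isfinite(pred)
    n_unpred = int((truth_mask & ~np.isfinite(pred)).sum())
    if not usable.any():
        raise ValueError("no evaluable (prediction, truth) pairs")
    y_true = truth_aligned.to_numpy(dtype=float)[usable]
    y_pred = pred[usable]
    mse = float(mean_squared_error(y_true, y_pred))
    return ErrorMetrics(
        rmse=float(np.sqrt(mse)),
        mse=mse,
        mae=float(mean_absolute_error(y_true, y_pred)),
        n_pairs=int(usable.sum()),
        n_unpredictable=n_unpred,
    )


@dataclass(frozen=True)
class TopNConfusion:
    """Per-user mean confusion counts and derived rates for one list size."""

    list_size: int
    tp: float
    fp: float
    fn: float
    tn: float
    precision: float
    recall: float
    tpr: float
    fpr: float
    n_users: int = 0

    def to_dict(self) -> dict:
        return {
            "list_size": self.list_size,
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "tpr": self.tpr, "fpr": self.fpr, "n_users": self.n_users,
        }


def confusion_from_counts(
    list_size: int, tp: float, fp: float, fn: float, tn: float, n_users: int = 0
) -> TopNConfusion:
    """Derive precision / recall / TPR / FPR from mean confusion counts.

    precision = TP/(TP+FP); recall = TPR = TP/(TP+FN); FPR = FP/(FP+TN).
    A zero denominator yields 0.
    """
    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else 0.0

    return TopNConfusion(
        list_size=list_size, tp=tp, fp=fp, fn=fn, tn=tn,
        precision=ratio(tp, tp + fp),
        recall=ratio(tp, tp + fn),
        tpr=ratio(tp, tp + fn),
        fpr=ratio(fp, fp + tn),
        n_users=n_users,
    )


def topn_confusion(
    recs: Mapping[object, RecommendationList],
    withheld: pd.DataFrame,
    universe: Mapping[object, Iterable[str]],
    good_rating: float = 1.0,
    list_size: int | None = None,
) -> TopNConfusion:
    """Score recommendation lists against withheld consumption.

    Per user: relevant = withheld items with rating >= ``good_rating``;
    TP = recommended ∩ relevant, FP = recommended \\ relevant,
    FN = relevant \\ recommended, TN = the rest of the user's candidate
    universe. Counts are averaged over users and rates derived from the
    mean counts. Recommending an item outside the universe (i.e. one of
    the user's visible given items) is a protocol violation.
    """
    if list_size is None:
        list_size = max((len(rl) for rl in recs.values()), default=0)
    tps, fps, fns, tns = [], [], [], []
    for user, rl in recs.items():
        uni = set(universe[user])
        rec_items = set(rl.items)
        outside = rec_items - uni
        if outside:
            raise ValueError(
                f"protocol violation: user {user!r} was recommended given/visible "
                f"items {sorted(outside)}"
            )
        row = withheld.loc[user]
        relevant = set(row.index[(row.notna()) & (row >= good_rating)])
        tp = len(rec_items & relevant)
        fp = len(rec_items - relevant)
        fn = len(relevant - rec_items)
        tn = len(uni) - tp - fp - fn
        tps.append(tp); fps.append(fp); fns.append(fn); tns.append(tn)
    n = len(tps)
    if n == 0:
        raise ValueError("no users to score")
    return confusion_from_counts(
        list_size,
        tp=float(np.mean(tps)), fp=float(np.mean(fps)),
        fn=float(np.mean(fns)), tn=float(np.mean(tns)),
        n_users=n,
    )


def random_ranking_base_rate(
    withheld: pd.DataFrame,
    universe: Mapping[object, Iterable[str]],
    good_rating: float = 1.0,
) -> float:
    """Expected precision of a uniformly random ranker.

    Drawing any list uniformly from a user's candidate universe hits
    relevant items at rate |relevant|/|universe|; the mean of that ratio
    over users is the precision a structure-free recommender attains at
    every list size.
    """
    rates = []
    for user in withheld.index:
        row = withheld.loc[user]
        relevant = int(((row.notna()) & (row >= good_rating)).sum())
        uni = len(set(universe[user]))
        if uni > 0:
            rates.append(relevant / uni)
    return float(np.mean(rates))


_ESTIMATORS = {"UBCF": UserBasedCF, "IBCF": ItemBasedCF}

DEFAULT_CONFIGS: dict[str, NeighborhoodConfig] = {
    "UBCF": NeighborhoodConfig(method="UBCF", k_neighbors=25),
    "IBCF": NeighborhoodConfig(method="IBCF", k_neighbors=30),
}


def _global_mean_metrics(combined: pd.DataFrame, withheld: pd.DataFrame) -> ErrorMetrics:
    """Baseline: predict the grand mean of all visible ratings everywhere."""
    gmean = float(np.nanmean(combined.to_numpy(dtype=float)))
    truth = withheld.to_numpy(dtype=float)
    mask = np.isfinite(truth)
    y_true = truth[mask]
    y_pred = np.full(y_true.shape, gmean)
    mse = float(mean_squared_error(y_true, y_pred))
    return ErrorMetrics(
        rmse=float(np.sqrt(mse)), mse=mse,
        mae=float(mean_absolute_error(y_true, y_pred)),
        n_pairs=int(mask.sum()), n_unpredictable=0,
    )


def evaluate_sweep(
    R: pd.DataFrame,
    scheme: EvaluationScheme,
    catalog: FoodGroupCatalog,
    cfgs: Mapping[str, NeighborhoodConfig] | None = None,
    train_users: Sequence | None = None,
    eligible_only: bool = False,
    return_details: bool = False,
):
    """Run the full withheld-item evaluation for UBCF and IBCF.

    Each method learns from the training users only; test users present
    their ``given`` visible ratings and the model estimates the withheld
    cells (UBCF relates a test user to the training base via
    cross-similarity, IBCF applies the training item-item similarities
    to the test user's own visible ratings). The report carries
    rating-error metrics (with a global-mean baseline), one confusion
    row per list size, and the ROC / precision-recall curve points.
    ``eligible_only`` defaults to False here: evaluation scores the full
    candidate universe, leaving the health constraint to recommendation
    mode.

    Returns a JSON-serializable report dict, plus a details dict
    (split, per-method predictions and recommendation lists) when
    ``return_details`` is set.
    """
    if cfgs is None:
        cfgs = DEFAULT_CONFIGS
    split = split_scheme(R, scheme, train_users=train_users)
    train, test_given, test_withheld = split
    combined = pd.concat([train, test_given])
    test_users = test_given.index

    # candidate universe: everything except the user's visible items
    universe = {
        user: [c for c in R.columns if pd.isna(test_given.loc[user, c])]
        for user in test_users
    }

    report: dict = {
        "scheme": scheme.to_dict(),
        "n_train_users": int(len(train)),
        "n_test_users": int(len(test_users)),
        "universe_sizes": {str(u): len(v) for u, v in universe.items()},
        "base_rate_precision": random_ranking_base_rate(
            test_withheld, universe, scheme.good_rating
        ),
        "error_metrics": {}, "confusion": {}, "curves": {},
    }
    report["baseline"] = _global_mean_metrics(combined, test_withheld).to_dict()

    details: dict = {"split": split, "predictions": {}, "recommendations": {}}
    for method, cfg in cfgs.items():
        est = _ESTIMATORS[cfg.method](
            k_neighbors=cfg.k_neighbors,
            min_overlap=cfg.min_overlap,
            positive_only=cfg.positive_only,
        )
        est.fit(train)
        P_test = est.predict(test_given)
        details["predictions"][method] = P_test
        report["error_metrics"][method] = rating_error_metrics(
            P_test, test_withheld
        ).to_dict()

        full_recs = top_n_recommend(
            P_test, catalog, n_max=max(scheme.list_sizes), eligible_only=eligible_only
        )
        details["recommendations"][method] = full_recs
        rows = []
        for L in scheme.list_sizes:
            recs_L = {u: rl.truncate(L) for u, rl in full_recs.items()}
            rows.append(
                topn_confusion(
                    recs_L, test_withheld, universe,
                    good_rating=scheme.good_rating, list_size=L,
                ).to_dict()
            )
        report["confusion"][method] = rows
        report["curves"][method] = {
            "roc": [[r["fpr"], r["tpr"]] for r in rows],
            "pr": [[r["recall"], r["precision"]] for r in rows],
        }
        logger.info(
            "%s: rmse=%.3f precision@%d=%.3f", method,
            report["error_metrics"][method]["rmse"],
            scheme.list_sizes[0], rows[0]["precision"],
        )
    if return_details:
        return report, details
    return report


def plot_curves(report: dict, path_prefix: str) -> list[str]:
    """Write ROC and precision-recall curve plots as PNG files.

    Returns the written file paths.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    panels = [
        ("roc", "False positive rate", "True positive rate", "ROC curve"),
        ("pr", "Recall", "Precision", "Precision-recall curve"),
    ]
    for key, xlabel, ylabel, title in panels:
        fig, ax = plt.subplots(figsize=(5, 4))
        for method, curves in report["curves"].items():
            pts = curves[key]
            ax.plot([p[0] for p in pts], [p[1] for p in pts], marker="o", label=method)
        ax.set_xlabel(xlabel)
        ax.set_ylabel(ylabel)
        ax.set_title(title)
        ax.legend()
        fig.tight_layout()
        out = f"{path_prefix}_{key}.png"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    return written
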