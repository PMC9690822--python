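import warnings

import numpy as np
import pandas as pd
import pytest

from dietrec.catalog import default_catalog
from dietrec.cf import OBSERVED, PREDICTED, UNPREDICTABLE, PredictedRatings
from dietrec.evaluation import (
    EvaluationScheme,
    confusion_from_counts,
    evaluate_sweep,
    plot_curves,
    random_ranking_base_rate,
    rating_error_metrics,
    split_scheme,
    topn_confusion,
)
from dietrec.recommend import RecommendationList

from cf_oracles import random_rating_matrix


@pytest.fixture(scope="module")
def sweep_report(small_cohort_ratings, catalog):
    R, _ = small_cohort_ratings
    scheme = EvaluationScheme(seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return evaluate_sweep(R, scheme, catalog)


class TestScheme:
    def test_defaults_match_protocol(self):
        s = EvaluationScheme()
        assert s.train_fraction == 0.70
        assert s.given == 10
        assert s.list_sizes == (1, 3, 5, 10)

    @pytest.mark.parametrize(
        "kwargs", [{"train_fraction": 0.0}, {"train_fraction": 1.0},
                   {"given": 0}, {"list_sizes": (3, 1)}]
    )
    def test_invalid_scheme_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EvaluationScheme(**kwargs)


class TestSplit:
    def _matrix(self, n_users=100, n_items=21, seed=0, p_missing=0.1):
        rng = np.random.default_rng(seed)
        return random_rating_matrix(rng, n_users, n_items, p_missing)

    def test_split_sizes_and_reproducibility(self):
        R = self._matrix()
        scheme = EvaluationScheme(seed=3)
        s1 = split_scheme(R, scheme)
        s2 = split_scheme(R, scheme)
        assert len(s1.train) == 70
        assert len(s1.test_given) == 30
        pd.testing.assert_frame_equal(s1.train, s2.train)
        pd.testing.assert_frame_equal(s1.test_withheld, s2.test_withheld)

    def test_partition_of_observed_cells(self):
        R = self._matrix(seed=1)
        scheme = EvaluationScheme(seed=2)
        train, given, withheld = split_scheme(R, scheme)
        assert set(train.index).isdisjoint(given.index)
        for user in given.index:
            g = given.loc[user].dropna()
            w = withheld.loc[user].dropna()
            obs = R.loc[user].dropna()
            assert len(g) == scheme.given
            assert set(g.index).isdisjoint(w.index)
            assert set(g.index) | set(w.index) == set(obs.index)
            # values unchanged
            pd.testing.assert_series_equal(obs[g.index], g)
            pd.testing.assert_series_equal(obs[w.index], w)

    def test_sparse_test_users_dropped_with_warning(self):
        R = self._matrix(n_users=40, seed=4, p_missing=0.6)  # ~8 obs/user
        scheme = EvaluationScheme(given=10, seed=0)
        with pytest.warns(UserWarning, match="dropping"):
            split = split_scheme(R, scheme)
        for user in split.test_given.index:
            assert R.loc[user].notna().sum() > scheme.given

    def test_explicit_train_users_respected(self):
        R = self._matrix(seed=6)
        train_users = list(R.index[:50])
        split = split_scheme(R, EvaluationScheme(seed=0), train_users=train_users)
        assert list(split.train.index) == train_users
        assert set(split.test_given.index) == set(R.index[50:])


def _pr(pred_rows, prov_rows, index, columns):
    return PredictedRatings(
        ratings=pd.DataFrame(pred_rows, index=index, columns=columns, dtype=float),
        provenance=pd.DataFrame(prov_rows, index=index, columns=columns),
    )


class TestErrorMetrics:
    def test_perfect_predictions_zero_error(self):
        P = _pr([[1.0, 5.0]], [[PREDICTED, PREDICTED]], ["u"], ["a", "b"])
        truth = pd.DataFrame([[1.0, 5.0]], index=["u"], columns=["a", "b"])
        em = rating_error_metrics(P, truth)
        assert em.rmse == em.mse == em.mae == 0.0

    def test_unit_errors(self):
        P = _pr([[2.0, 4.0]], [[PREDICTED, PREDICTED]], ["u"], ["a", "b"])
        truth = pd.DataFrame([[1.0, 5.0]], index=["u"], columns=["a", "b"])
        em = rating_error_metrics(P, truth)
        assert (em.rmse, em.mse, em.mae) == (1.0, 1.0, 1.0)

    def test_matches_loop_oracle_on_random_pairs(self):
        rng = np.random.default_rng(9)
        pred = rng.uniform(1, 5, 50)
        true = rng.integers(1, 6, 50).astype(float)
        P = _pr([pred], [[PREDICTED] * 50], ["u"], [f"g{i}" for i in range(50)])
        truth = pd.DataFrame([true], index=["u"], columns=[f"g{i}" for i in range(50)])
        em = rating_error_metrics(P, truth)
        errs = [p - t for p, t in zip(pred, true)]
        assert em.mse == pytest.approx(sum(e * e for e in errs) / 50, abs=1e-12)
        assert em.rmse == pytest.approx((sum(e * e for e in errs) / 50) ** 0.5, abs=1e-12)
        assert em.mae == pytest.approx(sum(abs(e) for e in errs) / 50, abs=1e-12)

    def test_unpredictable_cells_excluded_but_counted(self):
        P = _pr(
            [[2.0, np.nan]], [[PREDICTED, UNPREDICTABLE]], ["u"], ["a", "b"]
        )
        truth = pd.DataFrame([[1.0, 4.0]], index=["u"], columns=["a", "b"])
        em = rating_error_metrics(P, truth)
        assert em.n_pairs == 1 and em.n_unpredictable == 1
        assert em.mae == 1.0

    def test_truth_overlapping_observed_rejected(self):
        P = _pr([[2.0]], [[OBSERVED]], ["u"], ["a"])
        truth = pd.DataFrame([[2.0]], index=["u"], columns=["a"])
        with pytest.raises(ValueError, match="observed"):
            rating_error_metrics(P, truth)

    def test_no_pairs_rejected(self):
        P = _pr([[np.nan]], [[UNPREDICTABLE]], ["u"], ["a"])
        truth = pd.DataFrame([[2.0]], index=["u"], columns=["a"])
        with pytest.raises(ValueError, match="no evaluable"):
            rating_error_metrics(P, truth)


class TestConfusion:
    def test_rates_from_printed_style_mean_counts(self):
        # mean counts like a published top-1 row: TP 0.88, FP 0.12
        row = confusion_from_counts(1, tp=0.88, fp=0.12, fn=9.08, tn=0.92)
        assert round(row.precision, 2) == 0.88
        assert round(row.recall, 2) == 0.09

    def test_exact_hit_list(self):
        withheld = pd.DataFrame(
            [[4.0, 5.0, np.nan]], index=["u"], columns=["a", "b", "c"]
        )
        recs = {"u": RecommendationList("u", (("a", 4.5), ("b", 4.0)), 2)}
        out = topn_confusion(recs, withheld, {"u": ["a", "b", "c"]})
        assert (out.tp, out.fp, out.fn, out.tn) == (2.0, 0.0, 0.0, 1.0)
        assert out.precision == out.recall == 1.0

    def test_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(12)
        items = [f"g{j}" for j in range(11)]
        users = [f"u{i}" for i in range(30)]
        withheld = pd.DataFrame(np.nan, index=users, columns=items)
        recs, universe = {}, {}
        for u in users:
            rel = rng.choice(items, size=rng.integers(0, 8), replace=False)
            withheld.loc[u, rel] = rng.integers(1, 6, len(rel)).astype(float)
            picked = rng.choice(items, size=3, replace=False)
            recs[u] = RecommendationList(u, tuple((i, 3.0) for i in picked), 3)
            universe[u] = items
        out = topn_confusion(recs, withheld, universe, list_size=3)
        tp = fp = fn = tn = 0
        for u in users:
            rel = set(withheld.columns[withheld.loc[u].notna()])
            rec = set(recs[u].items)
            tp += len(rec & rel); fp += len(rec - rel)
            fn += len(rel - rec); tn += len(set(items) - rec - rel)
        n = len(users)
        assert out.tp == pytest.approx(tp / n)
        assert out.fp == pytest.approx(fp / n)
        assert out.fn == pytest.approx(fn / n)
        assert out.tn == pytest.approx(tn / n)

    def test_recommending_visible_item_is_protocol_violation(self):
        withheld = pd.DataFrame([[4.0]], index=["u"], columns=["a"])
        recs = {"u": RecommendationList("u", (("b", 3.0),), 1)}
        with pytest.raises(ValueError, match="protocol violation"):
            topn_confusion(recs, withheld, {"u": ["a"]})


class TestSweepReport:
    def test_metric_identities(self, sweep_report):
        for method, em in sweep_report["error_metrics"].items():
            assert em["mse"] == pytest.approx(em["rmse"] ** 2, abs=1e-12)
            assert em["mae"] <= em["rmse"] + 1e-12
        for method, rows in sweep_report["confusion"].items():
            for r in rows:
                tp, fp, fn, tn = r["tp"], r["fp"], r["fn"], r["tn"]
                assert r["precision"] == pytest.approx(tp / (tp + fp), abs=1e-12)
                assert r["recall"] == pytest.approx(tp / (tp + fn), abs=1e-12)
                assert r["tpr"] == r["recall"]
                assert r["fpr"] == pytest.approx(fp / (fp + tn), abs=1e-12)

    def test_counts_conserved_and_monotone_in_list_size(self, sweep_report):
        for method, rows in sweep_report["confusion"].items():
            totals = [r["tp"] + r["fp"] + r["fn"] + r["tn"] for r in rows]
            assert max(totals) - min(totals) < 1e-9
            tps = [r["tp"] for r in rows]
            fps = [r["fp"] for r in rows]
            fns = [r["fn"] for r in rows]
            tns = [r["tn"] for r in rows]
            recalls = [r["recall"] for r in rows]
            assert tps == sorted(tps) and fps == sorted(fps)
            assert fns == sorted(fns, reverse=True) and tns == sorted(tns, reverse=True)
            assert recalls == sorted(recalls)

    def test_curves_trace_confusion_rows(self, sweep_report):
        for method, rows in sweep_report["confusion"].items():
            roc = sweep_report["curves"][method]["roc"]
            pr = sweep_report["curves"][method]["pr"]
            assert roc == [[r["fpr"], r["tpr"]] for r in rows]
            assert pr == [[r["recall"], r["precision"]] for r in rows]

    def test_seed_determinism(self, small_cohort_ratings, catalog, sweep_report):
        R, _ = small_cohort_ratings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            again = evaluate_sweep(R, EvaluationScheme(seed=5), catalog)
        assert again == sweep_report

    def test_plot_files_written(self, sweep_report, tmp_path):
        paths = plot_curves(sweep_report, str(tmp_path / "curves"))
        assert len(paths) == 2
        for p in paths:
            assert (tmp_path / p.split("/")[-1]).stat().st_size > 0


def test_base_rate_is_mean_relevant_share():
    items = ["a", "b", "c", "d"]
    withheld = pd.DataFrame(
        [[4.0, 2.0, np.nan, np.nan], [5.0, np.nan, np.nan, np.nan]],
        index=["u", "v"], columns=items,
    )
    universe = {"u": items, "v": items[:2]}
    rate = random_ranking_base_rate(withheld, universe)
    assert rate == pytest.approx((2 / 4 + 1 / 2) / 2)
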