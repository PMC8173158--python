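"""ReliefF ranking, the discrete AdaBoost ensemble, CV sweep and evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epiaging import markers

from ._oracles import adaboost_margins, textbook_adaboost
from .conftest import separable_fixture


class TestReliefF:
    def test_perfect_separator_ranked_first(self):
        rng = np.random.default_rng(0)
        n = 60
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(rng.standard_normal((n, 20)), columns=[f"f{j}" for j in range(20)])
        X["f7"] = y * 10.0 + rng.standard_normal(n) * 0.01
        ranking = markers.relieff_rank(X, y, n_neighbors=5)
        assert ranking.index[0] == "f7"

    def test_duplicate_columns_get_equal_scores(self):
        X, y = separable_fixture(seed=1)
        X["dup"] = X["f0"]
        ranking = markers.relieff_rank(X, y)
        assert ranking["f0"] == pytest.approx(ranking["dup"], abs=1e-12)

    def test_single_class_rejected(self):
        X, _ = separable_fixture()
        with pytest.raises(ValueError):
            markers.relieff_rank(X, np.zeros(len(X)))

    def test_null_labels_leave_planted_site_unranked(self):
        # with shuffled labels the formerly separating site gets no credit:
        # its median rank over reseeds sits well away from the top
        n_sites = 40
        ranks = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.repeat([0, 1], 30)
            X = pd.DataFrame(
                rng.standard_normal((60, n_sites)),
                columns=[f"f{j}" for j in range(n_sites)],
            )
            X["f0"] = X["f0"] + 2.0 * y
            y_null = rng.permutation(y)
            ranking = markers.relieff_rank(X, y_null, n_neighbors=5)
            ranks.append(list(ranking.index).index("f0") + 1)
        assert np.median(ranks) > n_sites / 4


class TestBoosting:
    def test_matches_textbook_oracle_round_by_round(self):
        for seed in range(5):
            X, y = separable_fixture(seed=seed, n=60, p=5, gap=1.0)
            n_rounds = 20
            rng = np.random.default_rng(seed)
            tree_seeds = [int(rng.integers(2**31 - 1)) for _ in range(n_rounds)]
            model = markers.boost_fit(X, y, n_estimators=n_rounds, seed=seed)
            trees, alphas = textbook_adaboost(
                X, y, n_rounds, max_depth=2, tree_seeds=tree_seeds
            )
            assert len(model.learners) == len(trees)
            assert np.allclose(model.alphas, alphas, atol=1e-12)
            for r in range(1, len(trees) + 1):
                partial = markers.BoostedEnsemble(
                    model.learners[:r], model.alphas[:r], model.feature_names
                )
                oracle_margin = adaboost_margins(trees[:r], alphas[:r], X)
                assert np.array_equal(
                    partial.predict(X), (oracle_margin > 0).astype(int)
                )

    def test_alpha_is_zero_at_even_odds(self):
        # eps = 0.5 gives alpha = 0.5*ln(1) = 0 by the weight formula
        assert 0.5 * np.log((1 - 0.5) / 0.5) == 0.0

    def test_separable_fixture_reaches_perfect_training_accuracy(self):
        X, y = separable_fixture(seed=3, gap=4.0)
        model = markers.boost_fit(X, y, n_estimators=10, seed=0)
        assert (model.predict(X) == y).all()
        assert model.n_estimators <= 10

    def test_weight_bookkeeping_invariants(self):
        X, y = separable_fixture(seed=2, gap=0.5)
        model = markers.boost_fit(X, y, n_estimators=15, seed=1)
        assert all(np.isfinite(model.alphas))
        assert all(0.0 <= e < 0.5 for e in model.train_errors)
        assert all(a > 0 for a in model.alphas)

    def test_single_learner_equals_its_tree(self):
        X, y = separable_fixture(seed=4)
        model = markers.boost_fit(X, y, n_estimators=1, seed=0)
        labels, margins = markers.boost_predict(model, X)
        assert np.array_equal(labels, model.learners[0].predict(X.to_numpy()))

    def test_flipping_alpha_signs_flips_labels(self):
        X, y = separable_fixture(seed=5, gap=1.0)
        model = markers.boost_fit(X, y, n_estimators=5, seed=0)
        flipped = markers.BoostedEnsemble(
            model.learners, [-a for a in model.alphas], model.feature_names
        )
        m1 = model.margins(X)
        m2 = flipped.margins(X)
        assert np.allclose(m1, -m2)

    def test_feature_mismatch_raises(self):
        X, y = separable_fixture(seed=6)
        model = markers.boost_fit(X, y, n_estimators=3, seed=0)
        with pytest.raises(KeyError):
            model.predict(X.rename(columns={"f0": "other"}))


class TestTopKSelection:
    def test_planted_top_sites_give_small_selected_k(self):
        rng = np.random.default_rng(7)
        n = 120
        y = np.repeat([0, 1], n // 2)
        X = pd.DataFrame(
            rng.standard_normal((n, 30)), columns=[f"f{j}" for j in range(30)]
        )
        for j in range(3):
            X[f"f{j}"] += 1.6 * y
        ranking = markers.relieff_rank(X, y, n_neighbors=8)
        ms = markers.select_top_k_cv(
            X, y, ranking, k_max=15, folds=5, n_estimators=15, seed=0
        )
        assert ms.selected_k <= 10
        assert ms.cv_accuracy_by_k[ms.selected_k] >= ms.cv_accuracy_by_k[1]
        assert ms.selected_k == int(ms.cv_accuracy_by_k.idxmax())

    def test_selected_k_breaks_ties_at_smallest(self):
        # monotone-saturating curve: argmax must take the first maximum
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 40)
        X = pd.DataFrame(rng.standard_normal((80, 10)), columns=[f"f{j}" for j in range(10)])
        X["f0"] += 10.0 * y  # k=1 already perfect; all larger k tie at 1.0
        ranking = markers.relieff_rank(X, y)
        ms = markers.select_top_k_cv(X, y, ranking, k_max=6, folds=4, n_estimators=5, seed=0)
        assert ms.selected_k == 1


class TestBalancedDiseaseFit:
    def test_single_subgroup_reduces_to_plain_selection(self):
        rng = np.random.default_rng(2)
        Xc = pd.DataFrame(rng.standard_normal((40, 12)), columns=[f"f{j}" for j in range(12)])
        Xd = pd.DataFrame(rng.standard_normal((40, 12)), columns=Xc.columns)
        Xd["f3"] += 2.5
        ms = markers.balanced_disease_fit(
            Xc, Xd, n_subgroups=1, k_max=8, folds=4, n_estimators=10, seed=5
        )
        assert ms.ranked_site_ids[0] == "f3"
        assert 1 <= ms.selected_k <= 8

    def test_class_mass_weights_balance(self):
        y = np.array([0] * 30 + [1] * 10)
        w = markers.class_mass_weights(y)
        assert w[y == 0].sum() == pytest.approx(w[y == 1].sum())
        assert w.sum() == pytest.approx(1.0)


class TestEvaluate:
    def test_perfect_margins_give_auc_one(self):
        X, y = separable_fixture(seed=8, gap=6.0)
        model = markers.boost_fit(X, y, n_estimators=5, seed=0)
        ev = markers.evaluate(model, X, y)
        assert ev["auc"] == pytest.approx(1.0)
        assert ev["accuracy"] == pytest.approx(1.0)

    def test_auc_equals_mann_whitney(self):
        X, y = separable_fixture(seed=9, n=80, gap=0.8)
        model = markers.boost_fit(X, y, n_estimators=10, seed=3)
        ev = markers.evaluate(model, X, y)
        m = ev["margins"]
        u = stats.mannwhitneyu(m[y == 1], m[y == 0], alternative="two-sided").statistic
        assert ev["auc"] == pytest.approx(u / ((y == 1).sum() * (y == 0).sum()))

    def test_single_class_test_set_signals(self):
        X, y = separable_fixture(seed=10)
        model = markers.boost_fit(X, y, n_estimators=3, seed=0)
        with pytest.raises(ValueError, match="single-class"):
            markers.evaluate(model, X, np.ones(len(X), dtype=int))
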