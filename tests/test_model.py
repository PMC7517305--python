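"""Balanced random forest, OOB permutation importance, logistic baseline."""

import numpy as np
import pytest

from _oracles import auroc_pair_counting
from rearrest.model import (
    BalancedRandomForest,
    TwoStageRandomForest,
    UnivariateLogistic,
    fit_univariate_logistic,
    select_and_retrain,
    train_rf,
)


def _planted(rng, n=200, p=8, shift=2.0):
    """Noise matrix with one informative column (index 0)."""
    y = (rng.random(n) < 0.34).astype(int)
    X = rng.normal(size=(n, p))
    X[:, 0] += shift * y
    return X, y


class TestBalancedBootstrap:
    def test_training_sets_exactly_balanced(self):
        rng = np.random.default_rng(0)
        y = np.r_[np.ones(20, int), np.zeros(100, int)]
        rf = BalancedRandomForest(n_trees=50, random_state=0)
        for _ in range(50):
            train_idx, boot = rf._balanced_bootstrap(y, rng)
            classes, counts = np.unique(y[train_idx], return_counts=True)
            assert classes.size == 2
            assert counts[0] == counts[1]

    def test_bootstrap_size_is_five_percent(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(55, int), np.zeros(107, int)]
        rf = BalancedRandomForest(random_state=0)
        _, boot = rf._balanced_bootstrap(y, rng)
        assert boot.size == int(np.ceil(0.05 * 162))


class TestBalancedRandomForest:
    def test_separable_data_high_training_auroc(self):
        rng = np.random.default_rng(2)
        X, y = _planted(rng, shift=6.0)
        m = BalancedRandomForest(n_trees=100, random_state=0).fit(X, y)
        s = m.predict_likelihood(X)
        assert auroc_pair_counting(s, y) >= 99.0

    def test_scores_are_vote_fractions(self):
        rng = np.random.default_rng(3)
        X, y = _planted(rng)
        m = BalancedRandomForest(n_trees=300, random_state=0).fit(X, y)
        s = m.predict_likelihood(X[:40])
        votes = s * 300
        np.testing.assert_allclose(votes, np.round(votes), atol=1e-9)
        assert np.all((s >= 0) & (s <= 1))

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(4)
        X, y = _planted(rng)
        Xt = rng.normal(size=(30, X.shape[1]))
        s1 = BalancedRandomForest(random_state=9).fit(X, y).predict_likelihood(Xt)
        s2 = BalancedRandomForest(random_state=9).fit(X, y).predict_likelihood(Xt)
        np.testing.assert_array_equal(s1, s2)

    def test_tie_resolves_to_negative(self):
        rng = np.random.default_rng(5)
        X, y = _planted(rng)
        m = BalancedRandomForest(n_trees=2, random_state=0).fit(X, y)
        s = m.predict_likelihood(X)
        pred = m.predict(X)
        assert np.all(pred[s == 0.5] == 0)

    def test_affine_feature_transform_leaves_scores_unchanged(self):
        # split midpoints commute with affine maps, so rescaling features
        # (changing units) leaves every vote unchanged
        rng = np.random.default_rng(6)
        X, y = _planted(rng, p=4)
        Xt = rng.normal(size=(60, 4))
        g = lambda v: 3.0 * v + 7.0
        m1 = BalancedRandomForest(n_trees=80, random_state=3).fit(X, y)
        m2 = BalancedRandomForest(n_trees=80, random_state=3).fit(g(X), y)
        s1 = m1.predict_likelihood(Xt)
        s2 = m2.predict_likelihood(g(Xt))
        np.testing.assert_allclose(s1, s2, atol=1e-12)
        assert auroc_pair_counting(s1, np.r_[np.ones(30, int), np.zeros(30, int)]) == \
            auroc_pair_counting(s2, np.r_[np.ones(30, int), np.zeros(30, int)])

    def test_nonlinear_monotone_transform_preserves_ranking_closely(self):
        # trees split on order statistics; a nonlinear monotone transform can
        # move midpoint thresholds relative to unseen points, but the
        # induced ranking change is marginal
        rng = np.random.default_rng(6)
        X, y = _planted(rng, p=4)
        g = lambda v: 2 * v + v**3
        m1 = BalancedRandomForest(n_trees=150, random_state=3).fit(X, y)
        m2 = BalancedRandomForest(n_trees=150, random_state=3).fit(g(X), y)
        a1 = auroc_pair_counting(m1.predict_likelihood(X), y)
        a2 = auroc_pair_counting(m2.predict_likelihood(g(X)), y)
        assert a2 == pytest.approx(a1, abs=2.0)

    def test_single_class_rejected(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(30, 3))
        with pytest.raises(ValueError):
            BalancedRandomForest().fit(X, np.zeros(30, int))

    def test_missing_values_rejected(self):
        rng = np.random.default_rng(8)
        X, y = _planted(rng)
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            BalancedRandomForest().fit(X, y)


class TestPermutationImportance:
    def test_informative_feature_ranks_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X, y = _planted(rng, n=250, p=6, shift=3.0)
            m = BalancedRandomForest(n_trees=150, random_state=seed).fit(X, y)
            imp = m.permutation_importance()["importance"]
            hits += int(np.argmax(imp) == 0)
        assert hits >= 19

    def test_pure_noise_feature_importance_near_zero(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X, y = _planted(rng, n=250, p=6, shift=3.0)
            m = BalancedRandomForest(n_trees=150, random_state=seed).fit(X, y)
            vals.append(m.permutation_importance()["mean_increase"][-1])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) <= 2 * se + 1e-12

    def test_zero_variance_feature_importance_zero(self):
        rng = np.random.default_rng(9)
        X, y = _planted(rng, p=4)
        X[:, 2] = 1.0
        m = BalancedRandomForest(n_trees=50, random_state=0).fit(X, y)
        assert m.permutation_importance()["importance"][2] == 0.0

    def test_emptied_oob_sets_signal_error(self):
        rng = np.random.default_rng(10)
        X, y = _planted(rng)
        m = BalancedRandomForest(n_trees=20, random_state=0).fit(X, y)
        m.oob_indices_ = [np.array([], dtype=int)] * 20
        with pytest.raises(ValueError):
            m.permutation_importance()


class TestTwoStage:
    def test_nf_equals_p_uses_all_features(self):
        rng = np.random.default_rng(11)
        X, y = _planted(rng, p=5)
        m = TwoStageRandomForest(nf=5, n_trees=50, random_state=0).fit(X, y)
        np.testing.assert_array_equal(m.selected_features_, np.arange(5))

    def test_nf_one_selects_planted_feature(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            X, y = _planted(rng, n=250, p=6, shift=3.0)
            m = TwoStageRandomForest(nf=1, n_trees=150, random_state=seed).fit(X, y)
            hits += int(m.selected_features_[0] == 0)
        assert hits >= 19

    def test_stage2_never_uses_unselected_features(self):
        rng = np.random.default_rng(12)
        X, y = _planted(rng, p=8)
        m = TwoStageRandomForest(nf=3, n_trees=60, random_state=1).fit(X, y)
        used = set()
        for tree in m.model_.trees_:
            used |= set(tree.tree_.feature[tree.tree_.feature >= 0])
        assert used <= set(range(3))  # stage-2 columns are the selected ones

    def test_ranking_reproducible(self):
        rng = np.random.default_rng(13)
        X, y = _planted(rng)
        r1 = TwoStageRandomForest(nf=4, random_state=5).fit(X, y).ranking_
        r2 = TwoStageRandomForest(nf=4, random_state=5).fit(X, y).ranking_
        np.testing.assert_array_equal(r1, r2)

    def test_wrapper_equivalent(self):
        rng = np.random.default_rng(14)
        X, y = _planted(rng)
        m = select_and_retrain(X, y, nf=3, n_trees=40, seed=2)
        assert isinstance(m, TwoStageRandomForest)
        assert m.selected_features_.size == 3


class TestUnivariateLogistic:
    def test_separable_feature(self):
        rng = np.random.default_rng(15)
        y = (rng.random(300) < 0.34).astype(int)
        x = y + rng.normal(scale=0.01, size=300)
        m = fit_univariate_logistic(x, y)
        assert auroc_pair_counting(m.predict_likelihood(x), y) >= 99.0

    def test_null_feature_chance_level(self):
        aurocs = []
        for seed in range(10):
            rng = np.random.default_rng(400 + seed)
            y = (rng.random(400) < 0.34).astype(int)
            x = rng.normal(size=400)
            m = UnivariateLogistic().fit(x[:200], y[:200])
            aurocs.append(auroc_pair_counting(m.predict_likelihood(x[200:]), y[200:]))
        assert abs(np.mean(aurocs) - 50.0) < 5.0

    def test_slope_sign_matches_planted_direction(self):
        rng = np.random.default_rng(16)
        y = (rng.random(300) < 0.34).astype(int)
        up = y * 2.0 + rng.normal(size=300)
        down = -y * 2.0 + rng.normal(size=300)
        assert UnivariateLogistic().fit(up, y).coef_ > 0
        assert UnivariateLogistic().fit(down, y).coef_ < 0

    def test_constant_feature_degenerate(self):
        y = np.r_[np.ones(10, int), np.zeros(20, int)]
        m = UnivariateLogistic().fit(np.ones(30), y)
        assert m.degenerate_
        np.testing.assert_array_equal(m.predict_likelihood(np.ones(5)), 0.5)

    def test_train_rf_wrapper(self):
        rng = np.random.default_rng(17)
        X, y = _planted(rng)
        m = train_rf(X, y, n_trees=20, seed=1)
        assert len(m.trees_) == 20
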