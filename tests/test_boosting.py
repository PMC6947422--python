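"""Boosted-tree primitives, reference trainer, backend equivalence, CV search."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seqbind.boosting import (GradientBoostedTreesClassifier, SplitStats,
                              grid_search_cv, leaf_weight, split_gain,
                              tree_objective, _sigmoid, _tree_predict)
from seqbind.dataset import LabeledDataset

finite = st.floats(-50, 50, allow_nan=False)
positive = st.floats(0.01, 50, allow_nan=False)


class TestPrimitives:
    def test_leaf_weight_zero_gradient(self):
        assert leaf_weight(SplitStats(0.0, 7.3), 2.0) == 0.0

    def test_leaf_weight_direct_value(self):
        assert leaf_weight(SplitStats(-4.0, 3.0), 1.0) == pytest.approx(1.0)

    def test_leaf_weight_shrinks_with_lambda(self):
        s = SplitStats(-4.0, 3.0)
        ws = [abs(leaf_weight(s, lam)) for lam in (0.0, 1.0, 5.0, 50.0)]
        assert ws == sorted(ws, reverse=True)

    def test_leaf_weight_degenerate_denominator(self):
        with pytest.raises(ValueError):
            leaf_weight(SplitStats(1.0, 0.0), 0.0)

    def test_tree_objective_single_leaf(self):
        assert tree_objective([SplitStats(2.0, 1.0)], 1.0, 0.0) == pytest.approx(-1.0)

    def test_tree_objective_all_zero_gradients_costs_gamma_per_leaf(self):
        leaves = [SplitStats(0.0, 1.0)] * 3
        assert tree_objective(leaves, 1.0, 0.7) == pytest.approx(2.1)

    def test_adding_zero_gradient_leaf_adds_exactly_gamma(self):
        leaves = [SplitStats(2.0, 1.0), SplitStats(-1.0, 0.5)]
        base = tree_objective(leaves, 1.0, 0.3)
        more = tree_objective(leaves + [SplitStats(0.0, 1.0)], 1.0, 0.3)
        assert more - base == pytest.approx(0.3)

    def test_split_gain_direct_value(self):
        g = split_gain(SplitStats(-2.0, 1.0), SplitStats(2.0, 1.0), 0.0, 0.0)
        assert g == pytest.approx(4.0)

    def test_empty_side_costs_gamma(self):
        g = split_gain(SplitStats(-2.0, 1.0), SplitStats(0.0, 0.0), 1.0, 0.25)
        assert g == pytest.approx(-0.25)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(gl=finite, hl=positive, gr=finite, hr=positive,
           lam=st.floats(0, 10), gamma=st.floats(0, 5))
    def test_gain_equals_objective_drop(self, gl, hl, gr, hr, lam, gamma):
        """Gain is the parent objective minus the two-leaf objective, with
        gamma paying for the one extra leaf (algebraic identity)."""
        left, right = SplitStats(gl, hl), SplitStats(gr, hr)
        parent = left + right
        drop = (tree_objective([parent], lam, gamma)
                - tree_objective([left, right], lam, gamma))
        assert split_gain(left, right, lam, gamma) == pytest.approx(drop, abs=1e-8)


def exhaustive_best_split(X, g, h, lam, gamma):
    """Oracle: enumerate every (feature, midpoint-threshold) split."""
    best = (0.0, None, None)
    for f in range(X.shape[1]):
        vals = np.unique(X[:, f])
        for a, b in zip(vals[:-1], vals[1:]):
            thr = (a + b) / 2
            mask = X[:, f] <= thr
            left = SplitStats(g[mask].sum(), h[mask].sum(), int(mask.sum()))
            right = SplitStats(g[~mask].sum(), h[~mask].sum(), int((~mask).sum()))
            gain = split_gain(left, right, lam, gamma)
            if gain > best[0] + 1e-12:
                best = (gain, f, thr)
    return best


class TestReferenceTrainer:
    def test_root_split_matches_exhaustive_enumeration(self, rng):
        X = rng.normal(size=(100, 10))
        y = (X[:, 3] + 0.3 * rng.normal(size=100) > 0).astype(int)
        model = GradientBoostedTreesClassifier(
            n_estimators=1, max_depth=1, reg_lambda=1.0, gamma=0.1,
            backend="reference", base_score=0.5).fit(X, y)
        p = 0.5
        g = p - y
        h = np.full(100, p * (1 - p))
        gain, f, thr = exhaustive_best_split(X, g, h, 1.0, 0.1)
        root = model.trees_[0]
        assert root["feature"] == f
        assert root["threshold"] == pytest.approx(thr)
        assert root["gain"] == pytest.approx(gain)

    def test_separable_toy_set_fits_perfectly(self, rng):
        X = np.vstack([rng.normal(-2, 0.3, size=(10, 2)),
                       rng.normal(2, 0.3, size=(10, 2))])
        y = np.array([0] * 10 + [1] * 10)
        m = GradientBoostedTreesClassifier(n_estimators=10, max_depth=2,
                                           backend="reference").fit(X, y)
        assert (m.predict(X) == y).all()

    def test_zero_trees_is_constant_at_base_score(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([0, 1] * 10)
        m = GradientBoostedTreesClassifier(n_estimators=0, base_score=0.5,
                                           backend="reference").fit(X, y)
        np.testing.assert_allclose(m.predict_proba(X)[:, 1], 0.5)

    def test_base_score_defaults_to_prevalence(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([1] * 5 + [0] * 15)
        m = GradientBoostedTreesClassifier(n_estimators=0,
                                           backend="reference").fit(X, y)
        np.testing.assert_allclose(m.predict_proba(X)[:, 1], 0.25)

    def test_training_loss_non_increasing(self, rng):
        X = rng.normal(size=(60, 4))
        y = (X[:, 0] - X[:, 1] + 0.5 * rng.normal(size=60) > 0).astype(int)
        m = GradientBoostedTreesClassifier(n_estimators=15, max_depth=3,
                                           learning_rate=0.1, reg_lambda=1.0,
                                           backend="reference",
                                           base_score=0.5).fit(X, y)
        margin = np.zeros(60)
        losses = []
        for tree in [None] + m.trees_:
            if tree is not None:
                margin = margin + m.learning_rate * _tree_predict(tree, X)
            p = _sigmoid(margin)
            losses.append(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))

    def test_non_binary_labels_rejected(self, rng):
        X = rng.normal(size=(9, 2))
        with pytest.raises(ValueError, match="binary"):
            GradientBoostedTreesClassifier(backend="reference").fit(
                X, np.array([0, 1, 2] * 3))

    def test_nan_features_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        X[3, 1] = np.nan
        with pytest.raises(ValueError):
            GradientBoostedTreesClassifier(backend="reference").fit(
                X, np.array([0, 1] * 5))


class TestPrediction:
    @pytest.fixture()
    def model(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 0] > 0).astype(int)
        return GradientBoostedTreesClassifier(
            n_estimators=5, max_depth=2, backend="reference",
            random_state=0).fit(X, y), X

    def test_probabilities_in_open_unit_interval(self, model):
        m, X = model
        p = m.predict_proba(X)[:, 1]
        assert np.all((p > 0) & (p < 1))

    def test_duplicate_rows_score_identically(self, model, rng):
        m, _ = model
        row = rng.normal(size=(1, 3))
        X = np.repeat(row, 4, axis=0)
        assert len(set(m.predict_proba(X)[:, 1])) == 1

    def test_permutation_equivariance(self, model, rng):
        m, X = model
        perm = rng.permutation(X.shape[0])
        np.testing.assert_allclose(m.predict_proba(X)[perm],
                                   m.predict_proba(X[perm]))

    def test_dimension_mismatch_rejected(self, model, rng):
        m, _ = model
        with pytest.raises(ValueError, match="features"):
            m.predict_proba(rng.normal(size=(3, 5)))


class TestXGBoostBackend:
    def test_first_tree_root_matches_reference(self, rng):
        """Same objective, same exact-greedy search: identical root split."""
        X = rng.normal(size=(50, 5))
        y = (X[:, 2] + 0.4 * rng.normal(size=50) > 0).astype(int)
        kwargs = dict(n_estimators=1, max_depth=3, reg_lambda=1.0, gamma=0.0,
                      subsample=1.0, colsample_bytree=1.0, base_score=0.5)
        ref = GradientBoostedTreesClassifier(backend="reference",
                                             **kwargs).fit(X, y)
        xgb = GradientBoostedTreesClassifier(backend="xgboost",
                                             **kwargs).fit(X, y)
        xtree = json.loads(xgb.to_json())["trees"][0]
        assert xtree["feature"] == ref.trees_[0]["feature"]
        assert xtree["threshold"] == pytest.approx(ref.trees_[0]["threshold"],
                                                   rel=1e-5)

    @pytest.mark.parametrize("backend", ["reference", "xgboost"])
    def test_json_dump_reproduces_predictions(self, rng, backend):
        X = rng.normal(size=(60, 4))
        y = (X[:, 1] > 0).astype(int)
        m = GradientBoostedTreesClassifier(n_estimators=8, max_depth=3,
                                           backend=backend,
                                           random_state=1).fit(X, y)
        clone = GradientBoostedTreesClassifier.from_json(m.to_json())
        np.testing.assert_allclose(clone.predict_proba(X)[:, 1],
                                   m.predict_proba(X)[:, 1], atol=1e-6)

    def test_deterministic_under_seed(self, rng):
        X = rng.normal(size=(80, 6))
        y = (X[:, 0] > 0).astype(int)
        a = GradientBoostedTreesClassifier(backend="xgboost", n_estimators=20,
                                           subsample=0.8, random_state=3).fit(X, y)
        b = GradientBoostedTreesClassifier(backend="xgboost", n_estimators=20,
                                           subsample=0.8, random_state=3).fit(X, y)
        np.testing.assert_array_equal(a.predict_proba(X), b.predict_proba(X))


class TestGridSearch:
    def _signal_ds(self, rng, n=300):
        X = rng.normal(size=(n, 6))
        y = (X[:, 0] + 0.5 * rng.normal(size=n) > 0).astype(int)
        return LabeledDataset(X=X, y=y)

    def test_single_config_grid_returns_it(self, rng):
        ds = self._signal_ds(rng)
        cfg = {"n_estimators": 10, "max_depth": 2}
        best, scores = grid_search_cv(ds, grid=[cfg], folds=3, seed=0)
        assert best == cfg and len(scores) == 1

    def test_strictly_dominant_config_wins(self, rng):
        ds = self._signal_ds(rng)
        weak = {"n_estimators": 0, "max_depth": 1}   # constant model, AUC 0.5
        strong = {"n_estimators": 30, "max_depth": 3}
        best, scores = grid_search_cv(ds, grid=[weak, strong], folds=3, seed=0)
        assert best == strong
        by_cfg = {json.dumps(p, sort_keys=True): f for p, _, f in scores}
        assert all(s > w for w, s in zip(by_cfg[json.dumps(weak, sort_keys=True)],
                                         by_cfg[json.dumps(strong, sort_keys=True)]))

    def test_null_signal_cv_auc_near_half(self, rng):
        X = rng.normal(size=(2000, 10))
        y = rng.integers(0, 2, size=2000)
        ds = LabeledDataset(X=X, y=y)
        _, scores = grid_search_cv(
            ds, grid=[{"n_estimators": 30, "max_depth": 3}], folds=5, seed=0)
        assert scores[0][1] == pytest.approx(0.5, abs=0.05)

    def test_fold_with_single_class_rejected(self, rng):
        X = rng.normal(size=(20, 3))
        y = np.array([1, 1] + [0] * 18)
        ds = LabeledDataset(X=X, y=y)
        with pytest.raises(ValueError, match="single class|stratified|minority"):
            grid_search_cv(ds, grid=[{"n_estimators": 5}], folds=5, seed=0)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="empty"):
            grid_search_cv(self._signal_ds(rng), grid=[], folds=2, seed=0)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"learning_rate": 0.0}, {"learning_rate": 1.5}, {"max_depth": 0},
        {"reg_lambda": -1}, {"gamma": -0.1}, {"subsample": 0.0},
        {"colsample_bytree": 1.2}, {"backend": "lightgbm"},
    ])
    def test_invalid_params_rejected_at_fit(self, rng, kwargs):
        X = rng.normal(size=(10, 2))
        y = np.array([0, 1] * 5)
        with pytest.raises(ValueError):
            GradientBoostedTreesClassifier(**kwargs).fit(X, y)
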