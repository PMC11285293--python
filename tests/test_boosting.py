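"""Boosted stumps: split search, training invariants, baselines."""

import numpy as np
import pytest

from oncostump.boosting import (
    GiniTreeClassifier,
    StumpBoostingClassifier,
    confidence_percent,
    fit_stump,
    render_prediction,
    score_baseline,
    train,
)
from oncostump.errors import ShapeError
from oncostump.evaluation import roc_auc


def brute_force_stump(X, g, h, lam, gamma):
    """Enumerate every (feature, midpoint) split; closed-form leaf weights."""
    G, H = g.sum(), h.sum()
    parent = G * G / (H + lam)
    best = None
    for j in range(X.shape[1]):
        uniq = np.unique(X[:, j])
        for a, b in zip(uniq[:-1], uniq[1:]):
            thr = (a + b) / 2
            left = X[:, j] < thr
            GL, HL = g[left].sum(), h[left].sum()
            GR, HR = G - GL, H - HL
            gain = 0.5 * (GL**2 / (HL + lam) + GR**2 / (HR + lam) - parent) - gamma
            key = (gain, -j, -thr)
            if best is None or key > best[0]:
                best = (key, (j, thr, -GL / (HL + lam), -GR / (HR + lam)))
    if best is None or best[0][0] <= 0:
        return None
    return best[1]


class TestFitStump:
    def test_closed_form_leaf_weights_on_perfect_split(self):
        """2 benign left, 2 oncogenic right at p=0.5: w = -G/(H+lambda)."""
        X = np.array([[0.0], [0.25], [0.75], [1.0]])
        y = np.array([0, 0, 1, 1])
        p = np.full(4, 0.5)
        g, h = p - y, p * (1 - p)
        stump = fit_stump(X, g, h, lambda_=1.0, gamma_=0.0)
        assert stump.feature_index == 0 and stump.threshold == 0.5
        # left: G = 2*0.5 = 1, H = 0.5 -> w = -1/(1.5)
        assert stump.left_weight == pytest.approx(-1.0 / 1.5)
        assert stump.right_weight == pytest.approx(+1.0 / 1.5)

    def test_homogeneous_gradients_yield_no_split(self):
        X = np.linspace(0, 1, 8).reshape(-1, 1)
        g = np.full(8, 0.5)
        h = np.full(8, 0.25)
        assert fit_stump(X, g, h, 1.0, 0.1) is None

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(30):
            X = rng.normal(size=(30, 3))
            y = rng.integers(0, 2, size=30)
            p = rng.uniform(0.1, 0.9, size=30)
            g, h = p - y, p * (1 - p)
            lam, gamma = 1.0, 0.05
            got = fit_stump(X, g, h, lam, gamma)
            expected = brute_force_stump(X, g, h, lam, gamma)
            if expected is None:
                assert got is None
            else:
                j, thr, wl, wr = expected
                assert got.feature_index == j
                assert got.threshold == pytest.approx(thr)
                assert got.left_weight == pytest.approx(wl)
                assert got.right_weight == pytest.approx(wr)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fit_stump(np.empty((0, 2)), np.array([]), np.array([]))


class TestTraining:
    def test_zero_rounds_predicts_class_frequency(self):
        X = np.zeros((10, 2))
        y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
        model = StumpBoostingClassifier(n_rounds=0).fit(X, y)
        assert model.predict_proba(X)[:, 1] == pytest.approx(0.3)

    def test_linearly_separable_reaches_perfect_training_auc(self, rng):
        x = np.sort(rng.normal(size=40))
        X = x.reshape(-1, 1)
        y = (x > np.median(x)).astype(int)
        model = StumpBoostingClassifier(n_rounds=20).fit(X, y)
        assert roc_auc(y, model.predict_proba(X)[:, 1]) == 1.0

    def test_row_permutation_invariance_exact(self, rng, small_dataset):
        X, y = small_dataset.matrix, small_dataset.labels
        model_a = StumpBoostingClassifier(n_rounds=9).fit(X, y)
        perm = rng.permutation(len(y))
        model_b = StumpBoostingClassifier(n_rounds=9).fit(X[perm], y[perm])
        assert model_a.stumps_ == model_b.stumps_
        assert model_a.base_score_ == model_b.base_score_

    def test_feature_shift_leaves_partitions_unchanged(self, small_dataset):
        X, y = small_dataset.matrix, small_dataset.labels
        model_a = StumpBoostingClassifier(n_rounds=9).fit(X, y)
        shift = np.arange(X.shape[1], dtype=float) * 10.0
        model_b = StumpBoostingClassifier(n_rounds=9).fit(X + shift, y)
        np.testing.assert_allclose(
            model_a.decision_function(X), model_b.decision_function(X + shift),
            atol=1e-9)
        assert [s.feature_index for s in model_a.stumps_] == \
            [s.feature_index for s in model_b.stumps_]

    def test_margins_are_additive_over_rounds(self, small_dataset):
        X, y = small_dataset.matrix, small_dataset.labels
        model = StumpBoostingClassifier(n_rounds=6).fit(X, y)
        margins = np.full(X.shape[0], model.base_score_)
        for stump in model.stumps_:
            margins += model.eta * stump.contributions(X)
        np.testing.assert_allclose(model.decision_function(X), margins, rtol=0, atol=0)

    def test_single_class_labels_fit_base_only_with_warning(self):
        with pytest.warns(UserWarning, match="single-class"):
            model = StumpBoostingClassifier(n_rounds=5).fit(
                np.random.default_rng(0).normal(size=(8, 2)), np.ones(8, dtype=int))
        assert model.stumps_ == []
        assert (model.predict_proba(np.zeros((3, 2)))[:, 1] > 0.5).all()

    def test_column_mismatch_is_shape_error(self, small_dataset):
        model = train(small_dataset.matrix, small_dataset.labels, {"n_rounds": 3})
        with pytest.raises(ShapeError):
            model.predict_proba(np.zeros((2, 5)))

    def test_sklearn_param_protocol(self):
        model = StumpBoostingClassifier(n_rounds=7, eta=0.2)
        assert model.get_params()["n_rounds"] == 7
        model.set_params(eta=0.4)
        assert model.eta == 0.4


class TestReferenceParity:
    def test_margins_match_xgboost_exact_greedy(self, rng):
        """Independent oracle: xgboost depth-1 exact-greedy, same eta/lambda/gamma."""
        xgb = pytest.importorskip("xgboost")
        worst = 0.0
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = r.normal(size=(50, 2))
            y = (X[:, 0] + 0.5 * r.normal(size=50) > 0).astype(int)
            model = StumpBoostingClassifier(
                n_rounds=10, eta=0.3, lambda_=1.0, gamma_=0.0).fit(X, y)
            booster = xgb.train(
                {"max_depth": 1, "eta": 0.3, "reg_lambda": 1.0, "gamma": 0.0,
                 "min_child_weight": 0, "objective": "binary:logistic",
                 "tree_method": "exact", "base_score": float(y.mean()),
                 "nthread": 1},
                xgb.DMatrix(X, label=y), num_boost_round=10)
            ref = booster.predict(xgb.DMatrix(X), output_margin=True)
            worst = max(worst, float(np.abs(model.decision_function(X) - ref).max()))
        assert worst <= 1e-6


class TestTreeBaseline:
    def test_depth_one_agrees_with_stump_split(self, rng):
        X = rng.normal(size=(40, 3))
        y = (X[:, 1] > 0).astype(int)
        tree = GiniTreeClassifier(depth=1).fit(X, y)
        p = np.full(len(y), y.mean())
        stump = fit_stump(X, p - y, p * (1 - p), 1.0, 0.0)
        assert tree.tree_.feature_index == stump.feature_index
        assert tree.tree_.threshold == pytest.approx(stump.threshold)

    def test_pure_node_stops_splitting(self):
        X = np.arange(6, dtype=float).reshape(-1, 1)
        y = np.ones(6, dtype=int)
        tree = GiniTreeClassifier(depth=3).fit(X, y)
        assert tree.tree_.feature_index is None

    def test_chosen_split_maximises_gini_gain(self, rng):
        for _ in range(10):
            X = rng.normal(size=(25, 2))
            y = rng.integers(0, 2, size=25)
            if y.min() == y.max():
                continue
            tree = GiniTreeClassifier(depth=1).fit(X, y)
            if tree.tree_.feature_index is None:
                continue

            def weighted_gini(mask):
                total = 0.0
                for side in (mask, ~mask):
                    if side.sum():
                        p = y[side].mean()
                        total += side.sum() * 2 * p * (1 - p)
                return total

            chosen = weighted_gini(
                X[:, tree.tree_.feature_index] < tree.tree_.threshold)
            for j in range(2):
                uniq = np.unique(X[:, j])
                for thr in (uniq[:-1] + uniq[1:]) / 2:
                    assert chosen <= weighted_gini(X[:, j] < thr) + 1e-12


class TestBaselineScoresAndRendering:
    def test_orientation(self):
        v = np.array([0.2, -0.5, 0.9])
        np.testing.assert_array_equal(score_baseline(v), v)
        np.testing.assert_array_equal(
            score_baseline(v, "lower-is-oncogenic"), -v)

    def test_antisymmetry_of_auc(self, rng):
        y = rng.integers(0, 2, size=50)
        y[0], y[1] = 0, 1
        scores = rng.normal(size=50)  # continuous: tie-free
        assert roc_auc(y, scores) + roc_auc(y, -scores) == pytest.approx(1.0)

    @pytest.mark.parametrize("p,expected", [
        (0.995, "oncogenic, 100% confidence"),
        (0.81, "oncogenic, 81% confidence"),
        (0.19, "neutral, 81% confidence"),
        (0.5, "neutral, 50% confidence"),
    ])
    def test_confidence_rendering(self, p, expected):
        assert render_prediction(p) == expected

    def test_probability_complement_sums_to_one(self, small_dataset):
        model = train(small_dataset.matrix, small_dataset.labels, {"n_rounds": 5})
        proba = model.predict_proba(small_dataset.matrix)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
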