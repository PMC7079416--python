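import numpy as np
import pytest

from miress.gbm import (
    BoostedEnsemble,
    BoostParams,
    ModelError,
    feature_importance,
    find_best_split,
    fit,
    leaf_weight,
    load_model,
    logistic_grad_hess,
    predict,
    predict_raw,
    save_model,
    split_gain,
)


def sigmoid(x):
    return 1 / (1 + np.exp(-x))


def log_loss(y, p):
    eps = 1e-12
    return float(-(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)).mean())


def brute_force_best_split(X, g, h, lam, gamma, min_child_hessian):
    """Independent exhaustive search over every (feature, midpoint) split."""
    best = None
    n, d = X.shape
    for f in range(d):
        vals = np.unique(X[:, f])
        for lo, hi in zip(vals, vals[1:]):
            thr = (lo + hi) / 2
            if thr >= hi:
                thr = lo
            mask = X[:, f] <= thr
            GL, HL = g[mask].sum(), h[mask].sum()
            GR, HR = g[~mask].sum(), h[~mask].sum()
            if HL < min_child_hessian or HR < min_child_hessian:
                continue
            gain = split_gain(GL, HL, GR, HR, lam, gamma)
            if gain > 0 and (best is None or gain > best[2] + 1e-15):
                best = (f, thr, gain)
    return best


class TestLogisticGradHess:
    @pytest.mark.parametrize(
        "y,raw,g,h",
        [(1, 0.0, -0.5, 0.25), (0, 0.0, 0.5, 0.25), (1, 40.0, 0.0, 0.0)],
    )
    def test_values(self, y, raw, g, h):
        gg, hh = logistic_grad_hess(np.array([y]), np.array([raw]))
        assert gg[0] == pytest.approx(g, abs=1e-12)
        assert hh[0] == pytest.approx(h, abs=1e-12)


class TestLeafWeight:
    @pytest.mark.parametrize(
        "G,H,lam,w", [(0, 5, 1, 0.0), (2, 3, 1, -0.5), (-1, 0, 1, 1.0)]
    )
    def test_values(self, G, H, lam, w):
        assert leaf_weight(G, H, lam) == w

    def test_degenerate_denominator_rejected(self):
        with pytest.raises(ModelError):
            leaf_weight(1.0, 0.0, 0.0)

    def test_l2_monotonically_shrinks_weights(self):
        lams = np.linspace(0, 5, 20)
        ws = [abs(leaf_weight(2.0, 1.0, lam)) for lam in lams]
        assert all(a >= b for a, b in zip(ws, ws[1:]))


class TestSplitGain:
    def test_antisymmetric_gradients_gain(self):
        assert split_gain(-1, 1, 1, 1, 0, 0) == pytest.approx(1.0)

    def test_symmetric_halves_no_gain(self):
        assert split_gain(1, 1, 1, 1, 0, 0) == pytest.approx(0.0)

    def test_gamma_is_an_additive_penalty(self):
        base = split_gain(-1, 1, 1, 1, 0, 0)
        assert split_gain(-1, 1, 1, 1, 0, 0.5) == pytest.approx(base - 0.5)


class TestFindBestSplit:
    def test_constant_matrix_has_no_split(self):
        X = np.ones((6, 3))
        g = np.linspace(-1, 1, 6)
        h = np.full(6, 0.25)
        assert find_best_split(X, g, h, 0.0, 0.0) is None

    def test_two_point_hand_example(self):
        X = np.array([[0.0], [1.0]])
        g = np.array([0.5, -0.5])
        h = np.array([0.25, 0.25])
        feat, thr, gain = find_best_split(X, g, h, 0.0, 0.0)
        assert feat == 0
        assert thr == pytest.approx(0.5)
        assert gain == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, d = int(rng.integers(5, 40)), int(rng.integers(1, 5))
        X = np.round(rng.normal(size=(n, d)), 2)  # induce ties
        g = rng.normal(size=n)
        h = rng.uniform(0.01, 0.3, size=n)
        lam, gamma, mch = 0.5, 0.01, 0.05
        got = find_best_split(X, g, h, lam, gamma, mch)
        want = brute_force_best_split(X, g, h, lam, gamma, mch)
        if want is None:
            assert got is None
        else:
            assert got is not None
            assert got[2] == pytest.approx(want[2], rel=1e-9)


class TestFit:
    def test_two_point_hand_example(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        params = BoostParams(n_rounds=1, max_depth=1, lam=0.0, eta=1.0,
                             min_child_hessian=0.0)
        model = fit(X, y, params)
        weights = model.trees[0].predict_weight(X)
        np.testing.assert_allclose(weights, [-2.0, 2.0])
        np.testing.assert_allclose(
            predict(model, X), [sigmoid(-2), sigmoid(2)], atol=1e-12
        )

    def test_single_leaf_tree_uses_closed_form_weight(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        y = (rng.random(20) < 0.4).astype(int)
        lam = 0.7
        model = fit(X, y, BoostParams(n_rounds=1, max_depth=0, lam=lam))
        g, h = logistic_grad_hess(y, np.zeros(20))
        expected = -g.sum() / (h.sum() + lam)
        assert model.trees[0].root["weight"] == expected  # exact

    def test_saturation_gives_near_zero_late_weights(self):
        # once |raw| > 7 the gradients saturate (g ~ e^-|raw|), so with the
        # L2 penalty in the denominator late trees contribute almost nothing
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        params = BoostParams(n_rounds=2500, max_depth=1, lam=1.0, eta=1.0,
                             min_child_hessian=0.0)
        model = fit(X, y, params)
        raw = predict_raw(model, X)
        assert np.abs(raw).min() > 7
        last = model.trees[-1].predict_weight(X)
        assert np.abs(last).max() < 1e-3

    def test_training_log_loss_non_increasing(self, small_features):
        X, y, _ = small_features
        params = BoostParams(n_rounds=15, max_depth=3, eta=0.5)
        model = fit(X, y, params)
        losses = []
        raw = np.zeros(len(y))
        for tree in model.trees:
            raw = raw + params.eta * tree.predict_weight(X)
            losses.append(log_loss(y, sigmoid(raw)))
        assert all(a >= b - 1e-12 for a, b in zip(losses, losses[1:]))

    def test_separable_fixture_orders_classes(self, small_features):
        X, y, _ = small_features
        model = fit(X, y, BoostParams(n_rounds=20, max_depth=3))
        p = predict(model, X)
        assert p[y == 1].min() > p[y == 0].max()

    def test_single_class_rejected(self):
        with pytest.raises(ModelError, match="both classes"):
            fit(np.zeros((4, 2)), np.ones(4, dtype=int))

    def test_nan_rejected(self):
        X = np.zeros((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ModelError, match="NaN"):
            fit(X, np.array([0, 1, 0, 1]))

    def test_gamma_prunes_leaves(self, small_features):
        X, y, _ = small_features
        leaves = []
        for gamma in (0.0, 0.5, 5.0):
            params = BoostParams(n_rounds=3, max_depth=4, gamma=gamma,
                                 min_child_hessian=0.0)
            model = fit(X, y, params)
            leaves.append(sum(t.n_leaves for t in model.trees))
        assert leaves[0] >= leaves[1] >= leaves[2]

    def test_deterministic(self, small_features):
        X, y, _ = small_features
        params = BoostParams(n_rounds=5, max_depth=3)
        a, b = fit(X, y, params), fit(X, y, params)
        assert [t.root for t in a.trees] == [t.root for t in b.trees]


class TestPredict:
    def test_empty_tree_list_scores_half(self):
        model = BoostedEnsemble(trees=[], params=BoostParams(),
                                feature_names=["a", "b"])
        np.testing.assert_array_equal(predict(model, np.zeros((3, 2))), 0.5)

    def test_column_mismatch_rejected(self, small_features):
        X, y, _ = small_features
        model = fit(X, y, BoostParams(n_rounds=1, max_depth=1))
        with pytest.raises(ModelError, match="feature columns"):
            predict(model, X[:, :5])


class TestImportance:
    def test_single_feature_model_gets_all_importance(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([0, 1])
        model = fit(X, y, BoostParams(n_rounds=2, max_depth=1, lam=0.0, eta=1.0,
                                      min_child_hessian=0.0))
        imp = feature_importance(model)
        assert imp["f0"] == pytest.approx(1.0)

    def test_importances_sum_to_one(self, small_features):
        X, y, _ = small_features
        model = fit(X, y, BoostParams(n_rounds=5, max_depth=3))
        assert sum(feature_importance(model).values()) == pytest.approx(1.0, abs=1e-12)

    def test_no_split_model_warns_and_zeroes(self):
        X = np.ones((6, 2))
        y = np.array([0, 1] * 3)
        model = fit(X, y, BoostParams(n_rounds=1, max_depth=2))
        with pytest.warns(UserWarning, match="no splits"):
            imp = feature_importance(model)
        assert all(v == 0 for v in imp.values())

    def test_planted_two_feature_signal_recovered(self):
        rng = np.random.default_rng(4)
        n, d = 120, 8
        X = rng.normal(size=(n, d))
        y = (X[:, 2] + X[:, 5] + 0.3 * rng.normal(size=n) > 0).astype(int)
        model = fit(X, y, BoostParams(n_rounds=25, max_depth=3, eta=0.3))
        imp = feature_importance(model)
        top2 = sorted(imp, key=imp.get)[-2:]
        assert set(top2) == {"f2", "f5"}


class TestSerialization:
    def test_round_trip_predicts_identically(self, small_features, tmp_path):
        X, y, _ = small_features
        model = fit(X, y, BoostParams(n_rounds=4, max_depth=3),
                    feature_names=[f"feat{i}" for i in range(X.shape[1])])
        p = tmp_path / "model.json"
        save_model(model, p)
        loaded = load_model(p)
        np.testing.assert_array_equal(predict(model, X), predict(loaded, X))
        assert loaded.feature_names == model.feature_names
        assert loaded.params == model.params

    def test_truncated_file_rejected(self, small_features, tmp_path):
        X, y, _ = small_features
        model = fit(X, y, BoostParams(n_rounds=1, max_depth=1))
        p = tmp_path / "model.json"
        save_model(model, p)
        p.write_text(p.read_text()[: len(p.read_text()) // 2])
        with pytest.raises(ModelError):
            load_model(p)

    def test_non_model_json_rejected(self, tmp_path):
        p = tmp_path / "x.json"
        p.write_text('{"hello": 1}')
        with pytest.raises(ModelError, match="not a model"):
            load_model(p)


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_rounds": 0},
            {"max_depth": -1},
            {"eta": 0.0},
            {"eta": 1.5},
            {"lam": -1.0},
            {"gamma": -0.1},
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ModelError):
            BoostParams(**kwargs)
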