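import json

import numpy as np
import pandas as pd
import pytest

from mixboost.boosting import BoostedEnsemble, GbmParams, TreeArrays, fit_ensemble


def test_param_validation():
    with pytest.raises(ValueError):
        GbmParams(depth=0)
    with pytest.raises(ValueError):
        GbmParams(shrinkage=0.0)
    with pytest.raises(ValueError):
        GbmParams(subsample=1.5)
    with pytest.raises(ValueError):
        GbmParams(loss="poisson")


def test_zero_trees_predicts_constant():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((30, 2))
    y = rng.standard_normal(30)
    ens = fit_ensemble(X, y, GbmParams(n_trees=0))
    assert np.allclose(ens.predict(X), y.mean())
    ens = fit_ensemble(X, y, GbmParams(n_trees=0, loss="absolute"))
    assert np.allclose(ens.predict(X), np.median(y))


def test_single_stump_closed_form():
    # eta=1, lambda=1, d=1, M=1, squared loss on a balanced step function:
    # alpha = 0.5 and the stump's leaf means are -+0.5, so predictions hit
    # 0 and 1 exactly
    x = np.repeat([-1.0, 1.0], 20)[:, None]
    y = (x[:, 0] > 0).astype(float)
    params = GbmParams(n_trees=1, depth=1, shrinkage=1.0, subsample=1.0, seed=0)
    ens = fit_ensemble(x, y, params)
    assert np.allclose(ens.predict(x), y)


def test_training_mse_nonincreasing_with_full_sample():
    rng = np.random.default_rng(1)
    X = rng.standard_normal((100, 4))
    y = X[:, 0] ** 2 + rng.standard_normal(100)
    params = GbmParams(n_trees=60, depth=2, shrinkage=0.3, subsample=1.0, seed=2)
    ens = fit_ensemble(X, y, params)
    staged = ens.staged_predict(X, at=range(0, 61, 5))
    mses = [np.mean((y - staged[m]) ** 2) for m in sorted(staged)]
    assert all(b <= a + 1e-12 for a, b in zip(mses, mses[1:]))


def test_reproducibility_same_seed():
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
    y = rng.standard_normal(60)
    for backend in ("exact", "hist"):
        params = GbmParams(n_trees=15, depth=2, subsample=0.5, seed=42,
                           backend=backend, min_obs_per_leaf=5)
        p1 = fit_ensemble(X, y, params).predict(X)
        p2 = fit_ensemble(X, y, params).predict(X)
        assert np.array_equal(p1, p2)


def test_staged_prediction_is_additive(small_fit):
    ens, X, y = small_fit
    staged = ens.staged_predict(X, at=[0, 10, 39, 40])
    assert np.allclose(staged[0], ens.alpha)
    assert np.allclose(staged[40], ens.predict(X))
    # consecutive stages differ exactly by one shrunk tree
    contrib = ens.value_scale * ens.trees[39].predict(X.to_numpy(dtype=float))
    assert np.allclose(staged[40] - staged[39], contrib)


def test_predict_rejects_bad_tree_count(small_fit):
    ens, X, _ = small_fit
    with pytest.raises(ValueError):
        ens.predict(X, n_trees=ens.n_trees + 1)


def test_predict_requires_training_columns(small_fit):
    ens, X, _ = small_fit
    with pytest.raises(ValueError, match="missing training columns"):
        ens.predict(X.drop(columns=["a"]))


def test_non_finite_outcome_rejected():
    X = np.zeros((30, 2))
    y = np.zeros(30)
    y[0] = np.nan
    with pytest.raises(ValueError, match="non-finite"):
        fit_ensemble(X, y, GbmParams(n_trees=2))


def test_absolute_loss_fits_median_structure():
    # an asymmetric-outlier design: absolute loss tracks the median level
    rng = np.random.default_rng(8)
    x = np.repeat([-1.0, 1.0], 30)[:, None]
    y = np.where(x[:, 0] > 0, 1.0, 0.0) + rng.standard_normal(60) * 0.01
    y[0] = 50.0  # gross outlier
    params = GbmParams(n_trees=30, depth=1, shrinkage=0.5, subsample=1.0,
                       loss="absolute", seed=1)
    ens = fit_ensemble(x, y, params)
    pred = ens.predict(np.array([[-1.0], [1.0]]))
    assert pred[0] == pytest.approx(0.0, abs=0.05)
    assert pred[1] == pytest.approx(1.0, abs=0.05)


class TestImportance:
    def test_single_variable_stump(self):
        x = np.linspace(-1, 1, 40).reshape(-1, 2)  # 20 rows, 2 cols
        rng = np.random.default_rng(0)
        X = rng.standard_normal((40, 3))
        y = (X[:, 1] > 0).astype(float)
        ens = fit_ensemble(X, y, GbmParams(n_trees=1, depth=1, shrinkage=1.0,
                                           subsample=1.0, seed=0))
        imp = ens.variable_importance()
        assert imp["x1"] == 100.0
        assert imp["x0"] == 0.0 and imp["x2"] == 0.0

    def test_max_is_100_after_scaling(self, small_fit):
        ens, _, _ = small_fit
        imp = ens.variable_importance()
        assert imp.max() == pytest.approx(100.0)
        assert (imp >= 0).all()

    def test_constant_outcome_gives_zero_importance(self):
        X = np.random.default_rng(0).standard_normal((40, 3))
        y = np.ones(40)
        ens = fit_ensemble(X, y, GbmParams(n_trees=5, depth=2, subsample=1.0))
        assert (ens.variable_importance() == 0).all()


class TestSerialization:
    def test_json_round_trip(self, small_fit):
        ens, X, _ = small_fit
        restored = BoostedEnsemble.from_json(ens.to_json())
        assert np.allclose(restored.predict(X), ens.predict(X))
        assert restored.columns == ens.columns
        assert restored.params == ens.params

    def test_hist_backend_round_trip(self, interaction_xy):
        X, y = interaction_xy
        params = GbmParams(n_trees=20, depth=3, subsample=0.5, seed=1,
                           backend="hist", min_obs_per_leaf=5)
        ens = fit_ensemble(X, y, params)
        restored = BoostedEnsemble.from_json(ens.to_json())
        assert np.allclose(restored.predict(X), ens.predict(X))

    def test_payload_is_documented_json(self, small_fit):
        ens, _, _ = small_fit
        payload = json.loads(ens.to_json())
        assert set(payload) == {"alpha", "value_scale", "params", "columns", "trees"}
        assert len(payload["trees"]) == ens.n_trees


class TestTreeArrays:
    def test_weight_fractions_sum_to_parent(self, small_fit):
        ens, _, _ = small_fit
        for tree in ens.trees[:5]:
            internal = np.nonzero(tree.feature >= 0)[0]
            for i in internal:
                child_sum = tree.weight[tree.left[i]] + tree.weight[tree.right[i]]
                assert child_sum == pytest.approx(tree.weight[i])
            assert tree.weight[0] == pytest.approx(1.0)
            assert (tree.improvement[internal] >= 0).all()
            assert tree.max_depth() <= ens.params.depth

    def test_nested_construction_and_prediction(self):
        tree = TreeArrays.from_nested(
            {
                "feature": 0,
                "threshold": 0.0,
                "left": {"value": -1.0},
                "right": {"value": 1.0},
            }
        )
        X = np.array([[-2.0], [3.0]])
        assert np.array_equal(tree.predict(X), [-1.0, 1.0])
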