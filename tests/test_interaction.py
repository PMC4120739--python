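import numpy as np
import pandas as pd
import pytest

from mixboost.boosting import BoostedEnsemble, GbmParams, TreeArrays, fit_ensemble
from mixboost.interaction import (
    assessments_to_frame,
    h_higher,
    h_pairwise,
    h_statistic,
    h_total,
    make_null_outcome,
    null_distribution,
    split_stability,
)


def _pm1_design(k):
    """Full factorial +-1 design over k variables."""
    grids = np.meshgrid(*([[-1.0, 1.0]] * k), indexing="ij")
    return pd.DataFrame(
        np.column_stack([g.ravel() for g in grids]),
        columns=[f"x{j}" for j in range(k)],
    )


def _product_tree():
    # encodes f(x0, x1) = x0 * x1 on the +-1 design
    return TreeArrays.from_nested(
        {
            "feature": 0, "threshold": 0.0,
            "left": {"feature": 1, "threshold": 0.0,
                     "left": {"value": 1.0}, "right": {"value": -1.0}},
            "right": {"feature": 1, "threshold": 0.0,
                      "left": {"value": -1.0}, "right": {"value": 1.0}},
        }
    )


def _parity_tree():
    # f(x0,x1,x2) = x0*x1*x2 on the +-1 design (three-way parity)
    def sub(depth, sign):
        if depth == 3:
            return {"value": float(sign)}
        return {
            "feature": depth, "threshold": 0.0,
            "left": sub(depth + 1, -sign), "right": sub(depth + 1, sign),
        }

    return TreeArrays.from_nested(sub(0, 1))


class TestObservedH:
    def test_pure_product_interaction_is_one(self):
        # enumeration oracle: on the balanced design the centered 1-D PDs
        # vanish by symmetry, so the whole joint PD is interaction
        X = _pm1_design(2)
        ens = BoostedEnsemble(0.0, [_product_tree()], GbmParams(n_trees=1, depth=2),
                              list(X.columns), value_scale=1.0)
        assert h_pairwise(ens, "x0", "x1", X) == pytest.approx(1.0)

    def test_parity_three_way_is_one(self):
        X = _pm1_design(3)
        ens = BoostedEnsemble(0.0, [_parity_tree()], GbmParams(n_trees=1, depth=3),
                              list(X.columns), value_scale=1.0)
        assert h_higher(ens, ["x0", "x1", "x2"], X) == pytest.approx(1.0)
        # its pairwise margins carry no interaction on the balanced design
        assert h_pairwise(ens, "x0", "x1", X) == pytest.approx(0.0, abs=1e-8)

    def test_additive_stump_fit_has_zero_h(self, interaction_xy):
        X, y = interaction_xy
        params = GbmParams(n_trees=40, depth=1, shrinkage=0.3, subsample=1.0,
                           min_obs_per_leaf=5, seed=2)
        ens = fit_ensemble(X, y, params)
        assert h_pairwise(ens, "a", "b", X) == pytest.approx(0.0, abs=1e-8)
        assert h_total(ens, "a", X) == pytest.approx(0.0, abs=1e-8)

    def test_h_range_and_symmetry(self, small_fit):
        ens, X, _ = small_fit
        h_ab = h_pairwise(ens, "a", "b", X)
        assert 0.0 <= h_ab <= 1.0 + 1e-8
        assert h_ab == pytest.approx(h_pairwise(ens, "b", "a", X))
        h_abc = h_higher(ens, ["a", "b", "c"], X)
        assert h_abc == pytest.approx(h_higher(ens, ["c", "a", "b"], X))

    def test_detects_the_real_interaction(self, small_fit):
        # y = a*b + sin(c): the (a, b) pair carries far more interaction
        # than any pair involving the additive variable c
        ens, X, _ = small_fit
        assert h_pairwise(ens, "a", "b", X) > 3 * h_pairwise(ens, "a", "c", X)

    def test_single_variable_model_has_zero_total_h(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        y = np.where(X["a"] > 0, 1.0, -1.0)
        ens = fit_ensemble(X, y, GbmParams(n_trees=5, depth=2, shrinkage=1.0,
                                           subsample=1.0, seed=0))
        if (ens.variable_importance()[["b", "c"]] == 0).all():
            assert h_total(ens, "a", X) == pytest.approx(0.0, abs=1e-8)

    def test_location_invariance(self, interaction_xy):
        # adding a constant to y shifts alpha only; H is unchanged
        X, y = interaction_xy
        params = GbmParams(n_trees=30, depth=2, shrinkage=0.3, subsample=1.0,
                           min_obs_per_leaf=5, seed=4)
        h0 = h_pairwise(fit_ensemble(X, y, params), "a", "b", X)
        h1 = h_pairwise(fit_ensemble(X, y + 100.0, params), "a", "b", X)
        assert h0 == pytest.approx(h1, abs=1e-8)

    def test_degenerate_denominator_returns_zero_with_warning(self):
        X = _pm1_design(2)
        tree = TreeArrays.from_nested(
            {"feature": 0, "threshold": 0.0,
             "left": {"value": 0.0}, "right": {"value": 0.0}}
        )
        ens = BoostedEnsemble(0.0, [tree], GbmParams(n_trees=1, depth=1),
                              list(X.columns), value_scale=1.0)
        with pytest.warns(UserWarning, match="identically zero"):
            assert h_pairwise(ens, "x0", "x1", X) == 0.0


class TestNullOutcome:
    def test_identity_permutation_returns_y(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(20)
        fa = rng.standard_normal(20)
        assert np.array_equal(make_null_outcome(fa, y, np.arange(20)), y)

    def test_mean_preserved_exactly(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(50)
        fa = rng.standard_normal(50)
        perm = rng.permutation(50)
        y_tilde = make_null_outcome(fa, y, perm)
        assert y_tilde.mean() == pytest.approx(y.mean(), abs=1e-12)

    def test_zero_residuals_give_additive_fit(self):
        rng = np.random.default_rng(2)
        fa = rng.standard_normal(30)
        perm = rng.permutation(30)
        assert np.allclose(make_null_outcome(fa, fa, perm), fa)

    def test_invalid_permutation_rejected(self):
        with pytest.raises(ValueError, match="bijection"):
            make_null_outcome(np.zeros(5), np.zeros(5), [0, 0, 1, 2, 3])


class TestNullDistribution:
    @pytest.fixture(scope="class")
    def assessments(self, interaction_xy):
        X, y = interaction_xy
        params = GbmParams(n_trees=40, depth=2, shrinkage=0.2, subsample=1.0,
                           min_obs_per_leaf=5, seed=0)
        return null_distribution(
            X, y, params, [("a", "b"), ("a", "c"), ("a",)], n_rep=25, seed=9
        )

    def test_null_sample_count(self, assessments):
        assert all(len(a.null_samples) == 25 for a in assessments)
        assert all((a.null_samples >= 0).all() for a in assessments)

    def test_true_interaction_flagged_null_pair_not(self, assessments):
        by_subset = {a.subset: a for a in assessments}
        assert by_subset[("a", "b")].significant
        assert not by_subset[("a", "c")].significant

    def test_percentile_consistency(self, assessments):
        a = assessments[0]
        assert a.null_p95 == pytest.approx(np.percentile(a.null_samples, 95))
        p5, p50, p95 = a.null_percentiles()
        assert p5 <= p50 <= p95

    def test_small_n_rep_warns(self, interaction_xy):
        X, y = interaction_xy
        params = GbmParams(n_trees=5, depth=2, subsample=1.0, min_obs_per_leaf=5)
        with pytest.warns(UserWarning, match="unstable"):
            null_distribution(X, y, params, [("a", "b")], n_rep=3, seed=0)

    def test_record_export(self, assessments):
        frame = assessments_to_frame(assessments)
        assert list(frame.columns) == [
            "subset", "order", "h_observed",
            "null_p5", "null_p50", "null_p95", "significant",
        ]
        assert frame.loc[0, "subset"] == "a * b"


class TestSplitStability:
    def test_true_interaction_is_stable(self, interaction_xy):
        X, y = interaction_xy
        # larger sample so that half-splits still support the fit
        rng = np.random.default_rng(3)
        Xl = pd.DataFrame(rng.standard_normal((240, 4)), columns=list("abcd"))
        yl = (Xl["a"] * Xl["b"] + 0.3 * rng.standard_normal(240)).to_numpy()
        params = GbmParams(n_trees=40, depth=2, shrinkage=0.2, subsample=1.0,
                           min_obs_per_leaf=5, seed=0)
        res = split_stability(Xl, yl, params, [("a", "b"), ("c", "d")],
                              n_repeats=4, null_rep=25, seed=7)
        by_subset = {r.subset: r for r in res}
        assert by_subset[("a", "b")].n_detected == 4
        assert by_subset[("c", "d")].n_detected <= 1
        assert all(0 <= r.n_detected <= r.n_repeats for r in res)
        assert str(by_subset[("a", "b")]) == "4/4"


def test_h_statistic_dispatch(small_fit):
    ens, X, _ = small_fit
    assert h_statistic(ens, "a", X) == pytest.approx(h_total(ens, "a", X))
    assert h_statistic(ens, ["a", "b"], X) == pytest.approx(
        h_pairwise(ens, "a", "b", X)
    )
    assert h_statistic(ens, ["a", "b", "c"], X) == pytest.approx(
        h_higher(ens, ["a", "b", "c"], X)
    )
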