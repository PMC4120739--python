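"""Model / Results interface tying the pieces together.

`BoostedTreeModel` holds the data and hyper-parameters;
:meth:`BoostedTreeModel.fit` returns a :class:`BoostedTreeResults`
carrying the fitted ensemble with variable importance, partial
dependence, H statistics with parametric-bootstrap nulls, split-sample
stability and a text summary.  A typical session::

    model = BoostedTreeModel.from_dataframe(data, outcome="y")
    tuning = model.tune(d_values=[1, 3, 6], m_grid=range(500, 3501, 500))
    res = model.fit(tuning.best_params())
    res.variable_importance().head(10)
    tests = res.interaction_test([("p-p'-DDE", "PCB 170")], n_rep=250)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .boosting import BoostedEnsemble, GbmParams, fit_ensemble
from .interaction import (
    h_statistic,
    null_distribution,
    split_stability,
)
from .pd import PDFunction, pd_brute, pd_recursion, percentile_grid
from .tuning import TuningResult, bootstrap_tune

__all__ = ["BoostedTreeModel", "BoostedTreeResults"]


class BoostedTreeModel:
    """Boosted regression trees for a continuous outcome.

    Parameters
    ----------
    y : array-like
        Continuous outcome, one value per row of ``X``.
    X : DataFrame
        Numeric exposure table (continuous exposures and optional binary
        covariates); no missing values.
    params : GbmParams, optional
        Default hyper-parameters used by :meth:`fit` when none are given.
    """

    def __init__(self, y, X, params: GbmParams | None = None) -> None:
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
            X.columns = [f"x{j}" for j in range(X.shape[1])]
        bad = [c for c in X.columns if not np.issubdtype(X[c].dtype, np.number)]
        if bad:
            raise ValueError(f"non-numeric predictor columns: {bad}")
        if X.isna().any().any():
            raise ValueError("X contains missing values")
        y = np.asarray(y, dtype=float).ravel()
        if not np.isfinite(y).all():
            raise ValueError("y contains non-finite values")
        if len(y) != len(X):
            raise ValueError("y and X differ in length")
        self.X = X.reset_index(drop=True)
        self.y = y
        self.params = params or GbmParams()
        self.tuning_: TuningResult | None = None

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str = "y",
        params: GbmParams | None = None,
        log_outcome: bool = False,
    ) -> "BoostedTreeModel":
        """Build from one table holding predictors and the outcome column."""
        if outcome not in data.columns:
            raise ValueError(f"outcome column {outcome!r} not in data")
        y = data[outcome].to_numpy(dtype=float)
        if log_outcome:
            if (y <= 0).any():
                raise ValueError("log transform requires a positive outcome")
            y = np.log(y)
        return cls(y, data.drop(columns=[outcome]), params=params)

    # ------------------------------------------------------------------
    def tune(
        self,
        d_values=(1, 2, 3, 4, 5, 6),
        m_grid=None,
        n_boot: int = 25,
        seed: int | None = None,
        params: GbmParams | None = None,
    ) -> TuningResult:
        """Bootstrap grid search; remembers the result for later fits."""
        if m_grid is None:
            m_grid = list(range(500, 4001, 500))
        res = bootstrap_tune(
            self.X, self.y, d_values, m_grid, n_boot=n_boot,
            params=params or self.params, seed=seed,
        )
        self.tuning_ = res
        return res

    def fit(self, params: GbmParams | None = None, **overrides) -> "BoostedTreeResults":
        params = params or (
            self.tuning_.best_params(self.params) if self.tuning_ else self.params
        )
        if overrides:
            params = params.replace(**overrides)
        ensemble = fit_ensemble(self.X, self.y, params)
        return BoostedTreeResults(self, ensemble)


class BoostedTreeResults:
    """Fitted boosted-tree ensemble with interpretation tools."""

    def __init__(self, model: BoostedTreeModel, ensemble: BoostedEnsemble) -> None:
        self.model = model
        self.ensemble = ensemble
        self.params = ensemble.params

    # -- predictions ----------------------------------------------------
    def predict(self, X=None, n_trees: int | None = None) -> np.ndarray:
        return self.ensemble.predict(
            self.model.X if X is None else X, n_trees=n_trees
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    @property
    def resid(self) -> np.ndarray:
        return self.model.y - self.fittedvalues

    @property
    def rsquared(self) -> float:
        """Training (apparent) R^2; see :func:`mixboost.tuning.bootstrap_tune`
        for validated performance."""
        y = self.model.y
        return float(1.0 - np.mean(self.resid**2) / np.var(y))

    # -- interpretation -------------------------------------------------
    def variable_importance(self) -> pd.Series:
        return self.ensemble.variable_importance()

    def top_variables(self, k: int = 10) -> list[str]:
        return list(self.variable_importance().head(k).index)

    def partial_dependence(
        self,
        subset,
        points=None,
        method: str = "recursion",
        grid: bool = False,
        grid_points: int = 40,
    ) -> PDFunction:
        """Centered partial dependence of a variable subset.

        By default evaluated at the observed data rows (as the H
        statistics require); ``grid=True`` evaluates on a regular grid
        between the 10th and 90th percentile of each subset variable
        (for plots).
        """
        if isinstance(subset, (str, int)):
            subset = [subset]
        if grid:
            if points is not None:
                raise ValueError("give either grid=True or explicit points")
            axes = [
                percentile_grid(self.model.X[c], n_points=grid_points)
                for c in subset
            ]
            mesh = np.meshgrid(*axes, indexing="ij")
            points = np.column_stack([m.ravel() for m in mesh])
        if method == "recursion":
            return pd_recursion(self.ensemble, subset, points=points, X=self.model.X)
        if method == "brute":
            return pd_brute(self.ensemble, subset, self.model.X, points=points)
        raise ValueError("method must be 'recursion' or 'brute'")

    def h(self, subset) -> float:
        """Observed H statistic for a subset (1 = total, 2 = pairwise, ...)."""
        return h_statistic(self.ensemble, subset, self.model.X)

    def interaction_test(self, subsets, n_rep: int = 250,
                         seed: int | None = None, h_rows: int | None = None):
        """H with parametric-bootstrap null for each subset."""
        return null_distribution(
            self.model.X, self.model.y, self.params, subsets,
            n_rep=n_rep, seed=seed, ensemble=self.ensemble, h_rows=h_rows,
        )

    def split_stability(
        self, subsets, n_repeats: int = 10, null_rep: int = 50,
        seed: int | None = None,
    ):
        return split_stability(
            self.model.X, self.model.y, self.params, subsets,
            n_repeats=n_repeats, null_rep=null_rep, seed=seed,
        )

    # -- reporting ------------------------------------------------------
    def summary(self, top: int = 10) -> str:
        p = self.params
        imp = self.variable_importance().head(top)
        lines = [
            "Boosted regression trees",
            "=" * 44,
            f"observations:     {len(self.model.y)}",
            f"predictors:       {len(self.ensemble.columns)}",
            f"loss:             {p.loss}",
            f"trees (M):        {p.n_trees}",
            f"depth (d):        {p.depth}",
            f"shrinkage:        {p.shrinkage}",
            f"subsample:        {p.subsample}",
            f"backend:          {p.backend}",
            f"training R2:      {self.rsquared:.3f}",
            "",
            f"variable importance (top {top}, max = 100)",
            "-" * 44,
        ]
        lines += [f"{name:<20s} {val:8.1f}" for name, val in imp.items()]
        return "\n".join(lines)

    def save(self, path) -> None:
        self.ensemble.to_json(path)

    @classmethod
    def load(cls, path, model: BoostedTreeModel) -> "BoostedTreeResults":
        return cls(model, BoostedEnsemble.from_json(path))
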