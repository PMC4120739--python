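"""Bootstrap-validated grid search over ensemble size and tree depth.

For each bootstrap replicate the model is fitted once per depth at the
largest requested number of trees; staged predictions on the
out-of-bootstrap rows then provide the whole tree-count axis from that
single fit.  Performance is summarised as out-of-bootstrap RMSE and
R^2 = 1 - MSE/var(y_holdout), averaged across replicates, with the
standard error of R^2 across replicates.

The final choice uses the one-standard-error rule: among all grid points
whose mean R^2 is within one SE (at the optimum) of the best mean R^2,
take the most parsimonious — smallest depth first, then fewest trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boosting import GbmParams, fit_ensemble

__all__ = ["TuningResult", "bootstrap_tune", "one_se_select"]


@dataclass
class TuningResult:
    grid: pd.DataFrame          # depth, n_trees, mean_rmse, mean_r2, se_r2
    optimal: tuple[int, int]    # (depth, n_trees) maximising mean R^2
    one_se_choice: tuple[int, int]
    n_boot: int

    def best_params(self, base: GbmParams | None = None, rule: str = "one_se") -> GbmParams:
        d, m = self.one_se_choice if rule == "one_se" else self.optimal
        base = base or GbmParams()
        return base.replace(depth=d, n_trees=m)

    def at(self, depth: int, n_trees: int) -> pd.Series:
        g = self.grid
        row = g[(g["depth"] == depth) & (g["n_trees"] == n_trees)]
        if row.empty:
            raise KeyError((depth, n_trees))
        return row.iloc[0]

    def summary(self) -> str:
        d_o, m_o = self.optimal
        d_s, m_s = self.one_se_choice
        opt, one = self.at(d_o, m_o), self.at(d_s, m_s)
        return (
            f"bootstrap tuning ({self.n_boot} replicates)\n"
            f"  optimal: d={d_o}, M={m_o}  "
            f"RMSE={opt.mean_rmse:.3f}  R2={opt.mean_r2:.3f}\n"
            f"  one-SE:  d={d_s}, M={m_s}  "
            f"RMSE={one.mean_rmse:.3f}  R2={one.mean_r2:.3f}"
        )


def one_se_select(grid: pd.DataFrame) -> tuple[tuple[int, int], tuple[int, int]]:
    """Optimal and one-SE (depth, n_trees) choices from a grid table.

    ``grid`` needs columns depth, n_trees, mean_r2, se_r2.  Parsimony
    order: smaller depth beats fewer trees.
    """
    best = grid["mean_r2"].idxmax()
    optimal = (int(grid.loc[best, "depth"]), int(grid.loc[best, "n_trees"]))
    threshold = grid.loc[best, "mean_r2"] - grid.loc[best, "se_r2"]
    eligible = grid[grid["mean_r2"] >= threshold]
    eligible = eligible.sort_values(["depth", "n_trees"])
    row = eligible.iloc[0]
    return optimal, (int(row["depth"]), int(row["n_trees"]))


def bootstrap_tune(
    X,
    y,
    d_values,
    m_grid,
    n_boot: int = 25,
    params: GbmParams | None = None,
    seed: int | None = None,
) -> TuningResult:
    """Out-of-bootstrap grid search over (depth, n_trees)."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    m_grid = sorted(int(m) for m in m_grid)
    if m_grid[0] < 1 or len(set(m_grid)) != len(m_grid):
        raise ValueError("m_grid must be increasing positive tree counts")
    d_values = sorted(int(d) for d in d_values)
    base = params or GbmParams()

    if isinstance(X, pd.DataFrame):
        Xf = X
    else:
        Xf = pd.DataFrame(np.asarray(X, dtype=float))
        Xf.columns = [f"x{j}" for j in range(Xf.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n = Xf.shape[0]

    rng = np.random.default_rng(seed)
    mse = np.empty((n_boot, len(d_values), len(m_grid)))
    r2 = np.empty_like(mse)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), idx)
            if oob.size > 1:
                break
        y_oob = y[oob]
        var_oob = np.var(y_oob)
        for di, d in enumerate(d_values):
            fit = fit_ensemble(
                Xf.iloc[idx], y[idx],
                base.replace(depth=d, n_trees=m_grid[-1],
                             seed=int(rng.integers(2**31 - 1))),
            )
            staged = fit.staged_predict(Xf.iloc[oob], at=m_grid)
            for mi, m in enumerate(m_grid):
                e = np.mean((y_oob - staged[m]) ** 2)
                mse[b, di, mi] = e
                r2[b, di, mi] = 1.0 - e / var_oob

    rows = []
    for di, d in enumerate(d_values):
        for mi, m in enumerate(m_grid):
            rows.append(
                {
                    "depth": d,
                    "n_trees": m,
                    "mean_rmse": float(np.mean(np.sqrt(mse[:, di, mi]))),
                    "mean_r2": float(np.mean(r2[:, di, mi])),
                    "se_r2": float(np.std(r2[:, di, mi], ddof=1) / np.sqrt(n_boot)),
                }
            )
    grid = pd.DataFrame(rows)
    optimal, one_se = one_se_select(grid)
    return TuningResult(grid=grid, optimal=optimal, one_se_choice=one_se, n_boot=n_boot)
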