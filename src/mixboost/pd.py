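"""Partial dependence of a boosted-tree ensemble on subsets of variables.

The partial dependence of the fitted function on a variable subset S is
its average over the empirical distribution of the remaining variables:

    F_S(x_S) = (1/N) * sum_i F(x_S, x_{-S,i})

``pd_brute`` is the definition itself: overwrite the S-columns of the
reference data with the evaluation point and average the predictions.
It costs a full prediction pass per evaluation point (N * n_points row
descents per tree), which is what makes the definitional route
"computationally very expensive" for data-sized point sets.

``pd_recursion`` computes the same quantity from the tree structure with
two weight propagations per tree instead of the cross product.  Writing
a tree as a sum over leaves, T(x) = sum_l v_l * I[x in l], the brute
average factorises exactly:

    (1/N) sum_i T(p_S, x_{-S,i})
        = sum_l v_l * I[p satisfies l's S-constraints]
                    * #{i : x_i satisfies l's non-S constraints} / N

so one root-to-leaf propagation routes the evaluation points through the
S-splits (descending both children of any other split), a second routes
the reference rows through the non-S splits (descending both children of
S-splits), and a leaf-wise product finishes the job.  The result is
identical to ``pd_brute`` — for any reference data, any subsampling —
up to floating-point accumulation order.

When no reference data is supplied, ``pd_recursion`` falls back to the
classic single-pass weighted traversal that combines the children of
non-S splits by the node weight fractions recorded at fit time.  That
variant needs no data at all but is only an approximation to the
definitional average whenever splits on S occur above splits on
correlated complement variables (the recorded child fractions are
conditional on the path, where the definition requires marginal ones).

All partial-dependence values are centered to mean zero over their
evaluation points; the H statistics require centered functions, and
plots are unaffected by the constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boosting import LEAF, BoostedEnsemble

__all__ = ["PDFunction", "pd_brute", "pd_recursion", "percentile_grid"]


@dataclass
class PDFunction:
    """Centered partial-dependence values of subset ``subset`` at ``points``."""

    subset: tuple[str, ...]
    points: np.ndarray          # (n_points, len(subset))
    values: np.ndarray          # centered, mean 0 over points
    center: float               # constant removed by centering

    def __post_init__(self) -> None:
        if len(self.subset) < 1:
            raise ValueError("subset must contain at least one variable")
        if self.points.shape[0] != self.values.shape[0]:
            raise ValueError("points and values disagree in length")

    @property
    def uncentered(self) -> np.ndarray:
        return self.values + self.center

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.points, columns=list(self.subset))
        df["pd"] = self.values
        return df


def _resolve_subset(ensemble: BoostedEnsemble, subset) -> list[int]:
    cols = ensemble.columns
    idx: list[int] = []
    for s in subset if not isinstance(subset, (str, int)) else [subset]:
        if isinstance(s, str):
            if s not in cols:
                raise ValueError(f"variable {s!r} not among model columns")
            idx.append(cols.index(s))
        else:
            j = int(s)
            if not 0 <= j < len(cols):
                raise ValueError(f"variable index {j} out of range")
            idx.append(j)
    if len(set(idx)) != len(idx):
        raise ValueError("subset contains duplicate variables")
    return idx


def _points_matrix(ensemble, s_idx, points, X=None) -> np.ndarray:
    if points is None:
        if X is None:
            raise ValueError("either points or reference data X is required")
        Xm = ensemble._as_matrix(X)
        return Xm[:, s_idx]
    if isinstance(points, pd.DataFrame):
        points = points[[ensemble.columns[j] for j in s_idx]].to_numpy()
    P = np.asarray(points, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.shape[1] != len(s_idx):
        raise ValueError("points must have one column per subset variable")
    return P


def _tree_pd_exact(tree, in_s, P_full: np.ndarray, X_full: np.ndarray) -> np.ndarray:
    """One tree's exact PD contribution via two boolean propagations.

    Down the tree, each node accumulates (a) the evaluation points
    satisfying its S-constraints and (b) the reference rows satisfying
    its non-S constraints; ``None`` stands for "all rows" so untouched
    masks are shared, and leaves sharing the same S-mask are merged into
    a single weighted addition.
    """
    n_nodes = tree.n_nodes
    feature, threshold = tree.feature, tree.threshold
    left, right, value = tree.left, tree.right, tree.value
    pts_mask: list = [None] * n_nodes
    ref_mask: list = [None] * n_nodes
    for i in range(n_nodes):
        f = feature[i]
        if f == LEAF:
            continue
        l, r = left[i], right[i]
        if in_s[f]:
            cond = P_full[:, f] <= threshold[i]
            pm = pts_mask[i]
            pts_mask[l] = cond if pm is None else pm & cond
            pts_mask[r] = ~cond if pm is None else pm & ~cond
            ref_mask[l] = ref_mask[r] = ref_mask[i]
        else:
            cond = X_full[:, f] <= threshold[i]
            rm = ref_mask[i]
            ref_mask[l] = cond if rm is None else rm & cond
            ref_mask[r] = ~cond if rm is None else rm & ~cond
            pts_mask[l] = pts_mask[r] = pts_mask[i]

    n_ref = X_full.shape[0]
    frac_cache: dict[int, float] = {}
    coef: dict[int, list] = {}
    for i in range(n_nodes):
        if feature[i] != LEAF:
            continue
        rm = ref_mask[i]
        if rm is None:
            frac = 1.0
        else:
            key = id(rm)
            frac = frac_cache.get(key)
            if frac is None:
                frac = float(rm.sum()) / n_ref
                frac_cache[key] = frac
        entry = coef.setdefault(id(pts_mask[i]), [pts_mask[i], 0.0])
        entry[1] += value[i] * frac

    out = np.zeros(P_full.shape[0])
    for mask, c in coef.values():
        if mask is None:
            out += c
        else:
            out += c * mask
    return out


def _tree_pd_weighted(tree, s_pos: dict[int, int], P: np.ndarray) -> np.ndarray:
    """Classic single-pass traversal using recorded node weight fractions."""
    n_pts = P.shape[0]
    w = np.zeros((n_pts, tree.n_nodes))
    w[:, 0] = 1.0
    out = np.zeros(n_pts)
    for i in range(tree.n_nodes):
        f = tree.feature[i]
        wi = w[:, i]
        if f == LEAF:
            out += wi * tree.value[i]
            continue
        l, r = tree.left[i], tree.right[i]
        if f in s_pos:
            go_left = P[:, s_pos[f]] <= tree.threshold[i]
            w[:, l] += wi * go_left
            w[:, r] += wi * ~go_left
        else:
            if not (tree.weight[i] > 0) or np.isnan(tree.weight[l]):
                raise ValueError(
                    "tree lacks positive node weight fractions; refit the "
                    "model or supply reference data X"
                )
            w[:, l] += wi * (tree.weight[l] / tree.weight[i])
            w[:, r] += wi * (tree.weight[r] / tree.weight[i])
    return out


def pd_recursion(
    ensemble: BoostedEnsemble, subset, points=None, X=None
) -> PDFunction:
    """Partial dependence by tree recursion (no brute cross product).

    ``points`` are rows over the subset variables; if omitted, the rows
    of ``X`` projected onto the subset are used.  With reference data
    ``X`` the result equals :func:`pd_brute` exactly (see module notes);
    without it, the recorded training weight fractions stand in for the
    reference distribution and the result is the classic approximation.
    """
    s_idx = _resolve_subset(ensemble, subset)
    P = _points_matrix(ensemble, s_idx, points, X)
    vals = np.zeros(P.shape[0])
    if X is not None:
        Xm = ensemble._as_matrix(X)
        # spread the subset coordinates into full-width rows once
        P_full = np.zeros((P.shape[0], Xm.shape[1]))
        P_full[:, s_idx] = P
        in_s = np.zeros(Xm.shape[1], dtype=bool)
        in_s[s_idx] = True
        for tree in ensemble.trees:
            vals += _tree_pd_exact(tree, in_s, P_full, Xm)
    else:
        s_pos = {j: p for p, j in enumerate(s_idx)}
        for tree in ensemble.trees:
            vals += _tree_pd_weighted(tree, s_pos, P)
    vals = ensemble.alpha + ensemble.value_scale * vals
    center = float(vals.mean())
    return PDFunction(
        subset=tuple(ensemble.columns[j] for j in s_idx),
        points=P,
        values=vals - center,
        center=center,
    )


def pd_brute(ensemble: BoostedEnsemble, subset, X, points=None) -> PDFunction:
    """Partial dependence by the definitional average over reference data."""
    s_idx = _resolve_subset(ensemble, subset)
    Xm = ensemble._as_matrix(X)
    P = _points_matrix(ensemble, s_idx, points, X)
    vals = np.empty(P.shape[0])
    work = Xm.copy()
    for p in range(P.shape[0]):
        work[:, s_idx] = P[p]
        vals[p] = ensemble.predict(work).mean()
    center = float(vals.mean())
    return PDFunction(
        subset=tuple(ensemble.columns[j] for j in s_idx),
        points=P,
        values=vals - center,
        center=center,
    )


def percentile_grid(x, n_points: int = 40, lower: float = 10.0, upper: float = 90.0):
    """Evenly spaced grid between two percentiles of ``x`` (plot support)."""
    x = np.asarray(x, dtype=float)
    lo, hi = np.percentile(x, [lower, upper])
    return np.linspace(lo, hi, n_points)
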