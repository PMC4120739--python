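"""Stochastic gradient boosted regression trees.

The ensemble is the classic Friedman form: an initial constant plus a sum
of shallow CARTs, each fit to the negative gradient of the loss on a
random subsample of the data and shrunk by a learning rate::

    F_hat(x) = alpha + lambda * sum_m tree_m(x)

Two loss functions are supported: squared error (negative gradient = the
residual, loss-optimal leaf constant = leaf mean) and absolute error
(negative gradient = sign of the residual, leaf constant = leaf median).
The line-search step is absorbed into the loss-optimal leaf values, so no
separate step length is stored.

Two backends grow the trees:

``exact``
    A self-contained boosting loop around
    :class:`sklearn.tree.DecisionTreeRegressor` (exact greedy splits).
    Reference implementation; used for small models and oracle tests.
``hist``
    :func:`lightgbm.train` (histogram splits), single-threaded and
    deterministic.  Used for large ensembles where the exact loop is too
    slow to be practical.

Both backends are normalised into :class:`TreeArrays`, a flat per-node
representation carrying split variable, threshold, children, node value
and the fraction of the subsample reaching each node.  Everything
downstream (prediction, staged prediction, split-improvement importance,
partial dependence by recursion) runs on that single representation, so
the choice of backend only affects how the trees were grown.

Tree depth is counted as the maximum number of splits along any
root-to-leaf path; a depth-``d`` tree can represent interactions of at
most order ``d`` (``d=1`` is a stump and the ensemble is additive).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GbmParams",
    "TreeArrays",
    "BoostedEnsemble",
    "fit_ensemble",
]

LEAF = -1

_LOSSES = ("squared", "absolute")
_BACKENDS = ("exact", "hist")


@dataclass
class GbmParams:
    """Hyper-parameters of the boosted ensemble.

    Parameters
    ----------
    n_trees : int
        Number of boosting iterations M.
    depth : int
        Maximum splits along any root-to-leaf path; bounds the
        interaction order a single tree can express.
    shrinkage : float
        Learning rate lambda in (0, 1].  Small values (default 0.005)
        slow the learning; optima then occur at thousands of trees.
    subsample : float
        Fraction eta of observations drawn without replacement at each
        iteration (default 0.5).
    loss : str
        ``"squared"`` or ``"absolute"``.
    min_obs_per_leaf : int
        Nodes with fewer observations are not split further (default 10).
    seed : int
        Seed for subsampling and tie-breaking.
    backend : str
        ``"exact"`` or ``"hist"`` (see module docstring).
    """

    n_trees: int = 1000
    depth: int = 5
    shrinkage: float = 0.005
    subsample: float = 0.5
    loss: str = "squared"
    min_obs_per_leaf: int = 10
    seed: int = 0
    backend: str = "exact"

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not 0.0 < self.shrinkage <= 1.0:
            raise ValueError("shrinkage must be in (0, 1]")
        if not 0.0 < self.subsample <= 1.0:
            raise ValueError("subsample must be in (0, 1]")
        if self.loss not in _LOSSES:
            raise ValueError(f"loss must be one of {_LOSSES}")
        if self.backend not in _BACKENDS:
            raise ValueError(f"backend must be one of {_BACKENDS}")

    def replace(self, **kw) -> "GbmParams":
        return replace(self, **kw)


@dataclass
class TreeArrays:
    """Flat per-node arrays for one regression tree.

    Nodes are stored in preorder (every parent precedes its children).
    ``feature[i] == -1`` marks a leaf.  ``weight`` is the fraction of the
    training subsample reaching each node (1.0 at the root); these are the
    weights used by the partial-dependence recursion.  ``improvement`` is
    the decrease in (squared-error) training loss attributed to each
    internal split, the basis of the importance measure.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray
    weight: np.ndarray
    improvement: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.feature)
        for name in ("threshold", "left", "right", "value", "weight", "improvement"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array {name!r} has wrong length")

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    @property
    def is_leaf(self) -> np.ndarray:
        return self.feature == LEAF

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Vectorised descent of all rows of ``X`` to their leaf values."""
        n = X.shape[0]
        node = np.zeros(n, dtype=np.intp)
        internal = self.feature[node] >= 0
        while internal.any():
            feat = np.where(internal, self.feature[node], 0)
            go_left = X[np.arange(n), feat] <= self.threshold[node]
            nxt = np.where(go_left, self.left[node], self.right[node])
            node = np.where(internal, nxt, node)
            internal = self.feature[node] >= 0
        return self.value[node]

    def max_depth(self) -> int:
        depth = np.zeros(self.n_nodes, dtype=int)
        for i in range(self.n_nodes):
            if self.feature[i] >= 0:
                depth[self.left[i]] = depth[i] + 1
                depth[self.right[i]] = depth[i] + 1
        return int(depth.max(initial=0))

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "weight": self.weight.tolist(),
            "improvement": self.improvement.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeArrays":
        return cls(
            feature=np.asarray(d["feature"], dtype=np.intp),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.intp),
            right=np.asarray(d["right"], dtype=np.intp),
            value=np.asarray(d["value"], dtype=float),
            weight=np.asarray(d["weight"], dtype=float),
            improvement=np.asarray(d["improvement"], dtype=float),
        )

    @classmethod
    def from_nested(cls, node: dict) -> "TreeArrays":
        """Build from a nested node record.

        Internal nodes: ``{"feature": j, "threshold": t, "weight": w,
        "left": {...}, "right": {...}}``; leaves: ``{"value": v,
        "weight": w}``.  ``weight`` defaults to an equal split of the
        parent's weight, which matches a balanced design.  Intended for
        hand-built ensembles in tests and worked examples.
        """
        feature: list[int] = []
        threshold: list[float] = []
        left: list[int] = []
        right: list[int] = []
        value: list[float] = []
        weight: list[float] = []

        def walk(nd: dict, w: float) -> int:
            idx = len(feature)
            w = float(nd.get("weight", w))
            if "feature" in nd:
                feature.append(int(nd["feature"]))
                threshold.append(float(nd["threshold"]))
                value.append(0.0)
                weight.append(w)
                left.append(-9)
                right.append(-9)
                left[idx] = walk(nd["left"], w / 2.0)
                right[idx] = walk(nd["right"], w / 2.0)
            else:
                feature.append(LEAF)
                threshold.append(np.nan)
                value.append(float(nd["value"]))
                weight.append(w)
                left.append(LEAF)
                right.append(LEAF)
            return idx

        walk(node, 1.0)
        n = len(feature)
        return cls(
            feature=np.asarray(feature, dtype=np.intp),
            threshold=np.asarray(threshold, dtype=float),
            left=np.asarray(left, dtype=np.intp),
            right=np.asarray(right, dtype=np.intp),
            value=np.asarray(value, dtype=float),
            weight=np.asarray(weight, dtype=float),
            improvement=np.zeros(n),
        )


class BoostedEnsemble:
    """A fitted boosted-tree ensemble.

    Predictions are ``alpha + value_scale * sum_m tree_m(x)`` where
    ``value_scale`` is the shrinkage for the exact backend and 1.0 for the
    hist backend (whose stored leaf values already include it).
    """

    def __init__(
        self,
        alpha: float,
        trees: Sequence[TreeArrays],
        params: GbmParams,
        columns: Sequence[str],
        value_scale: float | None = None,
        booster=None,
    ) -> None:
        self.alpha = float(alpha)
        self.trees = list(trees)
        self.params = params
        self.columns = list(columns)
        self.value_scale = (
            float(value_scale) if value_scale is not None else params.shrinkage
        )
        self._booster = booster  # optional lightgbm fast path

    # ------------------------------------------------------------------
    @property
    def n_trees(self) -> int:
        return len(self.trees)

    def _as_matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.columns if c not in X.columns]
            if missing:
                raise ValueError(f"missing training columns: {missing}")
            X = X[self.columns].to_numpy()
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != len(self.columns):
            raise ValueError(
                f"X must have {len(self.columns)} columns in training order"
            )
        return X

    def predict(self, X, n_trees: int | None = None) -> np.ndarray:
        """Prediction from the first ``n_trees`` trees (default: all)."""
        m = self.n_trees if n_trees is None else int(n_trees)
        if m < 0 or m > self.n_trees:
            raise ValueError(f"n_trees must be in [0, {self.n_trees}]")
        X = self._as_matrix(X)
        if self._booster is not None and m > 0:
            return np.asarray(self._booster.predict(X, num_iteration=m))
        out = np.full(X.shape[0], self.alpha, dtype=float)
        for tree in self.trees[:m]:
            out += self.value_scale * tree.predict(X)
        return out

    def staged_predict(self, X, at: Sequence[int]) -> dict[int, np.ndarray]:
        """Predictions recorded at the tree counts in ``at`` (one pass)."""
        at = sorted(set(int(m) for m in at))
        if at and (at[0] < 0 or at[-1] > self.n_trees):
            raise ValueError("requested tree counts outside [0, n_trees]")
        X = self._as_matrix(X)
        out: dict[int, np.ndarray] = {}
        acc = np.full(X.shape[0], self.alpha, dtype=float)
        want = set(at)
        if 0 in want:
            out[0] = acc.copy()
        for m, tree in enumerate(self.trees, start=1):
            if m > at[-1]:
                break
            acc += self.value_scale * tree.predict(X)
            if m in want:
                out[m] = acc.copy()
        return out

    # ------------------------------------------------------------------
    def variable_importance(self) -> pd.Series:
        """Split-improvement importance, scaled so the maximum is 100.

        Every split's improvement (decrease in training loss) is summed
        per variable across all trees; frequent or strongly improving
        variables score high.  All-zero improvements are returned
        unscaled.
        """
        raw = np.zeros(len(self.columns))
        for tree in self.trees:
            internal = tree.feature >= 0
            np.add.at(raw, tree.feature[internal], tree.improvement[internal])
        if raw.max() > 0:
            raw = 100.0 * raw / raw.max()
        return pd.Series(raw, index=self.columns, name="importance").sort_values(
            ascending=False
        )

    # ------------------------------------------------------------------
    def to_json(self, path=None) -> str | None:
        payload = {
            "alpha": self.alpha,
            "value_scale": self.value_scale,
            "params": asdict(self.params),
            "columns": self.columns,
            "trees": [t.to_dict() for t in self.trees],
        }
        text = json.dumps(payload)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source) -> "BoostedEnsemble":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        return cls(
            alpha=payload["alpha"],
            trees=[TreeArrays.from_dict(t) for t in payload["trees"]],
            params=GbmParams(**payload["params"]),
            columns=payload["columns"],
            value_scale=payload["value_scale"],
        )


# ----------------------------------------------------------------------
# Fitting
# ----------------------------------------------------------------------

def _validate_xy(X, y):
    if isinstance(X, pd.DataFrame):
        columns = list(X.columns)
        Xm = X.to_numpy(dtype=float)
    else:
        Xm = np.asarray(X, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[:, None]
        columns = [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    if Xm.shape[0] != y.shape[0]:
        raise ValueError("X and y have different numbers of rows")
    if not np.isfinite(Xm).all():
        raise ValueError("X contains non-finite values")
    if not np.isfinite(y).all():
        raise ValueError("y contains non-finite values")
    return Xm, y, columns


def _alpha(y: np.ndarray, loss: str) -> float:
    return float(np.mean(y)) if loss == "squared" else float(np.median(y))


def _sklearn_tree_arrays(sk_tree, scale_weight: float = 1.0) -> TreeArrays:
    t = sk_tree.tree_
    feature = t.feature.astype(np.intp).copy()
    feature[feature < 0] = LEAF
    w = t.weighted_n_node_samples.astype(float)
    frac = w / w[0]
    imp = t.impurity
    improvement = np.zeros(t.node_count)
    internal = feature >= 0
    idx = np.nonzero(internal)[0]
    lc, rc = t.children_left[idx], t.children_right[idx]
    improvement[idx] = w[idx] * imp[idx] - w[lc] * imp[lc] - w[rc] * imp[rc]
    improvement = np.clip(improvement, 0.0, None) * scale_weight
    return TreeArrays(
        feature=feature,
        threshold=t.threshold.astype(float).copy(),
        left=t.children_left.astype(np.intp).copy(),
        right=t.children_right.astype(np.intp).copy(),
        value=t.value[:, 0, 0].astype(float).copy(),
        weight=frac,
        improvement=improvement,
    )


def _fit_exact(Xm: np.ndarray, y: np.ndarray, params: GbmParams, columns):
    from sklearn.tree import DecisionTreeRegressor

    rng = np.random.default_rng(params.seed)
    n = Xm.shape[0]
    alpha = _alpha(y, params.loss)
    F = np.full(n, alpha)
    X32 = np.asarray(Xm, dtype=np.float32)
    n_sub = max(1, int(round(params.subsample * n)))
    trees: list[TreeArrays] = []
    for _ in range(params.n_trees):
        if params.subsample < 1.0:
            idx = rng.choice(n, size=n_sub, replace=False)
        else:
            idx = np.arange(n)
        resid = y - F
        z = resid[idx] if params.loss == "squared" else np.sign(resid[idx])
        tree = DecisionTreeRegressor(
            max_depth=params.depth,
            min_samples_leaf=params.min_obs_per_leaf,
            random_state=int(rng.integers(2**31 - 1)),
        )
        tree.fit(X32[idx], z)
        arrays = _sklearn_tree_arrays(tree)
        if params.loss == "absolute":
            # loss-optimal leaf constant: median residual among the
            # subsampled observations in each leaf
            leaves = tree.apply(X32[idx])
            for leaf in np.unique(leaves):
                arrays.value[leaf] = np.median(resid[idx][leaves == leaf])
        contrib = arrays.value[tree.apply(X32)]
        F += params.shrinkage * contrib
        trees.append(arrays)
    return BoostedEnsemble(alpha, trees, params, columns)


def _lgb_tree_arrays(tree_structure: dict) -> TreeArrays:
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []
    count: list[float] = []
    improvement: list[float] = []

    def walk(nd: dict) -> int:
        idx = len(feature)
        if "split_feature" in nd:
            if nd.get("decision_type", "<=") != "<=":
                raise ValueError("unsupported split decision type")
            feature.append(int(nd["split_feature"]))
            threshold.append(float(nd["threshold"]))
            value.append(float(nd.get("internal_value", 0.0)))
            count.append(float(nd["internal_count"]))
            improvement.append(float(nd.get("split_gain", 0.0)))
            left.append(-9)
            right.append(-9)
            left[idx] = walk(nd["left_child"])
            right[idx] = walk(nd["right_child"])
        else:
            feature.append(LEAF)
            threshold.append(np.nan)
            value.append(float(nd["leaf_value"]))
            count.append(float(nd["leaf_count"]))
            improvement.append(0.0)
            left.append(LEAF)
            right.append(LEAF)
        return idx

    walk(tree_structure)
    cnt = np.asarray(count, dtype=float)
    root = cnt[0] if cnt[0] > 0 else 1.0
    return TreeArrays(
        feature=np.asarray(feature, dtype=np.intp),
        threshold=np.asarray(threshold, dtype=float),
        left=np.asarray(left, dtype=np.intp),
        right=np.asarray(right, dtype=np.intp),
        value=np.asarray(value, dtype=float),
        weight=cnt / root,
        improvement=np.asarray(improvement, dtype=float),
    )



def _fit_hist(Xm: np.ndarray, y: np.ndarray, params: GbmParams, columns):
    import lightgbm as lgb

    seed = int(params.seed) % (2**31 - 1)
    lgb_params = {
        "objective": "regression" if params.loss == "squared" else "regression_l1",
        "learning_rate": params.shrinkage,
        "max_depth": params.depth,
        "num_leaves": min(2**params.depth, 32768),
        "min_data_in_leaf": params.min_obs_per_leaf,
        "min_sum_hessian_in_leaf": 0.0,
        "bagging_fraction": params.subsample,
        "bagging_freq": 1 if params.subsample < 1.0 else 0,
        "bagging_seed": seed + 1,
        "feature_fraction": 1.0,
        "lambda_l1": 0.0,
        "lambda_l2": 0.0,
        "min_gain_to_split": 0.0,
        "verbosity": -1,
        "num_threads": 1,
        "deterministic": True,
        "seed": seed,
    }
    dataset = lgb.Dataset(Xm, label=y, params={"verbosity": -1})
    booster = lgb.train(lgb_params, dataset, num_boost_round=params.n_trees)
    ensemble = BoostedEnsemble(
        alpha=0.0,
        trees=[],
        params=params,
        columns=columns,
        value_scale=1.0,  # lightgbm leaf values already include shrinkage
        booster=booster,
    )

    # tree extraction (dump_model) is comparatively slow; do it lazily
    class _TreeList:
        def __init__(self):
            self._trees = None

        def materialise(self):
            if self._trees is None:
                dump = booster.dump_model()
                self._trees = [
                    _lgb_tree_arrays(t["tree_structure"]) for t in dump["tree_info"]
                ]
            return self._trees

    holder = _TreeList()

    class _LazyList:
        def __iter__(self):
            return iter(holder.materialise())

        def __len__(self):
            return booster.num_trees()

        def __getitem__(self, item):
            return holder.materialise()[item]

    ensemble.trees = _LazyList()  # type: ignore[assignment]
    return ensemble


def fit_ensemble(X, y, params: GbmParams) -> BoostedEnsemble:
    """Fit a stochastic gradient boosted tree ensemble.

    Follows the standard five steps: initialise to the loss-optimal
    constant alpha (mean for squared loss, median for absolute loss);
    then, for each of ``params.n_trees`` iterations, subsample a fraction
    ``subsample`` of the data without replacement, compute the negative
    gradient of the loss at the current fit, grow a depth-limited CART
    predicting it, replace leaf values with the loss-optimal constants,
    and add the tree scaled by ``shrinkage``.
    """
    Xm, y, columns = _validate_xy(X, y)
    if Xm.shape[0] < 2 * params.min_obs_per_leaf and params.n_trees > 0:
        raise ValueError("too few observations for the requested leaf size")
    if params.n_trees == 0:
        return BoostedEnsemble(_alpha(y, params.loss), [], params, columns)
    if params.backend == "exact":
        return _fit_exact(Xm, y, params, columns)
    return _fit_hist(Xm, y, params, columns)
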