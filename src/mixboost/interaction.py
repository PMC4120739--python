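"""Friedman-Popescu H statistics with a parametric-bootstrap null.

The H statistic measures the interaction strength of a variable subset as
the square root of the fraction of variance of its joint (centered)
partial dependence that is not captured by lower-order partial
dependences.  For a pair (j, k), evaluated at the N data points,

    H_jk^2 = sum_i [F_jk(x_ij, x_ik) - F_j(x_ij) - F_k(x_ik)]^2
             / sum_i F_jk(x_ij, x_ik)^2

and H = sqrt(H^2) in [0, 1]; 0 means additivity, 1 a pure interaction.
The "total" variant for a single variable j replaces the joint partial
dependence with the full fit and the additive decomposition with
F_j + F_{-j}.  For subsets of three or more variables, the numerator is
the inclusion-exclusion residual that isolates the pure |S|-way term:

    sum_i [ sum_{T subset of S, T nonempty} (-1)^{|S|-|T|} F_T(x_iT) ]^2

Because trees fit interactions by construction, sampling noise alone
produces nonzero H.  The reference distribution H0 is built by a
parametric bootstrap: fit the closest additive model F_A (depth-1 boosted
trees, same loss), form artificial outcomes

    y~_i = F_A(x_i) + y_{p(i)} - F_A(x_{p(i)})

for a random permutation p (additive signal plus exchanged residuals, so
any interaction signal is destroyed while the marginal error structure is
kept), refit the full-depth model, and recompute H.  A subset is flagged
significant when the observed H exceeds the 95th percentile of H0.

Split-sample stability repeats the verdict on random half-splits: fit on
the training half, evaluate observed and null H at the validation rows,
and report how many of the repeats flag the subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .boosting import BoostedEnsemble, GbmParams, fit_ensemble
from .pd import pd_recursion

__all__ = [
    "HAssessment",
    "StabilityResult",
    "h_statistic",
    "h_pairwise",
    "h_total",
    "h_higher",
    "make_null_outcome",
    "null_distribution",
    "split_stability",
]

_EPS_DENOM = 1e-300


@dataclass
class HAssessment:
    """Observed H for one subset together with its simulated null."""

    subset: tuple[str, ...]
    h_observed: float
    null_samples: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def order(self) -> int:
        # a single variable means "total interaction with all others"
        return len(self.subset)

    @property
    def null_p95(self) -> float:
        return float(np.percentile(self.null_samples, 95))

    @property
    def significant(self) -> bool:
        return self.h_observed > self.null_p95

    def null_percentiles(self, q=(5, 50, 95)) -> np.ndarray:
        return np.percentile(self.null_samples, q)

    def to_record(self) -> dict:
        p5, p50, p95 = self.null_percentiles()
        return {
            "subset": " * ".join(self.subset),
            "order": self.order,
            "h_observed": self.h_observed,
            "null_p5": p5,
            "null_p50": p50,
            "null_p95": p95,
            "significant": self.significant,
        }


@dataclass
class StabilityResult:
    """Detection count of one subset over repeated half-sample splits."""

    subset: tuple[str, ...]
    n_repeats: int
    n_detected: int
    h_values: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def fraction(self) -> float:
        return self.n_detected / self.n_repeats

    def __str__(self) -> str:  # e.g. "10/10"
        return f"{self.n_detected}/{self.n_repeats}"


# ----------------------------------------------------------------------
# Observed H
# ----------------------------------------------------------------------

def _centered_pd(ensemble, subset, Xm) -> np.ndarray:
    return pd_recursion(ensemble, subset, X=Xm).values


def _ratio(num: float, den: float) -> float:
    if den <= _EPS_DENOM:
        warnings.warn("joint partial dependence is identically zero; H set to 0")
        return 0.0
    return float(np.sqrt(max(num, 0.0) / den))


def h_pairwise(ensemble: BoostedEnsemble, j, k, X) -> float:
    """Two-way H for variables ``j`` and ``k`` evaluated at the rows of X."""
    ji, ki = _indices(ensemble, [j, k])
    Xm = ensemble._as_matrix(X)
    f_jk = _centered_pd(ensemble, [ji, ki], Xm)
    f_j = _centered_pd(ensemble, [ji], Xm)
    f_k = _centered_pd(ensemble, [ki], Xm)
    return _ratio(np.sum((f_jk - f_j - f_k) ** 2), np.sum(f_jk**2))


def h_total(ensemble: BoostedEnsemble, j, X) -> float:
    """Total interaction strength of variable ``j`` with all others.

    If j interacts with nothing, the full fit decomposes as
    F = F_j + F_{-j} and H is zero.
    """
    (ji,) = _indices(ensemble, [j])
    Xm = ensemble._as_matrix(X)
    full = ensemble.predict(Xm)
    full = full - full.mean()
    f_j = _centered_pd(ensemble, [ji], Xm)
    comp = [c for c in range(len(ensemble.columns)) if c != ji]
    f_comp = _centered_pd(ensemble, comp, Xm)
    return _ratio(np.sum((full - f_j - f_comp) ** 2), np.sum(full**2))


def h_higher(ensemble: BoostedEnsemble, subset, X) -> float:
    """Pure |S|-way interaction strength for ``len(subset) >= 3``."""
    s_idx = _indices(ensemble, subset)
    if len(s_idx) < 3:
        raise ValueError("h_higher requires a subset of three or more variables")
    Xm = ensemble._as_matrix(X)
    order = len(s_idx)
    resid = np.zeros(Xm.shape[0])
    den = 0.0
    for r in range(1, order + 1):
        sign = (-1) ** (order - r)
        for T in combinations(s_idx, r):
            vals = _centered_pd(ensemble, list(T), Xm)
            resid += sign * vals
            if r == order:
                den = float(np.sum(vals**2))
    return _ratio(float(np.sum(resid**2)), den)


def _indices(ensemble, subset) -> list[int]:
    from .pd import _resolve_subset

    return _resolve_subset(ensemble, subset)


def h_statistic(ensemble: BoostedEnsemble, subset, X) -> float:
    """Dispatch on subset size: 1 -> total, 2 -> pairwise, >=3 -> higher."""
    if isinstance(subset, (str, int)):
        subset = [subset]
    subset = list(subset)
    if len(subset) == 1:
        return h_total(ensemble, subset[0], X)
    if len(subset) == 2:
        return h_pairwise(ensemble, subset[0], subset[1], X)
    return h_higher(ensemble, subset, X)


# ----------------------------------------------------------------------
# Parametric-bootstrap null
# ----------------------------------------------------------------------

def make_null_outcome(f_additive: np.ndarray, y: np.ndarray, permutation) -> np.ndarray:
    """Artificial outcome with additive signal and exchanged residuals."""
    y = np.asarray(y, dtype=float).ravel()
    f_additive = np.asarray(f_additive, dtype=float).ravel()
    p = np.asarray(permutation)
    n = y.shape[0]
    if f_additive.shape[0] != n:
        raise ValueError("additive fit and outcome differ in length")
    if sorted(p.tolist()) != list(range(n)):
        raise ValueError("permutation must be a bijection of 0..N-1")
    # grouping the additive terms first makes the identity permutation
    # return y bit-for-bit
    return y[p] + (f_additive - f_additive[p])


def _spawn_seeds(seed, n) -> np.ndarray:
    ss = np.random.SeedSequence(seed)
    return ss.generate_state(n) % (2**31 - 1)


def null_distribution(
    X,
    y,
    params: GbmParams,
    subsets,
    n_rep: int = 250,
    seed: int | None = None,
    additive_params: GbmParams | None = None,
    ensemble: BoostedEnsemble | None = None,
    h_rows: int | None = None,
) -> list[HAssessment]:
    """Observed H and its parametric-bootstrap null for each subset.

    ``ensemble`` may pass in the already-fitted full model to avoid a
    refit; otherwise one is fitted with ``params``.  The additive
    reference is the same configuration restricted to depth 1.
    ``h_rows`` evaluates every H over a fixed random row subset instead
    of all N rows (a speed knob affecting only numerical precision; the
    same rows are used for the observed and all null statistics).
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if n_rep < 20:
        warnings.warn("n_rep < 20: the 95th null percentile is unstable")
    subsets = [tuple([s]) if isinstance(s, (str, int)) else tuple(s) for s in subsets]

    Xm = np.asarray(X, dtype=float) if not isinstance(X, pd.DataFrame) else X
    seeds = _spawn_seeds(seed, n_rep + 3)
    if ensemble is None:
        ensemble = fit_ensemble(Xm, y, params.replace(seed=int(seeds[-1])))
    n = len(Xm)
    if h_rows is not None and h_rows < n:
        row_rng = np.random.default_rng(int(seeds[-3]))
        rows = np.sort(row_rng.choice(n, size=h_rows, replace=False))
        X_eval = Xm.iloc[rows] if isinstance(Xm, pd.DataFrame) else Xm[rows]
    else:
        X_eval = Xm
    observed = [h_statistic(ensemble, list(s), X_eval) for s in subsets]

    if additive_params is None:
        additive_params = params.replace(depth=1, seed=int(seeds[-2]))
    additive = fit_ensemble(Xm, y, additive_params)
    f_a = additive.predict(Xm)

    y = np.asarray(y, dtype=float).ravel()
    null = np.empty((n_rep, len(subsets)))
    for r in range(n_rep):
        rng = np.random.default_rng(int(seeds[r]))
        perm = rng.permutation(y.shape[0])
        y_tilde = make_null_outcome(f_a, y, perm)
        null_fit = fit_ensemble(Xm, y_tilde, params.replace(seed=int(seeds[r])))
        for c, s in enumerate(subsets):
            null[r, c] = h_statistic(null_fit, list(s), X_eval)

    cols = ensemble.columns
    named = [tuple(cols[v] if isinstance(v, int) else v for v in s) for s in subsets]
    return [
        HAssessment(subset=named[c], h_observed=observed[c], null_samples=null[:, c])
        for c in range(len(subsets))
    ]


def split_stability(
    X,
    y,
    params: GbmParams,
    subsets,
    n_repeats: int = 10,
    null_rep: int = 50,
    seed: int | None = None,
) -> list[StabilityResult]:
    """Half-sample stability of the H-based interaction verdicts.

    Each repeat splits the sample in half at random, fits the full model
    to the training half, and evaluates both the observed H and its
    training-half null at the validation rows; a detection is an observed
    H above the null's 95th percentile.
    """
    subsets = [tuple([s]) if isinstance(s, (str, int)) else tuple(s) for s in subsets]
    if isinstance(X, pd.DataFrame):
        Xm = X.to_numpy(dtype=float)
        columns = list(X.columns)
    else:
        Xm = np.asarray(X, dtype=float)
        columns = [f"x{j}" for j in range(Xm.shape[1])]
    y = np.asarray(y, dtype=float).ravel()
    n = Xm.shape[0]
    seeds = _spawn_seeds(seed, n_repeats)
    detected = np.zeros(len(subsets), dtype=int)
    h_vals = np.empty((n_repeats, len(subsets)))

    for rep in range(n_repeats):
        rng = np.random.default_rng(int(seeds[rep]))
        order = rng.permutation(n)
        train, valid = order[: n // 2], order[n // 2 :]
        fit = fit_ensemble(
            pd.DataFrame(Xm[train], columns=columns), y[train],
            params.replace(seed=int(seeds[rep])),
        )
        additive = fit_ensemble(
            pd.DataFrame(Xm[train], columns=columns), y[train],
            params.replace(depth=1, seed=int(seeds[rep]) + 1),
        )
        f_a = additive.predict(Xm[train])
        null = np.empty((null_rep, len(subsets)))
        for r in range(null_rep):
            perm = rng.permutation(train.shape[0])
            y_tilde = make_null_outcome(f_a, y[train], perm)
            nf = fit_ensemble(
                pd.DataFrame(Xm[train], columns=columns), y_tilde,
                params.replace(seed=int(rng.integers(2**31 - 1))),
            )
            for c, s in enumerate(subsets):
                null[r, c] = h_statistic(nf, list(s), Xm[valid])
        for c, s in enumerate(subsets):
            h_obs = h_statistic(fit, list(s), Xm[valid])
            h_vals[rep, c] = h_obs
            if h_obs > np.percentile(null[:, c], 95):
                detected[c] += 1

    named = [tuple(columns[v] if isinstance(v, int) else v for v in s) for s in subsets]
    return [
        StabilityResult(
            subset=named[c],
            n_repeats=n_repeats,
            n_detected=int(detected[c]),
            h_values=h_vals[:, c],
        )
        for c in range(len(subsets))
    ]


def assessments_to_frame(assessments) -> pd.DataFrame:
    """Tidy table of H assessments (export / reporting helper)."""
    return pd.DataFrame([a.to_record() for a in assessments])
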