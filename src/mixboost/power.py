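"""Power study: H-based detection versus product-term regression.

Twenty independent standard-normal predictors carry a signal through one
of two generating models,

    two-way:   y = 1 + x1 + x2 + b12*x1*x2 + e
    three-way: y = 1 + x1 + x2 + x3 + b12*x1*x2 + b13*x1*x3 + b23*x2*x3
                 + b123*x1*x2*x3 + e

with main-effect coefficients fixed at 1 and e ~ N(0, sigma), sigma set
analytically so the signal-to-noise ratio is one (for independent
standard normals every product term has unit variance and all terms are
uncorrelated, so var(signal) is the sum of squared coefficients).

Two detection procedures are compared over repeated datasets:

* ``power_boosted`` — fit the boosted ensemble, build the
  parametric-bootstrap null for the target subset, declare the
  interaction when observed H exceeds the null's 95th percentile.
* ``power_parametric`` — the conventional screen-then-test bootstrap:
  in each resample (drawn with replacement), screen all 20 predictors
  for marginal association, adjust the p-values to control the FDR at
  10%, and record the product-term coefficient only when both members of
  the target pair survive the screen (zero otherwise); the interaction
  is declared when the percentile 95% CI of the recorded coefficient
  excludes zero.  For the three-way coefficient an outer bootstrap
  repeats the two-way procedure on resampled data; b123 is estimated
  (with its constituent two-way terms in the model) only when at least
  two of b12, b13, b23 were called significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .boosting import GbmParams
from .interaction import null_distribution

__all__ = ["PowerConfig", "PowerResult", "gen_power_data", "power_boosted", "power_parametric"]

N_PREDICTORS = 20


@dataclass
class PowerConfig:
    """One cell of the power study."""

    model: str = "two_way"          # or "three_way"
    n: int = 500
    beta12: float = 0.5             # two-way model coefficient
    beta_two_way: float = 0.5       # common b12=b13=b23 in the three-way model
    beta123: float = 0.5
    n_datasets: int = 100
    B: int = 100                    # inner bootstrap resamples
    outer_B: int = 100              # outer bootstrap (three-way only)
    fdr_level: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("two_way", "three_way"):
            raise ValueError("model must be 'two_way' or 'three_way'")
        if self.n < 10:
            raise ValueError("n too small")

    @property
    def target_subset(self) -> tuple[str, ...]:
        return ("x1", "x2") if self.model == "two_way" else ("x1", "x2", "x3")

    def signal_variance(self) -> float:
        if self.model == "two_way":
            return 2.0 + self.beta12**2
        return 3.0 + 3.0 * self.beta_two_way**2 + self.beta123**2


@dataclass
class PowerResult:
    config: PowerConfig
    method: str
    power: float
    n_datasets: int
    detections: np.ndarray = field(default_factory=lambda: np.empty(0))

    def to_record(self) -> dict:
        c = self.config
        return {
            "method": self.method,
            "model": c.model,
            "n": c.n,
            "beta12": c.beta12 if c.model == "two_way" else c.beta_two_way,
            "beta123": c.beta123 if c.model == "three_way" else np.nan,
            "power": self.power,
            "n_datasets": self.n_datasets,
        }


def gen_power_data(
    config: PowerConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw one dataset (X with columns x1..x20, outcome y) at SNR = 1."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n
    Xm = rng.standard_normal((n, N_PREDICTORS))
    x1, x2, x3 = Xm[:, 0], Xm[:, 1], Xm[:, 2]
    if config.model == "two_way":
        signal = 1.0 + x1 + x2 + config.beta12 * x1 * x2
    else:
        b, b123 = config.beta_two_way, config.beta123
        signal = (
            1.0 + x1 + x2 + x3
            + b * x1 * x2 + b * x1 * x3 + b * x2 * x3
            + b123 * x1 * x2 * x3
        )
    sigma = np.sqrt(config.signal_variance())  # SNR = 1
    y = signal + rng.normal(0.0, sigma, size=n)
    X = pd.DataFrame(Xm, columns=[f"x{j + 1}" for j in range(N_PREDICTORS)])
    return X, y


# ----------------------------------------------------------------------
# Boosted-H method
# ----------------------------------------------------------------------

def power_boosted(
    config: PowerConfig,
    gbm_params: GbmParams | None = None,
    n_rep_null: int = 50,
) -> PowerResult:
    """Detection rate of the H-based rule over repeated datasets."""
    params = gbm_params or GbmParams(n_trees=300, depth=3, shrinkage=0.05,
                                     backend="hist")
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_datasets)
    detect = np.zeros(config.n_datasets, dtype=bool)
    for d in range(config.n_datasets):
        rng = np.random.default_rng(int(seeds[d] % (2**31 - 1)))
        X, y = gen_power_data(config, rng)
        (assessment,) = null_distribution(
            X, y, params, [config.target_subset],
            n_rep=n_rep_null, seed=int(seeds[d] % (2**31 - 1)),
        )
        detect[d] = assessment.significant
    return PowerResult(config, "boosted_h", float(detect.mean()),
                       config.n_datasets, detect)


# ----------------------------------------------------------------------
# Parametric-bootstrap comparator
# ----------------------------------------------------------------------

def _marginal_pvalues(Xm: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Slope t-test p-value of y on each column alone (vectorised)."""
    n = Xm.shape[0]
    xc = Xm - Xm.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc**2).sum(axis=0))
    sy = np.sqrt((yc**2).sum())
    r = xc.T @ yc / (sx * sy)
    r = np.clip(r, -0.999999999, 0.999999999)
    t = r * np.sqrt((n - 2) / (1.0 - r**2))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def _ols_coef(columns: list[np.ndarray], y: np.ndarray, target: int) -> float:
    A = np.column_stack([np.ones_like(y)] + columns)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[1 + target])


def _pair_ci(
    Xm: np.ndarray,
    y: np.ndarray,
    pair: tuple[int, int],
    B: int,
    fdr_level: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Percentile 95% CI of the screened product-term coefficient."""
    n = Xm.shape[0]
    j1, j2 = pair
    draws = np.zeros(B)
    for b in range(B):
        while True:
            idx = rng.integers(0, n, n)
            Xb = Xm[idx]
            if Xb.std(axis=0).min() > 0:
                break
        yb = y[idx]
        pvals = _marginal_pvalues(Xb, yb)
        reject = multipletests(pvals, alpha=fdr_level, method="fdr_bh")[0]
        if reject[j1] and reject[j2]:
            x1, x2 = Xb[:, j1], Xb[:, j2]
            draws[b] = _ols_coef([x1, x2, x1 * x2], yb, target=2)
    return tuple(np.percentile(draws, [2.5, 97.5]))


def _ci_excludes_zero(ci: tuple[float, float]) -> bool:
    lo, hi = ci
    return not (lo <= 0.0 <= hi)


def power_parametric(config: PowerConfig) -> PowerResult:
    """Detection rate of the screen-then-test bootstrap comparator."""
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_datasets)
    detect = np.zeros(config.n_datasets, dtype=bool)
    pairs = [(0, 1), (0, 2), (1, 2)]
    for d in range(config.n_datasets):
        rng = np.random.default_rng(int(seeds[d] % (2**31 - 1)))
        X, y = gen_power_data(config, rng)
        Xm = X.to_numpy()
        if config.model == "two_way":
            ci = _pair_ci(Xm, y, (0, 1), config.B, config.fdr_level, rng)
            detect[d] = _ci_excludes_zero(ci)
        else:
            n = Xm.shape[0]
            draws = np.zeros(config.outer_B)
            for ob in range(config.outer_B):
                idx = rng.integers(0, n, n)
                Xo, yo = Xm[idx], y[idx]
                n_sig = sum(
                    _ci_excludes_zero(
                        _pair_ci(Xo, yo, p, config.B, config.fdr_level, rng)
                    )
                    for p in pairs
                )
                if n_sig >= 2:
                    x1, x2, x3 = Xo[:, 0], Xo[:, 1], Xo[:, 2]
                    draws[ob] = _ols_coef(
                        [x1, x2, x3, x1 * x2, x1 * x3, x2 * x3, x1 * x2 * x3],
                        yo, target=6,
                    )
            detect[d] = _ci_excludes_zero(tuple(np.percentile(draws, [2.5, 97.5])))
    return PowerResult(config, "parametric_bootstrap", float(detect.mean()),
                       config.n_datasets, detect)
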