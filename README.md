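# mixboost

Discovery of complex interaction and non-linear effects among many
correlated exposures with stochastic gradient boosted regression trees
and the Friedman–Popescu H statistic.

## The problem

Studies of chemical mixtures — environmental contaminants measured in
blood against a continuous health outcome — face three obstacles at
once: the exposures are numerous and correlated, they may act
non-linearly, and they may interact in combinations (two-way up to
four-way) that no regression model with hand-picked product terms can
enumerate.  `mixboost` addresses this with a statistical-learning
workflow: fit an ensemble of depth-limited regression trees by
stochastic gradient boosting, which represents non-linearities and
interactions automatically, then *measure* the interaction content of
the fitted surface and test it against a simulated no-interaction null.

## The method

The fitted function is F̂(x) = α + λ Σₘ bₘ(x), a shrunken sum of M
depth-d CARTs each fit to the negative loss gradient on a random half
of the data.  Its interpretation rests on the partial dependence of a
variable subset S, F̂_S(x_S) = N⁻¹ Σᵢ F̂(x_S, x₋S,ᵢ), computed here by
an exact tree recursion rather than the expensive definitional average.
The interaction strength of a pair (j, k) is the H statistic

    H²_jk = Σᵢ [F̂_jk − F̂_j − F̂_k]² / Σᵢ F̂²_jk,   H ∈ [0, 1],

with analogous total (one variable against all others) and
higher-order (inclusion–exclusion) forms.  Because trees fit
interactions even in additive data, an observed H is judged against a
parametric-bootstrap null H⁰: refit the model to artificial outcomes
ỹᵢ = F_A(xᵢ) + y_{p(i)} − F_A(x_{p(i)}) built from an additive
(depth-1) fit F_A and permuted residuals, many times; a subset is
flagged when H exceeds the 95th percentile of H⁰, and verdicts are
stress-tested by repeated split-sample validation.

The package also ships a synthetic contaminant-panel generator with a
known truth (a four-way synergy among PCB 170, p-p'-DDE, MMP and Cd, a
U-shaped OCDD term, and a BPA-by-sex interaction) for calibration and
power studies, plus a power benchmark against the conventional
screen-then-test product-term bootstrap with FDR-controlled screening.

## Worked example

```python
import numpy as np
from mixboost import BoostedTreeModel, GbmParams, SimulationConfig, simulate_study

data, outcome = simulate_study(SimulationConfig(snr=2.0, seed=1))
model = BoostedTreeModel.from_dataframe(data, outcome="y")
res = model.fit(GbmParams(n_trees=3500, depth=6, shrinkage=0.005,
                          subsample=0.5, backend="hist", seed=1))

print(res.summary(top=5))
print()
tests = res.interaction_test([("p-p'-DDE", "PCB 170"),
                              ("p-p'-DDE", "OCDD")], n_rep=50, seed=7)
for t in tests:
    print(f"H({' x '.join(t.subset)}) = {t.h_observed:.3f}  "
          f"null 95th = {t.null_p95:.3f}  significant: {t.significant}")
```

prints

```
Boosted regression trees
============================================
observations:     1000
predictors:       28
loss:             squared
trees (M):        3500
depth (d):        6
shrinkage:        0.005
subsample:        0.5
backend:          hist
training R2:      0.991

variable importance (top 5, max = 100)
--------------------------------------------
OCDD                    100.0
PCB 170                  36.7
p-p'-DDE                 23.4
MMP                      19.4
Cd                       15.6

H(p-p'-DDE x PCB 170) = 0.162  null 95th = 0.079  significant: True
H(p-p'-DDE x OCDD) = 0.030  null 95th = 0.073  significant: False
```

The fit recovers the target variables at the top of the importance
ranking; the planted p-p'-DDE × PCB 170 interaction stands far outside
its null, while the pair with the (purely additive) OCDD term does
not.  The same analysis runs from the shell on any CSV with a `y`
column:

```
mixboost simulate --seed 1 --out sim/
mixboost analyze sim/data.csv --seed 1 --out results/
mixboost power --seed 1 --out power/
```

Each command writes CSV/JSON tables, figures and a manifest with
configuration, seeds and artifact digests; `--full-budget` switches
from desk-scale to publication-scale replication counts.

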