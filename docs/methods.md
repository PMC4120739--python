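# Methods

## The problem

Epidemiological studies of chemical mixtures measure dozens of
correlated exposures against a health outcome.  Product-term regression
cannot enumerate the candidate interactions (hundreds of pairs, thousands
of triples), and pre-screening main effects misses interactions without
marginal signal.  `mixboost` implements an alternative: fit a stochastic
gradient boosted ensemble of regression trees — which represents
interactions and non-linearities automatically — and then *measure* the
interaction content of the fitted function with the Friedman–Popescu
H statistic, judged against a simulated null distribution.

## Model

The fitted function is an additive expansion of depth-limited CARTs,

    F̂(x) = α + λ Σₘ₌₁ᴹ bₘ(x),

grown by stochastic gradient boosting: initialise to the loss-optimal
constant α (mean for squared-error loss, median for absolute-error
loss); at each of M iterations draw a fraction η of the data without
replacement, fit a depth-d CART to the negative gradient of the loss at
the current fit, set each leaf to its loss-optimal constant (the line
search ρ is absorbed into the leaf values), and add the tree with
shrinkage λ.  A depth-d tree can express interactions of order at most
d, so d = 1 forces an additive model.

Parameters and defaults:

| parameter | meaning | default | notes |
|---|---|---|---|
| M (`n_trees`) | boosting iterations | 1000 | tuned by the bootstrap |
| d (`depth`) | max splits per root-leaf path | 5 | tuned; bounds interaction order |
| λ (`shrinkage`) | learning rate | 0.005 | small values need thousands of trees |
| η (`subsample`) | subsample fraction per iteration | 0.5 | the customary value |
| `min_obs_per_leaf` | smallest leaf | 10 | stops tree growth |
| `loss` | squared or absolute | squared | absolute for heavy-tailed outcomes |

Two tree-growing backends produce the same flat per-node representation:
an exact greedy CART loop (scikit-learn decision trees inside our own
boosting iteration; the reference path, used by the small-scale oracle
tests) and a histogram backend (LightGBM, 255 bins, single-threaded,
deterministic) that fits 3500-tree ensembles in seconds and is used for
the large simulation runs.  Everything downstream — prediction, staged
prediction, importance, partial dependence, H — runs on the shared
representation, so backend choice only affects how splits were found.

## Partial dependence

The partial dependence of F̂ on a variable subset S is the average of F̂
over the empirical distribution of the complement:
F̂_S(x_S) = N⁻¹ Σᵢ F̂(x_S, x₋S,i).  The package computes it two ways:

* **brute** — the definition, one full prediction pass per evaluation
  point (O(N · n_points) row descents per tree);
* **recursion** — per tree, the brute average factorises over leaves
  into (S-constraint indicator of the point) × (fraction of reference
  rows satisfying the leaf's non-S constraints); two root-to-leaf
  weight propagations per tree replace the cross product.  This is
  algebraically identical to brute (the test suite demands agreement to
  1e-8; it achieves ~1e-15) at roughly N + n_points instead of
  N · n_points work.

A data-free variant (the classic traversal that combines children of
non-S splits by stored training fractions) is kept for deserialised
models without data; it is only approximate when splits on S sit above
splits on correlated complement variables, because stored child counts
are conditional on the path where the definition needs marginal
fractions.  All PD functions are centered to mean zero over their
evaluation points before any H computation; H is a ratio of centered
second moments and is meaningless otherwise.

## H statistics and the parametric-bootstrap null

For a pair (j, k), evaluated at the N data rows,

    H²_jk = Σᵢ [F̂_jk(xᵢⱼ, xᵢₖ) − F̂_j(xᵢⱼ) − F̂_k(xᵢₖ)]² / Σᵢ F̂²_jk(xᵢⱼ, xᵢₖ),

and H = √H² ∈ [0, 1].  The "total" statistic of a single variable j
uses F̂ − F̂_j − F̂_{−j} in the numerator and Σ F̂² in the denominator.
For |S| ≥ 3 the numerator is the inclusion–exclusion residual
Σ_{T⊆S} (−1)^{|S|−|T|} F̂_T, the standard form isolating the pure
|S|-way term.  A zero denominator (a subset the model never uses)
returns H = 0 with a warning.

Trees fit interactions by construction, so H is biased above zero even
for additive truths.  The null H⁰ is built by a parametric bootstrap:
fit the best additive model F_A (the same boosting configuration with
d = 1 — stumps still capture non-linearities through iteration), form

    ỹᵢ = F_A(xᵢ) + y_{p(i)} − F_A(x_{p(i)})

for a uniform random permutation p (additive signal kept, residuals
exchanged, interactions destroyed), refit the full-depth model on
(X, ỹ), recompute H, and repeat (250 times at publication scale).  A
subset is declared significant when observed H exceeds the null's 95th
percentile.  The main study uses this rule for automation even though a
visual comparison of observed H against the null box is equally valid;
resampling p-values are exported as advisory only, because the
higher-order nulls are extremely narrow and small absolute H values can
be formally significant.

Split-sample stability repeats the verdict on ten random half-splits:
fit the training half, rebuild the null on the training half, evaluate
both observed and null H at the validation rows, and report the
detection count (e.g. 10/10).  Rebuilding the null per split and
evaluating at validation rows were design choices; the alternative
(reusing the full-data null) shares information across splits and was
rejected.

## Tuning

(M, d) are chosen by bootstrap-validated grid search: per replicate,
draw a bootstrap sample, fit once per depth at the largest M, and score
staged predictions on the out-of-bootstrap rows at every grid M (one
fit serves the whole M axis).  R² = 1 − MSE/var on the holdout, with
its SE across replicates.  The one-standard-error rule picks the most
parsimonious grid point within one SE of the best mean R²; parsimony
orders by smaller depth first, then fewer trees, since depth bounds the
interaction order and is the more consequential parameter.

## The synthetic mixture study

The generator emulates a blood-contaminant panel from an elderly
population cohort: 27 log-normal contaminant concentrations — six PCB
congeners with a correlated 4-marker block (Gaussian copula on the log
scale, default pairwise correlations 0.3–0.7), organochlorines, BDE47,
BPA, four phthalate metabolites, eleven metals — plus Bernoulli(0.5)
sex, n = 1000.  Log-scale means default to 0 and SDs cycle through
0.4–1.0; the unit-interval transform below makes the target function
insensitive to these choices.

The outcome truth is

    F = 11·e^{−3(1−s[PCB170])²}·e^{−3(1−s[DDE])²}·e^{−2(1−s[MMP])²}·e^{−2(1−s[Cd])²}
        − 1.6·sin(2π·s[OCDD]) + s[BPA]^{0.6 + 1.8·I[sex=male]},

i.e. a four-way synergy, a U-shaped (on the log scale) OCDD term and a
BPA-by-sex interaction, with y = F + N(0, σ) and σ = sd(F)/√SNR for
SNR ∈ {2, 1, 0.5, 0.1}.  The realized SNR, var(F)/var(ε) of the drawn
noise, is required to land within 10% of the target; the generator
redraws the noise on the rare misses.

Two choices deserve comment:

* **The s transform.**  s[·] maps concentrations onto [0, 1].  The
  default is min–max scaling of the log concentration, which for
  log-normal data yields a bell-shaped s (sd ≈ 0.15) and var(F) ≈ 1.7
  at n = 1000 — the scale that reproduces the published RMSE values of
  the reference study this generator is calibrated against.  A mid-rank
  probability-integral variant (`method="rank"`, uniform s, var(F) ≈
  3.5) is provided for distribution-free work; error metrics on the y
  scale change accordingly, R²-type results do not.
* **Transform-then-split.**  s is computed once on the full sample
  before any train/validation splitting, because the truth is defined
  on the complete dataset.

What the generator does *not* emulate: detection limits and censoring,
measurement error, missing data, skewed noise, correlations between
contaminant classes, and confounding by covariates other than sex.
Passing the simulation study therefore demonstrates the machinery on
clean, fully observed log-normal panels, not robustness to those
complications.

Known limitation: with the printed target function, sex enters only
through the BPA exponent, and its share of var(F) is a few percent.  In
our replications sex reliably reaches the top-10 importance list only
in the strong-signal scenario; at SNR ≤ 1 it is usually outranked by
spurious splits on noise contaminants.  The six continuous target
variables are recovered robustly at SNR ≥ 0.5.  Relatedly, the
generator's RMSE scale sits ~5 % below the reference values at SNR ≥ 1
(its var(F) ≈ 1.7 versus ≈ 1.8–1.9 implied by the published table);
R² values match throughout.

## Power study

Twenty independent N(0,1) predictors; outcomes

    y = 1 + x₁ + x₂ + β₁₂x₁x₂ + ε                      (two-way)
    y = 1 + x₁ + x₂ + x₃ + β₁₂x₁x₂ + β₁₃x₁x₃ + β₂₃x₂x₃ + β₁₂₃x₁x₂x₃ + ε

with β from {0.25, 0.5, 1}, the three two-way coefficients tied in the
three-way model, and σ set analytically for SNR = 1 (all terms are
uncorrelated with unit variance, so var(signal) is the sum of squared
coefficients).  The boosted method declares the target interaction when
observed H exceeds its null's 95th percentile.  The comparator is the
conventional screen-then-test bootstrap: per resample (drawn with
replacement), screen all 20 predictors marginally (simple linear
regression, slope t-test), Benjamini–Hochberg-adjust to a 10% FDR, and
record the product-term coefficient only when both pair members survive
(zero otherwise); significance is a percentile 95% CI excluding zero.
The three-way variant wraps an outer bootstrap around the pair
procedure and estimates β₁₂₃ (with its two-way components in the model)
only when at least two pairs were called significant.  Screen failures
enter the bootstrap distribution as exact zeros, so the CI's lower
bound collapses to zero whenever more than 2.5% of resamples fail the
screen — the mechanism behind the comparator's weak three-way power.

## Numerical choices

* Ties in split gain are broken by the backend (feature order in the
  exact backend, histogram order in LightGBM); H is insensitive to
  tie-breaks at the scales used.
* Split-improvement importance sums the decrease in (squared-error)
  training loss over all splits per variable, scaled so the maximum is
  100; all-zero improvements are reported unscaled.
* The 95th percentile of H⁰ uses linear interpolation
  (`numpy.percentile`); at the desk-scale 50 replicates this is the
  region between the 47th and 48th order statistic.
* H evaluation can be restricted to a fixed random row subset
  (`h_rows`) for speed; observed and null statistics always share the
  same rows.
* Degenerate inputs: constant y yields the constant ensemble; constant
  F is rejected (SNR undefined); non-finite values are rejected on
  entry.

## Desk-scale problem sizes

Published-scale replication (250 bootstrap replicates, 250 null
datasets, 100 power datasets with B = 100 bootstraps) is available
behind `--full-budget` in the CLI.  The test suite and the acceptance
script run the same code at desk scale, chosen as the smallest sizes at
which the checks are statistically meaningful: 25 out-of-bootstrap
replicates × 2 seeds for the performance table (the suite's fixture
uses 12); 50 null replicates for interaction recovery with a 400-tree
ensemble whose shrinkage is raised to 0.04375 so that λ·M matches the
full-scale 0.005 × 3500; 10 half-sample splits with 20-replicate nulls
for stability; 200 repetitions with 19-replicate nulls for the type-I
calibration; and 12 datasets per cell for power monotonicity.  One
subtlety of small nulls: the interpolated 95th percentile of n draws
sits near the ⌈0.95·n⌉-th order statistic, so the percentile rule's own
level is (0.05·n + 0.95)/(n + 1) — about 10% at n = 19, 6.8% at n = 50
and 5.4% at the publication-scale n = 250.  The type-I calibration
check therefore uses the exact finite-sample cut "observed exceeds
every null draw" (level exactly 1/(n + 1)); desk-scale detection
results should be read with the slightly inflated percentile-rule level
in mind.
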