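# Methods

`survcompare` implements two competing modelling tracks for right-censored
time-to-event cohorts and a framework for adjudicating between them. This
note records the models, the numerical choices, the synthetic-data
generator, and the limits of what the test suite demonstrates.

## Data model

A cohort is a set of records (tᵢ, δᵢ, xᵢ) with tᵢ > 0 a duration (hours in
the motivating cardiac-surgery application), δᵢ ∈ {0, 1} the event
indicator (1 = event observed, 0 = right-censored), and xᵢ a mixed
numeric/categorical covariate vector described by an ordered schema.
Categorical covariates carry an ordered level list whose first level is the
reference. Only right censoring is supported; left and interval censoring
are out of scope.

Ties between a death and a censoring at the same time follow the standard
convention that censoring occurs immediately after the death, so censored
records still count in the risk set at that time.

## Nonparametric core

* **Kaplan–Meier**: S^(t) = ∏_{j: t_j ≤ t} (1 − d_j/n_j) over distinct
  death times; censored records contribute to risk sets only.
* **Nelson–Aalen**: H^(t) = Σ_{j: t_j ≤ t} d_j/n_j, with companion
  survival S~(t) = exp(−H^(t)).
* **Log-rank test** (r groups): observed-minus-expected death counts per
  group summed over death times, standardized by the summed hypergeometric
  covariance; the statistic is referred to χ²(r−1) with no continuity
  correction (large-sample reference). Risk-set times with n_j ≤ 1
  contribute nothing.
* **Harrell C-index** with the survival-forest tie rules: permissible
  pairs exclude those whose shorter time is censored and equal-time pairs
  with both members censored; credit is 1 for a concordant ordering, 0.5
  for a score tie; equal-time pairs with two deaths score 1 when the
  scores are equal (else 0.5), and death/censoring ties score 1 when the
  death carries the higher score (else 0.5). Prediction error is 1 − C.

Step estimates are right-continuous: evaluation at t returns the value at
the largest step time ≤ t, with baseline 1 (survival) or 0 (hazard).

## Weibull accelerated failure time track

Model: Yᵢ = log Tᵢ = xᵢ'β + σνᵢ with νᵢ standard Gumbel-minimum, i.e. Tᵢ
Weibull with shape γ = 1/σ and characteristic life exp(xᵢ'β). The
right-censored log-likelihood on the log-time scale, with
zᵢ = (log tᵢ − xᵢ'β)/σ, is

    ℓ(β, τ) = Σᵢ [ δᵢ(−τ + zᵢ − e^{zᵢ}) + (1 − δᵢ)(−e^{zᵢ}) ],  σ = e^τ.

(The reported log-likelihood therefore differs from a time-scale
likelihood by the θ-free Jacobian Σ δᵢ log tᵢ, which cancels in any
likelihood-ratio statistic; the cross-check against lifelines in the test
suite accounts for this explicitly.)

Numerical choices:

* Optimization over (β, τ = log σ) keeps σ > 0 unconstrained. β is
  initialized by least squares of log t on the design (censored records
  included as-is), τ = 0. L-BFGS-B runs first; a Newton polish with a
  central-difference Hessian (step 1e-5·(1+|θ_k|)) then drives convergence.
  Convergence is declared on gradient norm ≤ 1e-8·(1+|ℓ|) or on a Newton
  decrement g'H⁻¹g below 1e-12·(1+|ℓ|) — the attainable likelihood gain,
  which is the robust criterion when float resolution of ℓ binds before
  the gradient does.
* e^{z} is clipped at z = 500 purely as an overflow guard far from any
  optimum (logged at debug level).
* τ is box-bounded at ±12; a solution at the bound sets a `boundary` flag
  (degenerate data such as all-equal times push σ → 0) and suppresses
  standard errors.
* Standard errors come from the inverse observed information (numerical
  Hessian at the optimum); Wald p-values use the two-sided normal
  reference, including for τ. `fix_scale=1` pins σ = 1, giving the
  censored-exponential sub-model whose intercept-only MLE
  log(Σtᵢ/Σδᵢ) serves as a closed-form oracle.
* The design matrix is reference-coded: intercept, numerics in schema
  order, then indicator columns per non-reference level. Rank deficiency
  is an error naming the collinear columns — including the practically
  important case of a categorical level absent from the data.

Diagnostics:

* Cox–Snell residuals êᵢ = (tᵢ e^{−μ̂ᵢ})^{1/σ̂}, with +1 added for
  censored records so they can be treated as uncensored unit-exponential
  draws. Martingale residuals m̂ᵢ = δᵢ − êᵢ are defined against the
  *adjusted* Cox–Snell residual: censored records then satisfy m̂ᵢ ≤ −1,
  and this convention is the one that reproduces the published worked
  values. Deviance residuals are
  sign(m̂ᵢ)·sqrt(−2(m̂ᵢ + δᵢ log(δᵢ − m̂ᵢ))), with the log term dropped
  for censored records.
* Goodness of fit compares the Kaplan–Meier curve of the Cox–Snell
  residuals (with their original censoring status) against exp(−e);
  numeric output only, plotting is out of scope.
* `predict_time` returns the characteristic life exp(x'β̂) — the scale on
  which the published worked predictions live — with the model q-quantile
  exp(x'β̂)(−log(1−q))^σ̂ available through a `quantile` argument.
  `median_time_ratio` returns exp(β̂_j), which is simultaneously the ratio
  of *every* quantile between patterns differing by one unit of x_j.
* Case-deletion refits report each coefficient and Wald p-value per
  deletion set and flag 5%-significance changes against the full fit.

## Random survival forest track

Trees are grown on bootstrap samples of size n (uniform, with
replacement). Tree features are the design columns without the intercept
(numerics plus reference-skipping 0/1 indicators), each tagged with its
parent covariate; candidate sampling and importance operate per covariate.

* **Split rule**: at each splittable node, mtry candidate covariates are
  drawn without replacement (default mtry = ⌈√p⌉ over the p covariates);
  for every candidate column all midpoints between consecutive distinct
  values are scanned and the split maximizing the absolute standardized
  log-rank statistic |LR(x, c)| is taken. Ties break to the first
  covariate in schema order, then the smallest threshold. Death times with
  node risk set ≤ 1 contribute to neither the numerator nor the variance
  sum; a zero variance sum defines LR = 0.
* **Stopping**: a node is terminal when it holds fewer than
  2·min_terminal_size records (default 10), contains no death, or admits
  no valid split (all candidates constant). Terminal nodes store the
  Nelson–Aalen cumulative hazard of their in-bag records.
* **Ensembles**: a pattern's tree hazard is that of the terminal node it
  routes to; the ensemble hazard is the pointwise average over trees on
  the union of their step grids. OOB averages restrict to trees whose
  bootstrap sample excluded the record. Mortality scores sum the ensemble
  hazard over the distinct ordered training death times; OOB error is
  1 − C of the OOB mortality scores.
* **VIMP** is random-daughter importance: each OOB record is dropped down
  each tree again, but at any node splitting on the target covariate it is
  sent to a uniformly random child; VIMP is the noised OOB error minus the
  original. A covariate never chosen by any node has VIMP exactly 0.

Randomness contract (reproducibility and the naive-reference oracle):
tree b draws from `default_rng([seed, b])` — bootstrap indices first, then
one mtry draw per splittable node in depth-first order (left subtree fully
grown before the right). VIMP for covariate index v draws from
`default_rng([seed, 2^20 + v])`, visiting trees in index order and drawing
one uniform per record at each v-node, records in ascending index order.
This makes the whole pipeline bit-reproducible and lets the test suite
demand *exact* agreement with an independent loop-based reference
implementation at small n and B.

## Comparison framework

`compare_models` produces a three-row report: RSF on the training
partition (OOB error), RSF on a held-out partition (all-tree ensemble
scores), and the Weibull track. The train/test split is a seeded holdout
stratified by the event indicator (default test fraction 0.3); the study
being emulated never describes its split, so this is a documented
assumption. The Weibull row is fitted and scored in-sample on the full
cohort by default — matching the single-fit narrative of the original
analysis — with a `holdout_weibull` switch for symmetry. Weibull variable
selection is backward elimination: repeatedly drop the covariate whose
worst Wald p-value across its columns exceeds α = 0.05. Forest selection
keeps covariates with VIMP > 0, in descending order.

The report serializes with sorted keys and floats at 6 significant digits;
a wall-clock timestamp field exists in memory but is excluded from the
canonical serialization so regeneration under the same seed is
byte-identical.

## Synthetic cohorts

The generator draws covariates independently per record (uniform or
truncated-normal-mixture numerics; categorical levels with fixed
probabilities), then log T = x'β + σν with ν = log E, E ~ Exp(1).
Censoring is independent uniform on [0, c*], with c* solved by Brent
root-finding so that the expected censored fraction of the drawn times,
E[min(Tᵢ/c, 1)] averaged over the sample, hits the target; realized
fractions concentrate within a few percent of the target for n in the
hundreds.

`default_cardiac_like_config` emulates the motivating cohort: n = 145;
protocol 61% fast-track; patient type 52% coronary; race 95/3/2%
white/black/Asian; sex 63% male; age a two-component mixture (young
congenital-like component, mean 11 ± 12 years, and an older coronary-like
component, mean 59 ± 11, clipped to the observed age ranges); true effects
intercept 1.59, fast-track −0.26, coronary 0.56 on log-hours, σ = 0.22;
censoring target 0.25 (≈75% of records uncensored). Age, race and sex
carry no effect, matching their nonsignificance in the final published
model. What the generator does **not** emulate: the dependence between age
and patient type present in the real cohort (covariates are drawn
independently), covariate-dependent censoring, and any misspecification of
the AFT form — so passing recovery tests demonstrates correctness of the
estimators under the model, not robustness to model violation.

## Problem sizes used by the test suite

Simulation-backed checks run at sizes chosen to make their sampling noise
small relative to the tolerances asserted: parameter recovery uses 100
replicates of n = 1000; forest sanity uses 20 replicates of n = 200 with
500 trees for both a five-noise-covariate null (OOB error near 0.5, mean
VIMP near 0) and a two-group signal with scale ratio 4 (OOB error well
below 0.5, informative VIMP positive); the exact-oracle comparison runs at
n = 22 with 5 trees where a loop-based reference is feasible. The
bundled acceptance script is deterministic: it rebuilds the published
final model from its printed coefficients and recomputes the worked-example
quantities (predictions, median-time ratios, residuals) from scratch.

## Known limitations

* Single error law (Weibull/Gumbel-minimum); no log-normal or
  log-logistic AFT, no Cox proportional hazards, no frailty.
* Exhaustive midpoint split scan only (no random-split subsampling); can
  be slow for nodes with many distinct numeric values.
* No competing risks, proximity matrices, or alternative split rules.
* Backward elimination uses the Wald criterion only; with k noise
  covariates tested at level α the probability of a perfectly clean
  selection is (1−α)^k by construction, not 1.
* Confidence bands for the nonparametric curves and all plotting are out
  of scope; outputs are numeric tables.
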