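# Methods

This note documents the models, the synthetic-data design, the numerical
choices, and the limits of what the test suite demonstrates.

## Setting and estimand

A cohort of n subjects carries a binary outcome Y, a continuous exposure X,
confounders Z = (Z1, Z2, Z3) and W, and auxiliary variables A = (A1, A2)
and D. The estimand is the conditional exposure effect βX in

    logit Pr(Y=1 | X, Z, W) = β0 + βX·X + βZ·Z + βW·W.

Y is missing not at random: its missingness indicator M^Y depends on Y
itself (and on X, A, D) even after conditioning on everything observed.
X, W and D are missing at random given the fully observed Z and A. Because
the observed data carry no information about the Y–M^Y dependence, both
bias models below contain one unidentified *bias parameter* and the
analyses place a Normal prior on it.

## The selection-model generator and the sign of δ^SM

The selection-model (SM) generator factorises the joint distribution as
W←Z, X←(W,Z), Y←(X,W,Z), A←(Y,X,W,Z), D←(A,Y,X,W,Z), M^Y←(D,A,Y,X), with
logistic regressions for binary variables and a linear regression for X.
The outcome-missingness model is parametrised

    logit Pr(M^Y=1 | D, A, Y, X) = ψ0 + ψD·D + ψA·A + ψX·X − δ^SM·Y,

i.e. **δ^SM is the increase in the log-odds of *observing* Y per unit of
Y**. With δ^SM = 7.85 — the very strong MNAR mechanism used throughout —
cases are almost always observed while most non-cases are not. This is the
only internally consistent orientation for the motivating setting: the
observed (tested) subset is strongly case-enriched (28.6% positive among
tested versus a few percent marginally), the matched informative priors
have opposite signs on the selection and pattern-mixture scales (+2.6
versus −2.6), and a reversed sign would leave essentially no observed
cases, making CCA infeasible.

### Default (demo) coefficients

The exact coefficient values of the motivating cohort are not
redistributable, so the package ships a self-contained demo set of similar
magnitudes, frozen in `synthetic_data.SMDGMParams` and chosen once to
emulate a large biobank-style epidemiological cohort:

- Z1 ~ Bernoulli(0.5) (sex-like), Z2 ~ N(0,1) (standardized age-like),
  Z3 ~ Bernoulli(0.33) (education-like); W (smoker-like, ~10%);
  A1 (~12%), A2 (~7%) and D (~30%) are comorbidity-like binaries with
  moderate-to-strong positive dependence on Y (log-odds 0.8–1.0), making
  them genuinely informative auxiliaries;
- X has conditional residual variance ξ² = 0.97 so that its marginal
  mean/SD are 0/1 to within Monte Carlo error;
- β0 is calibrated to a 5% marginal outcome prevalence (below);
  βX ∈ {0, ln 3} by scenario; δ^SM = 7.85;
- ψ0 = 1.9 with negative ψ coefficients on D, A, X yields ~80% missing
  outcomes overall with ~25% positivity among the observed — the same
  regime as the motivating cohort (98.9% untested, 28.6% positivity),
  compressed to a missingness fraction that keeps desk-scale complete-case
  analyses well conditioned;
- MAR mechanisms for X, W, D use the published logistic coefficients of the
  motivating cohort verbatim (intercepts −3.20/−2.90/−2.95), giving ~5%
  missingness each.

These values were fixed by design before any performance evaluation and
are not tuned; under them CCA underestimates βX by ≈ 0.20 log-odds at
n = 100,000, which is the "substantial bias, severe undercoverage" regime
the generator is meant to produce.

### Intercept calibration

`calibrate_y_intercept` fixes a calibration sample of (W, X, Z) with
common random numbers and root-finds β0 on the *exact* conditional mean
`mean_i expit(β0 + lp_i)` — smooth, strictly increasing in β0, no
Bernoulli noise — with Brent's method (default sample 200,000; tolerance
±0.002 on the prevalence). Degenerate targets (0 or 1) and non-bracketing
bounds raise.

## The pattern-mixture generator

The pattern-mixture (PMM) factorisation cannot be derived analytically
from the SM one, so its coefficients are maximum-likelihood fits of the
PMM component regressions to a large SM-generated sample (50,000,000 at
full scale; desk-scale runs use 0.8–2 million and inherit correspondingly
more Monte Carlo error in the fitted coefficients). The component order
places the fully observed variables and M^Y first and Y last, mirroring
the NARFCS bias model:

    Z marginals → A1|Z → A2|A1,Z → M^Y|A,Z → W|M^Y,A,Z → X|W,M^Y,A,Z
    → D|X,W,M^Y,A,Z → Y|X,W,D,A,Z,M^Y

The Y-model's coefficient on M^Y is δ^NARFCS — the log-odds difference in
Pr(Y=1) between missing and observed records. Under the default design it
is strongly negative (≈ −7.9): the missing are almost never cases. The two
factorisations agree closely but not exactly (each PMM conditional is only
approximately logistic/linear); the marginal outcome prevalences match to
within 0.005 at n = 200,000, and the PMM-truth βX is re-estimated from a
large pre-deletion PMM sample rather than taken from the SM parameter.

## Truth values

For the SM generator βX and δ^SM are parameters; δ^NARFCS is estimated by
fitting the pattern-mixture Y-model (with all four missingness-indicator
covariates) to a large complete sample. For the PMM generator δ^NARFCS is
the fitted parameter and βX is estimated from a large complete sample
before deletion. The default truth-sample size is 5,000,000 (tests and the
acceptance script use 150,000–1,000,000; the resulting Monte Carlo error
in δ^NARFCS_true is ~0.02–0.05 log-odds and is absorbed by the 3-SE
tolerances used in the recovery tests).

## NARFCS imputation engine

Standard FCS with pattern-mixture predictor sets: every univariate model
conditions on all other variables *plus the missingness indicators of the
other partially observed variables*; a variable's own indicator never
enters as a predictor. The MNAR outcome's model carries the fixed offset
δ·M^Y, inestimable from data (the model is fitted on observed-outcome rows
where M^Y ≡ 0) and applied to every imputed row. Setting δ = 0 reduces the
engine bit-exactly to MAR FCS — that identity is a regression test.

Parameter uncertainty propagates through posterior draws before each
imputation: exact Normal–inverse-chi-square draws for linear models
(prior ∝ 1/σ²) and a single multivariate Normal draw around the MLE with
inverse-observed-information covariance for logistic models (flat prior) —
the approximations used by mainstream chained-equations software. The
initial fill resamples each variable's observed values with replacement;
the visit order is least-missing-first (declared order breaks ties, and a
declared-order mode exists for order-sensitivity checks); burn-in defaults
to 10 sweeps; each of the K imputations is an independent chain with its
own seed substream.

Degenerate fits (separation, singular or constant designs) fall back to a
small ridge penalty (1e-4 on standardized predictors, intercept
unpenalized, degenerate constant columns pinned) with a logged warning, so
a 10,000-step Monte Carlo loop survives rare pathological imputations. A
constant observed outcome returns the saturated finite fit with a
regularized covariance.

## Monte Carlo NARFCS

Steps per draw s = 1..S: δ⁽ˢ⁾ ~ N(μ, σ²) (variance 0 returns μ — the
fixed-δ, deterministic bias analysis); K imputations at δ⁽ˢ⁾; per-imputation
substantive ML fits pooled by Rubin's rules; sampling error injected as
β̂X⁽ˢ⁾ ~ N(β̃X, ṼX). No δ draw is ever rejected or reweighted. Summaries
use the median and the 2.5th/97.5th percentiles with linear interpolation
between order statistics (the quantile rule is stated because nothing in
the method pins it down; the Bayesian summary uses the same rule).
Failed steps (non-convergent component fits) are recorded with their
reason, excluded from the summary, and more than 10% failures aborts.
Steps are seeded by per-step substreams so results are independent of
execution order; execution is sequential — at desk scale the loop is
minutes, not days, and a process-level parallel map can be layered on
without changing results.

Prior presets follow the evaluation design: vague N(0, 100), informative
N(truth, 4), very informative N(truth, 1) — second argument a *variance*.

`calibrate_delta` translates an external marginal-prevalence estimate into
δ: bisection on δ of the average completed-data outcome prevalence across
R imputations (default R = 5) under common random numbers. The completed
prevalence is bounded below by the observed cases alone (~5% under the
default design even at δ → −∞), so targets below that floor correctly
report non-bracketing bounds rather than extrapolating.

## Bayesian selection model

The full posterior over all component coefficients Ψ, δ^SM, ξ² and the
missing values of Y, X, W, D is sampled by Metropolis-within-Gibbs:

- one random-walk Metropolis block per logistic component, proposal
  covariance (scale²)×(inverse observed information at the initial ML
  fit); the scalar scale adapts toward ~30% acceptance during burn-in
  (Robbins–Monro on the log scale, gain capped at 0.05) and freezes
  afterwards, keeping the post-adaptation chain Markovian;
- (ζ, ξ²) by their exact conjugate conditionals
  (Normal / inverse-gamma with the Inv-Gamma(0.01, 0.01) prior);
- missing binary values drawn from their exact Bernoulli full
  conditionals — the product of every component likelihood the variable
  enters (verified against brute-force enumeration in the tests);
- missing X by per-row random-walk Metropolis with an adaptively scaled
  Normal proposal (exact conditionals are unavailable because X feeds
  downstream logistic terms).

Priors are N(0, 100) on all estimable coefficients and the user's Normal
prior on δ^SM (variance 0 pins the trace at the mean). Continuous
variables are standardized to observed mean 0 / SD 1 before sampling and
results are reported on that scale.

**Initialization matters.** Chains start from component MLEs on an
initial fill (chain 1 exact, later chains jittered by one SE); the missing
outcomes are filled from the δ-shifted substantive conditional
(logit p − δ_prior-mean) rather than by marginal resampling. A marginal
resample puts the observed case-rate among the missing, a state so
incompatible with a strong MNAR δ that the (δ, augmented-Y) pair — tightly
coupled and slow-mixing, which is why full-scale analyses run 50,000
iterations — can take many thousands of iterations to escape. Desk-scale
defaults are 5,000 iterations / 1,000 burn-in on n ≈ 2,000–5,000 subsamples.

Convergence checks use split-R̂ and effective sample size (via arviz) on
βX and δ^SM with thresholds R̂ < 1.05, ESS > 200 (configurable); constant
traces are flagged, single chains are marked "limited", and failed or
non-finite chains mark the run non-convergent rather than raising — the
simulation study excludes such replicates with counts reported.

## Comparators and pooling

CCA fits the substantive model on fully observed rows; MAR-MI is the FCS
engine at δ = 0 with the same pattern-mixture predictor sets (which is what
makes the auxiliary-driven bias amplification visible); the
population-based comparison group sets every missing outcome to "not a
case" and reports the implied marginal prevalence. All Wald intervals are
on the log-odds scale. Rubin's rules use the Barnard–Rubin small-sample
degrees of freedom (complete-data df = n − p); K = 1 passes the estimate
and variance through unchanged with infinite df, as required by the Monte
Carlo method's single-imputation default where the outer loop carries the
between-imputation uncertainty.

## Simulation study

Replicates are seeded by (root seed, replicate id) substreams, so any
replicate is reproducible in isolation and results are independent of
execution order. Per-method performance is bias, empirical SE, model-based
SE (interval methods: half-width / 1.96), and coverage of the 95%
interval, each with its Monte Carlo SE (bias: empSE/√R; coverage:
√(p(1−p)/R); empSE: empSE/√(2(R−1))). Methods that fail on a replicate are
excluded from that method's summary with counts reported. Desk-scale
defaults are R = 200–500 replicates of n = 100,000 for the fast methods;
Bayesian-arm replicates run on reduced subsamples (n = 5,000) and shorter
chains, reflecting that one full-scale MCMC fit is a multi-day computation.
The full-scale design (R = 1,000, S = 10,000, 50,000 iterations) is
reachable through `SimConfig` but is not exercised by the tests.

## What the tests do and do not show

The synthetic generators reproduce the *design* of the motivating setting
(prevalence, missingness pattern and strength, case enrichment), not real
covariate distributions, nonlinearities, interactions, measurement error
or non-monotone dependence between the covariate masks. Passing tests
therefore demonstrate internal validity — each method recovers the truth
of its own data-generating mechanism at the stated scales — not
performance on any real cohort. Coverage of the probabilistic bias
analyses under priors centred on the truth is expected to be *above*
nominal (the data are generated at a fixed bias-parameter value), so tests
assert interval-contains-truth rates, not exact nominal coverage.

## Known limitations

- Single scalar bias parameter; no joint priors, non-Normal priors, or
  multiple MNAR variables.
- Binary/continuous variables only; no categorical (>2 level) targets,
  predictive mean matching, or multilevel structure.
- The FCS-implied joint may not exist; no compatibility theory is
  attempted (the δ = 0 ≡ MAR-FCS identity and the order-robustness checks
  are empirical).
- The Bayesian sampler is random-walk based; its effective sample size per
  iteration is modest, and very short runs fail the convergence checks by
  design.
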