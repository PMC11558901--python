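# mnarpba — probabilistic bias analysis for outcomes missing not at random

`mnarpba` is a toolkit for epidemiologists and biostatisticians who need to
quantify how conclusions change when an outcome is **missing not at random
(MNAR)** — when the probability that the outcome is recorded depends on the
outcome itself, as when infection testing is largely restricted to the
symptomatic. In that setting complete case analysis (CCA) and multiple
imputation (MI) assuming missing at random (MAR) are both biased, and the
dependence between outcome and missingness is governed by a *bias parameter*
that the observed data cannot identify. The package implements two
probabilistic bias analyses that place a prior on that parameter, plus the
comparators and simulation machinery needed to validate them end to end.

## The models

The substantive analysis is a logistic regression of a binary outcome Y on a
continuous exposure X adjusted for confounders Z, W:

    logit Pr(Y=1 | X, Z, W) = β0 + βX·X + βZ·Z + βW·W

with auxiliary variables A (fully observed) and D (partially observed) that
predict Y and its missingness. Two bias models are supported:

- **Monte Carlo NARFCS** (`monte_carlo_pba`) — a pattern-mixture approach.
  Each partially observed variable is imputed by fully conditional
  specification (FCS); the outcome's imputation model carries a fixed offset
  δ·M^Y, where M^Y is the outcome's missingness indicator and δ (log-odds)
  is the shift in Pr(Y=1) between missing and observed records. The Monte
  Carlo loop repeats S times: draw δ⁽ˢ⁾ from its Normal prior, impute K
  times, fit the substantive model, pool by Rubin's rules into
  (β̃X, ṼX), and draw β̂X ~ N(β̃X, ṼX). The S draws of β̂X are summarized by
  their median and 2.5th/97.5th percentiles. δ is never updated against
  the data.
- **Bayesian selection model** (`bayesian_sm`) — a sequential factorisation
  of (W, X, Y, A, D, M^Y | Z) into univariate regressions, ending with
  logit Pr(M^Y=1 | D, A, Y, X) = ψ0 + ψ·(D,A,X) − δ^SM·Y, so δ^SM is the
  log-odds increase of *observing* Y per unit of Y. The joint posterior over
  all coefficients, δ^SM and the missing values of Y, X, W, D is sampled by
  Metropolis-within-Gibbs with data augmentation. Because the δ^SM prior is
  combined with the likelihood, values incompatible with the observed data
  are down-weighted — which is why a *vague* prior still removes much of the
  MNAR bias here, while the Monte Carlo method needs an informative one.

Around these sit a synthetic-data engine (selection-model and
pattern-mixture generators with MAR covariate missingness), comparator
methods (full-data fit, CCA, MAR-MI, population-based comparison group),
Rubin's-rules pooling, and a simulation-study driver reporting bias,
empirical/model SE and coverage with Monte Carlo standard errors.

## Worked example

```python
import numpy as np
import mnarpba as m

params = m.demo_params()                       # βX = ln 3, δ^SM = 7.85, 5% prevalence
complete = m.generate_sm_complete(20_000, params, seed=1)
obs = m.apply_missingness(complete, seed=2)    # ~80% of Y missing, ~5% of X, W, D

truth = m.derive_truth("SM", params, n_truth=1_000_000, seed=3)
print(f"true beta_x = {truth.beta_x_true:.3f}, "
      f"implied NARFCS delta = {truth.delta_narfcs_true:.2f}")

cca = m.run_cca(obs)
print(f"CCA:       {cca.estimate:.3f} ({cca.ci_low:.3f}, {cca.ci_high:.3f})")

prior = m.BiasPrior.very_informative(truth.delta_narfcs_true)
mc = m.run_mc_pba(obs, prior, S=200, K=1, seed=4)
print(f"MC-NARFCS: {mc.point:.3f} ({mc.interval[0]:.3f}, {mc.interval[1]:.3f})")
```

prints

```
true beta_x = 1.099, implied NARFCS delta = -7.86
CCA:       0.861 (0.768, 0.953)
MC-NARFCS: 1.112 (1.041, 1.191)
```

CCA underestimates the exposure effect (its interval misses the true
log-odds ratio ln 3 ≈ 1.099) because under this design being a case makes a
record far more likely to be observed; the Monte Carlo NARFCS analysis with
a well-centred prior recovers it. The same workflow is available from the
shell via the `mnarpba` CLI (`simulate`, `impute`, `mcpba`, `bayes-sm`,
`compare`, `simstudy`, `calibrate`).

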