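"""Bayesian selection model: log-joint oracle, exact full conditionals for
augmented values, posterior vs MLE on complete data, and prior behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mnarpba as m
from mnarpba.bayesian_sm import (
    BLOCKS,
    SMPriors,
    _augment_binary,
    component_loglik,
    sm_log_joint,
)
from mnarpba._glm import expit


def _zero_params(delta=0.0, xi2=1.0):
    return {"eta": np.zeros(4), "zeta": np.zeros(5), "xi2": xi2,
            "beta": np.zeros(6), "theta1": np.zeros(7), "theta2": np.zeros(7),
            "omega": np.zeros(9), "psi": np.zeros(5), "delta_sm": delta}


def _state_from_df(df):
    return {c: df[c].to_numpy(float).copy() for c in
            ("Y", "X", "W", "D", "A1", "A2", "Z1", "Z2", "Z3", "m_y")}


def _reference_log_joint(params, state, priors):
    """Independent row-by-row re-implementation using scipy distributions."""
    n = state["Y"].size
    total = 0.0
    for i in range(n):
        r = {k: v[i] for k, v in state.items()}
        p_w = expit(params["eta"] @ np.r_[1, r["Z1"], r["Z2"], r["Z3"]])
        total += stats.bernoulli.logpmf(int(r["W"]), p_w)
        mu_x = params["zeta"] @ np.r_[1, r["W"], r["Z1"], r["Z2"], r["Z3"]]
        total += stats.norm.logpdf(r["X"], mu_x, np.sqrt(params["xi2"]))
        p_y = expit(params["beta"] @ np.r_[1, r["X"], r["W"], r["Z1"],
                                           r["Z2"], r["Z3"]])
        total += stats.bernoulli.logpmf(int(r["Y"]), p_y)
        za = np.r_[1, r["Y"], r["X"], r["W"], r["Z1"], r["Z2"], r["Z3"]]
        total += stats.bernoulli.logpmf(int(r["A1"]), expit(params["theta1"] @ za))
        total += stats.bernoulli.logpmf(int(r["A2"]), expit(params["theta2"] @ za))
        zd = np.r_[1, r["A1"], r["A2"], r["Y"], r["X"], r["W"], r["Z1"],
                   r["Z2"], r["Z3"]]
        total += stats.bernoulli.logpmf(int(r["D"]), expit(params["omega"] @ zd))
        lp_m = (params["psi"] @ np.r_[1, r["D"], r["A1"], r["A2"], r["X"]]
                - params["delta_sm"] * r["Y"])
        total += stats.bernoulli.logpmf(int(r["m_y"]), expit(lp_m))
    for b in BLOCKS:
        v = np.atleast_1d(params[b])
        total += stats.norm.logpdf(v, 0, np.sqrt(priors.coef_variance)).sum()
    total += (-(priors.xi2_shape + 1) * np.log(params["xi2"])
              - priors.xi2_rate / params["xi2"])
    if priors.delta.variance > 0:
        total += -0.5 * (params["delta_sm"] - priors.delta.mean) ** 2 \
            / priors.delta.variance
    return total


class TestLogJoint:
    def test_single_zero_row_logistic_components_give_log_half(self):
        df = pd.DataFrame({c: [0.0] for c in
                           ("Y", "X", "W", "D", "A1", "A2", "Z1", "Z2", "Z3",
                            "m_y")})
        state = _state_from_df(df)
        params = _zero_params()
        for block in ("eta", "beta", "theta1", "theta2", "omega", "psi"):
            assert component_loglik(block, params, state) == pytest.approx(
                np.log(0.5))
        assert component_loglik("zeta", params, state) == pytest.approx(
            stats.norm.logpdf(0.0))

    def test_matches_brute_force_on_toy_data(self, demo, rng):
        df = m.generate_sm_complete(20, demo, seed=61)
        state = _state_from_df(df)
        params = _zero_params(delta=1.3)
        for b in BLOCKS:
            params[b] = rng.normal(0, 0.5, np.atleast_1d(params[b]).size) \
                if b != "zeta" else rng.normal(0, 0.5, 5)
        params["xi2"] = 0.8
        priors = SMPriors(delta=m.BiasPrior(2.0, 1.0))
        got = sm_log_joint(params, state, priors)
        want = _reference_log_joint(params, state, priors)
        assert got == pytest.approx(want, rel=1e-9)

    def test_doubling_rows_doubles_likelihood_portion(self, demo):
        df = m.generate_sm_complete(15, demo, seed=62)
        state1 = _state_from_df(df)
        state2 = _state_from_df(pd.concat([df, df], ignore_index=True))
        params = _zero_params(delta=0.5)
        priors = SMPriors(delta=m.BiasPrior(0.0, 1.0))
        prior_only = sm_log_joint(params,
                                  {k: v[:0] for k, v in state1.items()}, priors)
        ll1 = sm_log_joint(params, state1, priors) - prior_only
        ll2 = sm_log_joint(params, state2, priors) - prior_only
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_non_finite_parameter_rejected(self, demo):
        df = m.generate_sm_complete(5, demo, seed=63)
        params = _zero_params()
        params["beta"] = np.r_[np.inf, np.zeros(5)]
        with pytest.raises(ValueError):
            sm_log_joint(params, _state_from_df(df),
                         SMPriors(delta=m.BiasPrior(0, 1)))


class TestAugmentation:
    def test_binary_full_conditional_matches_enumeration(self, demo):
        """Augmented-Y frequencies match the brute-force conditional
        probability P(Y=1 | everything else) on a single row."""
        df = m.generate_sm_complete(1, demo, seed=64)
        params = _zero_params(delta=1.5)
        params["beta"] = np.array([-1.0, 0.8, 0.3, 0.1, 0.2, -0.1])
        params["theta1"][1] = 0.7
        params["theta2"][1] = 0.4
        params["omega"][3] = 0.9
        priors = SMPriors(delta=m.BiasPrior(0, 1))

        # brute force: unnormalized joint at Y=0 and Y=1
        weights = []
        for yval in (0.0, 1.0):
            state = _state_from_df(df)
            state["Y"][0] = yval
            weights.append(np.exp(sum(component_loglik(b, params, state)
                                      for b in BLOCKS)))
        p1 = weights[1] / (weights[0] + weights[1])

        state = _state_from_df(df)
        rows = np.array([0])
        rng = np.random.default_rng(65)
        draws = []
        for _ in range(4_000):
            _augment_binary("Y", rows, params, state, rng)
            draws.append(state["Y"][0])
        freq = np.mean(draws)
        mc_se = np.sqrt(p1 * (1 - p1) / 4_000)
        assert abs(freq - p1) < 3 * mc_se


@pytest.fixture(scope="module")
def complete_obs(demo):
    complete = m.generate_sm_complete(2_000, demo, seed=66)
    complete["m_y"] = 0
    mech = m.MARMechanism(coef={t: np.r_[-50.0, np.zeros(5)]
                                for t in ("X", "W", "D")})
    return m.apply_missingness(complete, mech, seed=67)


@pytest.fixture(scope="module")
def mnar_obs(demo):
    complete = m.generate_sm_complete(2_500, demo, seed=68)
    return m.apply_missingness(complete, seed=69)


class TestSampler:
    def test_posterior_matches_mle_on_complete_data(self, complete_obs):
        """Bernstein-von Mises: with complete data and vague priors the
        posterior concentrates on the ML estimate."""
        chains = m.run_bayes_sm(complete_obs, SMPriors(delta=m.BiasPrior.vague()),
                                n_iter=1_800, n_burn=600, chains=2, seed=70)
        assert not chains.nonconvergent
        mle = m.fit_substantive(complete_obs.data, complete_obs.roles)
        draws = chains.posterior("beta_x")
        assert abs(draws.mean() - mle.estimate) < 2 * draws.std()

    def test_degenerate_delta_prior_fixes_trace(self, mnar_obs):
        chains = m.run_bayes_sm(mnar_obs, SMPriors(delta=m.BiasPrior(7.85, 0.0)),
                                n_iter=300, n_burn=100, chains=1, seed=71)
        trace = chains.traces["delta_sm"]
        assert np.all(trace == 7.85)

    def test_vague_prior_shrinks_delta_posterior(self, mnar_obs):
        """Combining the vague prior with the likelihood gains information:
        posterior SD of delta well below the prior SD of 10."""
        chains = m.run_bayes_sm(mnar_obs, SMPriors(delta=m.BiasPrior.vague()),
                                n_iter=1_500, n_burn=500, chains=2, seed=72)
        draws = chains.posterior("delta_sm")
        assert draws.std() < 10.0 / 2

    def test_informative_prior_recovers_exposure_effect(self, mnar_obs, truth):
        prior = m.BiasPrior.very_informative(truth.delta_sm_true)
        chains = m.run_bayes_sm(mnar_obs, SMPriors(delta=prior),
                                n_iter=2_000, n_burn=700, chains=2, seed=73)
        med, lo, hi = m.summarize_posterior(chains, "beta_x")
        assert lo < truth.beta_x_true < hi

    def test_seed_reproducibility(self, mnar_obs):
        pr = SMPriors(delta=m.BiasPrior(7.85, 1.0))
        a = m.run_bayes_sm(mnar_obs, pr, n_iter=120, n_burn=50, chains=1, seed=74)
        b = m.run_bayes_sm(mnar_obs, pr, n_iter=120, n_burn=50, chains=1, seed=74)
        np.testing.assert_array_equal(a.traces["beta_x"], b.traces["beta_x"])


class TestDiagnostics:
    def test_constant_chains_flagged_not_passed(self):
        traces = {"beta_x": np.ones((2, 200)), "delta_sm": np.ones((2, 200))}
        chains = m.MCMCChains(traces=traces, n_iter=200, n_burn=50,
                              acceptance={}, seed=0)
        diag = m.check_convergence(chains)
        assert not diag["passed"]
        assert diag["beta_x"]["degenerate"]

    def test_short_run_fails_negative_control(self, mnar_obs):
        chains = m.run_bayes_sm(mnar_obs, SMPriors(delta=m.BiasPrior.vague()),
                                n_iter=60, n_burn=10, chains=2, seed=75)
        diag = m.check_convergence(chains)
        assert not diag["passed"]

    def test_well_mixing_chains_pass_rhat(self, complete_obs):
        chains = m.run_bayes_sm(complete_obs,
                                SMPriors(delta=m.BiasPrior(0.0, 0.0)),
                                n_iter=1_500, n_burn=500, chains=2, seed=76)
        diag = m.check_convergence(chains, parameters=("beta_x",),
                                   ess_limit=100.0)
        assert diag["beta_x"]["rhat"] < 1.05


class TestSummaries:
    def test_constant_trace(self):
        traces = {"beta_x": np.full((2, 100), 1.5)}
        chains = m.MCMCChains(traces=traces, n_iter=100, n_burn=20,
                              acceptance={}, seed=0)
        assert m.summarize_posterior(chains, "beta_x") == (1.5, 1.5, 1.5)

    def test_shared_quantile_rule_with_mc_summary(self):
        vals = np.arange(1.0, 101.0)
        traces = {"beta_x": np.vstack([vals, vals])}
        chains = m.MCMCChains(traces=traces, n_iter=100, n_burn=0,
                              acceptance={}, seed=0)
        assert m.summarize_posterior(chains, "beta_x") == \
            m.summarize_mc(np.concatenate([vals, vals]))

    def test_empty_trace_rejected(self):
        chains = m.MCMCChains(traces={"beta_x": np.empty((1, 0))}, n_iter=0,
                              n_burn=0, acceptance={}, seed=0)
        with pytest.raises(ValueError):
            m.summarize_posterior(chains, "beta_x")
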