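"""Bayesian bias analysis via a sequential selection model.

The joint distribution of (W, X, Y, A1, A2, D, M^Y | Z) is factorised into
univariate regressions, in this fixed order:

    W | Z                 logistic   (eta)
    X | W, Z              linear     (zeta, xi²)
    Y | X, W, Z           logistic   (beta, incl. the exposure effect βX)
    A1 | Y, X, W, Z       logistic   (theta1)
    A2 | Y, X, W, Z       logistic   (theta2)
    D | A, Y, X, W, Z     logistic   (omega)
    M^Y | D, A, Y, X      logistic   (psi, δ^SM)

with  logit Pr(M^Y=1) = ψ0 + ψD·D + ψA1·A1 + ψA2·A2 + ψX·X − δ^SM·Y,
so δ^SM is the log-odds increase of *observing* Y per unit of Y.  The
missingness model deliberately conditions on (D, A, Y, X) only.

Priors: N(0, 100) on every estimable coefficient, Inv-Gamma(0.01, 0.01) on
ξ², and a user-chosen Normal prior on the bias parameter δ^SM (variance 0
fixes it).  The sampler is Metropolis-within-Gibbs with data augmentation:

* one random-walk Metropolis block per logistic component, proposal
  covariance = (scale²) × inverse observed information at the initial ML
  fit, the scalar scale adapted towards ~25–40% acceptance during burn-in
  and frozen afterwards (keeping the post-adaptation chain Markovian);
* (zeta, xi²) by their exact conjugate conditionals;
* missing binary values (Y, W, D) redrawn from their exact Bernoulli full
  conditionals (the product of every component likelihood they enter);
* missing X by a per-row random-walk Metropolis step.

Because the bias-parameter prior is combined with the data likelihood,
δ^SM values incompatible with the observed data are down-weighted — the
defining difference from the Monte Carlo bias analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._glm import expit, fit_logistic, fit_linear, safe_cholesky
from .cli_io import ObservedDataset
from .monte_carlo_pba import BiasPrior

logger = logging.getLogger(__name__)

BLOCKS = ("eta", "zeta", "beta", "theta1", "theta2", "omega", "psi")

#: design-column layout per component (intercept implicit, first)
COMPONENT_PREDICTORS = {
    "eta": ("Z1", "Z2", "Z3"),              # target W
    "zeta": ("W", "Z1", "Z2", "Z3"),        # target X (linear)
    "beta": ("X", "W", "Z1", "Z2", "Z3"),   # target Y
    "theta1": ("Y", "X", "W", "Z1", "Z2", "Z3"),   # target A1
    "theta2": ("Y", "X", "W", "Z1", "Z2", "Z3"),   # target A2
    "omega": ("A1", "A2", "Y", "X", "W", "Z1", "Z2", "Z3"),  # target D
    "psi": ("D", "A1", "A2", "X"),          # target m_y; Y enters as −δ^SM·Y
}
COMPONENT_TARGET = {"eta": "W", "zeta": "X", "beta": "Y", "theta1": "A1",
                    "theta2": "A2", "omega": "D", "psi": "m_y"}


@dataclass(frozen=True)
class SMPriors:
    """Independent priors for the selection-model parameters."""

    delta: BiasPrior
    coef_variance: float = 100.0
    xi2_shape: float = 0.01
    xi2_rate: float = 0.01


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _design(state: dict[str, np.ndarray], block: str) -> np.ndarray:
    cols = COMPONENT_PREDICTORS[block]
    n = state["Z1"].size
    return np.column_stack([np.ones(n)] + [state[c] for c in cols])


def component_loglik(block: str, params: dict, state: dict[str, np.ndarray]) -> float:
    """Log-likelihood contribution of one component regression."""
    X = _design(state, block)
    if block == "zeta":
        resid = state["X"] - X @ params["zeta"]
        xi2 = params["xi2"]
        n = resid.size
        return float(-0.5 * n * np.log(2 * np.pi * xi2)
                     - 0.5 * resid @ resid / xi2)
    coef = params[block]
    lp = X @ coef
    if block == "psi":
        lp = lp - params["delta_sm"] * state["Y"]
    target = state[COMPONENT_TARGET[block]]
    return float(np.sum(target * lp) - np.sum(_softplus(lp)))


def _log_prior_coef(v: np.ndarray, variance: float) -> float:
    return float(-0.5 * np.sum(v**2) / variance
                 - 0.5 * v.size * np.log(2 * np.pi * variance))


def sm_log_joint(params: dict, state: dict[str, np.ndarray],
                 priors: SMPriors) -> float:
    """Log posterior kernel: component log-likelihoods plus log-priors."""
    for k, v in params.items():
        if not np.all(np.isfinite(np.atleast_1d(v))):
            raise ValueError(f"non-finite parameter {k}")
    ll = sum(component_loglik(b, params, state) for b in BLOCKS)
    lp = sum(_log_prior_coef(np.atleast_1d(params[b]), priors.coef_variance)
             for b in BLOCKS)
    xi2 = params["xi2"]
    lp += float(-(priors.xi2_shape + 1) * np.log(xi2) - priors.xi2_rate / xi2)
    if priors.delta.variance > 0:
        lp += float(-0.5 * (params["delta_sm"] - priors.delta.mean) ** 2
                    / priors.delta.variance)
    return ll + lp


@dataclass
class MCMCChains:
    """Per-chain parameter traces of the selection-model posterior."""

    traces: dict[str, np.ndarray]  # name -> (chains, n_iter) including burn-in
    n_iter: int
    n_burn: int
    acceptance: dict[str, float]
    seed: int
    nonconvergent: bool = False
    notes: list[str] = field(default_factory=list)

    def posterior(self, name: str) -> np.ndarray:
        """Pooled post-burn-in draws of a scalar parameter."""
        return self.traces[name][:, self.n_burn:].ravel()


# --------------------------------------------------------------------------
# sampler internals
# --------------------------------------------------------------------------

def _initial_state(obs: ObservedDataset, rng: np.random.Generator) -> tuple[dict, dict]:
    """Arrays of current column values plus missing-row index sets."""
    df = obs.data
    state, miss = {}, {}
    for col in ("Y", "X", "W", "D", "A1", "A2", "Z1", "Z2", "Z3", "m_y"):
        v = df[col].to_numpy(float).copy()
        nan = np.isnan(v)
        if nan.any():
            observed = v[~nan]
            v[nan] = rng.choice(observed, size=int(nan.sum()), replace=True)
            miss[col] = np.flatnonzero(nan)
        state[col] = v
    return state, miss


def _mle_blocks(state: dict[str, np.ndarray]) -> tuple[dict, dict]:
    """Initial ML fits per component: coefficient vectors and covariances."""
    coefs, covs = {}, {}
    for block in BLOCKS:
        X = _design(state, block)
        target = state[COMPONENT_TARGET[block]]
        if block == "zeta":
            fit = fit_linear(X, target)
            coefs["zeta"], covs["zeta"] = fit.coef, fit.cov
            coefs["xi2"] = fit.sigma2  # type: ignore[attr-defined]
        elif block == "psi":
            # fit with Y as an extra column to start (psi..., -delta)
            Xd = np.column_stack([X, state["Y"]])
            fit = fit_logistic(Xd, target)
            coefs["psi"], covs["psi"] = fit.coef[:-1], fit.cov[:-1, :-1]
            coefs["delta_sm"] = -fit.coef[-1]
        else:
            fit = fit_logistic(X, target)
            coefs[block], covs[block] = fit.coef, fit.cov
    return coefs, covs


def _augment_binary(
    var: str,
    rows: np.ndarray,
    params: dict,
    state: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> None:
    """Exact Bernoulli full-conditional draw for missing binary values.

    log-odds(var=1) = own-model linear predictor + Σ over downstream
    components [ t·c − softplus(lp0 + c) + softplus(lp0) ]  (+ the linear
    X-model term for W), where lp0 is the component's linear predictor at
    var=0, c its coefficient on var, and t its observed target value.
    """
    saved = state[var][rows].copy()
    state[var][rows] = 0.0

    if var == "Y":
        own = _design(state, "beta")[rows] @ params["beta"]
        downstream = [("theta1", params["theta1"][1]),
                      ("theta2", params["theta2"][1]),
                      ("omega", params["omega"][3]),
                      ("psi", -params["delta_sm"])]
    elif var == "W":
        own = _design(state, "eta")[rows] @ params["eta"]
        downstream = [("beta", params["beta"][2]),
                      ("theta1", params["theta1"][3]),
                      ("theta2", params["theta2"][3]),
                      ("omega", params["omega"][5])]
    elif var == "D":
        own = _design(state, "omega")[rows] @ params["omega"]
        downstream = [("psi", params["psi"][1])]
    else:  # pragma: no cover
        raise ValueError(var)

    logodds = own.copy()
    for block, c in downstream:
        X0 = _design(state, block)[rows]
        lp0 = X0 @ params[block]
        if block == "psi":
            lp0 = lp0 - params["delta_sm"] * state["Y"][rows]
        t = state[COMPONENT_TARGET[block]][rows]
        logodds += t * c - _softplus(lp0 + c) + _softplus(lp0)
    if var == "W":
        # linear X-model: N(mu0 + zeta_W, xi2) vs N(mu0, xi2)
        Xz = _design(state, "zeta")[rows]
        mu0 = Xz @ params["zeta"]
        zw, xi2 = params["zeta"][1], params["xi2"]
        xv = state["X"][rows]
        logodds += (-(xv - mu0 - zw) ** 2 + (xv - mu0) ** 2) / (2 * xi2)

    state[var][rows] = saved  # restore before drawing (paranoia for Y in psi)
    state[var][rows] = (rng.random(rows.size) < expit(logodds)).astype(float)


def _augment_x(
    rows: np.ndarray,
    params: dict,
    state: dict[str, np.ndarray],
    rng: np.random.Generator,
    scale: float,
) -> float:
    """Per-row random-walk Metropolis update of missing X values."""
    x_cur = state["X"][rows]
    prop = x_cur + scale * rng.standard_normal(rows.size)

    def logdens(xv: np.ndarray) -> np.ndarray:
        state["X"][rows] = xv
        Xz = _design(state, "zeta")[rows]
        mu = Xz @ params["zeta"]
        out = -0.5 * (xv - mu) ** 2 / params["xi2"]
        for block, idx in (("beta", 1), ("theta1", 2), ("theta2", 2),
                           ("omega", 4), ("psi", 4)):
            Xb = _design(state, block)[rows]
            lp = Xb @ params[block]
            if block == "psi":
                lp = lp - params["delta_sm"] * state["Y"][rows]
            t = state[COMPONENT_TARGET[block]][rows]
            out += t * lp - _softplus(lp)
        return out

    ld_cur = logdens(x_cur)
    ld_prop = logdens(prop)
    accept = np.log(rng.random(rows.size)) < ld_prop - ld_cur
    state["X"][rows] = np.where(accept, prop, x_cur)
    return float(accept.mean()) if rows.size else 1.0


def _run_chain(
    obs: ObservedDataset,
    priors: SMPriors,
    n_iter: int,
    n_burn: int,
    seed_seq: np.random.SeedSequence,
    jitter: float,
) -> tuple[dict[str, np.ndarray], dict[str, float], list[str]]:
    rng = np.random.default_rng(seed_seq)
    state, miss = _initial_state(obs, rng)
    # model-consistent initial fill for the missing outcomes: fit the
    # substantive component on observed-Y rows, then draw missing Y from the
    # δ-shifted conditional (a marginal resample would start the chain at a
    # missing-row case rate wildly incompatible with a strong MNAR δ)
    delta_init = priors.delta.mean
    if "Y" in miss and miss["Y"].size:
        obs_rows = np.setdiff1d(np.arange(obs.n), miss["Y"])
        Xb = _design(state, "beta")
        fit_b = fit_logistic(Xb[obs_rows], state["Y"][obs_rows])
        lp0 = Xb[miss["Y"]] @ fit_b.coef - delta_init
        state["Y"][miss["Y"]] = (rng.random(miss["Y"].size)
                                 < expit(lp0)).astype(float)
    coefs, covs = _mle_blocks(state)
    params = {b: coefs[b].copy() for b in BLOCKS}
    params["xi2"] = float(coefs["xi2"])
    params["delta_sm"] = (priors.delta.mean if priors.delta.variance == 0
                          else float(coefs["delta_sm"]))
    # overdispersed start: jitter coefficients by a multiple of their SE
    if jitter > 0:
        for b in BLOCKS:
            se = np.sqrt(np.clip(np.diag(covs[b]), 1e-10, None))
            params[b] = params[b] + jitter * se * rng.standard_normal(se.size)
        if priors.delta.variance > 0:
            params["delta_sm"] += jitter * np.sqrt(priors.delta.variance) \
                * rng.standard_normal()

    chol = {b: safe_cholesky((covs[b])) for b in BLOCKS
            if b != "zeta"}
    # psi block proposes (psi, delta) jointly unless delta is fixed
    psi_dim = params["psi"].size + (1 if priors.delta.variance > 0 else 0)
    Xd = np.column_stack([_design(state, "psi"), state["Y"]])
    fit_psi = fit_logistic(Xd, state["m_y"])
    if priors.delta.variance > 0:
        chol["psi"] = safe_cholesky((fit_psi.cov))

    log_scale = {b: np.log(2.38 / np.sqrt(chol[b].shape[0])) for b in chol}
    x_scale = np.sqrt(params["xi2"])
    accepts = {b: 0 for b in chol}
    accepts["x_mis"] = 0.0
    notes: list[str] = []

    track = {"beta_x": lambda p: p["beta"][1],
             "delta_sm": lambda p: p["delta_sm"],
             "beta0": lambda p: p["beta"][0],
             "xi2": lambda p: p["xi2"],
             "psi0": lambda p: p["psi"][0]}
    traces = {k: np.empty(n_iter) for k in track}

    n = obs.n
    for it in range(n_iter):
        adapting = it < n_burn
        # ---- conjugate updates for the linear component ------------------
        Xz = _design(state, "zeta")
        resid = state["X"] - Xz @ params["zeta"]
        params["xi2"] = 1.0 / rng.gamma(priors.xi2_shape + 0.5 * n,
                                        1.0 / (priors.xi2_rate + 0.5 * resid @ resid))
        prec = Xz.T @ Xz / params["xi2"] + np.eye(Xz.shape[1]) / priors.coef_variance
        cov_post = np.linalg.inv(prec)
        mean_post = cov_post @ (Xz.T @ state["X"]) / params["xi2"]
        Lz = safe_cholesky((cov_post))
        params["zeta"] = mean_post + Lz @ rng.standard_normal(Xz.shape[1])

        # ---- Metropolis blocks for logistic components -------------------
        for b in chol:
            cur_ll = component_loglik(b, params, state)
            cur_vec = (np.append(params["psi"], params["delta_sm"])
                       if b == "psi" and priors.delta.variance > 0
                       else params[b])
            cur_pr = _log_prior_coef(
                cur_vec[:params[b].size] if b == "psi" else cur_vec,
                priors.coef_variance)
            if b == "psi" and priors.delta.variance > 0:
                cur_pr += -0.5 * (params["delta_sm"] - priors.delta.mean) ** 2 \
                    / priors.delta.variance
            step = np.exp(log_scale[b]) * (chol[b] @ rng.standard_normal(
                chol[b].shape[0]))
            prop_vec = cur_vec + step
            saved_coef = params[b].copy()
            saved_delta = params["delta_sm"]
            if b == "psi" and priors.delta.variance > 0:
                params["psi"] = prop_vec[:-1]
                params["delta_sm"] = float(prop_vec[-1])
                prop_pr = _log_prior_coef(prop_vec[:-1], priors.coef_variance)
                prop_pr += -0.5 * (params["delta_sm"] - priors.delta.mean) ** 2 \
                    / priors.delta.variance
            else:
                params[b] = prop_vec
                prop_pr = _log_prior_coef(prop_vec, priors.coef_variance)
            prop_ll = component_loglik(b, params, state)
            if np.log(rng.random()) < (prop_ll + prop_pr) - (cur_ll + cur_pr):
                accepts[b] += 1
                acc = 1.0
            else:
                params[b] = saved_coef
                params["delta_sm"] = saved_delta
                acc = 0.0
            if adapting:
                log_scale[b] += min(0.05, 3.0 / np.sqrt(it + 1)) * (acc - 0.3)

        # ---- data augmentation -------------------------------------------
        for var in ("Y", "W", "D"):
            if var in miss and miss[var].size:
                _augment_binary(var, miss[var], params, state, rng)
        if "X" in miss and miss["X"].size:
            acc_x = _augment_x(miss["X"], params, state, rng, x_scale)
            accepts["x_mis"] += acc_x
            if adapting:
                x_scale *= np.exp(min(0.05, 3.0 / np.sqrt(it + 1))
                                  * (acc_x - 0.4))

        for k, getter in track.items():
            traces[k][it] = getter(params)
        if not np.isfinite(traces["beta_x"][it]):
            notes.append(f"non-finite state at iteration {it}")
            break

    acc_rates = {b: accepts[b] / n_iter for b in chol}
    acc_rates["x_mis"] = accepts["x_mis"] / n_iter
    return traces, acc_rates, notes


def run_bayes_sm(
    obs: ObservedDataset,
    priors: SMPriors,
    n_iter: int = 5_000,
    n_burn: int = 1_000,
    chains: int = 2,
    seed: int = 0,
) -> MCMCChains:
    """Sample the joint posterior of the selection-model parameters and the
    missing values of Y, X, W and D.  Reproducible given seed."""
    if n_iter <= n_burn:
        raise ValueError("n_iter must exceed n_burn")
    if chains < 1:
        raise ValueError("chains must be >= 1")
    root = np.random.SeedSequence((seed, 20_552))
    children = root.spawn(chains)
    all_traces: dict[str, list[np.ndarray]] = {}
    acc_all: dict[str, float] = {}
    notes: list[str] = []
    nonconvergent = False
    for c, child in enumerate(children):
        jitter = 0.0 if c == 0 else 1.0
        try:
            tr, acc, chain_notes = _run_chain(obs, priors, n_iter, n_burn,
                                              child, jitter)
        except Exception as exc:  # noqa: BLE001 - report, do not raise
            logger.warning("chain %d failed: %s", c, exc)
            notes.append(f"chain {c} failed: {exc}")
            nonconvergent = True
            continue
        if chain_notes:
            notes.extend(f"chain {c}: {m}" for m in chain_notes)
            nonconvergent = True
            continue
        for k, v in tr.items():
            all_traces.setdefault(k, []).append(v)
        for k, v in acc.items():
            acc_all[k] = acc_all.get(k, 0.0) + v / chains
    if not all_traces:
        return MCMCChains(traces={}, n_iter=n_iter, n_burn=n_burn,
                          acceptance=acc_all, seed=seed, nonconvergent=True,
                          notes=notes)
    traces = {k: np.vstack(v) for k, v in all_traces.items()}
    return MCMCChains(traces=traces, n_iter=n_iter, n_burn=n_burn,
                      acceptance=acc_all, seed=seed,
                      nonconvergent=nonconvergent, notes=notes)


def check_convergence(
    chains: MCMCChains,
    parameters: tuple[str, ...] = ("beta_x", "delta_sm"),
    rhat_limit: float = 1.05,
    ess_limit: float = 200.0,
) -> dict:
    """Split-R̂ and effective sample size on the post-burn-in traces."""
    import arviz as az

    out: dict[str, dict] = {"passed": True, "limited": False}
    arrs = {}
    for p in parameters:
        if p not in chains.traces:
            continue
        a = chains.traces[p][:, chains.n_burn:]
        if np.allclose(a.std(axis=1), 0.0):
            out[p] = {"rhat": np.nan, "ess": 0.0, "degenerate": True}
            out["passed"] = False
            continue
        arrs[p] = a
    if chains.traces and chains.traces[next(iter(chains.traces))].shape[0] < 2:
        out["limited"] = True
        logger.warning("single chain: R-hat diagnostics unavailable")
    for p, a in arrs.items():
        idata = az.convert_to_dataset({p: a})
        rhat = float(az.rhat(idata)[p].values) if a.shape[0] >= 2 else np.nan
        ess = float(az.ess(idata)[p].values)
        ok = (np.isnan(rhat) or rhat < rhat_limit) and ess > ess_limit
        out[p] = {"rhat": rhat, "ess": ess, "degenerate": False}
        out["passed"] = out["passed"] and ok and not (out["limited"] and np.isnan(rhat))
    if chains.nonconvergent:
        out["passed"] = False
    return out


def summarize_posterior(
    chains: MCMCChains, parameter: str
) -> tuple[float, float, float]:
    """Median and 2.5/97.5 percentiles of the pooled post-burn-in draws
    (same linear-interpolation quantile rule as the Monte Carlo summary)."""
    draws = chains.posterior(parameter)
    if draws.size == 0:
        raise ValueError(f"empty trace for {parameter}")
    med, lo, hi = np.percentile(draws, [50.0, 2.5, 97.5])
    return float(med), float(lo), float(hi)
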