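"""Monte Carlo probabilistic bias analysis via NARFCS imputation.

Each Monte Carlo step s = 1..S:

i.   draw the bias parameter δ⁽ˢ⁾ from its Normal prior (never rejected or
     reweighted against the data);
ii.  impute the observed data K times with the NARFCS bias model at δ⁽ˢ⁾,
     fit the substantive logistic model to each completed dataset by
     maximum likelihood, and pool by Rubin's rules into (β̃X⁽ˢ⁾, ṼX⁽ˢ⁾);
iii. inject random sampling error: β̂X⁽ˢ⁾ ~ Normal(β̃X⁽ˢ⁾, ṼX⁽ˢ⁾).

The frequency distribution of β̂X⁽¹⁾..β̂X⁽ˢ⁾ is summarized by its median and
2.5th/97.5th percentiles (linear interpolation between order statistics).
A degenerate prior (variance 0) gives the fixed-δ analysis.

The module also provides the δ ↔ marginal-prevalence calibration used to
translate external prevalence information into a prior for δ.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._glm import fit_logistic
from .cli_io import ObservedDataset
from .fcs_engine import ImputationModelSpec, run_fcs
from .pooling import rubin_pool

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiasPrior:
    """Normal prior on the bias parameter (mean, variance in log-odds²)."""

    mean: float
    variance: float
    label: str = "custom"

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("prior variance must be >= 0")

    @classmethod
    def vague(cls) -> "BiasPrior":
        return cls(0.0, 100.0, "vague")

    @classmethod
    def informative(cls, truth: float) -> "BiasPrior":
        return cls(truth, 4.0, "informative")

    @classmethod
    def very_informative(cls, truth: float) -> "BiasPrior":
        return cls(truth, 1.0, "very informative")

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        from scipy import stats
        half = stats.norm.ppf(0.5 + level / 2) * np.sqrt(self.variance)
        return self.mean - half, self.mean + half


def sample_delta(prior: BiasPrior, rng: np.random.Generator) -> float:
    """One draw from the prior; a variance-0 prior returns its mean."""
    if prior.variance == 0.0:
        return prior.mean
    return float(rng.normal(prior.mean, np.sqrt(prior.variance)))


@dataclass
class MCResult:
    """S-draw frequency distribution of bias-adjusted estimates."""

    draws: pd.DataFrame  # columns: s, delta, beta_tilde, v_tilde, beta_hat, status
    point: float
    interval: tuple[float, float]
    S: int
    K: int
    seed: int
    n_failed: int = 0

    @property
    def ok(self) -> pd.DataFrame:
        return self.draws[self.draws["status"] == "ok"]


def summarize_mc(beta_hats) -> tuple[float, float, float]:
    """Median and 2.5/97.5 percentiles (linear order-statistic interpolation)."""
    b = np.asarray(beta_hats, dtype=float)
    b = b[np.isfinite(b)]
    if b.size < 2:
        raise ValueError("need at least 2 finite draws to summarize")
    med, lo, hi = np.percentile(b, [50.0, 2.5, 97.5])
    return float(med), float(lo), float(hi)


def _substantive_beta_x(data: pd.DataFrame, obs: ObservedDataset) -> tuple[float, float]:
    roles = obs.roles
    preds = (roles.exposure,) + roles.confounders
    X = np.column_stack([np.ones(len(data))]
                        + [data[c].to_numpy(float) for c in preds])
    fit = fit_logistic(X, data[roles.outcome].to_numpy(float))
    if not fit.converged and not fit.ridged:
        raise RuntimeError("substantive fit did not converge")
    return float(fit.coef[1]), float(fit.cov[1, 1])


def mc_step(
    obs: ObservedDataset,
    delta: float,
    K: int,
    rng_or_seed,
    specs: list[ImputationModelSpec] | None = None,
    n_burn: int = 10,
) -> tuple[float, float, float]:
    """One bias-adjusted estimate at fixed δ: impute, fit, pool, add noise."""
    ss = (rng_or_seed if isinstance(rng_or_seed, np.random.SeedSequence)
          else np.random.SeedSequence(rng_or_seed))
    imp_seed, noise_seed = ss.spawn(2)
    imputations = run_fcs(obs, specs=specs, delta=delta, n_burn=n_burn,
                          K=K, seed=imp_seed)
    ests, variances = [], []
    for imp in imputations:
        b, v = _substantive_beta_x(imp.data, obs)
        ests.append(b)
        variances.append(v)
    pooled = rubin_pool(ests, variances, n_obs=obs.n,
                        n_params=2 + len(obs.roles.confounders))
    rng = np.random.default_rng(noise_seed)
    beta_hat = float(rng.normal(pooled.estimate, np.sqrt(pooled.total_variance)))
    return pooled.estimate, pooled.total_variance, beta_hat


def run_mc_pba(
    obs: ObservedDataset,
    prior: BiasPrior,
    S: int,
    K: int = 1,
    seed: int = 0,
    specs: list[ImputationModelSpec] | None = None,
    n_burn: int = 10,
    max_failure_fraction: float = 0.10,
) -> MCResult:
    """Full Monte Carlo bias analysis; failed steps are recorded, not dropped
    silently, and more than ``max_failure_fraction`` failures is an error."""
    if S < 2:
        raise ValueError("S must be >= 2")
    root = np.random.SeedSequence(seed)
    delta_rng = np.random.default_rng(root.spawn(1)[0])
    step_seeds = np.random.SeedSequence((seed, 1)).spawn(S)
    rows = []
    n_drawn = 0
    for s, child in enumerate(step_seeds):
        delta = sample_delta(prior, delta_rng)
        n_drawn += 1
        try:
            bt, vt, bh = mc_step(obs, delta, K, child, specs=specs, n_burn=n_burn)
            rows.append((s, delta, bt, vt, bh, "ok"))
        except Exception as exc:  # noqa: BLE001 - step failures are data
            logger.warning("MC step %d failed: %s", s, exc)
            rows.append((s, delta, np.nan, np.nan, np.nan, f"failed: {exc}"))
    draws = pd.DataFrame(rows, columns=["s", "delta", "beta_tilde", "v_tilde",
                                        "beta_hat", "status"])
    assert n_drawn == S, "every prior draw must be used: none rejected"
    n_failed = int((draws["status"] != "ok").sum())
    if n_failed > max_failure_fraction * S:
        raise RuntimeError(f"{n_failed}/{S} Monte Carlo steps failed")
    point, lo, hi = summarize_mc(draws.loc[draws["status"] == "ok", "beta_hat"])
    return MCResult(draws=draws, point=point, interval=(lo, hi), S=S, K=K,
                    seed=seed, n_failed=n_failed)


def calibrate_delta(
    obs: ObservedDataset,
    target_prevalence: float,
    bounds: tuple[float, float] = (-8.0, 3.0),
    R: int = 5,
    seed: int = 0,
    specs: list[ImputationModelSpec] | None = None,
    n_burn: int = 10,
    tol: float = 1e-3,
) -> float:
    """Find δ such that the completed-data marginal outcome prevalence
    (averaged over R imputations, common random numbers) hits the target.

    The completed prevalence is increasing in δ, so a bracketing
    root-finder applies; non-bracketing bounds raise with the prevalence
    reached at each bound.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    outcome = obs.roles.outcome
    common = np.random.SeedSequence((seed, 777))

    def completed_prevalence(delta: float) -> float:
        imps = run_fcs(obs, specs=specs, delta=delta, n_burn=n_burn, K=R,
                       seed=common)
        return float(np.mean([imp.data[outcome].mean() for imp in imps]))

    lo, hi = bounds
    p_lo, p_hi = completed_prevalence(lo), completed_prevalence(hi)
    if not (p_lo <= target_prevalence <= p_hi):
        raise RuntimeError(
            f"bounds do not bracket target prevalence {target_prevalence:.4f}: "
            f"prevalence {p_lo:.4f} at delta={lo}, {p_hi:.4f} at delta={hi}")
    return float(brentq(lambda d: completed_prevalence(d) - target_prevalence,
                        lo, hi, xtol=tol))
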