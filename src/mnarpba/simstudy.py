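"""Simulation-study engine: replicate generation, method application, and
performance summaries (bias, empirical/model SE, coverage) with Monte Carlo
standard errors.

Replicates are seeded by (root seed, replicate id) substreams, so each
replicate is reproducible independently of execution order, and methods
that fail on a replicate are excluded from that method's summaries with
their count reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import synthetic_data as sd
from .cli_io import ObservedDataset
from .bayesian_sm import SMPriors, run_bayes_sm, summarize_posterior
from .comparators import fit_substantive, run_cca, run_mi_mar, run_population_comparison
from .monte_carlo_pba import BiasPrior, run_mc_pba

logger = logging.getLogger(__name__)

PRIOR_PRESETS = ("vague", "informative", "very_informative")


def resolve_prior(preset: str, truth: float) -> BiasPrior:
    """Map a preset name to a prior, plugging in the true bias parameter."""
    if preset == "vague":
        return BiasPrior.vague()
    if preset == "informative":
        return BiasPrior.informative(truth)
    if preset == "very_informative":
        return BiasPrior.very_informative(truth)
    raise ValueError(f"unknown prior preset {preset!r}")


@dataclass
class SimConfig:
    """Study settings; defaults are the desk-scale configuration."""

    dgm: str = "SM"                      # "SM" or "PMM"
    beta_x: float = float(np.log(3.0))   # 0 or ln 3
    delta_sm: float = sd.DELTA_SM_DEFAULT
    n: int = 100_000
    n_replicates: int = 200
    methods: tuple[str, ...] = ("full", "cca")
    seed: int = 0
    # method settings
    mi_m: int = 50
    fcs_burnin: int = 10
    mc_steps: int = 50
    mc_k: int = 1
    mc_prior: str = "very_informative"
    bayes_iters: int = 5_000
    bayes_burnin: int = 1_000
    bayes_chains: int = 2
    bayes_n: int = 5_000                 # reduced per-replicate n for Bayes-SM
    bayes_prior: str = "very_informative"
    n_truth: int = 1_000_000
    n_pmm_fit: int = 2_000_000

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.dgm not in ("SM", "PMM"):
            raise ValueError("dgm must be 'SM' or 'PMM'")


@dataclass
class StudyInputs:
    """Resolved generator parameters and truth values for a study."""

    sm_params: sd.SMDGMParams
    pmm_params: sd.PMMDGMParams | None
    truth: sd.TruthValues


def prepare_inputs(config: SimConfig) -> StudyInputs:
    sm_params = sd.demo_params(beta_x=config.beta_x, delta_sm=config.delta_sm)
    pmm_params = None
    if config.dgm == "PMM":
        big = sd.generate_sm_complete(config.n_pmm_fit, sm_params,
                                      np.random.SeedSequence((config.seed, 90)))
        pmm_params = sd.fit_pmm_params(big)
        truth = sd.derive_truth("PMM", pmm_params, n_truth=config.n_truth,
                                seed=config.seed + 91)
    else:
        truth = sd.derive_truth("SM", sm_params, n_truth=config.n_truth,
                                seed=config.seed + 91)
    return StudyInputs(sm_params=sm_params, pmm_params=pmm_params, truth=truth)


def _generate(config: SimConfig, inputs: StudyInputs, rep_id: int, n: int
              ) -> tuple[pd.DataFrame, ObservedDataset]:
    ss = np.random.SeedSequence((config.seed, rep_id))
    gen_seed, mask_seed = ss.spawn(2)
    if config.dgm == "PMM":
        complete = sd.generate_pmm_complete(n, inputs.pmm_params,
                                            np.random.default_rng(gen_seed))
    else:
        complete = sd.generate_sm_complete(n, inputs.sm_params,
                                           np.random.default_rng(gen_seed))
    obs = sd.apply_missingness(complete, seed=np.random.default_rng(mask_seed))
    return complete, obs


def run_replicate(config: SimConfig, rep_id: int,
                  inputs: StudyInputs | None = None) -> list[dict]:
    """Generate one replicate, apply every configured method, return rows
    of (rep, method, estimate, low, high, se, converged)."""
    inputs = inputs or prepare_inputs(config)
    truth = inputs.truth
    complete, obs = _generate(config, inputs, rep_id, config.n)
    method_seed = int(np.random.SeedSequence((config.seed, rep_id, 7)
                                             ).generate_state(1)[0] % (2**31))
    rows: list[dict] = []

    def record(method, estimate, low, high, se, converged=True):
        rows.append(dict(rep=rep_id, method=method, estimate=estimate,
                         low=low, high=high, se=se, converged=converged))

    for method in config.methods:
        try:
            if method == "full":
                est = fit_substantive(complete, obs.roles, method="full")
                record(method, est.estimate, est.ci_low, est.ci_high, est.se)
            elif method == "cca":
                est = run_cca(obs)
                record(method, est.estimate, est.ci_low, est.ci_high, est.se)
            elif method == "popcomp":
                est, _ = run_population_comparison(obs)
                record(method, est.estimate, est.ci_low, est.ci_high, est.se)
            elif method == "mi":
                pooled = run_mi_mar(obs, M=config.mi_m, seed=method_seed,
                                    n_burn=config.fcs_burnin)
                lo, hi = pooled.ci()
                record(method, pooled.estimate, lo, hi, pooled.se)
            elif method == "mc_narfcs":
                prior = resolve_prior(config.mc_prior, truth.delta_narfcs_true)
                res = run_mc_pba(obs, prior, S=config.mc_steps, K=config.mc_k,
                                 seed=method_seed, n_burn=config.fcs_burnin)
                lo, hi = res.interval
                record(method, res.point, lo, hi, (hi - lo) / (2 * 1.959964))
            elif method == "bayes_sm":
                # reduced-n replicate: the sampler is run on a subsample
                n_b = min(config.bayes_n, config.n)
                _, obs_b = _generate(config, inputs, rep_id, n_b)
                prior = resolve_prior(config.bayes_prior, truth.delta_sm_true)
                chains = run_bayes_sm(obs_b, SMPriors(delta=prior),
                                      n_iter=config.bayes_iters,
                                      n_burn=config.bayes_burnin,
                                      chains=config.bayes_chains,
                                      seed=method_seed)
                if chains.nonconvergent or "beta_x" not in chains.traces:
                    record(method, np.nan, np.nan, np.nan, np.nan, False)
                else:
                    med, lo, hi = summarize_posterior(chains, "beta_x")
                    record(method, med, lo, hi, (hi - lo) / (2 * 1.959964))
            else:
                raise ValueError(f"unknown method {method!r}")
        except Exception as exc:  # noqa: BLE001 - a replicate never aborts the study
            logger.warning("rep %d method %s failed: %s", rep_id, method, exc)
            record(method, np.nan, np.nan, np.nan, np.nan, False)
    return rows


def compute_performance(rows: pd.DataFrame, truth: sd.TruthValues) -> pd.DataFrame:
    """Per-method bias, empirical SE, model SE and 95% coverage, each with
    its Monte Carlo standard error."""
    out = []
    target = truth.beta_x_true
    for method, grp in rows.groupby("method", sort=False):
        ok = grp[grp["converged"] & np.isfinite(grp["estimate"])]
        R = len(ok)
        if R < 2:
            raise ValueError(f"{method}: fewer than 2 converged replicates")
        est = ok["estimate"].to_numpy()
        se = ok["se"].to_numpy()
        bias = est.mean() - target
        emp_se = est.std(ddof=1)
        mod_se = float(np.sqrt(np.mean(se**2)))
        covered = ((ok["low"] <= target) & (target <= ok["high"])).to_numpy()
        cover = covered.mean()
        out.append(dict(
            method=method, n_converged=R, n_total=len(grp),
            bias=bias, bias_mcse=emp_se / np.sqrt(R),
            emp_se=emp_se, emp_se_mcse=emp_se / np.sqrt(2 * (R - 1)),
            mod_se=mod_se,
            mod_se_mcse=float(np.sqrt(np.var(se**2, ddof=1) / R)
                              / (2 * mod_se)) if mod_se > 0 else np.nan,
            coverage_pct=100 * cover,
            coverage_mcse_pct=100 * np.sqrt(cover * (1 - cover) / R),
        ))
    return pd.DataFrame(out)


def run_study(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, StudyInputs]:
    """Run all replicates and summarize; returns (summary, raw rows, inputs)."""
    inputs = prepare_inputs(config)
    rows: list[dict] = []
    for rep in range(config.n_replicates):
        rows.extend(run_replicate(config, rep, inputs))
    raw = pd.DataFrame(rows)
    summary = compute_performance(raw, inputs.truth)
    return summary, raw, inputs
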