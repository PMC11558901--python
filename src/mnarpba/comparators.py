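"""Reference analyses: full-data fit, CCA, MAR multiple imputation, and the
population-based comparison group (missing outcomes set to "not a case")."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._glm import fit_logistic
from .cli_io import ObservedDataset, VariableRoles
from .fcs_engine import ImputationModelSpec, default_imputation_specs, run_fcs
from .pooling import PooledEstimate, rubin_pool


@dataclass
class EstimateWithSE:
    """Exposure-effect estimate on the log-odds scale with Wald 95% CI."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    method: str
    n_used: int

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.estimate))


def fit_substantive(
    data: pd.DataFrame,
    roles: VariableRoles | None = None,
    method: str = "full",
) -> EstimateWithSE:
    """ML logistic regression of the outcome on exposure + confounders."""
    roles = roles or VariableRoles()
    cols = list(roles.analysis_vars)
    if data[cols].isna().any().any():
        raise ValueError("substantive fit requires complete analysis columns")
    preds = (roles.exposure,) + roles.confounders
    X = np.column_stack([np.ones(len(data))]
                        + [data[c].to_numpy(float) for c in preds])
    fit = fit_logistic(X, data[roles.outcome].to_numpy(float))
    if not fit.converged and not fit.ridged:
        raise RuntimeError("substantive model did not converge (separation?)")
    b, se = float(fit.coef[1]), float(fit.se[1])
    z = stats.norm.ppf(0.975)
    return EstimateWithSE(b, se, b - z * se, b + z * se, method, len(data))


def run_cca(obs: ObservedDataset) -> EstimateWithSE:
    """Complete case analysis: substantive fit on fully observed rows."""
    cc = obs.complete_rows()
    if cc.empty:
        raise ValueError("no complete rows for CCA")
    return fit_substantive(cc, obs.roles, method="cca")


def run_mi_mar(
    obs: ObservedDataset,
    M: int = 50,
    seed: int = 0,
    n_burn: int = 10,
    specs: list[ImputationModelSpec] | None = None,
) -> PooledEstimate:
    """MAR multiple imputation: FCS with δ=0, auxiliaries and the other
    variables' missingness indicators in every imputation model, pooled by
    Rubin's rules."""
    if M < 2:
        raise ValueError("M must be >= 2")
    specs = specs if specs is not None else default_imputation_specs()
    imputations = run_fcs(obs, specs=specs, delta=0.0, n_burn=n_burn,
                          K=M, seed=seed)
    ests, variances = [], []
    for imp in imputations:
        est = fit_substantive(imp.data, obs.roles, method="mi")
        ests.append(est.estimate)
        variances.append(est.se**2)
    return rubin_pool(ests, variances, n_obs=obs.n,
                      n_params=2 + len(obs.roles.confounders))


def run_population_comparison(
    obs: ObservedDataset,
) -> tuple[EstimateWithSE, float]:
    """Treat every missing outcome as a non-case and fit on all rows.

    Requires complete covariates (rows missing any covariate are dropped,
    with ``n_used`` reflecting that).  Returns the fit and the implied
    marginal outcome prevalence = observed cases / total n.
    """
    roles = obs.roles
    df = obs.data.copy()
    implied_prevalence = float(df[roles.outcome].sum(skipna=True)) / len(df)
    df[roles.outcome] = df[roles.outcome].fillna(0.0)
    covars = (roles.exposure,) + roles.confounders
    df = df.loc[df[list(covars)].notna().all(axis=1)]
    est = fit_substantive(df, roles, method="popcomp")
    return est, implied_prevalence
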