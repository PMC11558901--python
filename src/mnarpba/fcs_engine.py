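"""Fully conditional specification imputation with a NARFCS δ-offset.

Each partially observed variable gets a univariate conditional model
(logistic for binary, linear for continuous) whose predictors may include
the *values* of other variables and the *missingness indicators* of other
partially observed variables (pattern-mixture style).  The MNAR outcome's
model additionally carries a fixed offset δ × (own missingness indicator):
since the model is fitted on rows where the target is observed (indicator
identically 0) the offset coefficient is inestimable from data — it is the
externally supplied bias parameter, and it shifts the log-odds of every
imputed value by δ.  Setting δ = 0 reduces the engine bit-exactly to
ordinary MAR FCS.

Parameter uncertainty is propagated by redrawing the model parameters from
(an approximation of) their posterior before every imputation pass:
an exact Normal–inverse-chi-square draw for linear models and a single
multivariate Normal draw around the MLE for logistic models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._glm import expit, draw_linear_params, fit_logistic, safe_cholesky
from .cli_io import ObservedDataset, indicator_name

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputationModelSpec:
    """Univariate conditional model for one partially observed variable."""

    target: str
    family: str  # "logistic" or "linear"
    predictors: tuple[str, ...]
    offset_indicator: str | None = None  # the target's own m_* column

    def __post_init__(self) -> None:
        if self.family not in ("logistic", "linear"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.target in self.predictors:
            raise ValueError(f"{self.target} cannot predict itself")
        own = indicator_name(self.target)
        if own in self.predictors:
            raise ValueError(
                f"{self.target}: own missingness indicator {own} must enter "
                "via offset_indicator, not as a predictor")
        if self.offset_indicator is not None and self.offset_indicator != own:
            raise ValueError(
                f"offset indicator must be {own}, got {self.offset_indicator}")


@dataclass
class ParamDraw:
    """One draw of a conditional model's parameters."""

    coefficients: np.ndarray
    residual_variance: float | None = None
    method: str = ""


@dataclass
class ImputedDataset:
    """A completed table plus the provenance of its imputation run."""

    data: pd.DataFrame
    delta: float
    n_burn: int
    index: int
    seed_entropy: object = None


def default_imputation_specs(mnar_outcome: bool = True) -> list[ImputationModelSpec]:
    """Pattern-mixture model specs for the simulated cohort's Y, X, W, D.

    Every model conditions on all other analysis/auxiliary variables plus
    the missingness indicators of the *other* partially observed variables.
    With ``mnar_outcome`` the Y model carries the δ-offset on its own
    indicator; without it the specs are the MAR-FCS comparator models.
    """
    base = ("A1", "A2", "Z1", "Z2", "Z3")
    return [
        ImputationModelSpec("X", "linear",
                            ("Y", "W", "D") + base + ("m_y", "m_w", "m_d")),
        ImputationModelSpec("W", "logistic",
                            ("Y", "X", "D") + base + ("m_y", "m_x", "m_d")),
        ImputationModelSpec("D", "logistic",
                            ("Y", "X", "W") + base + ("m_y", "m_x", "m_w")),
        ImputationModelSpec("Y", "logistic",
                            ("X", "W", "D") + base + ("m_x", "m_w", "m_d"),
                            offset_indicator="m_y" if mnar_outcome else None),
    ]


def _design(data: pd.DataFrame, predictors: tuple[str, ...],
            rows: np.ndarray | None = None) -> np.ndarray:
    df = data if rows is None else data.loc[rows]
    return np.column_stack(
        [np.ones(len(df))] + [df[c].to_numpy(float) for c in predictors])


def draw_model_params(
    data: pd.DataFrame, spec: ImputationModelSpec, rng: np.random.Generator
) -> ParamDraw:
    """Posterior(-approximate) parameter draw from the observed-target rows."""
    obs_mask = data[indicator_name(spec.target)].to_numpy() == 0
    n_obs = int(obs_mask.sum())
    if n_obs < len(spec.predictors) + 2:
        raise ValueError(
            f"{spec.target}: only {n_obs} observed rows for "
            f"{len(spec.predictors)} predictors")
    X = _design(data, spec.predictors, obs_mask)
    y = data.loc[obs_mask, spec.target].to_numpy(float)
    if spec.family == "linear":
        d = draw_linear_params(X, y, rng)
        return ParamDraw(coefficients=d.coef, residual_variance=d.sigma2,
                         method="normal-inv-chi2")
    fit = fit_logistic(X, y)
    L = safe_cholesky((fit.cov))
    coef = fit.coef + L @ rng.standard_normal(fit.coef.size)
    return ParamDraw(coefficients=coef,
                     method="mle+normal" + ("-ridge" if fit.ridged else ""))


def impute_variable(
    data: pd.DataFrame,
    spec: ImputationModelSpec,
    draw: ParamDraw,
    delta: float,
    rng: np.random.Generator,
) -> pd.Series:
    """Redraw the missing entries of the target; observed rows untouched."""
    if delta != 0.0 and spec.offset_indicator is None:
        raise ValueError(f"{spec.target}: delta supplied but spec has no offset")
    col = data[spec.target].copy()
    mis_mask = data[indicator_name(spec.target)].to_numpy() == 1
    if not mis_mask.any():
        return col
    X = _design(data, spec.predictors, mis_mask)
    lp = X @ draw.coefficients
    if spec.offset_indicator is not None:
        # the indicator is 1 on every imputed row by construction
        lp = lp + delta
    if not np.all(np.isfinite(lp)):
        raise FloatingPointError(f"{spec.target}: non-finite linear predictor")
    if spec.family == "logistic":
        imputed = (rng.random(lp.size) < expit(lp)).astype(float)
    else:
        imputed = lp + np.sqrt(draw.residual_variance) * rng.standard_normal(lp.size)
    col.iloc[np.flatnonzero(mis_mask)] = imputed
    return col


def visit_order(obs: ObservedDataset,
                specs: list[ImputationModelSpec]) -> list[ImputationModelSpec]:
    """Least-missing-first visit order; ties keep the declared spec order."""
    return sorted(specs, key=lambda s: obs.missing_fraction(s.target))


def run_fcs(
    obs: ObservedDataset,
    specs: list[ImputationModelSpec] | None = None,
    delta: float = 0.0,
    n_burn: int = 10,
    K: int = 1,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
    order: str = "missingness",
) -> list[ImputedDataset]:
    """Run the FCS algorithm; returns K independently imputed datasets.

    Each imputation is an independent chain: random initial fill from the
    observed margins, then ``n_burn`` sweeps over the variables (least
    missing first, or the declared spec order with ``order="declared"``),
    redrawing model parameters and imputations each visit.  δ is applied
    only through the spec carrying an offset indicator.
    """
    if K < 1 or n_burn < 1:
        raise ValueError("K and n_burn must be >= 1")
    if order not in ("missingness", "declared"):
        raise ValueError("order must be 'missingness' or 'declared'")
    specs = specs if specs is not None else default_imputation_specs()
    targets = [s.target for s in specs]
    uncovered = [v for v in obs.roles.partially_observed
                 if obs.missing_fraction(v) > 0 and v not in targets]
    if uncovered:
        raise ValueError(f"no imputation spec for partially observed {uncovered}")
    order_specs = visit_order(obs, specs) if order == "missingness" else list(specs)
    ss = (seed if isinstance(seed, np.random.SeedSequence)
          else np.random.SeedSequence(seed))
    chains = ss.spawn(K)
    results: list[ImputedDataset] = []
    any_missing = any(obs.missing_fraction(t) > 0 for t in targets)
    if not any_missing:
        return [ImputedDataset(obs.data.copy(), delta, n_burn, k, c.entropy)
                for k, c in enumerate(chains)]

    # numpy working set: the inner loop runs tens of thousands of times in a
    # Monte Carlo analysis, so avoid per-visit DataFrame indexing
    base = {c: obs.data[c].to_numpy(float) for c in obs.data.columns}
    mis_masks = {t: base[indicator_name(t)] == 1 for t in targets}
    active = [s for s in order_specs if mis_masks[s.target].any()]
    n = obs.n
    ones = np.ones(n)

    for k, child in enumerate(chains):
        rng = np.random.default_rng(child)
        cols = {c: v.copy() for c, v in base.items()}
        for var in targets:  # initial fill from the observed margins
            mis = mis_masks[var]
            if mis.any():
                observed = cols[var][~mis]
                cols[var][mis] = rng.choice(observed, size=int(mis.sum()),
                                            replace=True)
        for sweep in range(n_burn):
            for spec in active:
                try:
                    _visit(cols, spec, mis_masks[spec.target], delta, ones, rng)
                except Exception as exc:
                    raise RuntimeError(
                        f"imputation {k}, sweep {sweep}, variable "
                        f"{spec.target}: {exc}") from exc
        frame = obs.data.copy()
        for var in targets:
            frame[var] = cols[var]
        results.append(ImputedDataset(frame, delta, n_burn, k, child.entropy))
    return results


def _visit(
    cols: dict[str, np.ndarray],
    spec: ImputationModelSpec,
    mis: np.ndarray,
    delta: float,
    ones: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """One FCS visit: redraw the model parameters from the observed-target
    rows, then redraw the missing entries (same draw sequence as the
    public draw_model_params/impute_variable pair)."""
    X = np.column_stack([ones] + [cols[p] for p in spec.predictors])
    obs_rows = ~mis
    if int(obs_rows.sum()) < len(spec.predictors) + 2:
        raise ValueError(
            f"{spec.target}: only {int(obs_rows.sum())} observed rows for "
            f"{len(spec.predictors)} predictors")
    y = cols[spec.target][obs_rows]
    Xmis = X[mis]
    if spec.family == "linear":
        d = draw_linear_params(X[obs_rows], y, rng)
        lp = Xmis @ d.coef
        if not np.all(np.isfinite(lp)):
            raise FloatingPointError("non-finite linear predictor")
        cols[spec.target][mis] = lp + np.sqrt(d.sigma2) \
            * rng.standard_normal(lp.size)
        return
    fit = fit_logistic(X[obs_rows], y)
    L = safe_cholesky(fit.cov)
    coef = fit.coef + L @ rng.standard_normal(fit.coef.size)
    lp = Xmis @ coef
    if spec.offset_indicator is not None:
        lp = lp + delta
    if not np.all(np.isfinite(lp)):
        raise FloatingPointError("non-finite linear predictor")
    cols[spec.target][mis] = (rng.random(lp.size) < expit(lp)).astype(float)
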