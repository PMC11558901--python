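"""Data-generating models for the MNAR-outcome simulation study.

Two factorisations of the same joint distribution are implemented:

* the **selection-model (SM) generator** draws, in order,
  W←Z, X←(W,Z), Y←(X,W,Z), A←(Y,X,W,Z), D←(A,Y,X,W,Z), and finally the
  outcome's missingness indicator M^Y←(D,A,Y,X).  The bias parameter
  δ^SM is the *increase in the log-odds of observing Y* per unit of Y,
  conditional on D, A and X, i.e.

      logit Pr(M^Y = 1 | D, A, Y, X) = ψ0 + ψD·D + ψA·A + ψX·X − δ^SM·Y

  (M^Y = 1 means Y is missing);

* the **pattern-mixture (PMM) generator** draws the fully observed
  variables and M^Y first and the partially observed ones afterwards,
  ending with Y given everything including M^Y.  Its coefficient on M^Y,
  δ^NARFCS, is the difference in the log-odds of Y=1 between subjects with
  missing and observed Y.  Because the PMM coefficients cannot be derived
  analytically from the SM ones, they are obtained by maximum-likelihood
  fits of the PMM factorisation to a large SM-generated sample.

On top of either complete-data generator, MAR missingness of X, W and D is
imposed via three independent logistic mechanisms driven by the fully
observed Z and A only, and Y is blanked wherever M^Y = 1.

The default (demo) coefficient set emulates a large biobank-style cohort:
binary outcome with 5% marginal prevalence (intercept calibrated),
continuous exposure and one continuous confounder with mean 0 / SD 1,
a very strong MNAR mechanism (δ^SM = 7.85) that leaves ~80% of outcomes
missing with the observed subset strongly case-enriched, and ~5%
MAR missingness in X, W and D.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from ._glm import expit, logit, fit_logistic, fit_linear
from .cli_io import ObservedDataset, VariableRoles, indicator_name

logger = logging.getLogger(__name__)

COLUMNS = ("Y", "X", "Z1", "Z2", "Z3", "W", "A1", "A2", "D", "m_y")

#: log-odds of the very strong MNAR mechanism used throughout the study
DELTA_SM_DEFAULT = 7.85


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

def _vec(x, k: int, name: str) -> np.ndarray:
    v = np.atleast_1d(np.asarray(x, dtype=float))
    if v.shape != (k,):
        raise ValueError(f"{name}: expected length {k}, got {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError(f"{name}: non-finite coefficient")
    return v


@dataclass
class SMDGMParams:
    """Coefficients of the selection-model data-generating factorisation.

    All binary-variable models are logistic (log-odds units); the exposure
    model is linear with residual variance ``xi2``.  ``delta_sm`` is the
    log-odds increase of *observing* Y per unit of Y.
    """

    # exogenous confounder marginals: Z1~Bern(pz1), Z2~N(0,1), Z3~Bern(pz3)
    pz1: float = 0.5
    pz3: float = 0.33
    # W | Z
    eta0: float = -2.30
    eta_z: np.ndarray = field(default_factory=lambda: np.array([0.30, -0.10, -0.40]))
    # X | W, Z  (linear)
    zeta0: float = -0.03
    zeta_w: float = 0.15
    zeta_z: np.ndarray = field(default_factory=lambda: np.array([0.10, 0.15, -0.10]))
    xi2: float = 0.97
    # Y | X, W, Z  (substantive model)
    beta0: float = -3.60
    beta_x: float = np.log(3.0)
    beta_w: float = 0.35
    beta_z: np.ndarray = field(default_factory=lambda: np.array([0.25, 0.30, -0.20]))
    # A_j | Y, X, W, Z  (rows: A1, A2; columns: const, Y, X, W, Z1, Z2, Z3)
    theta: np.ndarray = field(default_factory=lambda: np.array([
        [-2.10, 0.80, 0.15, 0.25, 0.10, 0.05, -0.10],
        [-2.80, 1.00, 0.35, 0.20, 0.15, 0.30, -0.20],
    ]))
    # D | A, Y, X, W, Z
    omega0: float = -1.10
    omega_a: np.ndarray = field(default_factory=lambda: np.array([0.40, 0.70]))
    omega_y: float = 0.90
    omega_x: float = 0.30
    omega_w: float = 0.20
    omega_z: np.ndarray = field(default_factory=lambda: np.array([0.20, 0.50, -0.15]))
    # M^Y | D, A, Y, X   (logit of being MISSING; Y enters with −delta_sm)
    psi0: float = 1.90
    psi_d: float = -0.50
    psi_a: np.ndarray = field(default_factory=lambda: np.array([-0.30, -0.45]))
    psi_x: float = -0.20
    delta_sm: float = DELTA_SM_DEFAULT

    def __post_init__(self) -> None:
        self.eta_z = _vec(self.eta_z, 3, "eta_z")
        self.zeta_z = _vec(self.zeta_z, 3, "zeta_z")
        self.beta_z = _vec(self.beta_z, 3, "beta_z")
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.shape != (2, 7):
            raise ValueError(f"theta: expected shape (2, 7), got {self.theta.shape}")
        self.omega_a = _vec(self.omega_a, 2, "omega_a")
        self.omega_z = _vec(self.omega_z, 3, "omega_z")
        self.psi_a = _vec(self.psi_a, 2, "psi_a")
        if not self.xi2 > 0:
            raise ValueError(f"xi2 must be > 0, got {self.xi2}")
        scalars = [self.pz1, self.pz3, self.eta0, self.zeta0, self.zeta_w,
                   self.beta0, self.beta_x, self.beta_w, self.omega0,
                   self.omega_y, self.omega_x, self.omega_w, self.psi0,
                   self.psi_d, self.psi_x, self.delta_sm]
        if not np.all(np.isfinite(self.theta)) or not all(np.isfinite(scalars)):
            raise ValueError("non-finite coefficient in SMDGMParams")
        if not (0 < self.pz1 < 1 and 0 < self.pz3 < 1):
            raise ValueError("pz1/pz3 must be in (0, 1)")

    # ---- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "pz1": self.pz1, "pz3": self.pz3,
            "eta": {"eta0": self.eta0, "eta_z": self.eta_z.tolist()},
            "zeta": {"zeta0": self.zeta0, "zeta_w": self.zeta_w,
                     "zeta_z": self.zeta_z.tolist()},
            "xi2": self.xi2,
            "beta": {"beta0": self.beta0, "beta_x": self.beta_x,
                     "beta_w": self.beta_w, "beta_z": self.beta_z.tolist()},
            "theta": self.theta.tolist(),
            "omega": {"omega0": self.omega0, "omega_a": self.omega_a.tolist(),
                      "omega_y": self.omega_y, "omega_x": self.omega_x,
                      "omega_w": self.omega_w, "omega_z": self.omega_z.tolist()},
            "psi": {"psi0": self.psi0, "psi_d": self.psi_d,
                    "psi_a": self.psi_a.tolist(), "psi_x": self.psi_x},
            "delta_sm": self.delta_sm,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SMDGMParams":
        return cls(
            pz1=d["pz1"], pz3=d["pz3"],
            eta0=d["eta"]["eta0"], eta_z=d["eta"]["eta_z"],
            zeta0=d["zeta"]["zeta0"], zeta_w=d["zeta"]["zeta_w"],
            zeta_z=d["zeta"]["zeta_z"], xi2=d["xi2"],
            beta0=d["beta"]["beta0"], beta_x=d["beta"]["beta_x"],
            beta_w=d["beta"]["beta_w"], beta_z=d["beta"]["beta_z"],
            theta=d["theta"],
            omega0=d["omega"]["omega0"], omega_a=d["omega"]["omega_a"],
            omega_y=d["omega"]["omega_y"], omega_x=d["omega"]["omega_x"],
            omega_w=d["omega"]["omega_w"], omega_z=d["omega"]["omega_z"],
            psi0=d["psi"]["psi0"], psi_d=d["psi"]["psi_d"],
            psi_a=d["psi"]["psi_a"], psi_x=d["psi"]["psi_x"],
            delta_sm=d["delta_sm"],
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SMDGMParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def null_sm_params(**overrides) -> SMDGMParams:
    """All slopes zero — every binary variable Bernoulli(1/2), X ~ N(0, 1)."""
    base = dict(
        pz1=0.5, pz3=0.5, eta0=0.0, eta_z=np.zeros(3),
        zeta0=0.0, zeta_w=0.0, zeta_z=np.zeros(3), xi2=1.0,
        beta0=0.0, beta_x=0.0, beta_w=0.0, beta_z=np.zeros(3),
        theta=np.zeros((2, 7)), omega0=0.0, omega_a=np.zeros(2),
        omega_y=0.0, omega_x=0.0, omega_w=0.0, omega_z=np.zeros(3),
        psi0=0.0, psi_d=0.0, psi_a=np.zeros(2), psi_x=0.0, delta_sm=0.0,
    )
    base.update(overrides)
    return SMDGMParams(**base)


@dataclass
class MARMechanism:
    """Independent logistic MAR mechanisms for X, W and D given (Z, A).

    Coefficient order per target: intercept, Z1, Z2, Z3, A1, A2 (log-odds).
    """

    coef: dict[str, np.ndarray] = field(default_factory=lambda: {
        # derived from the motivating cohort's observed covariate missingness
        "X": np.array([-3.20, 0.233, -0.0570, -0.133, 0.363, 0.763]),
        "W": np.array([-2.90, 0.0720, -0.232, -0.774, 0.169, 0.417]),
        "D": np.array([-2.95, -0.0590, -0.0290, -0.190, 0.130, 0.192]),
    })
    predictors: tuple[str, ...] = ("Z1", "Z2", "Z3", "A1", "A2")

    def __post_init__(self) -> None:
        if set(self.coef) != {"X", "W", "D"}:
            raise ValueError("MARMechanism must target exactly X, W and D")
        for k, v in self.coef.items():
            self.coef[k] = _vec(v, 1 + len(self.predictors), f"mar_{k}")

    def probabilities(self, df: pd.DataFrame, target: str) -> np.ndarray:
        missing = [c for c in self.predictors if c not in df.columns]
        if missing:
            raise KeyError(f"MAR mechanism for {target} needs columns {missing}")
        Xmat = np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(float) for c in self.predictors])
        return expit(Xmat @ self.coef[target])


@dataclass
class TruthValues:
    """True target values used by the performance evaluation."""

    beta_x_true: float
    delta_sm_true: float
    delta_narfcs_true: float
    provenance: dict = field(default_factory=dict)


# --------------------------------------------------------------------------
# SM generation
# --------------------------------------------------------------------------

def _bern(rng: np.random.Generator, p: np.ndarray) -> np.ndarray:
    return (rng.random(p.shape) < p).astype(float)


def generate_sm_complete(
    n: int, params: SMDGMParams, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw a complete dataset (including M^Y) from the SM factorisation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    z1 = _bern(rng, np.full(n, params.pz1))
    z2 = rng.standard_normal(n)
    z3 = _bern(rng, np.full(n, params.pz3))
    Z = np.column_stack([z1, z2, z3])

    w = _bern(rng, expit(params.eta0 + Z @ params.eta_z))
    x = (params.zeta0 + params.zeta_w * w + Z @ params.zeta_z
         + np.sqrt(params.xi2) * rng.standard_normal(n))
    y = _bern(rng, expit(params.beta0 + params.beta_x * x
                         + params.beta_w * w + Z @ params.beta_z))
    design_a = np.column_stack([np.ones(n), y, x, w, Z])
    a1 = _bern(rng, expit(design_a @ params.theta[0]))
    a2 = _bern(rng, expit(design_a @ params.theta[1]))
    d = _bern(rng, expit(params.omega0 + params.omega_a[0] * a1
                         + params.omega_a[1] * a2 + params.omega_y * y
                         + params.omega_x * x + params.omega_w * w
                         + Z @ params.omega_z))
    lp_my = (params.psi0 + params.psi_d * d + params.psi_a[0] * a1
             + params.psi_a[1] * a2 + params.psi_x * x - params.delta_sm * y)
    m_y = _bern(rng, expit(lp_my))
    return pd.DataFrame({
        "Y": y, "X": x, "Z1": z1, "Z2": z2, "Z3": z3,
        "W": w, "A1": a1, "A2": a2, "D": d, "m_y": m_y,
    })


def calibrate_y_intercept(
    params: SMDGMParams,
    target_prevalence: float,
    n_calib: int = 200_000,
    seed: int = 0,
    tol: float = 2e-3,
) -> float:
    """Solve for the Y-model intercept giving a target marginal prevalence.

    Uses a fixed calibration sample of (W, X, Z) (common random numbers) and
    root-finds on the exact conditional mean  mean_i expit(b0 + lp_i),
    which is smooth and strictly increasing in b0.  Deterministic given seed.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must be in (0, 1)")
    if n_calib < 10_000:
        raise ValueError("n_calib must be >= 10,000")
    rng = np.random.default_rng(seed)
    z1 = _bern(rng, np.full(n_calib, params.pz1))
    z2 = rng.standard_normal(n_calib)
    z3 = _bern(rng, np.full(n_calib, params.pz3))
    Z = np.column_stack([z1, z2, z3])
    w = _bern(rng, expit(params.eta0 + Z @ params.eta_z))
    x = (params.zeta0 + params.zeta_w * w + Z @ params.zeta_z
         + np.sqrt(params.xi2) * rng.standard_normal(n_calib))
    lp = params.beta_x * x + params.beta_w * w + Z @ params.beta_z

    def prevalence_gap(b0: float) -> float:
        return float(np.mean(expit(b0 + lp))) - target_prevalence

    lo, hi = logit(target_prevalence) - 15.0, logit(target_prevalence) + 15.0
    if prevalence_gap(lo) > 0 or prevalence_gap(hi) < 0:
        raise RuntimeError(
            "calibration failure: search bounds do not bracket the target")
    b0 = brentq(prevalence_gap, lo, hi, xtol=tol / 10)
    assert abs(prevalence_gap(b0)) < tol
    return float(b0)


@lru_cache(maxsize=16)
def _demo_intercept(beta_x: float, target: float) -> float:
    probe = SMDGMParams(beta_x=beta_x)
    return calibrate_y_intercept(probe, target, n_calib=200_000, seed=20_240_101)


def demo_params(
    beta_x: float = np.log(3.0),
    delta_sm: float = DELTA_SM_DEFAULT,
    target_prevalence: float = 0.05,
) -> SMDGMParams:
    """The study's default SM generator with the Y-intercept calibrated."""
    b0 = _demo_intercept(float(beta_x), float(target_prevalence))
    return SMDGMParams(beta0=b0, beta_x=float(beta_x), delta_sm=float(delta_sm))


# --------------------------------------------------------------------------
# PMM factorisation: fit to a large SM sample, then generate
# --------------------------------------------------------------------------

#: generation order and per-component (family, predictor columns) of the
#: pattern-mixture factorisation; fully observed variables and M^Y come
#: first, Y comes last so its M^Y coefficient is the bias parameter.
PMM_COMPONENTS: list[tuple[str, str, tuple[str, ...]]] = [
    ("A1", "logistic", ("Z1", "Z2", "Z3")),
    ("A2", "logistic", ("A1", "Z1", "Z2", "Z3")),
    ("m_y", "logistic", ("A1", "A2", "Z1", "Z2", "Z3")),
    ("W", "logistic", ("m_y", "A1", "A2", "Z1", "Z2", "Z3")),
    ("X", "linear", ("W", "m_y", "A1", "A2", "Z1", "Z2", "Z3")),
    ("D", "logistic", ("X", "W", "m_y", "A1", "A2", "Z1", "Z2", "Z3")),
    ("Y", "logistic", ("X", "W", "D", "A1", "A2", "Z1", "Z2", "Z3", "m_y")),
]


@dataclass
class PMMDGMParams:
    """Fitted coefficients of the pattern-mixture factorisation.

    ``components`` maps variable name -> coefficient vector (intercept
    first, then the predictors listed in :data:`PMM_COMPONENTS`).  The Y
    component's coefficient on M^Y is the bias parameter δ^NARFCS.
    """

    pz1: float
    z2_mean: float
    z2_sd: float
    pz3: float
    components: dict[str, np.ndarray]
    eps2: float
    n_fit: int

    def __post_init__(self) -> None:
        if not self.eps2 > 0:
            raise ValueError("eps2 must be > 0")
        for name, fam, preds in PMM_COMPONENTS:
            v = self.components.get(name)
            if v is None:
                raise ValueError(f"missing PMM component {name}")
            self.components[name] = _vec(v, 1 + len(preds), f"pmm_{name}")

    @property
    def delta_narfcs(self) -> float:
        return float(self.components["Y"][-1])  # M^Y is the last predictor


def fit_pmm_params(big: pd.DataFrame) -> PMMDGMParams:
    """ML fit of every PMM component regression to a large SM sample."""
    comps: dict[str, np.ndarray] = {}
    eps2 = np.nan
    ones = np.ones(len(big))
    for name, family, preds in PMM_COMPONENTS:
        Xmat = np.column_stack([ones] + [big[c].to_numpy(float) for c in preds])
        yv = big[name].to_numpy(float)
        if family == "logistic":
            fit = fit_logistic(Xmat, yv)
            if not fit.converged:
                raise RuntimeError(f"PMM component fit for {name} did not converge")
        else:
            fit = fit_linear(Xmat, yv)
            eps2 = fit.sigma2  # type: ignore[attr-defined]
        comps[name] = fit.coef
    z2 = big["Z2"].to_numpy(float)
    return PMMDGMParams(
        pz1=float(big["Z1"].mean()), z2_mean=float(z2.mean()),
        z2_sd=float(z2.std(ddof=1)), pz3=float(big["Z3"].mean()),
        components=comps, eps2=float(eps2), n_fit=len(big),
    )


def generate_pmm_complete(
    n: int, params: PMMDGMParams, seed: int | np.random.Generator
) -> pd.DataFrame:
    """Draw a complete dataset from the fitted pattern-mixture factorisation."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {
        "Z1": _bern(rng, np.full(n, params.pz1)),
        "Z2": params.z2_mean + params.z2_sd * rng.standard_normal(n),
        "Z3": _bern(rng, np.full(n, params.pz3)),
    }
    ones = np.ones(n)
    for name, family, preds in PMM_COMPONENTS:
        Xmat = np.column_stack([ones] + [cols[c] for c in preds])
        lp = Xmat @ params.components[name]
        if family == "logistic":
            cols[name] = _bern(rng, expit(lp))
        else:
            cols[name] = lp + np.sqrt(params.eps2) * rng.standard_normal(n)
    return pd.DataFrame({c: cols[c] for c in COLUMNS})


# --------------------------------------------------------------------------
# missingness imposition and truth derivation
# --------------------------------------------------------------------------

def apply_missingness(
    complete: pd.DataFrame,
    mech: MARMechanism | None = None,
    seed: int | np.random.Generator = 0,
) -> ObservedDataset:
    """Blank Y where M^Y=1 and impose the MAR mechanisms on X, W and D."""
    if "m_y" not in complete.columns:
        raise ValueError("complete dataset must contain the m_y indicator")
    mech = mech or MARMechanism()
    rng = np.random.default_rng(seed)
    df = complete.copy()
    df.loc[df["m_y"] == 1, "Y"] = np.nan
    for target in ("X", "W", "D"):
        m = _bern(rng, mech.probabilities(complete, target))
        df[indicator_name(target)] = m.astype(np.int8)
        df.loc[m == 1, target] = np.nan
    df["m_y"] = df["m_y"].astype(np.int8)
    return ObservedDataset(data=df, roles=VariableRoles())


def count_dataset(
    n_total: int,
    n_outcome_observed: int,
    n_cases_observed: int,
    seed: int = 0,
) -> ObservedDataset:
    """Minimal cohort matching published counts: ``n_total`` subjects,
    an outcome observed for ``n_outcome_observed`` of them with
    ``n_cases_observed`` cases, covariates complete and exposure-independent.

    Useful for reproducing summary arithmetic (testing fraction, positivity,
    implied prevalence under the population-comparison approach) from
    published marginal counts alone.
    """
    if not 0 <= n_cases_observed <= n_outcome_observed <= n_total:
        raise ValueError("counts must nest: cases <= observed <= total")
    df = generate_sm_complete(n_total, null_sm_params(), seed)
    y = np.full(n_total, np.nan)
    y[:n_cases_observed] = 1.0
    y[n_cases_observed:n_outcome_observed] = 0.0
    df["Y"] = y
    df["m_y"] = (np.arange(n_total) >= n_outcome_observed).astype(np.int8)
    for ind in ("m_x", "m_w", "m_d"):
        df[ind] = np.int8(0)
    return ObservedDataset(data=df, roles=VariableRoles())


def narfcs_delta_from_sample(complete: pd.DataFrame, obs: ObservedDataset) -> float:
    """Fit the pattern-mixture Y model (with all four missingness
    indicators) to complete, pre-deletion data; return the M^Y coefficient."""
    preds = ["X", "W", "D", "A1", "A2", "Z1", "Z2", "Z3",
             "m_x", "m_w", "m_d", "m_y"]
    ind = obs.data[["m_x", "m_w", "m_d"]]
    frame = complete.assign(**{c: ind[c].to_numpy() for c in ("m_x", "m_w", "m_d")})
    Xmat = np.column_stack([np.ones(len(frame))]
                           + [frame[c].to_numpy(float) for c in preds])
    fit = fit_logistic(Xmat, frame["Y"].to_numpy(float))
    if not fit.converged:
        raise RuntimeError("NARFCS truth fit did not converge")
    return float(fit.coef[-1])


def derive_truth(
    dgm_kind: str,
    params: SMDGMParams | PMMDGMParams,
    n_truth: int = 5_000_000,
    seed: int = 0,
) -> TruthValues:
    """Compute the true target values for performance evaluation.

    For the SM generator the exposure effect and δ^SM are parameters; the
    implied δ^NARFCS is estimated by fitting the pattern-mixture Y model to
    a large simulated sample.  For the PMM generator δ^NARFCS is a
    parameter and the exposure effect is estimated by fitting the
    substantive model to a large complete sample before data deletion.
    """
    if n_truth < 50_000_000:
        logger.info("deriving truth from n=%d (smaller than the full-scale "
                    "50,000,000); truth values carry Monte Carlo error", n_truth)
    if dgm_kind == "SM":
        assert isinstance(params, SMDGMParams)
        big = generate_sm_complete(n_truth, params, seed)
        obs = apply_missingness(big, seed=np.random.default_rng(seed + 1))
        delta_narfcs = narfcs_delta_from_sample(big, obs)
        return TruthValues(
            beta_x_true=params.beta_x,
            delta_sm_true=params.delta_sm,
            delta_narfcs_true=delta_narfcs,
            provenance={"beta_x": "parameter", "delta_sm": "parameter",
                        "delta_narfcs": f"estimate (n={n_truth})"},
        )
    if dgm_kind == "PMM":
        assert isinstance(params, PMMDGMParams)
        big = generate_pmm_complete(n_truth, params, seed)
        preds = ["X", "Z1", "Z2", "Z3", "W"]
        Xmat = np.column_stack([np.ones(len(big))]
                               + [big[c].to_numpy(float) for c in preds])
        fit = fit_logistic(Xmat, big["Y"].to_numpy(float))
        if not fit.converged:
            raise RuntimeError("substantive truth fit did not converge")
        return TruthValues(
            beta_x_true=float(fit.coef[1]),
            delta_sm_true=np.nan,
            delta_narfcs_true=params.delta_narfcs,
            provenance={"beta_x": f"estimate (n={n_truth})",
                        "delta_narfcs": "parameter (fitted PMM coefficient)"},
        )
    raise ValueError(f"dgm_kind must be 'SM' or 'PMM', got {dgm_kind!r}")
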