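"""Compact GLM fitting and posterior-draw primitives.

The imputation engine, the Monte Carlo loop and the simulation study fit
tens of thousands of small logistic/linear regressions; these routines keep
that affordable.  They are deliberately minimal: dense design matrices,
Newton–Raphson (IRLS) for the logistic likelihood, closed-form least squares
for the linear model, plus the standard posterior-draw approximations used
by chained-equations imputation software:

* linear regression under the Jeffreys-style prior p(coef, var) ∝ 1/var:
  scaled inverse-chi-square draw of the residual variance, then a Normal
  draw of the coefficients;
* logistic regression under a flat prior: maximum likelihood, then a single
  multivariate Normal draw with covariance equal to the inverse observed
  information.

Separation or a singular design triggers a ridge refit (small L2 penalty on
standardized predictors, intercept unpenalized) so long Monte Carlo runs
degrade gracefully instead of dying on a degenerate replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

logger = logging.getLogger(__name__)

_MAX_ABS_COEF = 30.0  # |log-odds| beyond this is numerically saturated


def expit(x: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable inverse logit."""
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=float)))


def logit(p):
    p = np.asarray(p, dtype=float)
    return np.log(p) - np.log1p(-p)


def bernoulli_loglik(y: np.ndarray, lp: np.ndarray) -> float:
    """Sum of Bernoulli log-likelihood terms for linear predictor ``lp``."""
    # log(expit(lp)) if y==1 else log(1-expit(lp)); stable via logaddexp
    return float(-np.sum(np.logaddexp(0.0, np.where(y > 0.5, -lp, lp))))


@dataclass
class GLMFit:
    coef: np.ndarray
    cov: np.ndarray          # inverse observed information (or ridge analogue)
    converged: bool
    n_iter: int
    ridged: bool = False
    loglik: float = np.nan

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


class SingularDesignError(np.linalg.LinAlgError):
    pass


def _solve_spd(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    try:
        c = np.linalg.cholesky(A)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(str(exc)) from exc
    y = solve_triangular(c, b, lower=True)
    return solve_triangular(c.T, y, lower=False)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    offset: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-9,
    ridge: float = 0.0,
    allow_fallback: bool = True,
) -> GLMFit:
    """Maximum-likelihood logistic regression by Newton–Raphson.

    ``X`` must include any intercept column explicitly.  ``ridge`` > 0 adds an
    L2 penalty on standardized non-constant columns.  On separation or a
    singular information matrix the fit is retried once with ridge=1e-4
    (``allow_fallback``); the returned fit is flagged ``ridged``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if offset is None:
        offset = 0.0
    penal = np.zeros(p)
    if ridge > 0.0:
        scale = X.std(axis=0)
        const = scale < 1e-12
        with np.errstate(divide="ignore"):
            penal = np.where(const, 0.0, ridge / np.maximum(scale, 1e-12) ** 2)
        # degenerate constant columns (other than the intercept) must be
        # pinned too, or the penalized information stays singular
        const_idx = np.flatnonzero(const)
        intercept = next((j for j in const_idx
                          if abs(X[0, j] - 1.0) < 1e-12), None)
        for j in const_idx:
            if j != intercept:
                penal[j] = max(penal[j], ridge)
    beta = np.zeros(p)
    # start intercept-only-ish: put the marginal log-odds on the first
    # constant column found, which speeds convergence for rare outcomes
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    const_cols = np.where(X.std(axis=0) < 1e-12)[0]
    has_intercept = const_cols.size and abs(X[0, const_cols[0]] - 1.0) < 1e-12
    if has_intercept:
        beta[const_cols[0]] = logit(ybar)
    if y.min() == y.max():
        # constant outcome: likelihood maximised at an infinite intercept;
        # return the saturated finite fit with a ridge-regularized covariance
        lp = X @ beta + offset
        mu = expit(lp)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        info = (X * w[:, None]).T @ X + 1e-4 * np.eye(p)
        return GLMFit(coef=beta, cov=np.linalg.inv(info), converged=True,
                      n_iter=0, ridged=True, loglik=bernoulli_loglik(y, lp))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lp = X @ beta + offset
        mu = expit(lp)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu) - penal * beta
        info = (X * w[:, None]).T @ X + np.diag(penal)
        try:
            step = _solve_spd(info, grad)
        except SingularDesignError:
            if allow_fallback and ridge == 0.0:
                logger.warning("singular design in logistic fit; ridge fallback")
                fit = fit_logistic(X, y, offset=offset, ridge=1e-4,
                                   allow_fallback=False)
                fit.ridged = True
                return fit
            raise
        beta_new = beta + step
        if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(beta))):
            beta = beta_new
            converged = True
            break
        beta = beta_new
    separated = np.max(np.abs(beta)) > _MAX_ABS_COEF
    if (not converged or separated) and allow_fallback and ridge == 0.0:
        logger.warning("logistic fit separated/unconverged; ridge fallback")
        fit = fit_logistic(X, y, offset=offset, ridge=1e-4, allow_fallback=False)
        fit.ridged = True
        return fit
    lp = X @ beta + offset
    mu = expit(lp)
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X + np.diag(penal)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError as exc:
        raise SingularDesignError(str(exc)) from exc
    return GLMFit(coef=beta, cov=cov, converged=converged, n_iter=it,
                  ridged=ridge > 0.0, loglik=bernoulli_loglik(y, lp))


def draw_logistic_params(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    offset: np.ndarray | None = None,
) -> np.ndarray:
    """One draw from the asymptotic Normal posterior under a flat prior."""
    fit = fit_logistic(X, y, offset=offset)
    L = safe_cholesky(fit.cov)
    return fit.coef + L @ rng.standard_normal(fit.coef.size)


def _nearest_spd(A: np.ndarray) -> np.ndarray:
    A = 0.5 * (A + A.T)
    try:
        np.linalg.cholesky(A)
        return A
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(A)
        floor = max(1e-10, 1e-10 * float(np.max(np.abs(w), initial=1.0)))
        w = np.clip(w, floor, None)
        return (V * w) @ V.T


def safe_cholesky(A: np.ndarray) -> np.ndarray:
    """Cholesky factor of A, coerced to be positive definite if needed."""
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        pass
    B = _nearest_spd(A)
    try:
        return np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        jitter = 1e-8 * (1.0 + float(np.trace(B)) / B.shape[0])
        return np.linalg.cholesky(B + jitter * np.eye(B.shape[0]))


@dataclass
class LinearDraw:
    coef: np.ndarray
    sigma2: float


def draw_linear_params(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
) -> LinearDraw:
    """Exact posterior draw for the Normal linear model under p(b, s2) ∝ 1/s2.

    sigma² | data ~ SSR / chi²(n−p); coef | sigma², data ~ N(b̂, sigma² (X'X)⁻¹).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more rows ({n}) than parameters ({p})")
    XtX = X.T @ X
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        XtX_inv = np.linalg.inv(XtX + 1e-8 * np.eye(p))
        logger.warning("singular design in linear draw; tiny ridge applied")
    bhat = XtX_inv @ (X.T @ y)
    resid = y - X @ bhat
    ssr = float(resid @ resid)
    sigma2 = ssr / rng.chisquare(n - p)
    L = safe_cholesky(XtX_inv)
    coef = bhat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    return LinearDraw(coef=coef, sigma2=sigma2)


def fit_linear(X: np.ndarray, y: np.ndarray) -> GLMFit:
    """OLS with classical covariance, for the PMM generating-model fits."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    bhat, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ bhat
    s2 = float(resid @ resid) / (n - p)
    cov = s2 * np.linalg.inv(X.T @ X)
    fit = GLMFit(coef=bhat, cov=cov, converged=True, n_iter=1)
    fit.sigma2 = s2  # type: ignore[attr-defined]
    return fit
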