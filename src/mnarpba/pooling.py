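"""Rubin's rules for combining estimates across multiple imputations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PooledEstimate:
    """Pooled scalar estimate with its variance decomposition.

    total_variance = within + (1 + 1/K) * between; ``df`` follows the
    Barnard–Rubin small-sample formula (infinite for K=1 or zero
    between-imputation variance).
    """

    estimate: float
    total_variance: float
    within_variance: float
    between_variance: float
    df: float
    K: int

    @property
    def se(self) -> float:
        return float(np.sqrt(self.total_variance))

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        q = (stats.t.ppf(0.5 + level / 2, self.df) if np.isfinite(self.df)
             else stats.norm.ppf(0.5 + level / 2))
        return self.estimate - q * self.se, self.estimate + q * self.se


def rubin_pool(
    estimates,
    variances,
    n_obs: int,
    n_params: int = 1,
) -> PooledEstimate:
    """Combine per-imputation estimates and variances.

    For K = 1 the estimate and variance pass through unchanged (the single
    imputation case, where between-imputation uncertainty is carried by an
    outer Monte Carlo loop instead).  ``n_obs``/``n_params`` give the
    complete-data degrees of freedom n_obs − n_params used by the
    Barnard–Rubin adjustment.
    """
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1 or q.size < 1:
        raise ValueError("estimates and variances must be equal-length vectors")
    if np.any(u <= 0):
        raise ValueError("variances must be positive")
    K = q.size
    if K == 1:
        return PooledEstimate(float(q[0]), float(u[0]), float(u[0]), 0.0,
                              np.inf, 1)
    qbar = float(q.mean())
    W = float(u.mean())
    B = float(q.var(ddof=1))
    T = W + (1.0 + 1.0 / K) * B
    if B == 0.0:
        return PooledEstimate(qbar, T, W, B, np.inf, K)
    lam = (1.0 + 1.0 / K) * B / T
    df_old = (K - 1) / lam**2
    nu_com = max(n_obs - n_params, 1)
    df_obs = (nu_com + 1.0) / (nu_com + 3.0) * nu_com * (1.0 - lam)
    df = df_old * df_obs / (df_old + df_obs)
    return PooledEstimate(qbar, T, W, B, df, K)
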