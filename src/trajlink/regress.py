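"""Small shared least-squares helpers.

All trajectory/branch/set tests in this package reduce to Gaussian OLS fits;
this module centralizes the fit, the coefficient t-statistics, and the
Gaussian profile log-likelihood used by the likelihood-ratio tests.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ComputationError

__all__ = ["OlsFit", "ols_fit", "one_sided_p"]


@dataclass
class OlsFit:
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    df_resid: int
    rss: float
    n: int

    @property
    def loglik(self) -> float:
        """Gaussian profile log-likelihood (sigma^2 profiled out)."""
        n = self.n
        if self.rss <= 0:
            raise ComputationError("zero residual sum of squares; likelihood unbounded")
        return -0.5 * n * (np.log(2.0 * np.pi * self.rss / n) + 1.0)


def ols_fit(X: np.ndarray, y: np.ndarray) -> OlsFit:
    """Ordinary least squares with homoskedastic coefficient t-statistics."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ComputationError(f"need more observations ({n}) than parameters ({k})")
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    if diag.min() <= 1e-10 * max(diag.max(), 1.0):
        raise np.linalg.LinAlgError("singular design matrix")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df_resid = n - k
    sigma2 = rss / df_resid
    r_inv = np.linalg.solve(r, np.eye(k))
    xtx_inv_diag = np.sum(r_inv**2, axis=1)
    se = np.sqrt(sigma2 * xtx_inv_diag)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.sign(beta) * np.inf)
    return OlsFit(beta=beta, se=se, t=t, df_resid=df_resid, rss=rss, n=n)


def one_sided_p(t: float, df: int) -> float:
    """Upper-tail probability of a Student t statistic."""
    return float(stats.t.sf(t, df))
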