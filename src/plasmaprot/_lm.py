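"""Small dense least-squares core used by all model-fitting stages.

The pipeline performs tens of thousands of small Gaussian fits (per protein,
per covariate, per variant), so the fits are done with numpy directly.
Coefficients, standard errors and p-values agree with statsmodels OLS to
machine precision (cross-checked in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class LinearFit:
    """Gaussian least-squares fit with an intercept in column 0."""

    params: np.ndarray        # (p,)
    se: np.ndarray            # (p,) NaN where not estimable
    rss: float
    n: int
    rank: int
    columns: list[str]

    @property
    def df_resid(self) -> int:
        return self.n - self.rank

    @property
    def loglik(self) -> float:
        return gaussian_loglik(self.rss, self.n)

    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.se

    def pvalues(self) -> np.ndarray:
        t = self.tvalues()
        if self.df_resid <= 0:
            return np.full_like(t, np.nan)
        return 2.0 * stats.t.sf(np.abs(t), self.df_resid)


def gaussian_loglik(rss: float, n: int) -> float:
    """Maximized Gaussian log-likelihood given the residual sum of squares."""
    if n <= 0:
        raise ValueError("n must be positive")
    sigma2 = max(rss, 1e-300) / n
    return -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0)


def add_intercept(X: np.ndarray | None, n: int) -> np.ndarray:
    ones = np.ones((n, 1))
    if X is None or X.size == 0:
        return ones
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return np.hstack([ones, X])


def ols(y: np.ndarray, X: np.ndarray, columns: list[str] | None = None) -> LinearFit:
    """Least squares of y on X (X must already contain the intercept)."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    df = n - rank
    se = np.full(p, np.nan)
    if df > 0:
        XtX = X.T @ X
        # pinv handles rank deficiency; se undefined for aliased columns
        cov = np.linalg.pinv(XtX) * (rss / df)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        se = np.sqrt(d)
        if rank < p:
            # flag aliased columns: their pinv variance is not a Wald se
            aliased = np.abs(np.diag(XtX @ np.linalg.pinv(XtX)) - 1.0) > 1e-8
            se[aliased] = np.nan
    cols = columns if columns is not None else [f"x{i}" for i in range(p)]
    return LinearFit(params=beta, se=se, rss=rss, n=n, rank=int(rank), columns=list(cols))


def residuals(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    beta, _, _, _ = np.linalg.lstsq(np.asarray(X, float), np.asarray(y, float), rcond=None)
    return np.asarray(y, float) - np.asarray(X, float) @ beta
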