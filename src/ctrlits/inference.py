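"""Variance estimators and error-structure corrections.

All sandwich estimators operate on an already-fitted least-squares design and
its residuals, returning a coefficient covariance matrix but never touching
the point estimates; FGLS and the AR(1) regression re-estimate coefficients
jointly with the error structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, StructuralError


@dataclass
class CovEstimate:
    vcov: np.ndarray
    method: str
    lag: int | None = None

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.vcov))


@dataclass
class GLSResult:
    params: np.ndarray
    cov: CovEstimate
    converged: bool = True
    rho_hat: float = np.nan
    extra: dict = field(default_factory=dict)


def _bread(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise StructuralError("design matrix is rank deficient")
    return np.linalg.inv(X.T @ X)


def default_dk_lag(n_periods: int) -> int:
    """Plug-in Bartlett lag floor(4 * (T/100)^(2/9))."""
    return int(np.floor(4.0 * (n_periods / 100.0) ** (2.0 / 9.0)))


def white_vcov(X, residuals, small_sample: bool = True) -> CovEstimate:
    """Heteroscedasticity-consistent sandwich (HC1 when small_sample)."""
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    n, k = X.shape
    bread = _bread(X)
    meat = (X * (e * e)[:, None]).T @ X
    vcov = bread @ meat @ bread
    if small_sample:
        if n <= k:
            raise StructuralError("no residual degrees of freedom")
        vcov = vcov * (n / (n - k))
    return CovEstimate(vcov=vcov, method="white")


def driscoll_kraay_vcov(X, residuals, time_index, lag: int | None = None,
                        small_sample: bool = True) -> CovEstimate:
    """Driscoll-Kraay sandwich for a balanced panel stacked over groups.

    Scores are summed cross-sectionally per period; their autocovariances up
    to ``lag`` enter with Bartlett weights 1 - l/(lag+1).  With a single group
    and lag 0 this reduces exactly to the White estimator.
    """
    X = np.asarray(X, dtype=float)
    e = np.asarray(residuals, dtype=float)
    t_idx = np.asarray(time_index)
    periods = np.unique(t_idx)
    T = len(periods)
    if lag is None:
        lag = default_dk_lag(T)
    if lag < 0:
        raise ParameterError("lag must be >= 0")
    if lag >= T:
        raise ParameterError(f"lag {lag} must be < number of periods {T}")
    n, k = X.shape
    scores = X * e[:, None]
    h = np.zeros((T, k))
    for row, period in enumerate(periods):
        h[row] = scores[t_idx == period].sum(axis=0)
    S = h.T @ h
    for l in range(1, lag + 1):
        w = 1.0 - l / (lag + 1.0)
        omega = h[l:].T @ h[:-l]
        S = S + w * (omega + omega.T)
    bread = _bread(X)
    vcov = bread @ S @ bread
    if small_sample:
        vcov = vcov * (n / (n - k))
    return CovEstimate(vcov=vcov, method="driscoll_kraay", lag=lag)


def newey_west_vcov(X, residuals, lag: int | None = None) -> CovEstimate:
    """Single-series HAC estimator (each observation its own period)."""
    n = len(np.asarray(residuals))
    cov = driscoll_kraay_vcov(X, residuals, np.arange(n), lag=lag)
    return CovEstimate(vcov=cov.vcov, method="newey_west", lag=cov.lag)


def _ar1_corr(T: int, rho: float) -> np.ndarray:
    idx = np.arange(T)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def panel_fgls(y, X, group_index, time_index, *, ar1_within: bool = True,
               cross_corr: bool = True, panel_het: bool = True,
               iterations: int = 1) -> GLSResult:
    """Two-step feasible GLS on a balanced two-way panel.

    Step 1 estimates, from OLS residuals, a common within-panel AR(1)
    coefficient, per-panel variances and the cross-panel covariance; step 2
    runs GLS with the assembled Kronecker covariance (panel structure x AR(1)
    correlation).  ``iterations`` extra passes re-estimate from GLS residuals.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.unique(group_index)
    periods = np.unique(time_index)
    G, T = len(groups), len(periods)
    if G * T != len(y):
        raise StructuralError("panel is unbalanced")
    # reorder observations as (group-major, time ascending)
    order = np.lexsort((time_index, group_index))
    y_o, X_o = y[order], X[order]

    beta, *_ = np.linalg.lstsq(X_o, y_o, rcond=None)
    rho_hat = 0.0
    for _ in range(1 + max(iterations, 0)):
        E = (y_o - X_o @ beta).reshape(G, T)
        if ar1_within:
            num = float((E[:, 1:] * E[:, :-1]).sum())
            den = float((E * E).sum())
            rho_hat = np.clip(num / den if den > 0 else 0.0, -0.98, 0.98)
        else:
            rho_hat = 0.0
        R = _ar1_corr(T, rho_hat)
        # innovations after removing the common AR(1) correlation structure
        V = (E @ np.linalg.inv(R) @ E.T) / T
        if not panel_het:
            V = np.eye(G) * float(np.trace(V)) / G
        elif not cross_corr:
            V = np.diag(np.diag(V))
        sigma = np.kron(V, R)
        try:
            L = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return GLSResult(params=np.full(X.shape[1], np.nan),
                             cov=CovEstimate(np.full((X.shape[1],) * 2, np.nan), "fgls"),
                             converged=False, rho_hat=rho_hat)
        Xw = np.linalg.solve(L, X_o)
        yw = np.linalg.solve(L, y_o)
        xtx = Xw.T @ Xw
        if np.linalg.matrix_rank(xtx) < X.shape[1]:
            return GLSResult(params=np.full(X.shape[1], np.nan),
                             cov=CovEstimate(np.full((X.shape[1],) * 2, np.nan), "fgls"),
                             converged=False, rho_hat=rho_hat)
        vcov = np.linalg.inv(xtx)
        beta = vcov @ (Xw.T @ yw)
    return GLSResult(params=beta, cov=CovEstimate(vcov=vcov, method="fgls"),
                     converged=True, rho_hat=float(rho_hat))


def arma_ols(X, y, ar_order: int = 1) -> GLSResult:
    """Regression with AR(p) errors fitted by maximum likelihood."""
    from statsmodels.tsa.arima.model import ARIMA

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(y) <= X.shape[1] + ar_order:
        raise StructuralError("series too short for the requested AR order")
    k = X.shape[1]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ARIMA(y, exog=X, order=(ar_order, 0, 0), trend="n")
            res = model.fit(method_kwargs={"maxiter": 200})
            converged = bool(res.mle_retvals.get("converged", True))
            if not converged:
                # the optimizer frequently stops with "precision loss" at an
                # effective optimum; accept if restarting there goes nowhere
                res2 = model.fit(start_params=res.params,
                                 method_kwargs={"maxiter": 200})
                if (bool(res2.mle_retvals.get("converged", False))
                        or res2.llf <= res.llf + 1e-4):
                    res = res2 if res2.llf >= res.llf else res
                    converged = True
    except Exception:  # noqa: BLE001 - non-convergence is an expected outcome
        return GLSResult(params=np.full(k, np.nan),
                         cov=CovEstimate(np.full((k, k), np.nan), "arma", ar_order),
                         converged=False)
    params = np.asarray(res.params[:k], dtype=float)
    vcov = np.asarray(res.cov_params())[:k, :k]
    rho_hat = float(res.arparams[0]) if ar_order >= 1 else np.nan
    return GLSResult(params=params,
                     cov=CovEstimate(vcov=vcov, method="arma", lag=ar_order),
                     converged=converged, rho_hat=rho_hat,
                     extra={"sigma2": float(res.params[-1])})
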