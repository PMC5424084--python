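"""Direct-ML linear mixed model with crossed random intercepts and weights.

Trait models need random intercepts for *individual* and *measurement date*
simultaneously (crossed, not nested), optionally with known observation
weights (precision weights 1/SE for curve-derived parameters).  The
marginal covariance is

    V = sigma^2 * ( diag(1/w) + sum_k lambda_k Z_k Z_k' )

with lambda_k = tau_k^2 / sigma^2.  Fixed effects and sigma^2 are profiled
out analytically; the remaining log-lambda_k are optimized by Nelder-Mead.
Sample sizes here are small (tens to a few hundred observations), so the
dense-V Cholesky route is both simple and fast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize


@dataclass
class CrossedLmmFit:
    beta: np.ndarray
    beta_names: list
    cov_beta: np.ndarray
    sigma2: float
    tau2: dict                  # variance component per random factor
    loglik: float               # exact ML log-likelihood
    n_obs: int
    n_params: int               # fixed effects + variance components + sigma
    converged: bool
    boundary: list = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_beta), 0.0, None))


def _indicator(codes) -> np.ndarray:
    codes = np.asarray(codes)
    levels, inv = np.unique(codes, return_inverse=True)
    Z = np.zeros((len(codes), len(levels)))
    Z[np.arange(len(codes)), inv] = 1.0
    return Z


def loglik_at(y: np.ndarray, X: np.ndarray, V: np.ndarray,
              beta: np.ndarray, scale: float = 1.0) -> float:
    """Gaussian log-likelihood of y ~ N(X beta, scale * V) -- evaluation
    helper independent of the profiling shortcut (used by oracle tests)."""
    n = len(y)
    Vs = scale * V
    sign, logdet = np.linalg.slogdet(Vs)
    if sign <= 0:
        return -np.inf
    r = y - X @ beta
    quad = float(r @ np.linalg.solve(Vs, r))
    return -0.5 * (n * math.log(2 * math.pi) + logdet + quad)


def fit_crossed_lmm(y, X, groups: dict, weights=None,
                    beta_names: Optional[Sequence[str]] = None,
                    theta0=None) -> CrossedLmmFit:
    """ML fit of y = X beta + sum_k Z_k u_k + e with optional weights.

    ``groups`` maps factor name -> per-observation level codes;
    ``weights`` are precision weights (residual variance sigma^2 / w_i);
    ``theta0`` optionally warm-starts the log variance-ratio search.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if weights is None:
        winv = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w <= 0):
            raise ValueError("weights must be > 0")
        winv = 1.0 / w
    names = list(groups.keys())
    Zs = [_indicator(groups[k]) for k in names]
    ZZt = [Z @ Z.T for Z in Zs]
    K = len(Zs)

    def build_V0(lams):
        V0 = np.diag(winv).astype(float)
        for lam, M in zip(lams, ZZt):
            V0 += lam * M
        return V0

    def neg2ll(theta):
        lams = np.exp(np.clip(theta, -30.0, 30.0))
        V0 = build_V0(lams)
        try:
            cf = cho_factor(V0, lower=True)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        logdet = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        Vi_X = cho_solve(cf, X)
        Vi_y = cho_solve(cf, y)
        XtVX = X.T @ Vi_X
        try:
            XtVX_inv = np.linalg.inv(XtVX)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        beta = XtVX_inv @ (X.T @ Vi_y)
        r = y - X @ beta
        q = float(r @ cho_solve(cf, r))
        if q <= 0:
            return np.inf, None, None, None
        sigma2 = q / n
        val = n * math.log(2 * math.pi * sigma2) + logdet + n
        return val, beta, XtVX_inv, sigma2

    starts = [np.full(K, math.log(0.3)), np.full(K, -12.0)]
    if theta0 is not None:
        starts.insert(0, np.asarray(theta0, dtype=float))
    best, best_x = None, None
    for x0 in starts:
        res = minimize(lambda t: neg2ll(t)[0], x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 800})
        if best is None or res.fun < best.fun:
            best, best_x = res, res.x

    val, beta, XtVX_inv, sigma2 = neg2ll(best_x)
    lams = np.exp(np.clip(best_x, -30.0, 30.0))
    boundary = [names[k] for k in range(K) if lams[k] < 1e-8]
    if boundary:
        warnings.warn(f"variance component(s) at boundary: {boundary}",
                      stacklevel=2)
    return CrossedLmmFit(
        beta=beta, beta_names=list(beta_names or [f"b{i}" for i in range(p)]),
        cov_beta=sigma2 * XtVX_inv, sigma2=sigma2,
        tau2={names[k]: float(lams[k] * sigma2) for k in range(K)},
        loglik=-0.5 * val, n_obs=n, n_params=p + K + 1,
        converged=bool(best.success), boundary=boundary)


def marginal_covariance(fit: CrossedLmmFit, groups: dict, weights=None) -> np.ndarray:
    """Reconstruct V (including sigma^2) for a fitted model -- oracle helper."""
    names = list(groups.keys())
    n = fit.n_obs
    winv = np.ones(n) if weights is None else 1.0 / np.asarray(weights, float)
    V = fit.sigma2 * np.diag(winv)
    for k in names:
        Z = _indicator(groups[k])
        V += fit.tau2[k] * (Z @ Z.T)
    return V
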