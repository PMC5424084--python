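"""Non-rectangular hyperbola (NRH) light-response model and per-curve fitting.

Net assimilation as a function of incident light P (PPFD) is

    A_net(P) = [phi*P + Amax - sqrt((phi*P + Amax)^2 - 4*theta*phi*P*Amax)]
               / (2*theta)  -  Rd

with Amax the gross maximum photosynthetic rate (asymptote), phi the apparent
quantum yield (initial slope), Rd daytime dark respiration (|A_net| at zero
light), and theta in [0, 1) the convexity interpolating between the
rectangular hyperbola (theta -> 0) and the Blackman limit (theta -> 1).

Derived quantities:

* light compensation point (LCP): the PPFD where A_net = 0,
  LCP = Rd*(Amax - theta*Rd) / (phi*(Amax - Rd));
* light saturation point (LSP): the PPFD where gross assimilation reaches a
  fraction f (default 0.9) of the asymptote,
  LSP = f*Amax*(Amax - theta*f*Amax) / (phi*(1 - f)*Amax),
  which at f = 0.9 reduces to 9*Amax*(1 - 0.9*theta)/phi.

Both closed forms come from inverting the NRH for a target gross rate A:
P(A) = A*(Amax - theta*A) / (phi*(Amax - A)); the LCP is P(Rd), the LSP is
P(f*Amax).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .records import CurveDataset

_THETA_LIMIT = 1e-6  # below this, use the rectangular-hyperbola limit


def nrh_anet(ppfd, a_max: float, phi: float, r_d: float, theta: float):
    """Evaluate the NRH net-assimilation model (vectorized over ppfd)."""
    p = np.asarray(ppfd, dtype=float)
    if np.any(p < 0):
        raise ValueError("ppfd must be >= 0")
    s = phi * p + a_max
    if theta < _THETA_LIMIT:
        with np.errstate(divide="ignore", invalid="ignore"):
            gross = np.where(s > 0, phi * p * a_max / s, 0.0)
        out = gross - r_d
    else:
        disc = s * s - 4.0 * theta * phi * p * a_max
        if np.any(disc < -1e-9):
            raise FloatingPointError("negative discriminant in NRH")
        disc = np.clip(disc, 0.0, None)
        out = (s - np.sqrt(disc)) / (2.0 * theta) - r_d
    return out if out.ndim else float(out)


def _gross_inverse(a: float, a_max: float, phi: float, theta: float) -> float:
    """PPFD at which gross assimilation equals ``a`` (NRH inverse)."""
    if not 0.0 <= a < a_max:
        raise ValueError("target gross rate must lie in [0, a_max)")
    return a * (a_max - theta * a) / (phi * (a_max - a))


@dataclass
class LightResponseFit:
    a_max: float
    phi: float
    r_d: float
    theta: float
    se: dict = field(default_factory=dict)  # keys: a_max, phi, r_d, theta
    lcp: Optional[float] = None
    lsp: Optional[float] = None
    rss: float = math.nan
    n_points: int = 0
    converged: bool = False
    flags: list = field(default_factory=list)
    curve_id: str = ""

    def predict(self, ppfd):
        return nrh_anet(ppfd, self.a_max, self.phi, self.r_d, self.theta)


def light_compensation_point(fit: LightResponseFit | None = None, *,
                             a_max=None, phi=None, r_d=None, theta=None) -> float:
    """PPFD where net assimilation crosses zero (x-axis intercept)."""
    if fit is not None:
        a_max, phi, r_d, theta = fit.a_max, fit.phi, fit.r_d, fit.theta
    if r_d == 0:
        return 0.0
    if not r_d < a_max:
        raise ValueError("LCP undefined unless r_d < a_max")
    return _gross_inverse(r_d, a_max, phi, theta)


def light_saturation_point(fit: LightResponseFit | None = None, fraction: float = 0.9,
                           *, a_max=None, phi=None, theta=None) -> float:
    """Smallest PPFD where gross assimilation reaches ``fraction`` of Amax."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    if fit is not None:
        a_max, phi, theta = fit.a_max, fit.phi, fit.theta
    return _gross_inverse(fraction * a_max, a_max, phi, theta)


def _initial_guesses(p: np.ndarray, a: np.ndarray) -> list[np.ndarray]:
    order = np.argsort(p)
    p_s, a_s = p[order], a[order]
    r_d0 = max(abs(a_s[0]), 1e-3) if a_s[0] < 0 else max(a_s[0], 1e-3) * 0.1 + 1e-3
    # initial slope from the 3 lowest-light points (gross scale)
    lo = slice(0, min(3, len(p_s)))
    dp = np.ptp(p_s[lo])
    phi0 = (np.ptp(a_s[lo]) / dp) if dp > 0 else 0.05
    phi0 = min(max(phi0, 1e-3), 0.124)
    hi = a_s[-max(2, len(a_s) // 4):]
    a_max0 = max(float(np.mean(hi)) + r_d0, r_d0 + 0.5, 1e-2)
    return [np.array([a_max0, phi0, r_d0, th]) for th in (0.3, 0.6, 0.9)]


_BOUNDS = (np.array([1e-8, 1e-8, 0.0, 0.0]),
           np.array([np.inf, 0.5, np.inf, 0.999]))


def fit_light_response(curve: CurveDataset, options: dict | None = None) -> LightResponseFit:
    """Least-squares NRH fit of one light-response curve, with multi-start.

    SEs come from the final-iteration Jacobian (sigma^2 * (J'J)^-1).
    Degenerate inputs (flat response, singular covariance) are reported via
    ``converged``/``flags``, never by silent defaults.
    """
    options = options or {}
    df = curve.frame()
    p = df["ppfd"].to_numpy(dtype=float)
    a = df["a_net"].to_numpy(dtype=float)
    if len(np.unique(np.round(p, 6))) < 5:
        raise ValueError(
            f"curve {curve.curve_id}: fewer than 5 distinct PPFD levels; "
            "cannot identify a 4-parameter light-response model")

    fit = LightResponseFit(a_max=math.nan, phi=math.nan, r_d=math.nan,
                           theta=math.nan, n_points=len(p), curve_id=curve.curve_id)
    if float(np.ptp(a)) < 1e-10:
        fit.flags.append("degenerate_flat_response")
        return fit

    def resid(q):
        return nrh_anet(p, *q) - a

    best = None
    for x0 in _initial_guesses(p, a):
        x0 = np.clip(x0, _BOUNDS[0] + 1e-9, _BOUNDS[1] - 1e-9)
        try:
            sol = least_squares(resid, x0, bounds=_BOUNDS,
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        fit.flags.append("optimizer_failure")
        return fit

    a_max, phi, r_d, theta = best.x
    rss = float(2 * best.cost)
    fit.a_max, fit.phi, fit.r_d, fit.theta, fit.rss = a_max, phi, r_d, theta, rss
    fit.converged = True
    if theta >= 0.999 - 1e-9 or theta <= 1e-12:
        fit.flags.append("theta_at_boundary")

    dof = len(p) - 4
    if dof > 0:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (rss / dof)
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            fit.se = dict(zip(("a_max", "phi", "r_d", "theta"), map(float, ses)))
        except np.linalg.LinAlgError:
            fit.flags.append("singular_covariance")
    else:
        fit.flags.append("no_residual_dof")

    try:
        if r_d < a_max:
            fit.lcp = light_compensation_point(fit)
        frac = options.get("lsp_fraction", 0.9)
        fit.lsp = light_saturation_point(fit, fraction=frac)
    except ValueError:
        fit.flags.append("derived_points_unavailable")
    return fit


def fits_to_frame(fits) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for f in fits:
        rows.append({
            "curve_id": f.curve_id, "a_max": f.a_max, "phi": f.phi,
            "r_d": f.r_d, "theta": f.theta,
            "se_a_max": f.se.get("a_max"), "se_phi": f.se.get("phi"),
            "se_r_d": f.se.get("r_d"), "se_theta": f.se.get("theta"),
            "lcp": f.lcp, "lsp": f.lsp, "rss": f.rss,
            "n_points": f.n_points, "converged": f.converged,
            "flags": ";".join(f.flags),
        })
    return pd.DataFrame(rows)
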