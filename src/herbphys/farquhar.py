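"""Biochemical (Farquhar-type) model of C3 photosynthesis and A/Ci fitting.

Net assimilation is the minimum of two limiting rates minus daytime
mitochondrial respiration:

    A_net = min(Av, Aj) - Rday
    Av = Vcmax * (Ci - Gamma*) / (Ci + Kc*(1 + O/Ko))     (RuBisCO-limited)
    Aj = Jmax  * (Ci - Gamma*) / (4*Ci + 8*Gamma*)        (RuBP-limited)

Ci and Kc are partial pressures in Pa; O and Ko are in kPa, so O/Ko is
dimensionless.  Default kinetic constants (25 C): Kc = 40.4 Pa,
Ko = 24.8 kPa, O = 21 kPa, Gamma* = 3.7 Pa.

The fitter estimates Vcmax, Jmax and Rday jointly by non-linear least
squares over all curve points simultaneously (no pre-assignment of points
to limitation regimes); the strict pointwise minimum is used, with no
smoothing of the transition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .records import CurveDataset


@dataclass(frozen=True)
class KineticConstants:
    """RuBisCO kinetic constants at 25 C (Pa / kPa mixed-unit convention)."""

    kc: float = 40.4        # Pa
    ko: float = 24.8        # kPa
    o: float = 21.0         # kPa
    gamma_star: float = 3.7  # Pa

    def __post_init__(self):
        for name in ("kc", "ko", "o", "gamma_star"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def km_eff(self) -> float:
        """Effective Michaelis constant Kc*(1 + O/Ko), Pa."""
        return self.kc * (1.0 + self.o / self.ko)


DEFAULT_CONSTANTS = KineticConstants()


def rubisco_limited_rate(ci, v_cmax: float, constants: KineticConstants = DEFAULT_CONSTANTS):
    """Av: RuBP-saturated (CO2-limited) assimilation, umol m-2 s-1."""
    ci = np.asarray(ci, dtype=float)
    out = v_cmax * (ci - constants.gamma_star) / (ci + constants.km_eff)
    return out if out.ndim else float(out)


def rubp_limited_rate(ci, j_max: float, constants: KineticConstants = DEFAULT_CONSTANTS):
    """Aj: RuBP-regeneration-limited assimilation, umol m-2 s-1."""
    ci = np.asarray(ci, dtype=float)
    out = j_max * (ci - constants.gamma_star) / (4.0 * ci + 8.0 * constants.gamma_star)
    return out if out.ndim else float(out)


def fvcb_net(ci, v_cmax: float, j_max: float, r_day: float,
             constants: KineticConstants = DEFAULT_CONSTANTS,
             return_limitation: bool = False):
    """Net assimilation min(Av, Aj) - Rday; optionally the limiting regime."""
    av = np.asarray(rubisco_limited_rate(ci, v_cmax, constants))
    aj = np.asarray(rubp_limited_rate(ci, j_max, constants))
    a_net = np.minimum(av, aj) - r_day
    if return_limitation:
        limitation = np.where(av <= aj, "rubisco", "rubp")
        if a_net.ndim == 0:
            return float(a_net), str(limitation)
        return a_net, limitation
    return a_net if a_net.ndim else float(a_net)


CI_SEARCH_MAX = 200.0  # Pa; upper bound of the physiological search range


def transition_ci(v_cmax: float, j_max: float,
                  constants: KineticConstants = DEFAULT_CONSTANTS) -> Optional[float]:
    """Ci (Pa) where Av = Aj, if a crossover exists in (Gamma*, 200 Pa).

    Solving Vcmax*(4Ci + 8*Gamma*) = Jmax*(Ci + Km_eff) gives

        Ci* = (Jmax*Km_eff - 8*Gamma**Vcmax) / (4*Vcmax - Jmax).

    Returns None when the rates never cross in the physiological range
    (one regime limits everywhere below 200 Pa).
    """
    if v_cmax <= 0 or j_max <= 0:
        raise ValueError("v_cmax and j_max must be > 0")
    denom = 4.0 * v_cmax - j_max
    if abs(denom) < 1e-12 * max(v_cmax, j_max):
        return None  # degenerate: limbs parallel in the rearranged form
    ci_star = (j_max * constants.km_eff - 8.0 * constants.gamma_star * v_cmax) / denom
    if not (constants.gamma_star < ci_star < CI_SEARCH_MAX):
        return None
    return float(ci_star)


def everywhere_limiting_regime(v_cmax: float, j_max: float,
                               constants: KineticConstants = DEFAULT_CONSTANTS) -> Optional[str]:
    """When no crossover exists, which limb limits throughout (Gamma*, 200 Pa)."""
    if transition_ci(v_cmax, j_max, constants) is not None:
        return None
    probe = 0.5 * (constants.gamma_star + CI_SEARCH_MAX)
    av = rubisco_limited_rate(probe, v_cmax, constants)
    aj = rubp_limited_rate(probe, j_max, constants)
    return "rubisco" if av <= aj else "rubp"


@dataclass
class FvCBFit:
    v_cmax: float
    j_max: float
    r_day: float
    se: dict = field(default_factory=dict)
    ci_transition: Optional[float] = None
    limitation: list = field(default_factory=list)
    rss: float = math.nan
    n_points: int = 0
    converged: bool = False
    flags: list = field(default_factory=list)
    constants: KineticConstants = DEFAULT_CONSTANTS
    curve_id: str = ""

    def predict(self, ci):
        return fvcb_net(ci, self.v_cmax, self.j_max, self.r_day, self.constants)


def _aci_initial_guesses(ci: np.ndarray, a: np.ndarray,
                         constants: KineticConstants) -> list[np.ndarray]:
    r0 = max(0.3, -float(np.min(a)))
    gross = a + r0
    # low-Ci points: Av ~= Vcmax * x with x = (Ci - G*)/(Ci + Km)
    x = (ci - constants.gamma_star) / (ci + constants.km_eff)
    lo = ci <= np.median(ci)
    v0 = float(np.sum(x[lo] * gross[lo]) / max(np.sum(x[lo] ** 2), 1e-9))
    v0 = max(v0, 1.0)
    # high-Ci plateau: Aj -> Jmax/4
    j0 = max(4.0 * float(np.max(gross)), 1.0)
    guesses = []
    for fv in (0.5, 1.0, 2.0):
        for fj in (0.6, 1.0):
            guesses.append(np.array([v0 * fv, j0 * fj, r0]))
    # coarse profiled-Rday grid around the data-driven scales: the min()
    # objective is piecewise and can trap gradient descent in the wrong
    # limitation assignment, so seed the best grid basins too
    scored = []
    for fv in np.geomspace(0.3, 3.0, 10):
        for fj in np.geomspace(0.3, 3.0, 10):
            pred0 = np.minimum(rubisco_limited_rate(ci, v0 * fv, constants),
                               rubp_limited_rate(ci, j0 * fj, constants))
            r_prof = max(0.0, float(np.mean(pred0 - a)))
            rss = float(np.sum((pred0 - r_prof - a) ** 2))
            scored.append((rss, np.array([v0 * fv, j0 * fj, r_prof])))
    scored.sort(key=lambda t: t[0])
    guesses.extend(g for _, g in scored[:3])
    return guesses


_ACI_BOUNDS = (np.array([1e-6, 1e-6, 0.0]), np.array([np.inf, np.inf, np.inf]))


def fit_aci(curve: CurveDataset, constants: KineticConstants = DEFAULT_CONSTANTS,
            options: dict | None = None) -> FvCBFit:
    """Simultaneous NLS estimation of (Vcmax, Jmax, Rday) from an A/Ci curve.

    All points enter one least-squares objective on min(Av, Aj) - Rday;
    limitation labels are assigned from the fitted model afterwards.
    ``options['fix_r_day']`` pins Rday to a supplied value (off by default).
    """
    options = options or {}
    df = curve.frame()
    mask = df["ci"].notna()
    ci = df.loc[mask, "ci"].to_numpy(dtype=float)
    a = df.loc[mask, "a_net"].to_numpy(dtype=float)
    if len(ci) < 3:
        raise ValueError(f"curve {curve.curve_id}: too few points with Ci")
    if curve.n_distinct_ci < 8:
        warnings.warn(f"curve {curve.curve_id}: fewer than 8 distinct Ci values",
                      stacklevel=2)

    fit = FvCBFit(v_cmax=math.nan, j_max=math.nan, r_day=math.nan,
                  n_points=len(ci), constants=constants, curve_id=curve.curve_id)

    fixed_r = options.get("fix_r_day")

    def resid(q):
        if fixed_r is None:
            v, j, r = q
        else:
            v, j = q
            r = fixed_r
        return fvcb_net(ci, v, j, r, constants) - a

    best = None
    for x0 in _aci_initial_guesses(ci, a, constants):
        if fixed_r is not None:
            x0 = x0[:2]
        bounds = (_ACI_BOUNDS[0][: len(x0)], _ACI_BOUNDS[1][: len(x0)])
        try:
            sol = least_squares(resid, x0, bounds=bounds,
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=3000)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not best.success:
        fit.flags.append("optimizer_failure")
        return fit

    if fixed_r is None:
        v, j, r = best.x
    else:
        (v, j), r = best.x, fixed_r
    fit.v_cmax, fit.j_max, fit.r_day = float(v), float(j), float(r)
    fit.rss = float(2 * best.cost)
    fit.converged = True
    fit.ci_transition = transition_ci(v, j, constants)

    _, lim = fvcb_net(ci, v, j, r, constants, return_limitation=True)
    fit.limitation = list(np.atleast_1d(lim))
    n_rub = sum(1 for s in fit.limitation if s == "rubisco")
    if n_rub == 0:
        fit.flags.append("v_cmax_unidentified")
    if n_rub == len(fit.limitation):
        fit.flags.append("j_max_unidentified")

    dof = len(ci) - len(best.x)
    if dof > 0 and not fit.flags:
        jtj = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(jtj) * (fit.rss / dof)
            names = ("v_cmax", "j_max", "r_day")[: len(best.x)]
            ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
            fit.se = dict(zip(names, map(float, ses)))
        except np.linalg.LinAlgError:
            fit.flags.append("singular_covariance")
    elif fit.flags:
        # one limb unidentified -> its SE is unavailable, never a silent number
        pass
    return fit


def fits_to_frame(fits) -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for f in fits:
        rows.append({
            "curve_id": f.curve_id, "v_cmax": f.v_cmax, "j_max": f.j_max,
            "r_day": f.r_day,
            "se_v_cmax": f.se.get("v_cmax"), "se_j_max": f.se.get("j_max"),
            "se_r_day": f.se.get("r_day"),
            "ci_transition": f.ci_transition, "rss": f.rss,
            "n_points": f.n_points, "converged": f.converged,
            "flags": ";".join(f.flags),
        })
    return pd.DataFrame(rows)
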