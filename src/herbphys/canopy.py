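"""Canopy-closure detection and mixed-model inference on understory light.

Two analyses share this module:

1. **Closure day.** Daily mean PPFD (10:00-14:00) from a fixed understory
   sensor is smoothed with a penalized regression spline (P-spline: cubic
   B-spline basis, second-order difference penalty, smoothing parameter by
   GCV).  The first derivative of the smooth and its pointwise 95 % CI are
   computed from the coefficient covariance; the closure day is the first
   day -- scanning forward from the onset of a significantly negative slope
   -- at which the derivative CI contains zero.

2. **Treatment divergence.** Plant-level mean PPFD is modelled on the log
   scale with fixed effects {day, day^2, fencing, day x fencing}, a random
   intercept per measurement day, and residual variance allowed to change
   with day and to differ between treatments (power-of-covariate variance
   function, sd proportional to |day|^delta_g).  Fitting is maximum
   likelihood with fixed effects profiled out by GLS at each variance-
   parameter evaluation; nested models are compared by likelihood ratio
   tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import time
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.optimize import minimize

from .records import records_to_frame

# ---------------------------------------------------------------------------
# Daily sensor means
# ---------------------------------------------------------------------------


def daily_means(records, window: tuple[time, time] = (time(10, 0), time(14, 0))
                ) -> pd.DataFrame:
    """Per-day arithmetic mean PPFD over the time window [start, end).

    Days with no in-window records are omitted (their count is available
    from the difference in unique days).
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = records_to_frame(list(records))
    ts = pd.to_datetime(df["timestamp"])
    tod = ts.dt.time
    start, end = window
    inside = (tod >= start) & (tod < end)
    sub = df.loc[inside].copy()
    if sub.empty:
        return pd.DataFrame(columns=["day_of_year", "mean_ppfd", "n_obs"])
    sub["day_of_year"] = pd.to_datetime(sub["timestamp"]).dt.dayofyear
    out = (sub.groupby("day_of_year")["ppfd"]
           .agg(mean_ppfd="mean", n_obs="size").reset_index())
    return out


# ---------------------------------------------------------------------------
# Penalized-spline smooth of the seasonal series
# ---------------------------------------------------------------------------

@dataclass
class SmoothFitResult:
    days: np.ndarray
    fitted: np.ndarray
    se_fit: np.ndarray
    derivative: np.ndarray
    deriv_se: np.ndarray
    deriv_lo: np.ndarray          # 95 % pointwise CI
    deriv_hi: np.ndarray
    lam: float
    edf: float
    sigma2: float
    coefficients: np.ndarray
    knots: np.ndarray
    degree: int

    def spline(self) -> BSpline:
        return BSpline(self.knots, self.coefficients, self.degree)


def _pspline_basis(x: np.ndarray, n_segments: int, degree: int):
    lo, hi = float(np.min(x)), float(np.max(x))
    h = (hi - lo) / n_segments
    knots = lo + h * np.arange(-degree, n_segments + degree + 1)
    n_basis = len(knots) - degree - 1
    bspl = BSpline(knots, np.eye(n_basis), degree, extrapolate=True)
    return knots, n_basis, bspl


def fit_canopy_smooth(series: pd.DataFrame, options: dict | None = None
                      ) -> SmoothFitResult:
    """P-spline fit of mean daily PPFD on day of year.

    options: n_segments (default: one knot per ~4 days), criterion
    ('aicc' default, 'gcv' optional -- GCV tends to undersmooth the
    strongly heteroscedastic daily-light noise, which destabilizes the
    derivative-based closure detector), lambda_grid (log-spaced).
    """
    options = options or {}
    n_segments = options.get("n_segments")
    degree = options.get("degree", 3)
    criterion = options.get("criterion", "aicc")
    lam_grid = options.get("lambda_grid",
                           np.logspace(-4, 8, 49))

    x = series["day_of_year"].to_numpy(dtype=float)
    y = series["mean_ppfd"].to_numpy(dtype=float)
    order = np.argsort(x)
    x, y = x[order], y[order]
    n = len(x)
    if n < 15:
        raise ValueError("need at least 15 days to fit the seasonal smooth")
    if n_segments is None:
        # generous basis (about one knot per 4 days), penalty does the work
        n_segments = int(np.clip((x[-1] - x[0]) / 4.0, 8, n // 3))

    knots, n_basis, bspl = _pspline_basis(x, n_segments, degree)
    B = bspl(x)
    D = np.diff(np.eye(n_basis), n=2, axis=0)
    P = D.T @ D
    BtB, Bty = B.T @ B, B.T @ y

    best = None
    for lam in lam_grid:
        A = BtB + lam * P
        try:
            A_inv = np.linalg.inv(A)
        except np.linalg.LinAlgError:
            continue
        c = A_inv @ Bty
        resid = y - B @ c
        rss = float(resid @ resid)
        edf = float(np.trace(A_inv @ BtB))
        if criterion == "aicc":
            score = (n * math.log(max(rss, 1e-300) / n)
                     + 2 * (edf + 1) * n / max(n - edf - 2, 1e-6))
        else:  # gcv
            score = n * rss / max(n - edf, 1e-6) ** 2
        if best is None or score < best[0]:
            best = (score, lam, c, A_inv, rss, edf)

    _, lam, c, A_inv, rss, edf = best
    sigma2 = rss / max(n - edf, 1.0)
    cov_c = sigma2 * A_inv  # Bayesian posterior covariance of coefficients

    grid = np.arange(x[0], x[-1] + 0.5)
    Bg = bspl(grid)
    B1g = BSpline(knots, np.eye(n_basis), degree,
                  extrapolate=True).derivative()(grid)
    fitted = Bg @ c
    se_fit = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", Bg, cov_c, Bg), 0, None))
    deriv = B1g @ c
    deriv_se = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", B1g, cov_c, B1g), 0, None))
    z = stats.norm.ppf(0.975)
    return SmoothFitResult(
        days=grid, fitted=fitted, se_fit=se_fit, derivative=deriv,
        deriv_se=deriv_se, deriv_lo=deriv - z * deriv_se,
        deriv_hi=deriv + z * deriv_se, lam=float(lam), edf=edf,
        sigma2=float(sigma2), coefficients=c, knots=knots, degree=degree)


def closure_day(smooth: SmoothFitResult, persistence: int = 4) -> Optional[int]:
    """First day, after the decline begins, whose slope CI contains zero.

    Flatness must persist: the CI has to contain zero for ``persistence``
    consecutive days (or through the end of the series), so that momentary
    zero-touches inside a noisy decline are not mistaken for the plateau.

    The scan starts at the longest sustained run of significantly negative
    slope (CI entirely below zero): the canopy decline spans weeks while
    noise wiggles produce only isolated significant days, so the longest
    run identifies the decline unambiguously.  Returns None -- with a
    warning naming the reason -- when the series never declines
    significantly, or when the slope never flattens within the observed
    range.
    """
    neg = smooth.deriv_hi < 0.0
    if not np.any(neg):
        warnings.warn("no significantly negative slope: decline precondition unmet",
                      stacklevel=2)
        return None
    # start of the longest run of True in `neg`
    padded = np.concatenate([[False], neg, [False]]).astype(int)
    edges = np.diff(padded)
    run_starts = np.flatnonzero(edges == 1)
    run_ends = np.flatnonzero(edges == -1)
    start = int(run_starts[np.argmax(run_ends - run_starts)])
    contains0 = (smooth.deriv_lo[start:] <= 0.0) & (smooth.deriv_hi[start:] >= 0.0)
    m = len(contains0)
    for i in range(m):
        window = contains0[i:min(i + persistence, m)]
        if window.all() and len(window) > 0 and contains0[i]:
            return int(round(smooth.days[start + i]))
    warnings.warn("slope never flattens within the observed day range",
                  stacklevel=2)
    return None


# ---------------------------------------------------------------------------
# Heteroscedastic linear mixed model for plant-level PPFD
# ---------------------------------------------------------------------------

ALL_TERMS = ("1", "day", "day2", "fencing", "day:fencing")


@dataclass
class LmmResult:
    terms: tuple
    beta: np.ndarray
    beta_names: list
    cov_beta: np.ndarray
    tau2: float                 # day random-intercept variance
    sigma2: float               # residual scale
    delta: dict                 # variance-power exponent by treatment
    loglik: float
    n_params: int
    n_obs: int
    converged: bool
    heteroscedastic: bool
    log_scale: bool
    boundary: bool = False
    data: pd.DataFrame = field(default=None, repr=False)
    day_center: float = 0.0
    day_scale: float = 1.0
    var_ref: float = 1.0
    theta_opt: np.ndarray = None  # optimal variance params (warm-start aid)


def _design(df: pd.DataFrame, terms: Sequence[str],
            day_center: float, day_scale: float):
    s = (df["day_of_year"].to_numpy(float) - day_center) / day_scale
    fenced = (df["treatment"].to_numpy() == "fenced").astype(float)
    cols, names = [], []
    for t in terms:
        if t == "1":
            cols.append(np.ones(len(df)))
        elif t == "day":
            cols.append(s)
        elif t == "day2":
            cols.append(s ** 2)
        elif t == "fencing":
            cols.append(fenced)
        elif t == "day:fencing":
            cols.append(s * fenced)
        else:
            raise ValueError(f"unknown term {t!r}")
        names.append(t)
    return np.column_stack(cols), names


def _profiled_ml(theta, X, y, blocks, vcov, fenced, hetero):
    """-2 x profiled log-likelihood at variance parameters theta.

    theta = [log lambda] (+ [delta_fenced, delta_unfenced] when hetero);
    lambda = tau^2/sigma^2.  Fixed effects and sigma^2 are profiled out.
    Returns (neg2ll, beta, XtVX_inv, sigma2, logdetV).
    """
    lam = math.exp(min(theta[0], 30.0))
    if hetero:
        d_f, d_u = theta[1], theta[2]
        delta = np.where(fenced, d_f, d_u)
        logw = 2.0 * delta * np.log(vcov)
        logw -= np.mean(logw)  # normalize so sigma^2 keeps its scale
        w = np.exp(logw)
    else:
        w = np.ones(len(y))

    p = X.shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    for idx in blocks:
        wi = w[idx]
        Xi, yi = X[idx], y[idx]
        inv_w = 1.0 / wi
        s = float(np.sum(inv_w))
        factor = lam / (1.0 + lam * s)
        # V_i^-1 = diag(1/w) - factor * (1/w)(1/w)'
        Xw = Xi * inv_w[:, None]
        yw = yi * inv_w
        xs = Xw.sum(axis=0)
        ys = float(yw.sum())
        XtVX += Xi.T @ Xw - factor * np.outer(xs, xs)
        XtVy += Xi.T @ yw - factor * xs * ys
        yty += float(yi @ yw) - factor * ys * ys
        logdet += float(np.sum(np.log(wi))) + math.log1p(lam * s)

    try:
        XtVX_inv = np.linalg.inv(XtVX)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None, None
    beta = XtVX_inv @ XtVy
    q = yty - float(beta @ XtVy)
    n = len(y)
    if q <= 0:
        return np.inf, None, None, None, None
    sigma2 = q / n
    neg2ll = n * math.log(2.0 * math.pi * sigma2) + logdet + n
    return neg2ll, beta, XtVX_inv, sigma2, logdet


def fit_ppfd_lmm(data: pd.DataFrame, terms: Sequence[str] = ALL_TERMS,
                 heteroscedastic: bool = True, log_transform: bool = True,
                 var_covariate: str = "day_of_year",
                 theta0=None) -> LmmResult:
    """ML fit of the day-random-effect model of (log) plant-mean PPFD.

    ``data`` needs columns plant_id, treatment, day_of_year, mean_ppfd.
    The parameter count (for LRT bookkeeping) is
    len(fixed effects) + 2 (tau, sigma) + 2 variance exponents if
    heteroscedastic.
    """
    df = data.reset_index(drop=True)
    if df["day_of_year"].nunique() < 2:
        raise ValueError("need at least 2 measurement days")
    if df["treatment"].nunique() < 2 and any(
            t in terms for t in ("fencing", "day:fencing")):
        raise ValueError("both treatments must be present for fencing terms")

    y = df["mean_ppfd"].to_numpy(float)
    if log_transform:
        y = np.log(y)
    day_center = float(df["day_of_year"].mean())
    day_scale = float(df["day_of_year"].std()) or 1.0
    X, names = _design(df, terms, day_center, day_scale)
    fenced = (df["treatment"].to_numpy() == "fenced")
    vraw = np.abs(df[var_covariate].to_numpy(float))
    var_ref = float(np.exp(np.mean(np.log(np.maximum(vraw, 1e-12)))))
    vcov = np.maximum(vraw, 1e-12) / var_ref

    day_codes = df["day_of_year"].to_numpy()
    blocks = [np.flatnonzero(day_codes == d) for d in np.unique(day_codes)]

    def objective(theta):
        return _profiled_ml(theta, X, y, blocks, vcov, fenced, heteroscedastic)[0]

    if heteroscedastic:
        starts = [np.array([math.log(0.1), 0.0, 0.0]),
                  np.array([math.log(1.0), 1.0, 1.0])]
    else:
        starts = [np.array([math.log(0.1)]), np.array([math.log(1.0)])]
    if theta0 is not None:
        starts.insert(0, np.asarray(theta0, dtype=float))
    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 800})
        if best is None or res.fun < best.fun:
            best = res

    neg2ll, beta, XtVX_inv, sigma2, _ = _profiled_ml(
        best.x, X, y, blocks, vcov, fenced, heteroscedastic)
    lam = math.exp(min(best.x[0], 30.0))
    delta = ({"fenced": float(best.x[1]), "unfenced": float(best.x[2])}
             if heteroscedastic else {"fenced": 0.0, "unfenced": 0.0})
    n_params = X.shape[1] + 2 + (2 if heteroscedastic else 0)
    return LmmResult(
        terms=tuple(terms), beta=beta, beta_names=names,
        cov_beta=sigma2 * XtVX_inv, tau2=lam * sigma2, sigma2=sigma2,
        delta=delta, loglik=-0.5 * neg2ll, n_params=n_params, n_obs=len(y),
        converged=bool(best.success), heteroscedastic=heteroscedastic,
        log_scale=log_transform, boundary=lam < 1e-10,
        data=df, day_center=day_center, day_scale=day_scale, var_ref=var_ref,
        theta_opt=np.asarray(best.x))


@dataclass
class LrTestResult:
    statistic: float
    df: int
    p_value: float
    df_pair: str  # "(k_reduced, k_full)" notation


def lr_test(full: LmmResult, reduced: LmmResult) -> LrTestResult:
    """Likelihood ratio test of nested ML fits: 2*(ll_full - ll_reduced)."""
    if not set(reduced.terms).issubset(set(full.terms)):
        raise ValueError("reduced model terms must be a subset of the full model")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < 0:
        warnings.warn(f"negative LR statistic ({stat:.3g}) clipped to 0",
                      stacklevel=2)
        stat = 0.0
    dof = full.n_params - reduced.n_params
    p = float(stats.chi2.sf(stat, dof)) if dof > 0 else 1.0
    return LrTestResult(statistic=float(stat), df=dof, p_value=p,
                        df_pair=f"({reduced.n_params},{full.n_params})")


MODEL_SEQUENCE = (
    ("Time", ("1",), ("1", "day")),
    ("Time^2", ("1", "day"), ("1", "day", "day2")),
    ("Fencing", ("1", "day", "day2"), ("1", "day", "day2", "fencing")),
    ("Time x fencing", ("1", "day", "day2", "fencing"), ALL_TERMS),
)


def significance_code(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    if p < 0.1:
        return "+"
    return ""


def lmm_term_table(data: pd.DataFrame, heteroscedastic: bool = True,
                   log_transform: bool = True) -> pd.DataFrame:
    """Sequential-term LRT table for the light-divergence model.

    Each term is tested by comparing the model with it against the model
    without it (all models ML, same random-effect and variance structure).
    """
    cache: dict[tuple, LmmResult] = {}
    last_theta = [None]

    def fit(terms):
        if terms not in cache:
            res = fit_ppfd_lmm(data, terms=terms,
                               heteroscedastic=heteroscedastic,
                               log_transform=log_transform,
                               theta0=last_theta[0])
            cache[terms] = res
            last_theta[0] = res.theta_opt
        return cache[terms]

    rows = []
    for label, red_terms, full_terms in MODEL_SEQUENCE:
        res = lr_test(fit(full_terms), fit(red_terms))
        rows.append({"term": label, "df": res.df_pair,
                     "likelihood_ratio": res.statistic, "p": res.p_value,
                     "signif": significance_code(res.p_value)})
    return pd.DataFrame(rows)


def treatment_means_original_scale(model: LmmResult, day: float) -> pd.DataFrame:
    """Predicted treatment means (+/- SE) of PPFD at ``day``, original scale.

    Re-fits the selected fixed-effect structure on untransformed mean PPFD
    with the same random-effect/variance structure, then predicts each
    treatment at the requested day.  Refuses to extrapolate outside the
    observed day range.
    """
    df = model.data
    lo, hi = df["day_of_year"].min(), df["day_of_year"].max()
    if not lo <= day <= hi:
        raise ValueError(f"day {day} outside observed range [{lo}, {hi}]")
    raw = (model if not model.log_scale else
           fit_ppfd_lmm(df, terms=model.terms,
                        heteroscedastic=model.heteroscedastic,
                        log_transform=False))
    rows = []
    for treatment in ("unfenced", "fenced"):
        probe = pd.DataFrame({"day_of_year": [day], "treatment": [treatment]})
        x, _ = _design(probe, raw.terms, raw.day_center, raw.day_scale)
        mean = float((x @ raw.beta).item())
        se = float(np.sqrt((x @ raw.cov_beta @ x.T).item()))
        rows.append({"treatment": treatment, "day_of_year": day,
                     "mean_ppfd": mean, "se": se})
    return pd.DataFrame(rows)
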