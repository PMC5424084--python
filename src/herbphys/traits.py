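"""Treatment inference on leaf traits and photosynthetic parameters.

Covers four analyses:

* a fencing x month ANOVA of light-saturated photosynthesis (Asat), with
  within-month treatment contrasts using the pooled residual variance;
* mixed-model likelihood-ratio tests (chi^2, 1 df) for each trait, with
  random intercepts for individual and measurement date and optional 1/SE
  precision weights for curve-derived parameters;
* precision-weighted group means (weights exactly 1/SE, not 1/SE^2);
* signed percent differences between treatment means, rounded half away
  from zero for reporting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .lmm import CrossedLmmFit, fit_crossed_lmm
from .canopy import significance_code


# ---------------------------------------------------------------------------
# Asat ANOVA and monthly contrasts
# ---------------------------------------------------------------------------

@dataclass
class AsatAnovaResult:
    model: object                 # statsmodels OLS results
    data: pd.DataFrame
    log_transformed: bool
    response: str
    anova_table: pd.DataFrame

    @property
    def df_resid(self) -> int:
        return int(self.model.df_resid)


def _needs_log(resid: np.ndarray, groups: np.ndarray,
               skew_threshold: float = 1.0, levene_p: float = 0.01) -> bool:
    """Documented transform diagnostic: residual skew or cell-variance
    heterogeneity (Levene) triggers a log transform."""
    if abs(float(stats.skew(resid))) > skew_threshold:
        return True
    cells = [resid[groups == g] for g in np.unique(groups)]
    cells = [c for c in cells if len(c) >= 3]
    if len(cells) >= 2:
        _, p = stats.levene(*cells)
        if p < levene_p:
            return True
    return False


def asat_anova(data: pd.DataFrame, log_transform: str = "auto") -> AsatAnovaResult:
    """OLS cell-means ANOVA of Asat with fencing, month and interaction.

    ``data`` needs columns a_net, treatment, month (one species at a time).
    ``log_transform``: 'auto' (diagnostic-triggered), 'always', 'never'.
    """
    df = data.copy()
    if df["month"].nunique() < 2:
        warnings.warn("single month: model reduces to a two-sample comparison",
                      stacklevel=2)
    formula = "y ~ C(treatment) * C(month)"
    df["y"] = df["a_net"].astype(float)
    fit = smf.ols(formula, data=df).fit()
    logged = False
    if log_transform == "always" or (
            log_transform == "auto"
            and np.all(df["y"] > 0)
            and _needs_log(fit.resid.to_numpy(),
                           (df["treatment"].astype(str) + ":"
                            + df["month"].astype(str)).to_numpy())):
        df["y"] = np.log(df["y"])
        fit = smf.ols(formula, data=df).fit()
        logged = True
    try:
        table = sm.stats.anova_lm(fit, typ=2)
    except Exception:
        table = pd.DataFrame()
    return AsatAnovaResult(model=fit, data=df, log_transformed=logged,
                           response="log(a_net)" if logged else "a_net",
                           anova_table=table)


@dataclass
class ContrastResult:
    species: str
    label: str                   # month or trait name
    estimate: float
    t_statistic: float
    df: int
    p_value: float
    signif: str = ""
    flags: list = field(default_factory=list)


def monthly_contrasts(result: AsatAnovaResult, months: Sequence | None = None,
                      species: str = "", adjust: str = "none") -> list[ContrastResult]:
    """Within-month unfenced-minus-fenced differences, pooled residual variance.

    ``adjust``: 'none' (default) or 'bonferroni'.  Months with one treatment
    absent are flagged and carry no test.
    """
    df = result.data
    s2 = float(result.model.mse_resid)
    dof = result.df_resid
    months = sorted(df["month"].unique()) if months is None else list(months)
    out = []
    for m in months:
        sub = df[df["month"] == m]
        groups = {t: sub.loc[sub["treatment"] == t, "y"] for t in ("unfenced", "fenced")}
        if any(len(g) == 0 for g in groups.values()):
            out.append(ContrastResult(species=species, label=str(m),
                                      estimate=math.nan, t_statistic=math.nan,
                                      df=dof, p_value=math.nan,
                                      flags=["treatment_missing"]))
            continue
        n1, n2 = len(groups["unfenced"]), len(groups["fenced"])
        diff = float(groups["unfenced"].mean() - groups["fenced"].mean())
        se = math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
        t = diff / se if se > 0 else 0.0
        p = 2.0 * float(stats.t.sf(abs(t), dof))
        out.append(ContrastResult(species=species, label=str(m), estimate=diff,
                                  t_statistic=t, df=dof, p_value=p))
    if adjust == "bonferroni":
        k = sum(1 for c in out if not c.flags)
        for c in out:
            if not c.flags:
                c.p_value = min(1.0, c.p_value * k)
    for c in out:
        if not c.flags:
            c.signif = significance_code(c.p_value)
    return out


# ---------------------------------------------------------------------------
# Trait mixed-model LRT
# ---------------------------------------------------------------------------

@dataclass
class TraitComparison:
    trait: str
    species: str
    unfenced_mean: float
    unfenced_se: float
    fenced_mean: float
    fenced_se: float
    chi_sq: Optional[float]
    p_value: Optional[float]
    signif: str = ""
    weighting: str = "none"
    flags: list = field(default_factory=list)
    full_fit: CrossedLmmFit = None
    reduced_fit: CrossedLmmFit = None


def trait_lrt(data: pd.DataFrame, value_col: str = "value",
              random_effects: Sequence[str] = ("plant_id", "date_id"),
              weights_col: Optional[str] = None,
              trait: str = "", species: str = "") -> TraitComparison:
    """LRT (chi^2, 1 df) for the fencing effect on one trait.

    Both the full model (intercept + fencing) and the reduced model
    (intercept only) carry the same random intercepts and weights and are
    fit by ML; the statistic is 2 * (ll_full - ll_reduced).
    When ``weights_col`` names an SE column, observations are weighted by
    1/SE (the precision convention for curve-derived parameters).
    """
    df = data.reset_index(drop=True)
    if df["treatment"].nunique() < 2:
        raise ValueError("both treatments must be present")
    y = df[value_col].to_numpy(float)
    fenced = (df["treatment"].to_numpy() == "fenced").astype(float)
    X_full = np.column_stack([np.ones(len(df)), fenced])
    X_red = X_full[:, :1]
    groups = {g: df[g].to_numpy() for g in random_effects if g in df.columns}
    weighting = "none"
    weights = None
    if weights_col is not None:
        ses = df[weights_col].to_numpy(float)
        if np.any(ses <= 0):
            raise ValueError("SEs for weighting must be > 0")
        weights = 1.0 / ses
        weighting = "inverse_se"

    full = fit_crossed_lmm(y, X_full, groups, weights=weights,
                           beta_names=["intercept", "fenced"])
    warm = [math.log(max(full.tau2[g], 1e-12) / full.sigma2) for g in groups]
    red = fit_crossed_lmm(y, X_red, groups, weights=weights,
                          beta_names=["intercept"], theta0=warm)
    stat = max(0.0, 2.0 * (full.loglik - red.loglik))
    p = float(stats.chi2.sf(stat, 1))

    flags = []
    if full.boundary or red.boundary:
        flags.append("variance_component_boundary")

    means = {}
    for tname, indicator in (("unfenced", fenced == 0), ("fenced", fenced == 1)):
        vals = y[indicator]
        if weights is None:
            means[tname] = (float(np.mean(vals)),
                            float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
                            if len(vals) > 1 else math.nan)
        else:
            means[tname] = weighted_group_mean(vals, ses[indicator])
    return TraitComparison(
        trait=trait, species=species,
        unfenced_mean=means["unfenced"][0], unfenced_se=means["unfenced"][1],
        fenced_mean=means["fenced"][0], fenced_se=means["fenced"][1],
        chi_sq=stat, p_value=p, signif=significance_code(p),
        weighting=weighting, flags=flags, full_fit=full, reduced_fit=red)


# ---------------------------------------------------------------------------
# Weighted means and percent differences
# ---------------------------------------------------------------------------

def weighted_group_mean(values, ses) -> tuple[float, float]:
    """Precision-weighted mean with weights w_i = 1/SE_i (as reported, not
    inverse-variance), and its SE from the weighted-variance estimator

        SE^2 = sum(w_i (v_i - m)^2) / sum(w_i) / (n_eff - 1),
        n_eff = (sum w)^2 / sum(w^2).

    A single value returns (value, its own SE).
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(ses, dtype=float)
    if v.shape != s.shape:
        raise ValueError("values and ses must have the same length")
    if np.any(s <= 0):
        raise ValueError("all SEs must be > 0")
    if len(v) == 1:
        return float(v[0]), float(s[0])
    w = 1.0 / s
    m = float(np.sum(w * v) / np.sum(w))
    n_eff = float(np.sum(w)) ** 2 / float(np.sum(w ** 2))
    var = float(np.sum(w * (v - m) ** 2) / np.sum(w)) / max(n_eff - 1.0, 1e-12)
    return m, math.sqrt(var)


def inverse_variance_mean(values, ses) -> tuple[float, float]:
    """Inverse-variance weighted mean (w = 1/SE^2): the textbook estimator,
    provided as a labelled alternative to the 1/SE convention above."""
    v = np.asarray(values, dtype=float)
    s = np.asarray(ses, dtype=float)
    if np.any(s <= 0):
        raise ValueError("all SEs must be > 0")
    w = 1.0 / s ** 2
    m = float(np.sum(w * v) / np.sum(w))
    return m, math.sqrt(1.0 / float(np.sum(w)))


@dataclass(frozen=True)
class PercentChange:
    value: float      # unrounded signed percent
    rounded: int      # nearest integer, half away from zero

    def __str__(self) -> str:
        sign = "+" if self.rounded > 0 else ""
        return f"{sign}{self.rounded} %"


def percent_change(new_mean: float, baseline_mean: float) -> PercentChange:
    """Signed percent difference 100*(new - baseline)/baseline."""
    if baseline_mean == 0:
        raise ValueError("baseline mean must be nonzero")
    value = 100.0 * (new_mean - baseline_mean) / baseline_mean
    rounded = int(math.floor(abs(value) + 0.5)) * (1 if value >= 0 else -1)
    return PercentChange(value=value, rounded=rounded)


# ---------------------------------------------------------------------------
# Trait-panel report
# ---------------------------------------------------------------------------

TRAIT_PANEL = ("sla", "leaf_area", "a_max", "r_d", "phi", "lsp", "lcp",
               "v_cmax", "j_max")


def table2_report(trait_data: dict, species: str = "",
                  random_effects: Sequence[str] = ("plant_id", "date_id"),
                  ) -> pd.DataFrame:
    """Full per-species trait panel: means +/- SE by treatment, chi^2, stars.

    ``trait_data`` maps trait name -> either a tidy DataFrame (columns
    treatment, value, optional se for weighting, optional random-effect
    columns) or None for an unavailable panel (rendered NA, mirroring
    one-treatment A/Ci designs).  The report is a pure function of its
    inputs.
    """
    rows = []
    for trait in TRAIT_PANEL:
        df = trait_data.get(trait)
        if df is None:
            rows.append({"trait": trait, "species": species,
                         "unfenced_mean": math.nan, "unfenced_se": math.nan,
                         "fenced_mean": math.nan, "fenced_se": math.nan,
                         "chi_sq": math.nan, "p": math.nan, "signif": "NA"})
            continue
        if df["treatment"].nunique() < 2:
            # one-treatment panel: report the available mean, no test
            t = df["treatment"].iloc[0]
            vals = df["value"].to_numpy(float)
            if "se" in df.columns:
                m, se = weighted_group_mean(vals, df["se"].to_numpy(float))
            else:
                m = float(np.mean(vals))
                se = float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
            row = {"trait": trait, "species": species,
                   "unfenced_mean": math.nan, "unfenced_se": math.nan,
                   "fenced_mean": math.nan, "fenced_se": math.nan,
                   "chi_sq": math.nan, "p": math.nan, "signif": "NA"}
            row[f"{t}_mean"], row[f"{t}_se"] = m, se
            rows.append(row)
            continue
        comp = trait_lrt(df, value_col="value",
                         random_effects=[g for g in random_effects
                                         if g in df.columns],
                         weights_col="se" if "se" in df.columns else None,
                         trait=trait, species=species)
        rows.append({"trait": trait, "species": species,
                     "unfenced_mean": comp.unfenced_mean,
                     "unfenced_se": comp.unfenced_se,
                     "fenced_mean": comp.fenced_mean,
                     "fenced_se": comp.fenced_se,
                     "chi_sq": comp.chi_sq, "p": comp.p_value,
                     "signif": comp.signif})
    return pd.DataFrame(rows)


def headline_percentages(table2: dict | None = None) -> list[dict]:
    """The treatment-effect percentages implied by the published group means.

    Computes each reported headline percent difference from the trait-panel
    means (and the late-June light means) via :func:`percent_change`.
    """
    from . import reference

    t2 = table2 or reference.TABLE2
    specs = [
        # (species, trait, new, baseline, description)
        ("Alliaria", "a_max", "unfenced", "fenced",
         "maximum photosynthetic rate, unfenced vs fenced"),
        ("Alliaria", "sla_rosette", "unfenced", "fenced",
         "rosette SLA, unfenced vs fenced"),
        ("Alliaria", "sla_rosette", "fenced", "unfenced",
         "rosette SLA, fenced vs unfenced"),
        ("Maianthemum", "a_max", "unfenced", "fenced",
         "maximum photosynthetic rate, unfenced vs fenced"),
        ("Maianthemum", "sla", "unfenced", "fenced",
         "SLA, unfenced vs fenced"),
        ("Trillium", "a_max", "unfenced", "fenced",
         "maximum photosynthetic rate, unfenced vs fenced"),
        ("Alliaria", "lsp", "unfenced", "fenced",
         "light saturation point, unfenced vs fenced"),
    ]
    out = []
    for species, trait, new, base, desc in specs:
        entry = t2[species][trait]
        pc = percent_change(entry[new][0], entry[base][0])
        out.append({"species": species, "trait": trait, "direction": f"{new}_vs_{base}",
                    "percent": pc.rounded, "percent_unrounded": pc.value,
                    "description": desc})
    from .reference import PPFD_MEANS
    pc = percent_change(PPFD_MEANS["late_june"]["fenced"][0],
                        PPFD_MEANS["late_june"]["unfenced"][0])
    out.append({"species": "all", "trait": "ppfd_late_june",
                "direction": "fenced_vs_unfenced", "percent": pc.rounded,
                "percent_unrounded": pc.value,
                "description": "late-June plant-level PPFD, fenced vs unfenced"})
    return out
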