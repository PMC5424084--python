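# Methods

`herbphys` implements the leaf-level gas-exchange and understory-light
analyses used in herbivore-exclosure studies of forest herbs: light-response
and A/Ci curve fitting, canopy-closure detection from a seasonal light
series, mixed-model inference on treatment divergence in light availability,
and trait contrasts between fenced (herbivore-excluded) and unfenced areas.
This note records the models, the defaults and why, what the synthetic-data
generator does and does not emulate, and the numerical choices.

## Light-response model (non-rectangular hyperbola)

Net assimilation versus PPFD (P) is modelled as

    A_net(P) = [phi*P + Amax − sqrt((phi*P + Amax)^2 − 4*theta*phi*P*Amax)]
               / (2*theta) − Rd

* `Amax` — gross maximum photosynthetic rate (asymptote), μmol CO2 m⁻² s⁻¹
* `phi` — apparent quantum yield (initial slope), mol CO2 mol photons⁻¹,
  constrained to (0, 0.5] in the fitter (physiology caps it near 0.125)
* `Rd` — daytime dark respiration, μmol CO2 m⁻² s⁻¹ (= |A_net| at P = 0)
* `theta` — convexity in [0, 0.999]; theta → 0 is the rectangular
  hyperbola, theta → 1 the Blackman limit.  Below 1e-6 the rectangular
  limit is evaluated directly to avoid 0/0.

Fitting is non-linear least squares (`scipy.optimize.least_squares`, tight
tolerances) with multi-start initialization: `phi` from the slope of the
three lowest-light points, `Rd` from |A_net| at minimum light, `Amax` from
the top-light mean plus `Rd`, and theta started at {0.3, 0.6, 0.9}; the
lowest-RSS solution wins.  Theta is estimated per curve (not fixed) and
boundary solutions are flagged.  Standard errors come from the final
Gauss–Newton covariance `sigma² (JᵀJ)⁻¹`.  Curves with fewer than five
distinct light levels are refused; degenerate (flat) curves return a
non-converged fit, never silent defaults.

Derived points are closed forms obtained by inverting the gross-rate curve
P(A) = A(Amax − theta·A)/(phi(Amax − A)):

* light compensation point LCP = P(Rd) (zero net assimilation);
* light saturation point LSP = P(0.9·Amax), i.e. "90 % of the model
  asymptote" read on the gross scale, which reduces to
  9·Amax·(1 − 0.9·theta)/phi.

Both are verified against bisection on the model in the test suite.

## Biochemical A/Ci model

Net assimilation is the strict pointwise minimum of a RuBisCO-limited and
an RuBP-regeneration-limited rate minus daytime respiration:

    A_net = min(Av, Aj) − Rday
    Av = Vcmax (Ci − Γ*) / (Ci + Kc (1 + O/Ko))
    Aj = Jmax  (Ci − Γ*) / (4 Ci + 8 Γ*)

with fixed 25 °C kinetic constants Kc = 40.4 Pa, Ko = 24.8 kPa, O = 21 kPa,
Γ* = 3.7 Pa (overridable).  Ci is carried in Pa throughout; instrument mole
fractions (μmol mol⁻¹) are converted at read time using the logged chamber
pressure, or standard pressure (101.325 kPa) when absent — the assumption
is recorded in the run-metadata sidecar.  There is no smoothing of the
limb transition and no third (triose-phosphate) limb.

`Vcmax`, `Jmax` and `Rday` are estimated simultaneously over all curve
points in one least-squares objective; limitation labels are assigned from
the fitted model afterwards.  Repeated 400 μmol mol⁻¹ stability-check steps
are retained as data.  When every point sits in a single limitation regime
the unidentified parameter is flagged and its SE withheld.  `Rday` may
optionally be fixed (e.g. to the light-curve Rd); free estimation is the
default.  The crossover Ci solving Av = Aj has the closed form
(Jmax·Km_eff − 8 Γ* Vcmax)/(4 Vcmax − Jmax); when it falls outside
(Γ*, 200 Pa) the everywhere-limiting regime is reported instead.

## Canopy-closure detection

Daily mean PPFD (10:00–14:00, inclusive start / exclusive end) from a fixed
understory sensor is smoothed with a penalized regression spline: cubic
B-spline basis with one knot per ~4 days, second-order difference penalty
(P-spline), smoothing parameter chosen on a log-spaced grid.  The selection
criterion defaults to AICc; GCV is available but tends to undersmooth this
kind of strongly heteroscedastic series (day-to-day light noise is roughly
proportional to the light level), which destabilizes the derivative.  The
coefficient covariance is the Bayesian posterior `sigma² (BᵀB + λP)⁻¹`,
from which pointwise 95 % CIs of the first derivative follow analytically.

The closure day is the first day at which the derivative CI contains zero,
scanning forward from the start of the longest sustained run of
significantly negative slope, and requiring the zero-containing condition
to persist for 4 consecutive days.  The run-based origin and the
persistence rule make the detector robust to isolated significant wiggles
in the pre-decline plateau and to momentary zero-touches inside a noisy
decline; on noise-free input they change nothing.  If the series never
declines significantly, or never flattens, the result is `None` with a
diagnostic warning.  The detected day is invariant to rescaling the series
(units).

## Light-divergence mixed model

Plant-level mean PPFD is modelled on the log scale with fixed effects
{day, day², fencing, day × fencing}, a random intercept for measurement
day (shared across treatments), and residual standard deviation
proportional to |day|^δ_g with a separate exponent per treatment (the
power-of-covariate variance function).  Days are centred and scaled
internally for the fixed effects; the variance covariate is normalized by
its geometric mean so the exponents stay well-scaled.

Fitting is maximum likelihood with nested profiling: at each variance-
parameter evaluation (log λ = log τ²/σ², δ_fenced, δ_unfenced) the fixed
effects are profiled out by generalized least squares and σ² analytically;
the per-day block structure makes each evaluation O(n) via the
Sherman–Morrison identity.  The remaining 1–3 parameters are optimized by
Nelder–Mead from multiple starts (warm-startable between nested models).
ML — not REML — is used for every model entering a likelihood-ratio test
of fixed effects.  The homoscedastic submodel (δ = 0) reproduces an
independent direct ML fit (statsmodels MixedLM) to < 1e-4 log-likelihood
units, which the test suite asserts.

Terms are tested sequentially (Time, Time², Fencing, Time × Fencing) by
LRTs of nested models sharing the same random-effect and variance
structure; parameter counts run 5 → 9, reported in "(k, k+1)" notation.
The selected structure is re-fit on untransformed PPFD — same random and
variance structure — to report treatment means ± SE on the original scale
at a requested day; extrapolation beyond the observed day range is refused.

## Trait inference

* **Seasonal Asat ANOVA** — OLS cell-means model with fencing, month and
  their interaction, fit per species.  A log transform is applied when a
  documented diagnostic triggers (absolute residual skew > 1, or Levene's
  test across cells at p < 0.01), never silently.  Within-month
  fenced-vs-unfenced contrasts use the pooled residual variance and the
  model's residual df; no multiplicity adjustment by default (Bonferroni
  available).  Residual df is n minus the number of cells in the fitted
  design — the df accounting is exposed by the result object rather than
  assumed.
* **Trait LRTs** — each trait is compared with and without the fencing
  fixed effect by an LRT (χ², 1 df) under a linear mixed model with
  crossed random intercepts for individual and measurement date, fit by
  direct ML (dense marginal covariance, variance ratios optimized by
  Nelder–Mead with fixed effects and σ² profiled out).  Curve-derived
  parameters are precision-weighted with observation weights exactly 1/SE;
  an inverse-variance (1/SE²) alternative exists but is labelled as such.
  Boundary variance components are flagged; the LRT is still reported.
* **Weighted group means** — mean = Σ(wᵢvᵢ)/Σwᵢ with wᵢ = 1/SEᵢ; its SE
  uses the weighted-variance estimator with effective sample size
  n_eff = (Σw)²/Σw².
* **Percent differences** — 100·(new − baseline)/baseline, reported
  rounded to the nearest integer, half away from zero; the unrounded value
  is retained and satisfies exact forward/backward reciprocity.

## Synthetic-data generator

The generator encodes the study conditions and returns ground truth
alongside every dataset; tests recover truth only through the public
fitting interfaces.

* **Light curves**: 11 light steps over 0–1500 μmol m⁻² s⁻¹, Gaussian
  instrument noise on A_net with sd 0.2 μmol m⁻² s⁻¹ (typical IRGA
  stability; the default is a calibration choice, config-exposed).
* **A/Ci curves**: the 11-step chamber-CO2 protocol
  (400, 300, 200, 100, 50, 400, 400, 600, 800, 1000, 1500 μmol mol⁻¹) with
  a linear supply function Ci = 0.7 × chamber CO2 (converted to Pa), which
  spans both limitation regimes around a typical crossover near 36 Pa.
  Sub-Γ* steps are kept; negative A_net there is legitimate data.
* **Season**: a fixed-sensor series (April–July) following a logistic
  decline from an open-canopy level (350) to a closed-canopy level (15),
  98 % complete at the true closure day (148); lognormal daily noise
  (sd 0.15 on the log).  Plant-level light: 75 fenced and 110 unfenced
  plants spread over 11 measurement days (mid-May–late June), each plant's
  mean built from 1–16 raw measurements (truncated-geometric counts tuned
  to mean 5.95).  Treatment trajectories are log-linear between the
  mid-May and late-June anchors — fenced declining 57.4 → 15.6, unfenced
  flat at 52 — with a shared lognormal day effect (sd 0.2) and among-plant
  lognormal scatter (sd 0.7 on the log, mean-preserving on the arithmetic
  scale).  These levels mirror the magnitude of divergence the package is
  designed to detect.
* **Traits**: value = cell mean + individual intercept + date intercept +
  residual, with leaf area drawn lognormally and dry mass back-computed so
  SLA = area/mass holds exactly; spot Asat tables are generated on a
  month × fencing grid.

What the generator does **not** emulate: weather autocorrelation in the
sensor series (days are independent given the trend), browse damage and
missing-leaf censoring, within-season repeated measures on the same plant,
spatial structure among plants, temperature responses of the kinetic
constants, and any stomatal or energy-balance dynamics.  Passing tests
therefore demonstrate estimator correctness and calibration under the
assumed noise structure, not robustness to these field realities.

## Numerical choices and problem sizes

* Optimizer tolerances: curve fitters run `least_squares` with
  xtol = ftol = gtol = 1e-14 (noise-free round trips recover truth to
  < 1e-12 relative); variance-parameter searches use Nelder–Mead with
  fatol = 1e-8, which fixes log-likelihoods far beyond LRT precision.
* CI coverage checks use the nominal 95 % t-interval
  (t₀.₉₇₅,ₙ₋ₚ × SE) — the finite-sample interval for least squares with
  estimated σ at n = 11 points.
* Simulation studies in the test suite use 20 instances for noise-free
  round trips, 200 replicates for estimator calibration, 500 null
  replicates for type-I error (asserted inside binomial 99 % bands around
  0.05), and 100 replicates for closure-day recovery; all seeded.
* Negative LRT statistics (possible at optimizer precision) are clipped to
  zero with a warning; identical models give statistic 0, p = 1.
* Ties/degenerate inputs: constant light-response curves are flagged, not
  fit; single-treatment trait panels are reported without a test (NA),
  mirroring designs where one treatment was never measured.

## Known limitations

* The day random effect is shared between treatments (not nested); the
  variance covariate and grouping are configurable but the default
  follows the power-of-day form.
* The original-scale re-fit inherits the log-scale model's fixed-effect
  structure; if the true arithmetic-scale trend is strongly curved, its
  day-polynomial is a local approximation and treatment means at the
  window edges carry that approximation error.
* The closure detector's persistence window (4 days) trades a few days of
  detection delay against false flattening inside noisy declines; both the
  window and the CI level are options.
* Weighted trait models treat 1/SE weights as known constants, ignoring
  uncertainty in the SEs themselves.
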