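# herbphys

Leaf gas-exchange and understory-light analysis for herbivore-exclosure
experiments on forest herbs.

Overabundant deer change the light environment of the forest understory by
browsing down the vegetation layer.  Studies that fence deer out and compare
plants inside and outside the exclosure need a reproducible pipeline from
raw gas-exchange logs to treatment-level inference.  `herbphys` provides
that pipeline for ecophysiologists: curve-level photosynthesis model
fitting, detection of the overstory canopy-closure date from a seasonal
light series, mixed-model tests of whether fenced and unfenced light
availability diverge over the season, and trait contrasts (specific leaf
area, photosynthetic capacity) between treatments — plus a synthetic-data
generator with known ground truth, so every stage is testable without field
data.

## Models

**Light response** (non-rectangular hyperbola): net assimilation at
irradiance *P* is

    A_net(P) = [φP + A_max − √((φP + A_max)² − 4θφP·A_max)] / (2θ) − R_d

with gross asymptote *A_max*, apparent quantum yield *φ*, daytime dark
respiration *R_d*, and convexity *θ* ∈ [0, 1).  Fits give closed-form light
compensation and saturation points (LCP; LSP at 90 % of the asymptote).

**A/Ci response** (biochemical model of C3 photosynthesis):

    A_net = min(A_v, A_j) − R_day
    A_v = V_cmax (C_i − Γ*) / (C_i + K_c (1 + O/K_o))
    A_j = J_max (C_i − Γ*) / (4C_i + 8Γ*)

with 25 °C kinetics K_c = 40.4 Pa, K_o = 24.8 kPa, O = 21 kPa, Γ* = 3.7 Pa.
*V_cmax*, *J_max* and *R_day* are estimated simultaneously by non-linear
least squares over the whole curve.

**Canopy closure**: daily mean PPFD (10:00–14:00) is smoothed with a
penalized regression spline; the closure day is the first day — after the
decline begins — whose slope is statistically indistinguishable from zero
(95 % CI of the spline derivative contains 0, sustained).

**Light divergence**: log plant-level mean PPFD ~ day + day² + fencing +
day × fencing, with a day random intercept and residual sd ∝ |day|^δ per
treatment; terms tested by likelihood-ratio tests of nested ML fits, and
treatment means reported on the original scale from a re-fit.

**Traits**: per-trait mixed-model LRTs (χ², 1 df) with individual and
measurement-date random intercepts, 1/SE precision weights for
curve-derived parameters, fencing × month ANOVAs with within-month
contrasts, and signed percent differences between treatment means.

## Worked example

```python
from herbphys.simulate import LightCurveTruth, simulate_light_curve
from herbphys.light_response import fit_light_response

curve = simulate_light_curve(LightCurveTruth(), noise_sd=0.2, seed=7)
fit = fit_light_response(curve)
print(f"Amax = {fit.a_max:.2f} +/- {fit.se['a_max']:.2f}")
print(f"phi  = {fit.phi:.4f} +/- {fit.se['phi']:.4f}")
print(f"Rd   = {fit.r_d:.2f} +/- {fit.se['r_d']:.2f}")
print(f"LCP  = {fit.lcp:.1f}  LSP = {fit.lsp:.1f}")
```

prints

```
Amax = 9.42 +/- 0.16
phi  = 0.0769 +/- 0.0050
Rd   = 0.50 +/- 0.13
LCP  = 6.5  LSP = 237.2
```

— an 11-point light curve generated from truth (A_max 9.40, φ 0.077,
R_d 0.52, θ 0.9) with 0.2 μmol m⁻² s⁻¹ instrument noise, re-fit to within
one standard error of every generating parameter.  The LCP (6.5 μmol
photons m⁻² s⁻¹) is the irradiance where the leaf breaks even on carbon;
the LSP (237 μmol m⁻² s⁻¹) is where it reaches 90 % of its gross
photosynthetic ceiling.

The same workflow is available from the shell:

```bash
herbphys simulate --seed 1 --out data/          # synthetic dataset + truth
herbphys fit-light --in data/gas_exchange.csv --out fits.csv
herbphys closure-day --in data/sensor_daily.csv
herbphys light-lmm --in data/plant_ppfd.csv --out lmm.csv
herbphys report --headline-percentages
```

`report --headline-percentages` computes the treatment-effect percentages
implied by the published group means — e.g. +50 % maximum photosynthetic
rate and −48 % rosette SLA for the invader where deer have access, and
−70 % late-June plant-level light where deer are excluded.

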