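"""Synthetic gas-exchange, seasonal-light and leaf-trait data with known truth.

Every generator is deterministic given its seed and emits data in the same
schemas the readers consume, so each downstream stage can be tested end to
end without field data.  Ground-truth parameters are always returned (or
written as a sidecar table) alongside the data; tests recover them through
the public fitting interfaces only.

What the generators emulate (and what they do not) is documented in
docs/methods.md; the defaults below encode the study conditions of a
two-treatment (deer fenced/unfenced) understory experiment: per-plant
light-response curves in 10-12 light steps, 11-step A/Ci curves with a
thrice-repeated 400 umol mol-1 stability check, a fixed-sensor PPFD season
with a canopy-closure decline, and plant-level light summaries on 11
measurement days (75 fenced, 110 unfenced plants; 1-16 measurements per
plant, mean about 5.95).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Sequence

import numpy as np
import pandas as pd

from .farquhar import DEFAULT_CONSTANTS, KineticConstants, fvcb_net
from .light_response import nrh_anet
from .records import CurveDataset, GasExchangeRecord, LeafTraitRecord, STANDARD_PRESSURE_KPA

#: the instrument's chamber-CO2 step sequence (umol mol-1); 400 repeats as a
#: stability check and is retained as data
ACI_CO2_SEQUENCE = (400, 300, 200, 100, 50, 400, 400, 600, 800, 1000, 1500)

#: default light-step sequence for simulated light-response curves
LIGHT_PPFD_LEVELS = (0, 25, 50, 100, 200, 400, 600, 800, 1000, 1200, 1500)

#: default instrument noise on a_net, umol m-2 s-1 (typical IRGA stability)
DEFAULT_ANET_NOISE_SD = 0.2

#: default Ci supply coefficient: Ci = k * chamber CO2
DEFAULT_CI_SUPPLY_K = 0.7


@dataclass(frozen=True)
class LightCurveTruth:
    a_max: float = 9.40   # gross maximum photosynthesis, umol m-2 s-1
    phi: float = 0.077    # apparent quantum yield, mol CO2 / mol photons
    r_d: float = 0.52     # daytime dark respiration, umol m-2 s-1
    theta: float = 0.9    # convexity

    def __post_init__(self):
        if not (self.a_max > 0 and 0 < self.phi <= 0.125 and self.r_d >= 0
                and 0 <= self.theta < 1):
            raise ValueError("light-curve truth outside valid ranges")
        if self.r_d >= self.a_max:
            raise ValueError("r_d must be < a_max")


@dataclass(frozen=True)
class ACiTruth:
    v_cmax: float = 27.73  # umol CO2 m-2 s-1
    j_max: float = 43.49   # umol e- m-2 s-1
    r_day: float = 0.5     # umol CO2 m-2 s-1

    def __post_init__(self):
        if not (self.v_cmax > 0 and self.j_max > 0 and self.r_day >= 0):
            raise ValueError("A/Ci truth parameters must be positive")
        if self.j_max <= self.v_cmax:
            import warnings

            warnings.warn("j_max <= v_cmax is unusual for C3 leaves", stacklevel=2)


def _mk_record(plant_id, species, treatment, ts, ppfd, a_net, ci=None,
               co2_ref=None, life_stage="NA") -> GasExchangeRecord:
    return GasExchangeRecord(
        plant_id=plant_id, species=species, treatment=treatment, timestamp=ts,
        ppfd=float(ppfd), a_net=float(a_net), ci=ci, leaf_temp=25.0,
        co2_ref=co2_ref, pressure=STANDARD_PRESSURE_KPA, life_stage=life_stage)


def simulate_light_curve(truth: LightCurveTruth,
                         ppfd_levels: Sequence[float] = LIGHT_PPFD_LEVELS,
                         noise_sd: float = DEFAULT_ANET_NOISE_SD,
                         seed: int = 0, *,
                         plant_id: str = "sim", species: str = "Alliaria",
                         treatment: str = "unfenced",
                         start: datetime = datetime(2015, 7, 10, 10, 0)) -> CurveDataset:
    """One light-response curve: NRH(truth) + Gaussian instrument noise."""
    levels = np.asarray(ppfd_levels, dtype=float)
    if np.any(levels < 0) or np.any(levels > 2000):
        raise ValueError("ppfd_levels must lie in [0, 2000]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    a = nrh_anet(levels, truth.a_max, truth.phi, truth.r_d, truth.theta)
    a = np.atleast_1d(a) + rng.normal(0.0, noise_sd, size=len(levels))
    records = [
        _mk_record(plant_id, species, treatment, start + timedelta(minutes=3 * i),
                   p, v)
        for i, (p, v) in enumerate(zip(levels, a))
    ]
    return CurveDataset(curve_id=f"{plant_id}-lr", plant_id=plant_id,
                        curve_kind="light_response", records=records)


def simulate_aci_curve(truth: ACiTruth,
                       constants: KineticConstants = DEFAULT_CONSTANTS,
                       co2_ref_sequence: Sequence[float] = ACI_CO2_SEQUENCE,
                       seed: int = 0,
                       noise_sd: float = DEFAULT_ANET_NOISE_SD, *,
                       ci_supply_k: float = DEFAULT_CI_SUPPLY_K,
                       pressure_kpa: float = STANDARD_PRESSURE_KPA,
                       plant_id: str = "sim", species: str = "Alliaria",
                       treatment: str = "unfenced",
                       start: datetime = datetime(2015, 7, 10, 12, 0)) -> CurveDataset:
    """One A/Ci curve along the chamber-CO2 step sequence.

    Ci is derived from chamber CO2 through a linear supply function
    (Ci = k * CO2_ref, mole fraction) and converted to Pa at the chamber
    pressure.  Steps with Ci at or below Gamma* are kept: negative net
    assimilation there is legitimate data.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    co2 = np.asarray(co2_ref_sequence, dtype=float)
    ci_pa = ci_supply_k * co2 * pressure_kpa / 1000.0
    a = np.atleast_1d(fvcb_net(ci_pa, truth.v_cmax, truth.j_max, truth.r_day,
                               constants))
    a = a + rng.normal(0.0, noise_sd, size=len(co2))
    records = [
        _mk_record(plant_id, species, treatment, start + timedelta(minutes=4 * i),
                   800.0, v, ci=float(c), co2_ref=float(ref))
        for i, (c, ref, v) in enumerate(zip(ci_pa, co2, a))
    ]
    return CurveDataset(curve_id=f"{plant_id}-aci", plant_id=plant_id,
                        curve_kind="aci", records=records)


# ---------------------------------------------------------------------------
# Seasonal understory light
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeasonScenario:
    """Study conditions for one simulated growing season.

    The treatment trajectories follow a logistic decline from the
    pre-closure to the post-closure level; ``closure_day_true`` is the day
    by which 98 % of the decline is complete (the plateau onset the
    detector should find).  ``noise_lognorm_sd`` acts on the log of plant
    means; ``sensor_lognorm_sd`` on the log of daily sensor means.
    """

    closure_day_true: int = 148
    pre_closure_ppfd: dict = field(default_factory=lambda: {"fenced": 57.4, "unfenced": 52.0})
    post_closure_ppfd: dict = field(default_factory=lambda: {"fenced": 15.6, "unfenced": 52.0})
    sensor_pre_ppfd: float = 350.0         # open canopy, April mid-day mean
    sensor_post_ppfd: float = 15.0         # closed canopy
    decline_steepness: float = 0.25        # sensor logistic rate, day^-1
    plant_anchor_days: tuple = (135, 172)  # mid-May and late-June anchors
    plant_count: dict = field(default_factory=lambda: {"fenced": 75, "unfenced": 110})
    measurements_per_plant_mean: float = 5.95
    measurements_per_plant_max: int = 16
    noise_lognorm_sd: float = 0.7          # among-plant, log scale
    day_effect_sd: float = 0.2             # shared day-to-day effect, log scale
    sensor_lognorm_sd: float = 0.15        # fixed-sensor daily means, log scale
    season_start_day: int = 91             # April 1
    season_end_day: int = 212              # July 31
    measurement_days: tuple = (135, 139, 143, 148, 152, 156, 160, 165, 169, 173, 177)
    year: int = 2015
    seed: int = 0

    def __post_init__(self):
        for g in ("fenced", "unfenced"):
            if self.post_closure_ppfd[g] > self.pre_closure_ppfd[g]:
                raise ValueError("post-closure PPFD must be <= pre-closure PPFD")
            if self.plant_count[g] < 2:
                raise ValueError("need at least 2 plants per treatment")


def season_trajectory(scenario: SeasonScenario, treatment: str, day) -> np.ndarray:
    """Noise-free trajectory of mean PPFD versus day of year.

    ``treatment = "sensor"`` gives the fixed understory sensor: a logistic
    decline from the open-canopy to the closed-canopy level, 98 % complete
    at ``closure_day_true``.  Plant-level treatment trajectories are
    log-linear between the mid-May and late-June anchor days (flat when
    pre == post), matching the straight divergence the log-scale mixed
    model assumes.
    """
    day = np.asarray(day, dtype=float)
    if treatment == "sensor":
        pre, post = scenario.sensor_pre_ppfd, scenario.sensor_post_ppfd
        r = scenario.decline_steepness
        # midpoint placed so the decline is 98% complete at closure day
        mid = scenario.closure_day_true - np.log(0.98 / 0.02) / r
        frac_remaining = 1.0 / (1.0 + np.exp(r * (day - mid)))
        out = post + (pre - post) * frac_remaining
    else:
        pre = scenario.pre_closure_ppfd[treatment]
        post = scenario.post_closure_ppfd[treatment]
        d0, d1 = scenario.plant_anchor_days
        out = np.exp(np.log(pre)
                     + (np.log(post) - np.log(pre)) * (day - d0) / (d1 - d0))
    return out if out.ndim else float(out)


def truncated_geometric_pmf(mean: float, kmax: int) -> np.ndarray:
    """pmf on 1..kmax of a truncated geometric tuned to the given mean."""
    ks = np.arange(1, kmax + 1)

    def mean_at(q):
        w = q ** (ks - 1)
        return float(np.sum(ks * w) / np.sum(w))

    lo, hi = 1e-9, 1.0 - 1e-9
    if not mean_at(lo) <= mean <= mean_at(hi):
        raise ValueError("target mean unreachable for truncated geometric")
    for _ in range(200):
        q = 0.5 * (lo + hi)
        if mean_at(q) < mean:
            lo = q
        else:
            hi = q
    w = q ** (ks - 1)
    return w / np.sum(w)


@dataclass
class SeasonData:
    sensor: pd.DataFrame          # day_of_year, mean_ppfd, n_obs
    plants: pd.DataFrame          # plant_id, treatment, day_of_year, mean_ppfd, n_measurements
    plant_records: list           # raw GasExchangeRecord per measurement
    truth: dict


def simulate_season(scenario: SeasonScenario) -> SeasonData:
    """Simulate one season: fixed-sensor daily series + plant-level light.

    Plant means are lognormal around the treatment trajectory (arithmetic
    mean preserved: the log-mean is shifted by -sd^2/2), with a shared
    day-level effect; each plant contributes ``n_i`` raw measurement
    records whose average is its summary value.
    """
    rng = np.random.default_rng(scenario.seed)
    days = np.arange(scenario.season_start_day, scenario.season_end_day + 1)

    sensor_truth = season_trajectory(scenario, "sensor", days)
    noise = rng.normal(0.0, scenario.sensor_lognorm_sd, size=len(days)) \
        if scenario.sensor_lognorm_sd > 0 else np.zeros(len(days))
    sensor = pd.DataFrame({
        "day_of_year": days,
        "mean_ppfd": sensor_truth * np.exp(noise - 0.5 * scenario.sensor_lognorm_sd ** 2),
        "n_obs": 48,
    })

    pmf = truncated_geometric_pmf(scenario.measurements_per_plant_mean,
                                  scenario.measurements_per_plant_max)
    ks = np.arange(1, scenario.measurements_per_plant_max + 1)
    mdays = np.asarray(scenario.measurement_days)
    day_effects = {int(d): (rng.normal(0.0, scenario.day_effect_sd)
                            if scenario.day_effect_sd > 0 else 0.0)
                   for d in mdays}

    rows, raw = [], []
    within_sd = 0.3 if scenario.noise_lognorm_sd > 0 else 0.0
    for treatment in ("fenced", "unfenced"):
        n_plants = scenario.plant_count[treatment]
        plant_days = mdays[np.arange(n_plants) % len(mdays)]
        for i, d in enumerate(plant_days):
            pid = f"{treatment[0]}{i:03d}"
            traj = season_trajectory(scenario, treatment, float(d))
            sd = scenario.noise_lognorm_sd
            mu = np.log(traj) - 0.5 * sd ** 2 + day_effects[int(d)]
            plant_level = np.exp(mu + (rng.normal(0.0, sd) if sd > 0 else 0.0))
            n_i = int(rng.choice(ks, p=pmf))
            meas = plant_level * np.exp(
                rng.normal(0.0, within_sd, size=n_i) - 0.5 * within_sd ** 2) \
                if within_sd > 0 else np.full(n_i, plant_level)
            ts0 = datetime(scenario.year, 1, 1, 10, 30) + timedelta(days=int(d) - 1)
            for k, m in enumerate(meas):
                raw.append(_mk_record(pid, "other", treatment,
                                      ts0 + timedelta(minutes=5 * k),
                                      m, 0.0))
            rows.append({"plant_id": pid, "treatment": treatment,
                         "day_of_year": int(d),
                         "mean_ppfd": float(np.mean(meas)),
                         "n_measurements": n_i})

    plants = pd.DataFrame(rows)
    truth = {
        "closure_day": scenario.closure_day_true,
        "trajectory": {g: {"pre": scenario.pre_closure_ppfd[g],
                           "post": scenario.post_closure_ppfd[g]}
                       for g in ("fenced", "unfenced")},
        "scenario": scenario,
    }
    return SeasonData(sensor=sensor, plants=plants, plant_records=raw, truth=truth)


# ---------------------------------------------------------------------------
# Leaf traits and spot Asat tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitScenario:
    """Grouped trait data: treatment shift + individual/date random effects."""

    species: str = "Alliaria"
    life_stage: str = "rosette"
    trait_mean: dict = field(default_factory=lambda: {"unfenced": 350.0, "fenced": 674.0})
    sd_individual: float = 40.0
    sd_date: float = 20.0
    sd_residual: float = 50.0
    n_individuals: dict = field(default_factory=lambda: {"unfenced": 50, "fenced": 50})
    n_dates: int = 4
    leaves_per_individual: int = 2
    mean_leaf_area: float = 8.0   # cm2
    seed: int = 0

    def __post_init__(self):
        if min(self.sd_individual, self.sd_date, self.sd_residual) < 0:
            raise ValueError("variance components must be >= 0")


@dataclass
class TraitData:
    records: list                  # LeafTraitRecord
    frame: pd.DataFrame            # plant_id, treatment, date_id, value (= SLA)
    truth: dict


def simulate_trait_table(scenario: TraitScenario) -> TraitData:
    """Trait values = cell mean + individual RE + date RE + residual.

    The trait here is SLA (cm2 g-1); leaf area is drawn lognormally and dry
    mass back-computed so records satisfy sla = area/mass exactly.
    """
    rng = np.random.default_rng(scenario.seed)
    date_eff = rng.normal(0.0, scenario.sd_date, size=scenario.n_dates) \
        if scenario.sd_date > 0 else np.zeros(scenario.n_dates)
    base_date = datetime(2015, 6, 1)

    records, rows = [], []
    for treatment in ("unfenced", "fenced"):
        cell = scenario.trait_mean[treatment]
        for i in range(scenario.n_individuals[treatment]):
            pid = f"{scenario.species[:2]}{treatment[0]}{i:03d}"
            ind_eff = rng.normal(0.0, scenario.sd_individual) \
                if scenario.sd_individual > 0 else 0.0
            for leaf in range(scenario.leaves_per_individual):
                d = int(rng.integers(scenario.n_dates))
                resid = rng.normal(0.0, scenario.sd_residual) \
                    if scenario.sd_residual > 0 else 0.0
                value = cell + ind_eff + date_eff[d] + resid
                value = max(value, 1.0)
                area = scenario.mean_leaf_area * float(np.exp(
                    rng.normal(0.0, 0.3) - 0.045)) if scenario.sd_residual > 0 \
                    else scenario.mean_leaf_area
                rec = LeafTraitRecord(
                    plant_id=pid, species=scenario.species, treatment=treatment,
                    sample_date=base_date + timedelta(days=7 * d),
                    leaf_area=area, dry_mass=area / value,
                    life_stage=scenario.life_stage)
                records.append(rec)
                rows.append({"plant_id": pid, "treatment": treatment,
                             "date_id": d, "value": value})
    frame = pd.DataFrame(rows)
    truth = {"trait_mean": dict(scenario.trait_mean),
             "effect": scenario.trait_mean["unfenced"] - scenario.trait_mean["fenced"],
             "scenario": scenario}
    return TraitData(records=records, frame=frame, truth=truth)


def simulate_asat_table(cell_means: dict, n_per_cell: int = 12,
                        sd_individual: float = 0.0, sd_residual: float = 1.0,
                        seed: int = 0, species: str = "Alliaria",
                        year: int = 2015) -> pd.DataFrame:
    """Spot light-saturated Asat observations on a month x fencing grid.

    ``cell_means`` maps (month, treatment) -> mean Asat.  Returns a tidy
    frame with columns plant_id, species, treatment, month, a_net.
    """
    rng = np.random.default_rng(seed)
    rows = []
    counter = 0
    for (month, treatment), mu in sorted(cell_means.items()):
        for _ in range(n_per_cell):
            pid = f"{species[:2]}{counter:04d}"
            counter += 1
            ind = rng.normal(0.0, sd_individual) if sd_individual > 0 else 0.0
            eps = rng.normal(0.0, sd_residual) if sd_residual > 0 else 0.0
            rows.append({"plant_id": pid, "species": species,
                         "treatment": treatment, "month": int(month),
                         "a_net": mu + ind + eps})
    return pd.DataFrame(rows)


def paper_like_season(seed: int = 0, **overrides) -> SeasonScenario:
    """The default two-treatment season scenario with a given seed."""
    return replace(SeasonScenario(), seed=seed, **overrides)
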