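"""Synthetic scenario generation: weather seasons, soil profiles, management.

Emulates a long-term P-fertilisation contrast on a temperate silty clay
loam: a P-depleted "control" topsoil (Olsen-P ~6.9 mg kg-1, total P
~373 mg kg-1) versus a P-replete "p_added" topsoil (Olsen-P ~30.6,
total P ~584), two contrasting October-July growing seasons (a cooler
7.9 degC / 672 mm season with a wet winter, and a warmer 10.1 degC /
814 mm one), and the standard management calendar (autumn sowing, 15 kg
P ha-1 as triple superphosphate before sowing on the P-added treatment,
300 kg N ha-1 split 50/200/50 across March-May, summer harvest).

All generators are pure functions of (spec, seed): the same seed
reproduces the same files bit for bit.  Realised seasonal mean
temperature and precipitation totals are rescaled after generation to
match the scenario statistics exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as Date, timedelta
from typing import Dict, List

import numpy as np
import pandas as pd

from . import units
from .config import LayerConfig, SimulationConfig
from .engine import ManagementEvent, SimulationResult

#: months of the growing season, October through July
SEASON_MONTHS = (10, 11, 12, 1, 2, 3, 4, 5, 6, 7)

#: relative monthly precipitation weights: wet Oct-Dec, drier Apr-Jul
DEFAULT_PRECIP_WEIGHTS = {10: 1.5, 11: 1.5, 12: 1.4, 1: 1.1, 2: 0.9,
                          3: 0.9, 4: 0.7, 5: 0.7, 6: 0.6, 7: 0.7}

#: soil templates for the two treatments: topsoil measured means
SOIL_TEMPLATES = {
    "control": {"olsen_p": 6.9, "total_p": 373.0, "organic_c_pct": 0.93, "ph": 6.82},
    "p_added": {"olsen_p": 30.6, "total_p": 584.0, "organic_c_pct": 1.05, "ph": 6.6},
}

SEASON_TEMPLATES = {
    2012: {"mean_temp": 7.9, "total_precip": 672.0, "total_sunshine": 1268.0},
    2013: {"mean_temp": 10.1, "total_precip": 814.0, "total_sunshine": 1363.0},
}


@dataclass
class ScenarioSpec:
    """Everything needed to generate one treatment-season fixture."""

    start_year: int = 2012  # season runs Oct(start_year) - Jul(start_year+1)
    mean_temp: float = 7.9  # degC over the season
    total_precip: float = 672.0  # mm over the season
    total_sunshine: float = 1268.0  # h
    precip_weights: Dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PRECIP_WEIGHTS)
    )
    seed: int = 0

    @classmethod
    def season(cls, start_year: int, seed: int = 0) -> "ScenarioSpec":
        t = SEASON_TEMPLATES.get(start_year, SEASON_TEMPLATES[2012])
        return cls(start_year=start_year, mean_temp=t["mean_temp"],
                   total_precip=t["total_precip"], total_sunshine=t["total_sunshine"],
                   seed=seed)


def _season_dates(start_year: int) -> List[Date]:
    d = Date(start_year, 10, 1)
    end = Date(start_year + 1, 7, 31)
    out = []
    while d <= end:
        out.append(d)
        d += timedelta(days=1)
    return out


def generate_weather(spec: ScenarioSpec) -> pd.DataFrame:
    """Daily weather for one Oct-Jul season matching the spec's statistics.

    Temperature: seasonal sinusoid (winter minimum in late January) plus
    AR(1) day-to-day anomalies; rescaled so the realised seasonal mean
    equals ``spec.mean_temp`` exactly.  Precipitation: seeded wet-day
    occurrence and gamma amounts shaped by monthly weights; rescaled to
    ``spec.total_precip``.  tmax >= tmin every day.
    """
    rng = np.random.default_rng(spec.seed)
    dates = _season_dates(spec.start_year)
    n = len(dates)
    doy = np.array([d.timetuple().tm_yday for d in dates], dtype=float)

    seasonal = -np.cos(2.0 * np.pi * (doy - 28.0) / 365.25)  # -1 late Jan, +1 late Jul
    base = 6.0 * seasonal
    anomaly = np.empty(n)
    anomaly[0] = rng.normal(0, 1.5)
    for i in range(1, n):
        anomaly[i] = 0.7 * anomaly[i - 1] + rng.normal(0, 1.5)
    tmean = base + anomaly
    tmean += spec.mean_temp - tmean.mean()  # exact seasonal mean
    diurnal = np.clip(rng.normal(7.0, 1.5, n), 2.0, None)
    tmax = tmean + diurnal / 2.0
    tmin = tmean - diurnal / 2.0

    weights = np.array([spec.precip_weights[d.month] for d in dates])
    wet = rng.random(n) < np.clip(0.45 * weights, 0.05, 0.95)
    amounts = rng.gamma(shape=0.9, scale=5.0, size=n) * weights * wet
    if amounts.sum() <= 0:
        amounts[:] = weights
    precip = amounts * (spec.total_precip / amounts.sum())  # exact seasonal total

    daylen = 12.0 + 4.5 * seasonal
    sun_frac = np.clip(rng.beta(2.0, 2.5, n) + 0.15 * (~wet), 0.0, 1.0)
    sunshine = daylen * sun_frac
    sunshine *= spec.total_sunshine / sunshine.sum()

    return pd.DataFrame({
        "date": [d.isoformat() for d in dates],
        "tmax_C": np.round(tmax, 3),
        "tmin_C": np.round(tmin, 3),
        "precip_mm": np.round(precip, 3),
        "sunshine_h": np.round(sunshine, 3),
    })


#: default split of the non-labile inorganic remainder
INORGANIC_SPLIT = {"precipitated": 0.45, "stable_inorganic": 0.55, "mineral": 0.0}
#: default split of organic P
ORGANIC_SPLIT = {"active_organic": 0.30, "stable_organic": 0.65, "microbial": 0.05}
#: Olsen-P is modelled as soluble + this share of the adsorbed pool
OLSEN_ADSORBED_SHARE = 0.5
#: quasi-equilibrium adsorbed:soluble ratio implied by the default rate constants
ADSORBED_TO_SOLUBLE = 12.0
#: assumed organic matter C:P mass ratio for initialising organic P
ORGANIC_CP = 100.0


def generate_soil(
    spec: ScenarioSpec,
    treatment: str = "control",
    *,
    subsoil_olsen_fraction: float = 0.5,
    jitter_sd_fraction: float = 0.0,
) -> List[LayerConfig]:
    """Two-layer (0-23, 23-46 cm) soil profile for a treatment.

    The template total P is split into the eight pools: the labile pools
    honour the Olsen-P proxy (Olsen ~ soluble + 0.5 * adsorbed, with
    adsorbed/soluble at the sorption quasi-equilibrium ratio), organic P
    comes from organic C at an assumed C:P of 100, and the remainder goes
    to the slow inorganic pools.  Pools sum to the template total exactly.
    With ``jitter_sd_fraction`` > 0 the template means are perturbed by a
    seeded relative Gaussian before splitting.
    """
    if treatment not in SOIL_TEMPLATES:
        raise ValueError(f"unknown treatment {treatment!r}")
    tpl = SOIL_TEMPLATES[treatment]
    rng = np.random.default_rng(spec.seed + 1)
    layers = []
    for li, (top, thick) in enumerate(((0.0, 23.0), (23.0, 23.0))):
        bd = 1.30
        olsen = tpl["olsen_p"] * (1.0 if li == 0 else subsoil_olsen_fraction)
        total = tpl["total_p"] * (1.0 if li == 0 else 0.75)
        oc = tpl["organic_c_pct"] * (1.0 if li == 0 else 0.55)
        if jitter_sd_fraction > 0:
            olsen *= max(0.1, 1.0 + rng.normal(0, jitter_sd_fraction))
            total *= max(0.1, 1.0 + rng.normal(0, jitter_sd_fraction))

        total_kg = units.mg_kg_to_kg_ha(total, bd, thick)
        olsen_kg = units.mg_kg_to_kg_ha(olsen, bd, thick)
        soluble = olsen_kg / (1.0 + OLSEN_ADSORBED_SHARE * ADSORBED_TO_SOLUBLE)
        adsorbed = ADSORBED_TO_SOLUBLE * soluble

        total_c_kg = oc / 100.0 * bd * thick * 1e5  # kg C ha-1
        organic_p = min(total_c_kg / ORGANIC_CP, 0.45 * total_kg)
        remainder = total_kg - soluble - adsorbed - organic_p
        if remainder < 0:  # degenerate template: shrink organic share
            organic_p += remainder
            remainder = 0.0
        pools = {"soluble": soluble, "adsorbed": adsorbed}
        for name, f in ORGANIC_SPLIT.items():
            pools[name] = organic_p * f
        for name, f in INORGANIC_SPLIT.items():
            pools[name] = remainder * f
        layers.append(LayerConfig(
            thickness_cm=thick, bulk_density=bd,
            field_capacity=0.32, wilting_point=0.12, saturation=0.46,
            initial_water=0.28, pools=pools,
            organic_carbon_pct=oc, olsen_p_mg_kg=olsen,
        ))
    return layers


def generate_management(spec: ScenarioSpec, treatment: str = "control") -> List[ManagementEvent]:
    """Season management calendar for one treatment.

    The P-added treatment gets one autumn application of 15 kg P ha-1 as
    triple superphosphate incorporated before sowing; both treatments get
    300 kg N ha-1 split 50/200/50 over March, April and May, sowing in
    October and harvest at the end of July.
    """
    y0, y1 = spec.start_year, spec.start_year + 1
    events = []
    if treatment == "p_added":
        events.append(ManagementEvent(Date(y0, 10, 5), "fertilise_P", 15.0,
                                      "triple_superphosphate"))
    events.append(ManagementEvent(Date(y0, 10, 10), "sow"))
    for month, amount in ((3, 50.0), (4, 200.0), (5, 50.0)):
        events.append(ManagementEvent(Date(y1, month, 15), "fertilise_N", amount))
    events.append(ManagementEvent(Date(y1, 7, 25), "harvest"))
    return events


def build_scenario(
    treatment: str = "control",
    start_years: tuple = (2012, 2013),
    seed: int = 0,
) -> tuple:
    """(config, weather, events) for a multi-season run of one treatment."""
    spec0 = ScenarioSpec.season(start_years[0], seed=seed)
    layers = generate_soil(spec0, treatment)
    config = SimulationConfig(layers=layers)
    frames, events = [], []
    for y in start_years:
        spec = ScenarioSpec.season(y, seed=seed + (y - start_years[0]))
        frames.append(generate_weather(spec))
        events.extend(generate_management(spec, treatment))
    weather = pd.concat(frames, ignore_index=True)
    # bridge the Aug-Sep gap between seasons with a simple summer fill
    weather = _fill_gaps(weather)
    return config, weather, events


def _fill_gaps(weather: pd.DataFrame) -> pd.DataFrame:
    """Make the date series contiguous, filling gaps with mild dry weather."""
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.date
    w = w.sort_values("date").reset_index(drop=True)
    rows = [w.iloc[0].to_dict()]
    for i in range(1, len(w)):
        prev = rows[-1]["date"]
        cur = w.iloc[i]["date"]
        d = prev + timedelta(days=1)
        while d < cur:
            rows.append({"date": d, "tmax_C": 19.0, "tmin_C": 10.0,
                         "precip_mm": 1.5, "sunshine_h": 6.0})
            d += timedelta(days=1)
        rows.append(w.iloc[i].to_dict())
    out = pd.DataFrame(rows)
    out["date"] = out["date"].astype(str)
    return out


def generate_pseudo_obs(
    sim: SimulationResult,
    column: str = "aboveground_dm",
    noise_sd_fraction: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    every: int = 28,
) -> pd.DataFrame:
    """Pseudo-observations: replicated noisy subsamples of a simulated series.

    Samples the daily series every ``every`` days and perturbs each value
    into ``n_reps`` replicates with multiplicative lognormal noise of
    relative scale ``noise_sd_fraction``.  With zero noise, evaluating the
    simulation against its own pseudo-observations returns the
    perfect-agreement statistics block (r=1, EF=1, CD=1, RE=0, RMSE=0).
    """
    if n_reps < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(seed)
    sub = sim.daily.iloc[::every]
    rows = []
    for _, row in sub.iterrows():
        base = float(row[column])
        for rep in range(n_reps):
            noise = rng.lognormal(0.0, noise_sd_fraction) if noise_sd_fraction > 0 else 1.0
            rows.append({"date": row["date"], "rep": rep + 1, "value": base * noise})
    return pd.DataFrame(rows)
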