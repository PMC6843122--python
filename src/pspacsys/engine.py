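"""Daily simulation loop: drivers, management, pools, uptake, plant growth.

The engine advances one day at a time in a fixed order — weather-derived
drivers, management events, organic-matter decomposition and
mineralisation/immobilisation, inorganic pool transfers, root P uptake,
plant growth and partitioning, then leaching — so that uptake always sees
the post-transfer soluble pool.  The soil water and temperature drivers
are deliberately simple (tipping-bucket cascade, damped/lagged running
mean) and sit behind a seam so fuller physics can replace them.

A whole-run P balance is tracked:

    soil + plant + leached + harvested = initial soil + fertiliser + seed P

and closes to numerical precision; :meth:`SimulationResult.balance_error`
reports the relative residual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date as Date
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import units
from .config import SimulationConfig
from .plant import (
    EnvResponse,
    GrowthDriver,
    OrganicPool,
    PlantState,
    decomposition_rate,
    partition_uptake,
    remobilise_to_grain,
    zadoks_stage,
)
from .pools import (
    FluxRecord,
    LayerEnvironment,
    PoolState,
    apply_fertiliser,
    leach_soluble,
    mineralise_immobilise,
    moisture_response,
    step_pools,
    temperature_response,
)
from .uptake import uptake_per_layer

WEATHER_COLUMNS = ("date", "tmax_C", "tmin_C", "precip_mm", "sunshine_h")


class InputError(ValueError):
    pass


@dataclass
class ManagementEvent:
    date: Date
    kind: str  # sow | fertilise_P | fertilise_N | harvest
    amount: float = 0.0
    form: str = "triple_superphosphate"

    KINDS = ("sow", "fertilise_P", "fertilise_N", "harvest")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise InputError(f"unknown management kind {self.kind!r}")
        if self.amount < 0:
            raise InputError("event amount must be >= 0")


@dataclass
class DailyDrivers:
    """Weather for one day plus derived per-layer soil physics."""

    date: Date
    tmax: float
    tmin: float
    precipitation: float
    sunshine: float
    soil_temperature: List[float] = field(default_factory=list)  # degC per layer
    volumetric_water: List[float] = field(default_factory=list)  # per layer
    drainage: List[float] = field(default_factory=list)  # mm d-1 leaving each layer

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise InputError(f"{self.date}: tmax < tmin")
        if self.precipitation < 0:
            raise InputError(f"{self.date}: negative precipitation")

    @property
    def tmean(self) -> float:
        return 0.5 * (self.tmax + self.tmin)


def check_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Validate the weather frame: columns present, dates contiguous."""
    missing = [c for c in WEATHER_COLUMNS if c not in weather.columns]
    if missing:
        raise InputError(f"weather missing columns: {missing}")
    w = weather.copy()
    w["date"] = pd.to_datetime(w["date"]).dt.date
    w = w.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(w["date"])
    gaps = dates.diff().dt.days.iloc[1:]
    bad = gaps[gaps != 1]
    if len(bad):
        gap_list = [str(w["date"].iloc[i]) for i in bad.index[:10]]
        raise InputError(f"weather series has gaps before: {gap_list}")
    return w


# ---------------------------------------------------------------------------
# simplified physical drivers


def reference_et(tmax: float, tmin: float, doy: int, latitude_deg: float) -> float:
    """Hargreaves-Samani reference evapotranspiration, mm d-1.

    Uses extraterrestrial radiation from latitude and day of year; a
    temperature-only stand-in for a full Penman-Monteith calculation.
    """
    lat = math.radians(latitude_deg)
    dr = 1 + 0.033 * math.cos(2 * math.pi * doy / 365)
    decl = 0.409 * math.sin(2 * math.pi * doy / 365 - 1.39)
    x = -math.tan(lat) * math.tan(decl)
    ws = math.acos(min(1.0, max(-1.0, x)))
    ra = (
        24 * 60 / math.pi * 0.0820 * dr
        * (ws * math.sin(lat) * math.sin(decl) + math.cos(lat) * math.cos(decl) * math.sin(ws))
    )  # MJ m-2 d-1
    ra_mm = 0.408 * ra
    tmean = 0.5 * (tmax + tmin)
    et = 0.0023 * ra_mm * (tmean + 17.8) * math.sqrt(max(tmax - tmin, 0.0))
    return max(et, 0.0)


def water_driver(
    weather: pd.DataFrame, config: SimulationConfig
) -> Tuple[np.ndarray, np.ndarray]:
    """Tipping-bucket water balance over the whole weather series.

    Rain fills layers toward saturation from the top; water held above
    field capacity drains to the next layer (or out of the profile) at
    ``drainage_coefficient`` per day; evapotranspiration (Hargreaves
    reference ET times a crop coefficient) is drawn from the layers
    weighted toward the surface, limited by a moisture-stress factor.

    Returns (theta, drainage): arrays of shape (n_days, n_layers) with
    volumetric water and the water flux (mm d-1) leaving each layer's
    bottom.
    """
    layers = config.layers
    n_days, n_layers = len(weather), len(layers)
    theta = np.empty((n_days, n_layers))
    drainage = np.zeros((n_days, n_layers))
    store = np.array([l.initial_water * l.thickness_cm * 10.0 for l in layers])  # mm
    cap_sat = np.array([l.saturation * l.thickness_cm * 10.0 for l in layers])
    cap_fc = np.array([l.field_capacity * l.thickness_cm * 10.0 for l in layers])
    cap_wp = np.array([l.wilting_point * l.thickness_cm * 10.0 for l in layers])
    et_weights = np.array([0.75] + [0.25 / max(n_layers - 1, 1)] * (n_layers - 1))[:n_layers]
    et_weights /= et_weights.sum()
    kd = config.engine.drainage_coefficient

    dates = pd.to_datetime(weather["date"])
    for i in range(n_days):
        row = weather.iloc[i]
        # evapotranspiration demand
        doy = int(dates.iloc[i].dayofyear)
        et0 = reference_et(row["tmax_C"], row["tmin_C"], doy, config.engine.latitude_deg) \
            * config.engine.crop_coefficient
        for j in range(n_layers):
            avail = store[j] - cap_wp[j]
            span = cap_fc[j] - cap_wp[j]
            stress = min(1.0, max(0.0, avail / span)) if span > 0 else 0.0
            take = min(et0 * et_weights[j] * stress, max(avail, 0.0))
            store[j] -= take
        # downward cascade: rain infiltrates the top layer; each layer sheds
        # instantaneous overflow above saturation plus kd * (water above FC)
        carry = float(row["precip_mm"])
        for j in range(n_layers):
            store[j] += carry
            overflow = max(0.0, store[j] - cap_sat[j])
            store[j] -= overflow
            out = kd * max(0.0, store[j] - cap_fc[j])
            store[j] -= out
            carry = overflow + out
            drainage[i, j] = carry
        theta[i] = store / (np.array([l.thickness_cm for l in layers]) * 10.0)
    return theta, drainage


def soil_temperature_driver(
    weather: pd.DataFrame, depths_cm: List[float], config: SimulationConfig
) -> np.ndarray:
    """Damped, lagged soil temperature per layer from air temperature.

    The air-temperature running mean (``temp_running_mean_days``) is
    filtered per layer with an exponential smoother whose gain decreases
    with depth (exp(-z/damping_depth)), so amplitude decreases and lag
    increases with depth; at depth 0 the soil temperature equals the
    running mean itself.
    """
    tmean = (weather["tmax_C"].to_numpy() + weather["tmin_C"].to_numpy()) / 2.0
    k = max(int(config.engine.temp_running_mean_days), 1)
    kernel = np.ones(k) / k
    padded = np.concatenate([np.full(k - 1, tmean[0]), tmean])
    running = np.convolve(padded, kernel, mode="valid")
    out = np.empty((len(tmean), len(depths_cm)))
    for j, z in enumerate(depths_cm):
        alpha = math.exp(-z / config.engine.damping_depth_cm)
        t = running[0]
        for i in range(len(tmean)):
            t = t + alpha * (running[i] - t)
            out[i, j] = t
    return out


# ---------------------------------------------------------------------------
# results container


@dataclass
class SimulationResult:
    daily: pd.DataFrame
    fluxes: pd.DataFrame  # date, layer, source_pool, sink_pool, flux_kgP_ha_d
    events: List[ManagementEvent]
    final_pools: List[PoolState]
    harvested: List[Dict[str, float]]
    balance: Dict[str, float]

    def balance_error(self) -> float:
        """Relative P-balance residual over the whole run."""
        b = self.balance
        inputs = b["initial_soil"] + b["fertiliser"] + b["seed"]
        final = b["final_soil"] + b["plant"] + b["leached"] + b["harvested"]
        return abs(final - inputs) / max(inputs, 1e-12)

    def summary(self) -> Dict[str, float]:
        last = self.daily.iloc[-1]
        return {
            "days": int(len(self.daily)),
            "final_aboveground_dm_g_m2": float(last["aboveground_dm"]),
            "final_grain_dm_g_m2": float(last["grain_dm"]),
            "total_p_uptake_kg_ha": float(self.daily["uptake_kg_ha"].sum()),
            "total_leached_kg_ha": float(self.balance["leached"]),
            "harvests": len(self.harvested),
            "p_balance_rel_error": self.balance_error(),
        }

    def write(self, outdir) -> None:
        import json
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.daily.to_csv(out / "daily.csv", index=False)
        self.fluxes.to_csv(out / "fluxes.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)


# ---------------------------------------------------------------------------
# main loop


def run_simulation(
    config: SimulationConfig,
    weather: pd.DataFrame,
    events: List[ManagementEvent],
) -> SimulationResult:
    """Run the daily P-cycling simulation over the weather window.

    Deterministic: identical config, weather and events give bit-identical
    results.  Daily order: drivers -> management -> decomposition and
    mineralisation -> inorganic pool transfers -> root uptake -> plant
    growth/partitioning/remobilisation -> leaching -> outputs.
    """
    config.validate()
    weather = check_weather(weather)
    events = sorted(events, key=lambda e: e.date)
    events_by_date: Dict[Date, List[ManagementEvent]] = {}
    for ev in events:
        events_by_date.setdefault(ev.date, []).append(ev)

    layers = config.layers
    n_layers = len(layers)
    depths = []
    z = 0.0
    for l in layers:
        depths.append(z + l.thickness_cm / 2.0)
        z += l.thickness_cm

    theta_series, drain_series = water_driver(weather, config)
    tsoil_series = soil_temperature_driver(weather, depths, config)

    pool_states = [l.initial_pool_state() for l in layers]
    initial_soil = sum(s.total for s in pool_states)
    # organic C stocks per layer, g C m-2 (active / stable / microbial split)
    carbon = []
    for l in layers:
        total_c = l.organic_carbon_pct / 100.0 * l.bulk_density * l.thickness_cm * 1e4  # gC m-2
        carbon.append({"active": 0.12 * total_c, "stable": 0.85 * total_c,
                      "microbial": 0.03 * total_c})

    eng = config.engine
    growth = GrowthDriver(
        mu=config.crop.mu, dm_max=config.crop.dm_max,
        initial_dm=config.crop.seed_dm, initial_p_conc=config.crop.seed_p_conc,
    )
    plant: Optional[PlantState] = None
    thermal_time = 0.0
    cumulative = {"fertiliser": 0.0, "leached": 0.0, "seed": 0.0, "harvested_p": 0.0}
    harvested: List[Dict[str, float]] = []
    daily_rows = []
    flux_rows = []

    for i in range(len(weather)):
        row = weather.iloc[i]
        day = row["date"]
        drv = DailyDrivers(
            date=day, tmax=float(row["tmax_C"]), tmin=float(row["tmin_C"]),
            precipitation=float(row["precip_mm"]), sunshine=float(row["sunshine_h"]),
            soil_temperature=list(tsoil_series[i]),
            volumetric_water=list(theta_series[i]),
            drainage=list(drain_series[i]),
        )
        envs = [
            LayerEnvironment(
                soil_temperature=drv.soil_temperature[j],
                volumetric_water=min(drv.volumetric_water[j], layers[j].saturation),
                layer_thickness=layers[j].thickness_cm,
                bulk_density=layers[j].bulk_density,
                drainage_flux=drv.drainage[j],
                saturation=layers[j].saturation,
            )
            for j in range(n_layers)
        ]

        # --- management ---------------------------------------------------
        for ev in events_by_date.get(day, []):
            if ev.kind == "sow":
                plant = growth.new_plant(
                    p_opt=config.crop.p_opt, p_min=config.crop.p_min,
                    remobilisation_rate=config.crop.remobilisation_rate,
                    structural_p_fraction=config.crop.structural_p_fraction,
                )
                thermal_time = 0.0
                cumulative["seed"] += plant.total_p * units.G_M2_TO_KG_HA
            elif ev.kind == "fertilise_P":
                pool_states[0] = apply_fertiliser(pool_states[0], ev.amount, ev.form)
                cumulative["fertiliser"] += ev.amount
            elif ev.kind == "fertilise_N":
                pass  # N supply is non-limiting in this stub
            elif ev.kind == "harvest" and plant is not None:
                above_p = sum(plant.p_content[o] for o in ("leaf", "stem", "grain"))
                harvested.append({
                    "date": day,
                    "aboveground_dm": plant.aboveground_dm,
                    "grain_dm": plant.dry_matter["grain"],
                    "aboveground_p_g_m2": above_p,
                    "grain_p_g_m2": plant.p_content["grain"],
                })
                cumulative["harvested_p"] += above_p * units.G_M2_TO_KG_HA
                # roots (and their P) return to the topsoil active organic pool
                root_p_kg_ha = plant.p_content["root"] * units.G_M2_TO_KG_HA
                pool_states[0].active_organic += root_p_kg_ha
                carbon[0]["active"] += 0.45 * plant.dry_matter["root"]
                plant = None

        # --- decomposition and mineralisation/immobilisation ---------------
        for j in range(n_layers):
            env = envs[j]
            resp = EnvResponse(
                ftemp=min(1.0, temperature_response(env.soil_temperature)),
                fwater=moisture_response(env.volumetric_water, env.saturation),
            )
            state = pool_states[j]
            cstock = carbon[j]
            assim = 0.0
            for cname, pool_attr, kmax in (
                ("active", "active_organic", eng.kmax_active),
                ("stable", "stable_organic", eng.kmax_stable),
            ):
                org = OrganicPool(
                    carbon=cstock[cname],
                    nitrogen=cstock[cname] / (layers[j].cn_active if cname == "active"
                                              else layers[j].cn_stable),
                    phosphorus=getattr(state, pool_attr) * units.KG_HA_TO_G_M2,
                    kmax=kmax,
                )
                d_c, _, d_p = decomposition_rate(org, resp, force_fcp_one=eng.force_fcp_one)
                d_p_kg = min(d_p * units.G_M2_TO_KG_HA, getattr(state, pool_attr))
                cstock[cname] -= d_c
                cstock["microbial"] += eng.assimilation_efficiency * d_c
                assim += eng.assimilation_efficiency * d_c
                setattr(state, pool_attr, getattr(state, pool_attr) - d_p_kg)
                state.microbial += d_p_kg
                if d_p_kg:
                    flux_rows.append((day, j, pool_attr, "microbial", d_p_kg))
            # microbial turnover back to active organic matter
            org_m = OrganicPool(
                carbon=cstock["microbial"],
                nitrogen=cstock["microbial"] / 8.0,
                phosphorus=state.microbial * units.KG_HA_TO_G_M2,
                kmax=eng.kmax_microbial,
            )
            d_c, _, d_p = decomposition_rate(org_m, resp, force_fcp_one=eng.force_fcp_one)
            d_p_kg = min(d_p * units.G_M2_TO_KG_HA, state.microbial)
            cstock["microbial"] -= d_c
            cstock["active"] += eng.humification_fraction * d_c
            state.microbial -= d_p_kg
            state.active_organic += d_p_kg
            if d_p_kg:
                flux_rows.append((day, j, "microbial", "active_organic", d_p_kg))
            # net mineralisation: restore microbial biomass C:P toward target
            target_p = cstock["microbial"] / eng.microbial_cp * units.G_M2_TO_KG_HA
            net_min = state.microbial - target_p  # kg P ha-1 d-1 (full adjustment)
            state, mm_ledger = mineralise_immobilise(state, net_min, env)
            pool_states[j] = state
            for rec in mm_ledger:
                flux_rows.append((day, j, rec.source, rec.sink, rec.flux))

        # --- inorganic pool transfers --------------------------------------
        for j in range(n_layers):
            pool_states[j], ledger = step_pools(pool_states[j], config.transfer_rates, envs[j])
            for rec in ledger:
                if rec.flux:
                    flux_rows.append((day, j, rec.source, rec.sink, rec.flux))

        # --- root uptake ----------------------------------------------------
        uptake_total = 0.0
        fp_today = float("nan")
        if plant is not None:
            root_dm = plant.dry_matter["root"]
            # luxury-uptake ceiling: the plant downregulates uptake once its
            # whole-plant P concentration reaches p_max_conc
            demand_cap = max(
                0.0,
                config.crop.p_max_conc * plant.total_dm - plant.total_p,
            ) * units.G_M2_TO_KG_HA
            for j in range(n_layers):
                if uptake_total >= demand_cap:
                    break
                frac = config.crop.root_layer_fractions[j]
                rld = root_dm * config.crop.specific_root_length * frac / (
                    100.0 * layers[j].thickness_cm
                )
                if rld <= 0:
                    continue
                got = uptake_per_layer(rld, envs[j], pool_states[j], config.uptake)
                got = min(got, pool_states[j].soluble, demand_cap - uptake_total)
                pool_states[j].soluble -= got
                uptake_total += got
                if got:
                    flux_rows.append((day, j, "soluble", "plant", got))

            # --- plant growth, partitioning, remobilisation ----------------
            thermal_time += max(0.0, drv.tmean - growth.t_base)
            plant.growth_stage = zadoks_stage(thermal_time)
            fp_today = 1.0 if eng.force_fp_one else plant.photosynthesis_factor()
            plant = growth.grow(plant, drv.tmean, force_fp_one=eng.force_fp_one)
            plant = partition_uptake(uptake_total * units.KG_HA_TO_G_M2, plant)
            plant = remobilise_to_grain(plant)

        # --- leaching cascade ----------------------------------------------
        leached_from = 0.0
        for j in range(n_layers):
            if leached_from:
                pool_states[j].soluble += leached_from
            pool_states[j], leached_from = leach_soluble(
                pool_states[j], envs[j], mobile_fraction=eng.leachable_fraction
            )
            if leached_from:
                flux_rows.append((day, j, "soluble", "leachate", leached_from))
        cumulative["leached"] += leached_from  # exits the profile bottom

        # --- outputs --------------------------------------------------------
        soil_total = sum(s.total for s in pool_states)
        rec = {
            "date": day,
            "tmean_C": drv.tmean,
            "precip_mm": drv.precipitation,
            "soil_total_p": soil_total,
            "uptake_kg_ha": uptake_total,
            "plant_p_g_m2": plant.total_p if plant is not None else 0.0,
            "aboveground_dm": plant.aboveground_dm if plant is not None else 0.0,
            "grain_dm": plant.dry_matter["grain"] if plant is not None else 0.0,
            "leaf_p_conc": plant.leaf_p_concentration if plant is not None else 0.0,
            "growth_stage": plant.growth_stage if plant is not None else 0.0,
            "fp": fp_today,
        }
        for j in range(n_layers):
            rec[f"theta_{j}"] = drv.volumetric_water[j]
            rec[f"tsoil_{j}"] = drv.soil_temperature[j]
            rec[f"soluble_{j}"] = pool_states[j].soluble
            rec[f"olsen_proxy_{j}"] = pool_states[j].soluble + 0.5 * pool_states[j].adsorbed
        daily_rows.append(rec)

    daily = pd.DataFrame(daily_rows)
    fluxes = pd.DataFrame(
        flux_rows, columns=["date", "layer", "source_pool", "sink_pool", "flux_kgP_ha_d"]
    )
    balance = {
        "initial_soil": initial_soil,
        "fertiliser": cumulative["fertiliser"],
        "seed": cumulative["seed"],
        "final_soil": sum(s.total for s in pool_states),
        "plant": (plant.total_p * units.G_M2_TO_KG_HA) if plant is not None else 0.0,
        "leached": cumulative["leached"],
        "harvested": cumulative["harvested_p"],
    }
    return SimulationResult(
        daily=daily, fluxes=fluxes, events=events,
        final_pools=pool_states, harvested=harvested, balance=balance,
    )
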