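"""Eight-pool soil phosphorus state and daily pool-to-pool transfer processes.

Soil P in each layer is partitioned by accessibility and extractability into
eight pools: soluble (solution + readily desorbable, immediately
plant-available), adsorbed, precipitated, stable inorganic, active organic,
stable organic, microbial, and mineral P.  Inorganic transformations are
reversible; mineral P dissolves to soluble P; organic pools decompose into
the microbial pool, which exchanges with mineral P through
mineralisation/immobilisation.

All transfers are first-order (donor-proportional) kinetics, each with a
rate constant (d-1) and an optional cap on the daily flux
(kg P ha-1 d-1), scaled by temperature and moisture response factors.
Integration is explicit Euler with automatic sub-stepping and per-substep
clamping of fluxes to donor availability, so pools can never go negative
and total P is conserved by internal transfers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Dict, Iterable, List, Tuple

POOL_NAMES = (
    "soluble",
    "adsorbed",
    "precipitated",
    "stable_inorganic",
    "active_organic",
    "stable_organic",
    "microbial",
    "mineral",
)

#: pool pairs connected in the default cycle topology (source, sink)
DEFAULT_TOPOLOGY = (
    ("soluble", "adsorbed"),
    ("adsorbed", "soluble"),
    ("soluble", "precipitated"),
    ("precipitated", "soluble"),
    ("adsorbed", "stable_inorganic"),
    ("stable_inorganic", "adsorbed"),
    ("precipitated", "stable_inorganic"),
    ("stable_inorganic", "precipitated"),
    ("mineral", "soluble"),  # dissolution
    ("active_organic", "microbial"),
    ("stable_organic", "microbial"),
    ("active_organic", "stable_organic"),
    ("stable_organic", "active_organic"),
    ("microbial", "active_organic"),  # microbial turnover
)


class ConfigurationError(ValueError):
    """Invalid pool-transfer configuration (bad rate, unknown pool/form)."""


@dataclass
class PoolState:
    """Per-layer P pool masses, kg P ha-1."""

    soluble: float = 0.0
    adsorbed: float = 0.0
    precipitated: float = 0.0
    stable_inorganic: float = 0.0
    active_organic: float = 0.0
    stable_organic: float = 0.0
    microbial: float = 0.0
    mineral: float = 0.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v < 0:
                raise ValueError(f"pool {f.name!r} negative: {v}")

    @property
    def total(self) -> float:
        return sum(getattr(self, name) for name in POOL_NAMES)

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, name) for name in POOL_NAMES}

    def copy(self) -> "PoolState":
        return replace(self)


@dataclass
class TransferRates:
    """First-order rate constants (d-1) and flux caps for active pool pairs.

    Pairs absent from ``rates`` are inactive (zero flux).  ``caps`` bounds the
    daily flux for a pair in kg P ha-1 d-1; pairs without a cap are unbounded.
    """

    rates: Dict[Tuple[str, str], float] = field(default_factory=dict)
    caps: Dict[Tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (src, dst), k in self.rates.items():
            if src not in POOL_NAMES or dst not in POOL_NAMES:
                raise ConfigurationError(f"unknown pool in pair {(src, dst)}")
            if src == dst:
                raise ConfigurationError(f"self-transfer {src!r}")
            if k < 0:
                raise ConfigurationError(f"negative rate constant for {(src, dst)}: {k}")
        for pair, cap in self.caps.items():
            if cap < 0:
                raise ConfigurationError(f"negative cap for {pair}: {cap}")

    @classmethod
    def from_dict(cls, mapping: Dict[str, float]) -> "TransferRates":
        """Build from flat keys of the form ``"source->sink"``."""
        rates = {}
        for key, k in mapping.items():
            src, _, dst = key.partition("->")
            rates[(src.strip(), dst.strip())] = float(k)
        return cls(rates=rates)

    def active_pairs(self) -> Iterable[Tuple[str, str]]:
        return (pair for pair, k in self.rates.items() if k > 0)


@dataclass
class LayerEnvironment:
    """Physical state of one soil layer for a day."""

    soil_temperature: float = 20.0  # degC
    volumetric_water: float = 0.30  # cm3 cm-3
    layer_thickness: float = 23.0  # cm
    bulk_density: float = 1.3  # g cm-3
    drainage_flux: float = 0.0  # mm d-1
    saturation: float = 0.50  # cm3 cm-3

    def __post_init__(self) -> None:
        if self.layer_thickness <= 0:
            raise ValueError("layer thickness must be positive")
        if not (0.0 <= self.volumetric_water <= self.saturation + 1e-12):
            raise ValueError(
                f"volumetric water {self.volumetric_water} outside [0, saturation]"
            )

    @property
    def water_depth_mm(self) -> float:
        """Water stored in the layer, mm."""
        return self.volumetric_water * self.layer_thickness * 10.0

    @classmethod
    def reference(cls) -> "LayerEnvironment":
        """Reference conditions under which rate modifiers equal 1."""
        return cls()


@dataclass
class FluxRecord:
    source: str
    sink: str
    flux: float  # kg P ha-1 over the step


def temperature_response(soil_temp: float, q10: float = 2.0, t_ref: float = 20.0) -> float:
    """Q10 response, = 1 at the reference temperature; clipped at 0 below -10 degC."""
    if soil_temp < -10.0:
        return 0.0
    return q10 ** ((soil_temp - t_ref) / 10.0)


def moisture_response(
    theta: float,
    saturation: float = 0.50,
    wfps_lo: float = 0.2,
    wfps_opt_lo: float = 0.5,
    wfps_opt_hi: float = 0.85,
    wfps_hi: float = 1.0,
) -> float:
    """Trapezoidal response to water-filled pore space, in [0, 1].

    The default reference environment (theta=0.30, saturation=0.50) sits at
    WFPS 0.6, inside the optimum plateau, so the modifier is exactly 1 there.
    """
    if saturation <= 0:
        return 0.0
    wfps = min(max(theta / saturation, 0.0), 1.0)
    if wfps <= wfps_lo or wfps >= wfps_hi:
        return 0.0 if wfps <= wfps_lo else max(
            0.0, (wfps_hi - wfps) / max(wfps_hi - wfps_opt_hi, 1e-12)
        )
    if wfps < wfps_opt_lo:
        return (wfps - wfps_lo) / (wfps_opt_lo - wfps_lo)
    if wfps <= wfps_opt_hi:
        return 1.0
    return (wfps_hi - wfps) / (wfps_hi - wfps_opt_hi)


def _env_modifier(env: LayerEnvironment) -> float:
    return temperature_response(env.soil_temperature) * moisture_response(
        env.volumetric_water, env.saturation
    )


def step_pools(
    state: PoolState,
    rates: TransferRates,
    env: LayerEnvironment,
    dt: float = 1.0,
    *,
    max_rate_dt: float = 0.02,
) -> Tuple[PoolState, List[FluxRecord]]:
    """Advance all first-order pool transfers over ``dt`` days.

    Explicit Euler with automatic sub-stepping: the step is subdivided so
    that no (modified) rate constant times the substep exceeds
    ``max_rate_dt`` (0.02 keeps the first-order discretisation error of a
    daily step under 1% for rate constants up to 0.5 d-1).  Within each substep, outgoing fluxes from a pool are
    jointly scaled down if they would overdraw it, so no pool goes negative
    and the clamped donor lands exactly at zero.

    Returns the new state and a ledger of the summed flux for every active
    pool pair.  Total P is conserved exactly (transfers are internal).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    mod = _env_modifier(env)
    vals = {name: getattr(state, name) for name in POOL_NAMES}
    pairs = [(pair, rates.rates[pair] * mod) for pair in rates.rates]
    ledger_totals: Dict[Tuple[str, str], float] = {pair: 0.0 for pair, _ in pairs}

    max_k = max((k for _, k in pairs), default=0.0)
    n_sub = max(1, math.ceil(max_k * dt / max_rate_dt)) if max_k > 0 else 1
    h = dt / n_sub

    for _ in range(n_sub):
        # proposed fluxes this substep
        proposed: Dict[Tuple[str, str], float] = {}
        outflow: Dict[str, float] = {name: 0.0 for name in POOL_NAMES}
        for (src, dst), k in pairs:
            f = k * vals[src] * h
            cap = rates.caps.get((src, dst))
            if cap is not None:
                f = min(f, cap * h)
            proposed[(src, dst)] = f
            outflow[src] += f
        # clamp jointly to donor availability
        scale = {
            name: (vals[name] / outflow[name]) if outflow[name] > vals[name] else 1.0
            for name in POOL_NAMES
        }
        for (src, dst), f in proposed.items():
            f *= scale[src]
            if f == 0.0:
                continue
            vals[src] -= f
            vals[dst] += f
            ledger_totals[(src, dst)] += f
        for name in POOL_NAMES:  # guard against roundoff undershoot
            if vals[name] < 0.0:
                vals[name] = 0.0

    new_state = PoolState(**vals)
    ledger = [FluxRecord(src, dst, f) for (src, dst), f in ledger_totals.items()]
    return new_state, ledger


FERTILISER_FORMS = ("triple_superphosphate", "manure")


def apply_fertiliser(
    state: PoolState,
    amount: float,
    form: str = "triple_superphosphate",
    *,
    manure_soluble_fraction: float = 0.4,
) -> PoolState:
    """Add fertiliser P to the receiving pools.

    Triple superphosphate is fully water-soluble: all of it enters the
    soluble pool.  Manure is split between soluble and active organic P by
    ``manure_soluble_fraction``.  Total P increases by exactly ``amount``.
    """
    if amount < 0:
        raise ValueError(f"fertiliser amount must be >= 0, got {amount}")
    if form not in FERTILISER_FORMS:
        raise ConfigurationError(f"unknown fertiliser form {form!r}")
    if amount == 0:
        return state.copy()
    new = state.copy()
    if form == "triple_superphosphate":
        new.soluble += amount
    else:
        new.soluble += amount * manure_soluble_fraction
        new.active_organic += amount * (1.0 - manure_soluble_fraction)
    return new


def leach_soluble(
    state: PoolState, env: LayerEnvironment, *, mobile_fraction: float = 1.0
) -> Tuple[PoolState, float]:
    """Leach soluble P with drainage water, complete-mixing proportionality.

    leached = soluble * (drainage leaving the layer / layer water volume),
    capped at the whole soluble pool.  The caller routes the leachate to the
    layer below or out of the profile.  ``mobile_fraction`` scales the share
    of the soluble (labile) pool that actually travels with water — at the
    default of 1 the whole pool is mobile; the engine passes the solution
    share (~1/buffer power) since most of the labile pool rides on the solid
    phase.
    """
    if env.drainage_flux < 0:
        raise ValueError("drainage flux must be >= 0")
    if not (0.0 <= mobile_fraction <= 1.0):
        raise ValueError("mobile_fraction must be in [0, 1]")
    if env.drainage_flux == 0:
        return state.copy(), 0.0
    water = env.water_depth_mm
    if water <= 0:
        raise ArithmeticError("nonzero drainage through a layer holding no water")
    frac = min(env.drainage_flux / water, 1.0) * mobile_fraction
    leached = state.soluble * frac
    new = state.copy()
    new.soluble -= leached
    if new.soluble < 0:
        new.soluble = 0.0
    return new, leached


def mineralise_immobilise(
    state: PoolState,
    net_mineralisation: float,
    env: LayerEnvironment,
    dt: float = 1.0,
) -> Tuple[PoolState, List[FluxRecord]]:
    """Exchange P between the microbial and mineral pools.

    ``net_mineralisation`` (kg P ha-1 d-1) is the net P release computed from
    the coupled organic-matter decomposition: positive means microbes release
    P to the mineral pool, negative means immobilisation of mineral P into
    microbial biomass.  Fluxes are capped by the donor pool.
    """
    new = state.copy()
    amount = net_mineralisation * dt
    ledger: List[FluxRecord] = []
    if amount == 0.0:
        return new, ledger
    if amount > 0:
        f = min(amount, new.microbial)
        new.microbial -= f
        new.mineral += f
        if f:
            ledger.append(FluxRecord("microbial", "mineral", f))
    else:
        f = min(-amount, new.mineral)
        new.mineral -= f
        new.microbial += f
        if f:
            ledger.append(FluxRecord("mineral", "microbial", f))
    return new, ledger


def default_transfer_rates() -> TransferRates:
    """Default rate constants (d-1) for the cycle topology.

    Sorption/desorption are fast relative to occlusion into stable forms;
    dissolution of mineral (fertiliser-derived) P is fast.  Values are
    order-of-magnitude defaults in the range used by field-scale P models
    and are all overridable in config.
    """
    k = {
        ("soluble", "adsorbed"): 0.06,
        ("adsorbed", "soluble"): 0.005,
        ("soluble", "precipitated"): 5e-4,
        ("precipitated", "soluble"): 5e-5,
        ("adsorbed", "stable_inorganic"): 1e-4,
        ("stable_inorganic", "adsorbed"): 1e-5,
        ("precipitated", "stable_inorganic"): 1e-4,
        ("stable_inorganic", "precipitated"): 1e-5,
        ("mineral", "soluble"): 0.2,
        ("active_organic", "stable_organic"): 0.0015,
        ("stable_organic", "active_organic"): 0.0002,
    }
    return TransferRates(rates=k)
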