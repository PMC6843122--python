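"""P coupling to organic-matter decomposition and crop growth.

Three response functions link soil/plant P status to rates elsewhere in
the model:

* decomposition of an organic-matter pool is scaled by the minimum of a
  C:N and a C:P stoichiometric factor (on top of temperature and moisture
  responses) — nutrient-poor litter decomposes more slowly;
* the leaf light-saturated photosynthetic rate is scaled by a
  piecewise-linear function of leaf P concentration between a variety-
  specific minimum (photosynthesis ceases) and optimum (no limitation);
* absorbed P is partitioned to organs with growth-stage-dependent
  coefficients, and after anthesis vegetative P is remobilised to grain
  at a constant relative rate.

The host crop-growth model here is a deliberately minimal logistic /
thermal-time driver: daily assimilation follows a logistic curve in
accumulated biomass, multiplied by a temperature response and by the leaf-P
factor.  It stands in for a full canopy photosynthesis model and exists so
that the P feedback has a growth process to act on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# stoichiometric and leaf-P response functions


def f_cn(cn_ratio: float) -> float:
    """C:N response of decomposition: 1 below 25, exponential decay above.

    f = 1                      for C:N < 25
    f = exp(-0.693*(CN-25)/25) for C:N >= 25   (continuous at 25)
    """
    if cn_ratio <= 0:
        raise ValueError(f"C:N ratio must be positive, got {cn_ratio}")
    if cn_ratio < 25.0:
        return 1.0
    return math.exp(-0.693 * (cn_ratio - 25.0) / 25.0)


def f_cp(cp_ratio: float) -> float:
    """C:P response of decomposition: 1 below 200, exponential decay above."""
    if cp_ratio <= 0:
        raise ValueError(f"C:P ratio must be positive, got {cp_ratio}")
    if cp_ratio < 200.0:
        return 1.0
    return math.exp(-0.693 * (cp_ratio - 200.0) / 200.0)


def f_p(p_con: float, p_min: float, p_opt: float) -> float:
    """Leaf-P limitation of light-saturated photosynthesis, in [0, 1].

    0 at/below the minimum leaf P concentration p_min, 1 at/above the
    optimum p_opt, linear in between (g P per g leaf DM).
    """
    if p_min >= p_opt:
        raise ConfigurationError(f"Pmin ({p_min}) must be below Popt ({p_opt})")
    if p_con <= p_min:
        return 0.0
    if p_con >= p_opt:
        return 1.0
    return (p_con - p_min) / (p_opt - p_min)


@dataclass
class EnvResponse:
    """Temperature and moisture modifiers of decomposition, each in [0, 1]."""

    ftemp: float = 1.0
    fwater: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.ftemp <= 1.0 and 0.0 <= self.fwater <= 1.0):
            raise ValueError("response factors must lie in [0, 1]")


@dataclass
class OrganicPool:
    """An organic-matter pool with C, N, P stocks and a specific decay rate."""

    carbon: float  # gC m-2
    nitrogen: float  # gN m-2
    phosphorus: float  # gP m-2
    kmax: float  # specific decomposition rate, d-1

    def __post_init__(self) -> None:
        if min(self.carbon, self.nitrogen, self.phosphorus, self.kmax) < 0:
            raise ValueError("organic pool stocks and kmax must be non-negative")

    @property
    def cn_ratio(self) -> float:
        return self.carbon / self.nitrogen

    @property
    def cp_ratio(self) -> float:
        return self.carbon / self.phosphorus


def decomposition_rate(
    pool: OrganicPool, env: EnvResponse, *, force_fcp_one: bool = False
) -> Tuple[float, float, float]:
    """Daily decomposition of an organic pool and the nutrients it releases.

    D = kmax * C * ftemp * fwater * min(fCN, fCP)  [gC m-2 d-1]

    N and P release follow the pool's N:C and P:C ratios.  Returns
    (carbon, nitrogen, phosphorus) fluxes.  ``force_fcp_one`` is the
    ablation switch that removes the C:P feedback.
    """
    if pool.carbon == 0.0:
        return 0.0, 0.0, 0.0
    fcn = f_cn(pool.cn_ratio) if pool.nitrogen > 0 else 0.0
    fcp = 1.0 if force_fcp_one else (f_cp(pool.cp_ratio) if pool.phosphorus > 0 else 0.0)
    d_c = pool.kmax * pool.carbon * env.ftemp * env.fwater * min(fcn, fcp)
    d_n = d_c * pool.nitrogen / pool.carbon
    d_p = d_c * pool.phosphorus / pool.carbon
    return d_c, d_n, d_p


# ---------------------------------------------------------------------------
# plant state, partitioning and remobilisation

ORGANS = ("leaf", "stem", "grain", "root")

ANTHESIS_GS = 60.0  # Zadoks stage: beginning of anthesis
STEM_ELONGATION_GS = 30.0


@dataclass
class PartitionBand:
    """Organ partition coefficients valid from ``gs_from`` (Zadoks stage)."""

    gs_from: float
    coefficients: Dict[str, float]

    def __post_init__(self) -> None:
        missing = set(ORGANS) - set(self.coefficients)
        if missing:
            raise ConfigurationError(f"partition band missing organs: {missing}")
        if any(v < 0 for v in self.coefficients.values()):
            raise ConfigurationError("partition coefficients must be >= 0")
        total = sum(self.coefficients[o] for o in ORGANS)
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"partition coefficients sum to {total}, expected 1"
            )


DEFAULT_P_PARTITION = [
    PartitionBand(0.0, {"leaf": 0.45, "stem": 0.15, "grain": 0.0, "root": 0.40}),
    PartitionBand(30.0, {"leaf": 0.35, "stem": 0.45, "grain": 0.0, "root": 0.20}),
    PartitionBand(60.0, {"leaf": 0.10, "stem": 0.20, "grain": 0.60, "root": 0.10}),
]

DEFAULT_DM_PARTITION = [
    PartitionBand(0.0, {"leaf": 0.55, "stem": 0.15, "grain": 0.0, "root": 0.30}),
    PartitionBand(30.0, {"leaf": 0.30, "stem": 0.55, "grain": 0.0, "root": 0.15}),
    PartitionBand(60.0, {"leaf": 0.05, "stem": 0.15, "grain": 0.75, "root": 0.05}),
]


def interpolate_partition(
    bands: Sequence[PartitionBand], gs: float, *, blend: float = 5.0
) -> Dict[str, float]:
    """Stage-dependent coefficients with linear blending across band edges.

    Within ``blend`` Zadoks units below a band boundary the coefficients
    interpolate linearly between the neighbouring bands, so partitioning is
    continuous in growth stage.  Result always sums to 1.
    """
    bands = sorted(bands, key=lambda b: b.gs_from)
    if gs <= bands[0].gs_from:
        return dict(bands[0].coefficients)
    for lo, hi in zip(bands, bands[1:]):
        if gs < hi.gs_from:
            if gs >= hi.gs_from - blend:
                w = (gs - (hi.gs_from - blend)) / blend
                return {
                    o: (1 - w) * lo.coefficients[o] + w * hi.coefficients[o]
                    for o in ORGANS
                }
            return dict(lo.coefficients)
    return dict(bands[-1].coefficients)


@dataclass
class PlantState:
    """Crop state: organ dry matter and P, development stage, variety thresholds."""

    dry_matter: Dict[str, float] = field(
        default_factory=lambda: {o: 0.0 for o in ORGANS}
    )  # g DM m-2
    p_content: Dict[str, float] = field(
        default_factory=lambda: {o: 0.0 for o in ORGANS}
    )  # g P m-2
    growth_stage: float = 0.0  # Zadoks index
    p_opt: float = 0.0030  # g P g-1 leaf DM, no limitation at/above
    p_min: float = 0.0012  # g P g-1 leaf DM, photosynthesis stops at/below
    remobilisation_rate: float = 0.02  # d-1, vegetative P to grain after anthesis
    structural_p_fraction: float = 0.3  # share of vegetative P not remobilisable

    def __post_init__(self) -> None:
        if self.p_min >= self.p_opt:
            raise ConfigurationError("Pmin must be below Popt")
        if any(v < 0 for v in self.p_content.values()):
            raise ValueError("organ P must be non-negative")

    @property
    def total_p(self) -> float:
        return sum(self.p_content.values())

    @property
    def total_dm(self) -> float:
        return sum(self.dry_matter.values())

    @property
    def aboveground_dm(self) -> float:
        return sum(self.dry_matter[o] for o in ("leaf", "stem", "grain"))

    @property
    def leaf_p_concentration(self) -> float:
        dm = self.dry_matter["leaf"]
        return self.p_content["leaf"] / dm if dm > 0 else 0.0

    def photosynthesis_factor(self) -> float:
        if self.dry_matter["leaf"] <= 0:
            return 1.0
        return f_p(self.leaf_p_concentration, self.p_min, self.p_opt)

    def copy(self) -> "PlantState":
        return replace(
            self, dry_matter=dict(self.dry_matter), p_content=dict(self.p_content)
        )


def partition_uptake(
    daily_uptake: float,
    plant: PlantState,
    bands: Sequence[PartitionBand] = tuple(DEFAULT_P_PARTITION),
) -> PlantState:
    """Distribute the day's P uptake (g P m-2 d-1) to organs by growth stage.

    Total plant P increases by exactly ``daily_uptake``.
    """
    if daily_uptake < 0:
        raise ValueError("daily uptake must be >= 0")
    new = plant.copy()
    if daily_uptake == 0.0:
        return new
    coefs = interpolate_partition(bands, plant.growth_stage)
    for organ in ORGANS:
        new.p_content[organ] += daily_uptake * coefs[organ]
    return new


def remobilise_to_grain(plant: PlantState, dt: float = 1.0) -> PlantState:
    """Constant-rate post-anthesis transfer of leaf+stem P to grain.

    Before anthesis (GS < 60) nothing moves.  The transfer is
    remobilisation_rate * dt * (remobilisable leaf+stem P), taken from leaf
    and stem proportionally, and donors never drop below the structural
    minimum (structural_p_fraction of their current P).  Total plant P is
    conserved.
    """
    new = plant.copy()
    if plant.growth_stage < ANTHESIS_GS:
        return new
    donors = ("leaf", "stem")
    available = sum(
        max(0.0, plant.p_content[o] * (1.0 - plant.structural_p_fraction))
        for o in donors
    )
    if available <= 0.0:
        return new
    pool = sum(plant.p_content[o] for o in donors)
    transfer = min(plant.remobilisation_rate * dt * pool, available)
    for o in donors:
        share = plant.p_content[o] / pool if pool > 0 else 0.0
        new.p_content[o] -= transfer * share
    new.p_content["grain"] += transfer
    return new


# ---------------------------------------------------------------------------
# minimal crop-growth driver (logistic + thermal time)


def zadoks_stage(thermal_time: float, table: Sequence[Tuple[float, float]] = ()) -> float:
    """Zadoks stage from accumulated thermal time (degC d, base 0) since sowing.

    Piecewise-linear interpolation of a thermal-time -> stage table for a
    UK autumn-sown winter wheat.
    """
    if not table:
        table = DEFAULT_ZADOKS_TABLE
    tts = [t for t, _ in table]
    gss = [g for _, g in table]
    if thermal_time <= tts[0]:
        return gss[0]
    for (t0, g0), (t1, g1) in zip(table, table[1:]):
        if thermal_time <= t1:
            return g0 + (g1 - g0) * (thermal_time - t0) / (t1 - t0)
    return gss[-1]


DEFAULT_ZADOKS_TABLE = (
    (0.0, 0.0),
    (150.0, 10.0),  # emergence
    (500.0, 21.0),  # tillering
    (950.0, 30.0),  # start of stem elongation
    (1150.0, 39.0),
    (1450.0, 60.0),  # anthesis
    (1700.0, 70.0),  # grain fill
    (2100.0, 92.0),  # ripening
)


@dataclass
class GrowthDriver:
    """Logistic daily assimilation with thermal-time development.

    dDM = mu * DM_green * (1 - DM/dm_max) * ftemp_growth * fP
    """

    mu: float = 0.09  # relative growth rate at optimum, d-1
    dm_max: float = 2000.0  # asymptotic total DM, g m-2
    t_base: float = 0.0  # degC, thermal-time base
    t_opt: float = 22.0  # degC, optimum for assimilation
    initial_dm: float = 4.0  # seedling DM at sowing, g m-2
    initial_p_conc: float = 0.0035  # seedling P concentration, g P g-1 DM
    dm_bands: Sequence[PartitionBand] = tuple(DEFAULT_DM_PARTITION)

    def temperature_factor(self, tmean: float) -> float:
        if tmean <= self.t_base:
            return 0.0
        return min(1.0, (tmean - self.t_base) / (self.t_opt - self.t_base))

    def new_plant(self, **plant_kwargs) -> PlantState:
        dm = {
            "leaf": 0.6 * self.initial_dm,
            "stem": 0.0,
            "grain": 0.0,
            "root": 0.4 * self.initial_dm,
        }
        p = {o: dm[o] * self.initial_p_conc for o in ORGANS}
        return PlantState(dry_matter=dm, p_content=p, **plant_kwargs)

    def grow(
        self, plant: PlantState, tmean: float, *, force_fp_one: bool = False
    ) -> PlantState:
        """One day of growth; the leaf-P factor multiplies assimilation."""
        new = plant.copy()
        dm_green = plant.dry_matter["leaf"] + plant.dry_matter["stem"]
        if dm_green <= 0:
            return new
        fp = 1.0 if force_fp_one else plant.photosynthesis_factor()
        total = plant.total_dm
        growth = (
            self.mu
            * dm_green
            * max(0.0, 1.0 - total / self.dm_max)
            * self.temperature_factor(tmean)
            * fp
        )
        coefs = interpolate_partition(self.dm_bands, plant.growth_stage)
        for organ in ORGANS:
            new.dry_matter[organ] += growth * coefs[organ]
        return new
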