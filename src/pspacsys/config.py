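"""Configuration schema for simulations: soil profile, crop, uptake, engine.

Configs are plain YAML with one block per concern; every key maps 1:1 onto
a dataclass field here.  Validation errors carry the path of the offending
key (e.g. ``soil.layers[0].pools.soluble``).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import yaml

from .pools import POOL_NAMES, PoolState, TransferRates, default_transfer_rates
from .uptake import UptakeParams


class ValidationError(ValueError):
    """Configuration violates the schema; message includes the key path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


@dataclass
class LayerConfig:
    thickness_cm: float
    bulk_density: float  # g cm-3
    field_capacity: float  # cm3 cm-3
    wilting_point: float
    saturation: float
    initial_water: float
    pools: Dict[str, float]  # kg P ha-1, keys = PoolState fields
    organic_carbon_pct: float = 1.0  # % of soil mass
    cn_active: float = 12.0
    cn_stable: float = 10.0
    olsen_p_mg_kg: Optional[float] = None  # informational

    def validate(self, path: str) -> None:
        if self.thickness_cm <= 0:
            raise ValidationError(f"{path}.thickness_cm", "must be > 0")
        if not (0 < self.wilting_point < self.field_capacity < self.saturation <= 1):
            raise ValidationError(
                path, "need 0 < wilting_point < field_capacity < saturation <= 1"
            )
        if not (0 <= self.initial_water <= self.saturation):
            raise ValidationError(f"{path}.initial_water", "outside [0, saturation]")
        for key in self.pools:
            if key not in POOL_NAMES:
                raise ValidationError(f"{path}.pools.{key}", "unknown pool name")
        for key, v in self.pools.items():
            if v < 0:
                raise ValidationError(f"{path}.pools.{key}", "must be >= 0")

    def initial_pool_state(self) -> PoolState:
        return PoolState(**{k: float(v) for k, v in self.pools.items()})


@dataclass
class CropConfig:
    p_opt: float = 0.0030  # g P g-1 leaf DM
    p_min: float = 0.0012
    remobilisation_rate: float = 0.02  # d-1
    structural_p_fraction: float = 0.3
    p_max_conc: float = 0.0045  # g P g-1 DM, whole-plant luxury-uptake ceiling
    specific_root_length: float = 150.0  # m g-1
    root_layer_fractions: List[float] = field(default_factory=lambda: [0.7, 0.3])
    mu: float = 0.12
    dm_max: float = 2000.0
    seed_dm: float = 4.0
    seed_p_conc: float = 0.0035

    def validate(self, path: str = "crop") -> None:
        if self.p_min >= self.p_opt:
            raise ValidationError(f"{path}.p_min", "must be below p_opt")
        if abs(sum(self.root_layer_fractions) - 1.0) > 1e-6:
            raise ValidationError(f"{path}.root_layer_fractions", "must sum to 1")


@dataclass
class EngineConfig:
    latitude_deg: float = 51.8
    microbial_cp: float = 60.0  # microbial biomass C:P ratio
    assimilation_efficiency: float = 0.4  # fraction of decomposed C to microbes
    humification_fraction: float = 0.3  # microbial turnover C back to active OM
    kmax_active: float = 8e-4  # d-1
    kmax_stable: float = 8e-6
    kmax_microbial: float = 5e-3
    drainage_coefficient: float = 0.5  # fraction of water above FC draining per day
    leachable_fraction: float = 0.05  # solution share of the labile pool (~1/b)
    temp_running_mean_days: int = 5
    damping_depth_cm: float = 30.0
    crop_coefficient: float = 0.8  # scales reference ET
    force_fp_one: bool = False  # ablation: remove leaf-P photosynthesis feedback
    force_fcp_one: bool = False  # ablation: remove C:P decomposition feedback

    def validate(self, path: str = "engine") -> None:
        if not (0 < self.assimilation_efficiency < 1):
            raise ValidationError(f"{path}.assimilation_efficiency", "must be in (0,1)")
        if not (0 <= self.drainage_coefficient <= 1):
            raise ValidationError(f"{path}.drainage_coefficient", "must be in [0,1]")


@dataclass
class SimulationConfig:
    layers: List[LayerConfig]
    uptake: UptakeParams = field(default_factory=UptakeParams)
    crop: CropConfig = field(default_factory=CropConfig)
    engine: EngineConfig = field(default_factory=EngineConfig)
    transfer_rates: TransferRates = field(default_factory=default_transfer_rates)

    def validate(self) -> None:
        if not self.layers:
            raise ValidationError("soil.layers", "at least one layer required")
        for i, layer in enumerate(self.layers):
            layer.validate(f"soil.layers[{i}]")
        self.crop.validate()
        self.engine.validate()
        if len(self.crop.root_layer_fractions) != len(self.layers):
            raise ValidationError(
                "crop.root_layer_fractions", "length must equal number of layers"
            )

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "soil": {"layers": [asdict(layer) for layer in self.layers]},
            "uptake": asdict(self.uptake),
            "crop": asdict(self.crop),
            "engine": asdict(self.engine),
            "transfer_rates": {
                f"{src}->{dst}": k for (src, dst), k in self.transfer_rates.rates.items()
            },
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        try:
            layer_dicts = raw["soil"]["layers"]
        except (KeyError, TypeError):
            raise ValidationError("soil.layers", "missing") from None
        layers = []
        for i, ld in enumerate(layer_dicts):
            try:
                layers.append(LayerConfig(**ld))
            except TypeError as exc:
                raise ValidationError(f"soil.layers[{i}]", str(exc)) from None
        kwargs = {}
        if "uptake" in raw:
            try:
                kwargs["uptake"] = UptakeParams(**raw["uptake"])
            except (TypeError, ValueError) as exc:
                raise ValidationError("uptake", str(exc)) from None
        if "crop" in raw:
            try:
                kwargs["crop"] = CropConfig(**raw["crop"])
            except TypeError as exc:
                raise ValidationError("crop", str(exc)) from None
        if "engine" in raw:
            try:
                kwargs["engine"] = EngineConfig(**raw["engine"])
            except TypeError as exc:
                raise ValidationError("engine", str(exc)) from None
        if "transfer_rates" in raw:
            kwargs["transfer_rates"] = TransferRates.from_dict(raw["transfer_rates"])
        cfg = cls(layers=layers, **kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ValidationError("<root>", "config must be a mapping")
        return cls.from_dict(raw)
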