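"""Run configuration: a YAML-serializable description of one simulation.

Every published parameter symbol is addressable by name under ``parameters:``
(V_Cell, V_CellInit, V_A, v_g, P_M, V_Death, P_ECMst, P_ECMv, V_ECMInit,
V_ECM, v_d, V_Delete, lambda_vol, Tm, J_medium_medium, J_cell_cell,
J_medium_cell, J_medium_ecm, J_cell_ecm, J_ecm_ecm); unknown keys are
rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .dynamics import DomainParameters, SimulationState
from .lattice import FIXED_MEDIUM, PERIODIC, Neighborhood
from .params import build_parameter_set

_GEOMETRY_KEYS = {"cylinder_diameter", "cylinder_height", "ratio_cell_ecmst_ecmv"}


@dataclass
class RunConfig:
    zone: str = "SZ"
    seed: int = 0
    total_mcs: int = 3120
    snapshot_every: int = 240
    n_cells: int = 1000
    unit_mode: str = "cell-slot"
    dims: tuple[int, int, int] | None = None
    boundary: str = FIXED_MEDIUM
    neighborhood_order: int = 2
    attempts_per_mcs: int | None = None
    ecm_target_mode: str = "decay"
    independent_action_draws: bool = False
    out_dir: str = "out"
    log_every: int = 0
    parameters: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.boundary not in (FIXED_MEDIUM, PERIODIC):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        build_parameter_set(self.zone, self.parameters)  # validates keys/zone
        for key in self.geometry:
            if key not in _GEOMETRY_KEYS:
                raise ValueError(f"unknown geometry key {key!r}")
        if self.dims is not None:
            self.dims = tuple(int(d) for d in self.dims)
        if "ratio_cell_ecmst_ecmv" in self.geometry:
            self.geometry["ratio_cell_ecmst_ecmv"] = [
                int(r) for r in self.geometry["ratio_cell_ecmst_ecmv"]]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["dims"] is not None:
            d["dims"] = list(d["dims"])
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        for key in data:
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
        return cls(**data)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    # -- assembly ---------------------------------------------------------

    def build_state(self) -> SimulationState:
        from .seeding import SeedingGeometry, initialize, zone_geometry
        geometry = zone_geometry(self.zone, self.n_cells, self.unit_mode)
        if self.geometry:
            geometry = SeedingGeometry(
                cylinder_diameter=self.geometry.get("cylinder_diameter",
                                                    geometry.cylinder_diameter),
                cylinder_height=self.geometry.get("cylinder_height",
                                                  geometry.cylinder_height),
                n_cells=self.n_cells,
                ratio_cell_ecmst_ecmv=tuple(self.geometry.get(
                    "ratio_cell_ecmst_ecmv", geometry.ratio_cell_ecmst_ecmv)),
                unit_mode=self.unit_mode)
        params = build_parameter_set(self.zone, self.parameters)
        domain = DomainParameters(
            Tm=params.Tm,
            attempts_per_mcs=self.attempts_per_mcs,
            neighborhood=Neighborhood(self.neighborhood_order),
            rng_seed=self.seed)
        return initialize(self.zone, self.n_cells, self.seed, dims=self.dims,
                          unit_mode=self.unit_mode, overrides=self.parameters,
                          domain=domain, geometry=geometry,
                          boundary=self.boundary,
                          ecm_target_mode=self.ecm_target_mode,
                          independent_action_draws=self.independent_action_draws)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def load_config(path) -> RunConfig:
    try:
        data = yaml.safe_load(Path(path).read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"config parse error in {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return RunConfig.from_dict(data)
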