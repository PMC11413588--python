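"""Zone-specific model parameters.

Each depth zone of articular cartilage (surface SZ, middle MZ, deep DZ) has its
own published parameter column: cell growth/mitosis settings, two ECM secretion
probabilities (structural ECMst, volumetric ECMv), ECM decay speed, the volume
constraint, the Boltzmann temperature of the domain, and the contact-energy
table.  Probabilities are stored exactly as published, in percent per MCS; use
the ``prob_*`` properties for fractions.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass


class Zone(enum.Enum):
    """Longitudinal depth zone of articular cartilage a chondrocyte came from."""

    SZ = "SZ"
    MZ = "MZ"
    DZ = "DZ"
    NONE = "none"

    @classmethod
    def coerce(cls, value: "Zone | str") -> "Zone":
        if isinstance(value, Zone):
            return value
        try:
            return cls[value.upper()] if value.lower() != "none" else cls.NONE
        except KeyError:
            raise ValueError(f"unknown zone {value!r}; expected SZ, MZ, DZ or none")


@dataclass
class ParameterSet:
    """One full zone column of the model parameter table plus domain settings.

    Volumes are in voxel^3, speeds in voxel^3/MCS, probabilities in percent per
    MCS (as published), contact energies in the model's arbitrary energy units.
    """

    zone: Zone
    # -- cell lifecycle --
    V_Cell: float = 30.0          # target volume of a cell
    V_CellInit: float = 27.0      # initial (realized) volume of a seeded cell
    V_A: float = 20.0             # action threshold: division/secretion cued above this
    v_g: float = 0.080            # growth speed of the cell target volume
    P_M: float = 1.0              # mitosis probability, %/MCS
    V_Death: float = 60.0         # cells above this realized volume are deleted
    # -- ECM lifecycle --
    P_ECMst: float = 3.2          # structural-ECM secretion probability, %/MCS
    P_ECMv: float = 3.2           # volumetric-ECM secretion probability, %/MCS
    V_ECMInit: float = 30.0       # target volume assigned to newly created ECM
    V_ECM: float | None = None    # no fixed ECM target: the target decays from V_ECMInit
    v_d: float = 0.003            # ECM decay speed (target volume per MCS)
    V_Delete: float = 3.0         # ECM below this realized volume is deleted
    # -- Hamiltonian --
    lambda_vol: float = 10.0      # volume-constraint magnitude
    Tm: float = 37.0              # Boltzmann temperature of the domain
    J_medium_medium: float = 0.0
    J_cell_cell: float = 5.0
    J_medium_cell: float = 5.0
    J_medium_ecm: float = 20.0
    J_cell_ecm: float = 10.0
    J_ecm_ecm: float = 10.0

    # V_parent / V_daughter are defined as V_Cell/2 in the published table.
    @property
    def V_parent(self) -> float:
        return self.V_Cell / 2.0

    @property
    def V_daughter(self) -> float:
        return self.V_Cell / 2.0

    @property
    def prob_mitosis(self) -> float:
        return self.P_M / 100.0

    @property
    def prob_ecmst(self) -> float:
        return self.P_ECMst / 100.0

    @property
    def prob_ecmv(self) -> float:
        return self.P_ECMv / 100.0

    def __post_init__(self) -> None:
        self.zone = Zone.coerce(self.zone)
        for name in ("P_M", "P_ECMst", "P_ECMv"):
            p = getattr(self, name)
            if not 0.0 <= p <= 100.0:
                raise ValueError(f"{name}={p} is not a percentage in [0, 100]")
        if not self.V_Death > self.V_Cell > self.V_CellInit > self.V_A:
            raise ValueError(
                "volume thresholds must be ordered V_Death > V_Cell > V_CellInit > V_A"
            )
        if self.v_d < 0:
            raise ValueError("decay speed v_d must be non-negative")
        if self.V_Delete >= self.V_ECMInit:
            raise ValueError("V_Delete must be below V_ECMInit")


# Zone-specific values; rows not listed here are identical across zones.
_ZONE_COLUMNS: dict[Zone, dict[str, float]] = {
    Zone.SZ: dict(v_g=0.080, P_ECMst=3.2, P_ECMv=3.2, v_d=0.003,
                  J_cell_cell=5.0, J_medium_ecm=20.0),
    Zone.MZ: dict(v_g=0.060, P_ECMst=0.67, P_ECMv=9.3, v_d=0.027,
                  J_cell_cell=2.5, J_medium_ecm=2.5),
    Zone.DZ: dict(v_g=0.060, P_ECMst=3.0, P_ECMv=8.3, v_d=0.097,
                  J_cell_cell=2.5, J_medium_ecm=2.5),
}

_FIELD_NAMES = {f.name for f in dataclasses.fields(ParameterSet)} - {"zone"}


def build_parameter_set(zone: Zone | str, overrides: dict | None = None) -> ParameterSet:
    """Return the full parameter column for ``zone`` merged with ``overrides``.

    Raises ``ValueError`` for an unknown zone or an unknown override key.
    """
    zone = Zone.coerce(zone)
    if zone not in _ZONE_COLUMNS:
        raise ValueError(f"no parameter column for zone {zone}")
    values = dict(_ZONE_COLUMNS[zone])
    for key, val in (overrides or {}).items():
        if key not in _FIELD_NAMES:
            raise ValueError(f"unknown parameter override {key!r}")
        values[key] = val
    return ParameterSet(zone=zone, **values)
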