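"""Day-1 initialization: cylindrical seeding of cells and ECM.

1,000 chondrocytes (plus ECMst/ECMv at a zone-specific ratio — 8:1:1 for SZ,
4:4:3 for MZ and DZ) are scattered as 3×3×3 voxel cubes inside a cylindrical
region resting on the substrate plane z = 0, emulating how seeded cells settle
concentrically at the bottom of a round-bottom well.

The published cylinder sizes (diameter 36/84/84, height 5/3/3 for SZ/MZ/DZ)
cannot hold 1,000 non-overlapping 27-voxel cubes if read as voxels (a 36×5
cylinder holds ≈5,089 voxels < 27,000).  The default ``unit_mode='cell-slot'``
therefore reads those numbers in 3-voxel cell-slot units, which accommodates
the stated counts; ``unit_mode='voxel'`` honors the literal voxel reading and
raises a capacity error naming the shortfall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import DomainParameters, SimulationState
from .lattice import CompartmentType, VoxelLattice, create_lattice
from .params import ParameterSet, Zone, build_parameter_set

SLOT = 3  # voxels per cell-slot edge (initial compartments are 3×3×3 cubes)


@dataclass
class SeedingGeometry:
    """Cylindrical seeding region for one zone.

    ``cylinder_diameter`` and ``cylinder_height`` are in the active
    ``unit_mode`` units (cell-slots by default, voxels otherwise).
    """

    cylinder_diameter: int
    cylinder_height: int
    n_cells: int = 1000
    ratio_cell_ecmst_ecmv: tuple[int, int, int] = (8, 1, 1)
    unit_mode: str = "cell-slot"

    def __post_init__(self) -> None:
        if self.unit_mode not in ("cell-slot", "voxel"):
            raise ValueError("unit_mode must be 'cell-slot' or 'voxel'")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")
        if any(r <= 0 for r in self.ratio_cell_ecmst_ecmv):
            raise ValueError("seeding ratios must be positive")

    @property
    def r_init(self) -> float:
        """Seeding radius in voxels."""
        scale = SLOT if self.unit_mode == "cell-slot" else 1
        return self.cylinder_diameter * scale / 2.0

    @property
    def ecm_counts(self) -> tuple[int, int]:
        rc, rst, rv = self.ratio_cell_ecmst_ecmv
        return (round(self.n_cells * rst / rc), round(self.n_cells * rv / rc))

    @property
    def total_compartments(self) -> int:
        n_st, n_v = self.ecm_counts
        return self.n_cells + n_st + n_v


_ZONE_GEOMETRY = {
    Zone.SZ: (36, 5, (8, 1, 1)),
    Zone.MZ: (84, 3, (4, 4, 3)),
    Zone.DZ: (84, 3, (4, 4, 3)),
}


def zone_geometry(zone: Zone | str, n_cells: int = 1000,
                  unit_mode: str = "cell-slot") -> SeedingGeometry:
    """Published geometry for a zone, proportionally rescaled for ``n_cells``.

    For reduced problem sizes the cylinder diameter shrinks as
    ``sqrt(n_cells/1000)`` at fixed height, preserving the thin-disk areal
    density of the full-scale seeding.
    """
    zone = Zone.coerce(zone)
    diameter, height, ratio = _ZONE_GEOMETRY[zone]
    if n_cells != 1000:
        diameter = math.ceil(diameter * math.sqrt(n_cells / 1000.0))
    return SeedingGeometry(diameter, height, n_cells, ratio, unit_mode)


def default_dims(geometry: SeedingGeometry) -> tuple[int, int, int]:
    """Lattice dimensions leaving growth margin around the seeding cylinder."""
    scale = SLOT if geometry.unit_mode == "cell-slot" else 1
    cyl = geometry.cylinder_diameter * scale
    hvox = geometry.cylinder_height * scale
    xy = cyl + 12
    nz = 60 if geometry.n_cells >= 500 else max(24, hvox + 21)
    return (xy, xy, nz)


def _slot_positions(geometry: SeedingGeometry, dims) -> np.ndarray:
    """Corner voxels of all 3×3×3 slots inside the cylinder, on the substrate."""
    nx, ny, nz = dims
    if geometry.unit_mode == "cell-slot":
        d_slots, h_slots = geometry.cylinder_diameter, geometry.cylinder_height
    else:
        d_slots = geometry.cylinder_diameter // SLOT
        h_slots = geometry.cylinder_height // SLOT
    r = d_slots / 2.0
    x0 = (nx - d_slots * SLOT) // 2
    y0 = (ny - d_slots * SLOT) // 2
    if x0 < 0 or y0 < 0 or h_slots * SLOT > nz:
        raise ValueError(f"lattice {dims} too small for the seeding cylinder")
    slots = []
    for i in range(d_slots):
        for j in range(d_slots):
            if (i + 0.5 - r) ** 2 + (j + 0.5 - r) ** 2 <= r * r:
                for k in range(h_slots):
                    slots.append((x0 + SLOT * i, y0 + SLOT * j, SLOT * k))
    return np.array(slots, dtype=np.int64)


def seed_zone(lattice: VoxelLattice, geometry: SeedingGeometry,
              params: ParameterSet, rng: np.random.Generator,
              domain: DomainParameters | None = None,
              **state_options) -> SimulationState:
    """Build the 0-MCS state: cells and ECM cubes scattered in the cylinder.

    Every compartment starts as a 27-voxel cube at a random non-overlapping
    slot; cells get target volume V_Cell, ECM gets V_ECMInit.  Raises a
    capacity error naming the required and available slot counts when the
    cylinder cannot hold the requested compartments.
    """
    slots = _slot_positions(geometry, lattice.dims)
    need = geometry.total_compartments
    if len(slots) < need:
        raise ValueError(
            f"seeding cylinder capacity insufficient: {need} compartments "
            f"requested but only {len(slots)} non-overlapping 3×3×3 slots fit "
            f"(unit_mode={geometry.unit_mode!r}, diameter="
            f"{geometry.cylinder_diameter}, height={geometry.cylinder_height})")
    chosen = slots[rng.choice(len(slots), size=need, replace=False)]
    n_st, n_v = geometry.ecm_counts
    kinds = ([CompartmentType.Cell] * geometry.n_cells +
             [CompartmentType.ECMst] * n_st + [CompartmentType.ECMv] * n_v)
    for corner, kind in zip(chosen, kinds):
        target = params.V_Cell if kind == CompartmentType.Cell else params.V_ECMInit
        cid = lattice.new_compartment(kind, params.zone, target_volume=target)
        lattice.place_block(cid, tuple(corner), (SLOT, SLOT, SLOT))
    lattice.check_bookkeeping()
    return SimulationState(lattice, params, domain, **state_options)


def initialize(zone: Zone | str, n_cells: int = 1000, seed: int = 0,
               dims: tuple[int, int, int] | None = None,
               unit_mode: str = "cell-slot",
               overrides: dict | None = None,
               domain: DomainParameters | None = None,
               geometry: SeedingGeometry | None = None,
               boundary: str = "fixed-medium",
               **state_options) -> SimulationState:
    """One-call setup: parameters, geometry, lattice and seeding for a zone."""
    params = build_parameter_set(zone, overrides)
    geometry = geometry or zone_geometry(zone, n_cells, unit_mode)
    lattice = create_lattice(dims or default_dims(geometry), boundary)
    domain = domain or DomainParameters(Tm=params.Tm, rng_seed=seed)
    rng = np.random.default_rng(seed)
    state = seed_zone(lattice, geometry, params, rng, domain, **state_options)
    return state
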