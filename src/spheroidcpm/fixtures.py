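"""Deterministic test-surface state generators.

Each family documents the ground truth tests rely on.  All fixtures use the
order-1 contact neighborhood so the energies stay hand-checkable, and default
to SZ parameters.
"""

from __future__ import annotations

import numpy as np

from .dynamics import DomainParameters, SimulationState
from .lattice import CompartmentType, Neighborhood, VoxelLattice, create_lattice
from .params import Zone, build_parameter_set

FAMILIES = ("isolated-cube", "two-cube-contact", "cell-shell-around-ecm",
            "random-dispersion", "mini-seeding")


def _state(lattice: VoxelLattice, zone: Zone, seed: int,
           order: int = 1) -> SimulationState:
    params = build_parameter_set(zone)
    domain = DomainParameters(Tm=params.Tm, rng_seed=seed,
                              neighborhood=Neighborhood(order))
    return SimulationState(lattice, params, domain)


def make_fixture(name: str, seed: int = 0, **kwargs) -> SimulationState:
    """Build one fixture family; deterministic given ``seed``.

    Families and their known ground truth:

    * ``isolated-cube``: one 3×3×3 SZ cell (volume 27, target 30) centered in
      medium.  Under order-1 contact: H_contact = 54·J(medium-cell) = 270,
      H_volume = 10·(27−30)² = 90, H = 360.
    * ``two-cube-contact``: two 3×3×3 SZ cells sharing a full 3×3 face —
      one all-matter cluster; 90 medium-cell + 9 cell-cell face pairs.
    * ``cell-shell-around-ecm``: an ECMv ball wrapped in a closed cell shell —
      the published SZ core-shell phenotype as a constructed ground truth for
      radial profiling (inner shells ECMv-rich, outer shells cell-rich).
    * ``random-dispersion``: ``n`` (default 8) non-overlapping 3×3×3
      compartments of cycling ``types`` at random slots in a small box.
    * ``mini-seeding``: the zone seeding scaled to ``n_cells`` (default 100)
      with ratio-scaled ECM counts.
    """
    rng = np.random.default_rng(seed)
    if name == "isolated-cube":
        zone = Zone.coerce(kwargs.get("zone", "SZ"))
        lat = create_lattice((16, 16, 16))
        params = build_parameter_set(zone)
        cid = lat.new_compartment(CompartmentType.Cell, zone,
                                  target_volume=params.V_Cell)
        lat.place_block(cid, (6, 6, 6), (3, 3, 3))
        return _state(lat, zone, seed)
    if name == "two-cube-contact":
        zone = Zone.coerce(kwargs.get("zone", "SZ"))
        lat = create_lattice((16, 16, 16))
        params = build_parameter_set(zone)
        for corner in ((5, 6, 6), (8, 6, 6)):
            cid = lat.new_compartment(CompartmentType.Cell, zone,
                                      target_volume=params.V_Cell)
            lat.place_block(cid, corner, (3, 3, 3))
        return _state(lat, zone, seed)
    if name == "cell-shell-around-ecm":
        zone = Zone.coerce(kwargs.get("zone", "SZ"))
        r_core = kwargs.get("r_core", 4.0)
        r_shell = kwargs.get("r_shell", 6.5)
        n = int(2 * r_shell + 5)
        lat = create_lattice((n, n, n))
        center = (np.array(lat.dims) - 1) / 2.0
        coords = np.argwhere(np.ones(lat.dims, dtype=bool))
        radii = np.linalg.norm(coords - center, axis=1)
        core = coords[radii <= r_core]
        shell = coords[(radii > r_core) & (radii <= r_shell)]
        ecm = lat.new_compartment(CompartmentType.ECMv, zone,
                                  target_volume=len(core))
        lat.assign_voxels(ecm, core)
        cell = lat.new_compartment(CompartmentType.Cell, zone,
                                   target_volume=len(shell))
        lat.assign_voxels(cell, shell)
        return _state(lat, zone, seed)
    if name == "random-dispersion":
        zone = Zone.coerce(kwargs.get("zone", "SZ"))
        n = kwargs.get("n", 8)
        types = kwargs.get("types", (CompartmentType.Cell, CompartmentType.ECMst,
                                     CompartmentType.ECMv))
        side = kwargs.get("side", 24)
        lat = create_lattice((side, side, side))
        params = build_parameter_set(zone)
        n_slots = side // 3
        slots = [(i, j, k) for i in range(n_slots) for j in range(n_slots)
                 for k in range(n_slots)]
        chosen = rng.choice(len(slots), size=n, replace=False)
        for idx, slot_i in enumerate(chosen):
            i, j, k = slots[slot_i]
            ctype = types[idx % len(types)]
            target = params.V_Cell if ctype == CompartmentType.Cell \
                else params.V_ECMInit
            cid = lat.new_compartment(ctype, zone, target_volume=target)
            lat.place_block(cid, (3 * i, 3 * j, 3 * k), (3, 3, 3))
        return _state(lat, zone, seed)
    if name == "mini-seeding":
        from .seeding import initialize
        zone = kwargs.get("zone", "SZ")
        n_cells = kwargs.get("n_cells", 100)
        return initialize(zone, n_cells=n_cells, seed=seed)
    raise ValueError(f"unknown fixture family {name!r}; choose from {FAMILIES}")
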