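"""The model Hamiltonian: contact energy plus volume constraint.

``H = H_contact + H_volume`` with

* ``H_contact = Σ_{neighbor pairs i,j} J(τ(σ_i), τ(σ_j)) · (1 − δ(σ_i, σ_j))``
  counted once per unordered neighbor pair, so each published J acts as a bond
  energy between voxels of *distinct* compartments;
* ``H_volume = Σ_σ λ_vol (V_σ − V_target,σ)²`` over cells and ECM (the medium
  carries no volume constraint).

Contact classes distinguish compartment type *and* depth zone because two
published rows are zone-specific: J(cell–cell) (5.0 SZ, 2.5 MZ/DZ) and
J(medium–ECM) (20 SZ, 2.5 MZ/DZ; applied to both ECMst and ECMv, which share a
single published row).  Simulations are single-zone, so cross-zone entries
default to the mean of the two zone values and are never exercised by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lattice import (FIXED_MEDIUM, MEDIUM_ID, CompartmentType, Neighborhood,
                      VoxelLattice, neighbor_voxels)
from .params import ParameterSet, Zone, build_parameter_set

N_CLASSES = 10  # medium + 3 zones × (cell, ECMst, ECMv)

_ZONE_INDEX = {Zone.SZ: 0, Zone.MZ: 1, Zone.DZ: 2}


def class_code(ctype: CompartmentType, zone: Zone) -> int:
    """Map (compartment type, zone) to a contact class index."""
    if ctype == CompartmentType.Medium:
        return 0
    if zone not in _ZONE_INDEX:
        raise ValueError(f"{ctype.name} compartment needs a depth zone, got {zone}")
    return 1 + (int(ctype) - 1) * 3 + _ZONE_INDEX[zone]


_CODE_TO_ZONE = [None, Zone.SZ, Zone.MZ, Zone.DZ]


def lattice_class_codes(lattice: VoxelLattice) -> np.ndarray:
    """Per-compartment-id contact class array for a lattice's registry."""
    n = lattice.n_ids
    ctype = lattice.ctype[:n].astype(np.int16)
    zone = lattice.zone_code[:n].astype(np.int16)
    live = lattice.alive[:n] & (ctype > 0)
    if np.any(live & (zone == 0)):
        bad = np.nonzero(live & (zone == 0))[0]
        raise ValueError(f"non-medium compartments without a depth zone: "
                         f"{bad.tolist()[:5]}")
    codes = np.where(live, 1 + (ctype - 1) * 3 + (zone - 1), 0)
    return codes.astype(np.int8)


@dataclass
class ContactEnergyTable:
    """Symmetric per-bond contact energies J over contact classes.

    ``matrix[a, b]`` is the energy of one heterotypic bond between classes a
    and b; entries left NaN are *missing* and raise when encountered.
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (N_CLASSES, N_CLASSES):
            raise ValueError(f"contact table must be {N_CLASSES}×{N_CLASSES}")
        if not np.array_equal(np.isnan(m), np.isnan(m.T)) or \
           np.nanmax(np.abs(m - m.T), initial=0.0) > 0:
            raise ValueError("contact table must be symmetric")
        self.matrix = m

    @classmethod
    def from_zone_parameters(cls, per_zone: dict[Zone, ParameterSet]) -> "ContactEnergyTable":
        per_zone = {Zone.coerce(z): p for z, p in per_zone.items()}
        for z in _ZONE_INDEX:
            per_zone.setdefault(z, build_parameter_set(z))
        m = np.full((N_CLASSES, N_CLASSES), np.nan)
        m[0, 0] = 0.0  # J(medium-medium) = 0
        cell = {z: class_code(CompartmentType.Cell, z) for z in _ZONE_INDEX}
        ecm = {z: [class_code(CompartmentType.ECMst, z), class_code(CompartmentType.ECMv, z)]
               for z in _ZONE_INDEX}
        for z, p in per_zone.items():
            m[0, cell[z]] = m[cell[z], 0] = p.J_medium_cell
            for e in ecm[z]:
                m[0, e] = m[e, 0] = p.J_medium_ecm
            m[cell[z], cell[z]] = p.J_cell_cell
        zones = list(_ZONE_INDEX)
        for za in zones:
            for zb in zones:
                pa, pb = per_zone[za], per_zone[zb]
                if za != zb:
                    j = 0.5 * (pa.J_cell_cell + pb.J_cell_cell)
                    m[cell[za], cell[zb]] = m[cell[zb], cell[za]] = j
                for ea in ecm[za]:
                    j = 0.5 * (pa.J_cell_ecm + pb.J_cell_ecm)
                    m[cell[zb], ea] = m[ea, cell[zb]] = j
                    for eb in ecm[zb]:
                        j = 0.5 * (pa.J_ecm_ecm + pb.J_ecm_ecm)
                        m[ea, eb] = m[eb, ea] = j
        return cls(m)

    @classmethod
    def from_parameters(cls, params: ParameterSet) -> "ContactEnergyTable":
        """Single-zone table; other zones fall back to their published defaults."""
        return cls.from_zone_parameters({params.zone: params})

    def j(self, class_a: int, class_b: int) -> float:
        v = self.matrix[class_a, class_b]
        if np.isnan(v):
            raise KeyError(f"missing contact energy for class pair ({class_a}, {class_b})")
        return float(v)


@dataclass
class VolumeConstraint:
    """Quadratic volume constraint λ_vol(V − V_target)² on non-medium types."""

    lambda_vol: float = 10.0
    applies_to: frozenset = field(default_factory=lambda: frozenset(
        {CompartmentType.Cell, CompartmentType.ECMst, CompartmentType.ECMv}))

    def __post_init__(self) -> None:
        if self.lambda_vol < 0:
            raise ValueError("lambda_vol must be non-negative")
        self.applies_to = frozenset(self.applies_to)

    def constrained_mask(self, lattice: VoxelLattice) -> np.ndarray:
        codes = np.array([int(t) for t in self.applies_to], dtype=np.int64)
        mask = np.isin(lattice.ctype[: lattice.n_ids], codes)
        mask &= lattice.alive[: lattice.n_ids]
        mask[MEDIUM_ID] = False
        return mask


@dataclass
class EnergyModel:
    """Bundle of everything needed to evaluate H for one lattice."""

    j_table: ContactEnergyTable
    constraint: VolumeConstraint
    neighborhood: Neighborhood = field(default_factory=lambda: Neighborhood(2))

    @classmethod
    def from_parameters(cls, params: ParameterSet,
                        neighborhood: Neighborhood | None = None) -> "EnergyModel":
        return cls(ContactEnergyTable.from_parameters(params),
                   VolumeConstraint(lambda_vol=params.lambda_vol),
                   neighborhood or Neighborhood(2))


def _half_offsets(neighborhood: Neighborhood) -> np.ndarray:
    offs = neighborhood.offsets
    keep = [tuple(o) > (0, 0, 0) for o in offs.tolist()]
    return offs[np.array(keep)]


def contact_energy(lattice: VoxelLattice, j_table: ContactEnergyTable,
                   neighborhood: Neighborhood = Neighborhood(1)) -> float:
    """Sum of J over unordered neighbor pairs spanning distinct compartments.

    Under the fixed-medium boundary, bonds between edge voxels and virtual
    out-of-lattice medium sites are included (they vanish for medium voxels
    since J(medium-medium)=0).
    """
    codes = lattice_class_codes(lattice)
    if np.any(np.isnan(j_table.matrix[np.ix_(np.unique(codes), np.unique(codes))])):
        raise KeyError("contact table is missing an entry for a present class pair")
    if lattice.boundary == FIXED_MEDIUM:
        labs = np.pad(lattice.labels, 1, constant_values=MEDIUM_ID)
        roll = False
    else:
        labs = lattice.labels
        roll = True
    cls_field = codes[labs]
    total = 0.0
    for off in _half_offsets(neighborhood):
        if roll:
            lab_b = np.roll(labs, shift=tuple(-off), axis=(0, 1, 2))
            cls_b = np.roll(cls_field, shift=tuple(-off), axis=(0, 1, 2))
            lab_a, cls_a = labs, cls_field
        else:
            dx, dy, dz = (int(o) for o in off)
            # slice pairs (i, i+off) without wrap
            lab_a = labs[_sl(labs.shape[0], dx, True), _sl(labs.shape[1], dy, True),
                         _sl(labs.shape[2], dz, True)]
            lab_b = labs[_sl(labs.shape[0], dx, False), _sl(labs.shape[1], dy, False),
                         _sl(labs.shape[2], dz, False)]
            cls_a = cls_field[_sl(labs.shape[0], dx, True), _sl(labs.shape[1], dy, True),
                              _sl(labs.shape[2], dz, True)]
            cls_b = cls_field[_sl(labs.shape[0], dx, False), _sl(labs.shape[1], dy, False),
                              _sl(labs.shape[2], dz, False)]
        distinct = lab_a != lab_b
        total += float(j_table.matrix[cls_a[distinct], cls_b[distinct]].sum())
    return total


def bond_counts(lattice: VoxelLattice,
                neighborhood: Neighborhood = Neighborhood(1)) -> np.ndarray:
    """Heterotypic bond counts per contact-class pair (symmetric matrix).

    Entry [a, b] (+ [b, a]) counts unordered neighbor voxel pairs spanning
    distinct compartments of classes a and b; used by the energy audit.
    """
    codes = lattice_class_codes(lattice)
    if lattice.boundary == FIXED_MEDIUM:
        labs = np.pad(lattice.labels, 1, constant_values=MEDIUM_ID)
        roll = False
    else:
        labs = lattice.labels
        roll = True
    cls_field = codes[labs]
    counts = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for off in _half_offsets(neighborhood):
        if roll:
            lab_b = np.roll(labs, shift=tuple(-off), axis=(0, 1, 2))
            cls_b = np.roll(cls_field, shift=tuple(-off), axis=(0, 1, 2))
            lab_a, cls_a = labs, cls_field
        else:
            dx, dy, dz = (int(o) for o in off)
            sls_a = (_sl(labs.shape[0], dx, True), _sl(labs.shape[1], dy, True),
                     _sl(labs.shape[2], dz, True))
            sls_b = (_sl(labs.shape[0], dx, False), _sl(labs.shape[1], dy, False),
                     _sl(labs.shape[2], dz, False))
            lab_a, lab_b = labs[sls_a], labs[sls_b]
            cls_a, cls_b = cls_field[sls_a], cls_field[sls_b]
        distinct = lab_a != lab_b
        np.add.at(counts, (cls_a[distinct], cls_b[distinct]), 1)
    return counts + counts.T - np.diag(np.diag(counts))


def _sl(n: int, d: int, first: bool) -> slice:
    if d == 0:
        return slice(0, n)
    if d > 0:
        return slice(0, n - d) if first else slice(d, n)
    return slice(-d, n) if first else slice(0, n + d)


def volume_energy(lattice: VoxelLattice, constraint: VolumeConstraint) -> float:
    """Σ λ_vol (V_σ − V_target,σ)² over constrained compartments; medium excluded."""
    mask = constraint.constrained_mask(lattice)
    dv = lattice.volume[: lattice.n_ids][mask] - lattice.target_volume[: lattice.n_ids][mask]
    return float(constraint.lambda_vol * np.sum(dv * dv))


def total_energy(lattice: VoxelLattice, model: EnergyModel,
                 neighborhood: Neighborhood | None = None) -> float:
    nb = neighborhood or model.neighborhood
    return contact_energy(lattice, model.j_table, nb) + \
        volume_energy(lattice, model.constraint)


def delta_for_relabel(lattice: VoxelLattice, model: EnergyModel, target_voxel,
                      new_label: int, neighborhood: Neighborhood | None = None) -> float:
    """Energy change of rewriting the target voxel's label to ``new_label``.

    Computed locally: only bonds incident to the target voxel and the two
    affected compartments' volume terms change.
    """
    nb = neighborhood or model.neighborhood
    old = lattice.label_at(target_voxel)
    if old == new_label:
        raise ValueError("relabel to the same compartment has no energy change")
    codes = lattice_class_codes(lattice)
    c_new, c_old = int(codes[new_label]), int(codes[old])
    dh = 0.0
    for site in neighbor_voxels(lattice, tuple(target_voxel), nb):
        lab_n = site.label
        c_n = int(codes[lab_n])
        if lab_n != new_label:
            dh += model.j_table.j(c_new, c_n)
        if lab_n != old:
            dh -= model.j_table.j(c_old, c_n)
    lam = model.constraint.lambda_vol
    mask = model.constraint.constrained_mask(lattice)
    for cid, gain in ((new_label, 1), (old, -1)):
        if cid != MEDIUM_ID and mask[cid]:
            v = float(lattice.volume[cid])
            t = float(lattice.target_volume[cid])
            dh += lam * ((v + gain - t) ** 2 - (v - t) ** 2)
    return dh


def delta_h(lattice: VoxelLattice, model: EnergyModel, source_voxel, target_voxel,
            neighborhood: Neighborhood | None = None) -> float:
    """Energy change of copying the source voxel's label onto the target voxel.

    Raises if the two voxels carry the same label (a caller logic error).
    """
    src = lattice.label_at(source_voxel)
    if src == lattice.label_at(target_voxel):
        raise ValueError("delta_h undefined for a same-label pair")
    return delta_for_relabel(lattice, model, target_voxel, src, neighborhood)
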