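"""Voxel lattice and compartment registry.

Every simulated object — a chondrocyte, a structural-ECM blob (ECMst), a
volumetric-ECM blob (ECMv), or the culture medium — is a *compartment*: a set
of lattice voxels sharing an integer id.  The medium is the singleton
compartment with id 0.  The registry is stored as growable parallel numpy
arrays (type, zone, volume, target volume, bounding box) so the Monte Carlo
kernel can index it directly; :class:`Compartment` is a lightweight read view.

Bookkeeping is exact by construction: every label rewrite goes through
:func:`apply_index_copy`, which updates the source and target compartment
volumes by ±1.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .params import Zone

MEDIUM_ID = 0

FIXED_MEDIUM = "fixed-medium"
PERIODIC = "periodic"


class CompartmentType(enum.IntEnum):
    Medium = 0
    Cell = 1
    ECMst = 2
    ECMv = 3


_ZONE_CODE = {Zone.NONE: 0, Zone.SZ: 1, Zone.MZ: 2, Zone.DZ: 3}
_CODE_ZONE = {v: k for k, v in _ZONE_CODE.items()}


@dataclass(frozen=True)
class Compartment:
    """Read-only view of one registry row."""

    id: int
    ctype: CompartmentType
    zone: Zone
    volume: int
    target_volume: float


@dataclass(frozen=True)
class Neighborhood:
    """Order-limited 3D neighborhood: 1 = 6 face, 2 = +12 edge, 3 = +8 corner."""

    order: int = 1

    def __post_init__(self) -> None:
        if self.order not in (1, 2, 3):
            raise ValueError("neighborhood order must be 1, 2 or 3")

    @property
    def offsets(self) -> np.ndarray:
        offs = []
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dz in (-1, 0, 1):
                    rank = abs(dx) + abs(dy) + abs(dz)
                    if 1 <= rank <= self.order:
                        offs.append((dx, dy, dz))
        return np.array(offs, dtype=np.int64)


class Site(NamedTuple):
    """A neighbor site; ``inside`` is False for virtual out-of-lattice medium."""

    coord: tuple[int, int, int]
    inside: bool
    label: int


class VoxelLattice:
    """3D integer label field plus the compartment registry."""

    def __init__(self, dims: tuple[int, int, int], boundary: str = FIXED_MEDIUM):
        dims = tuple(int(d) for d in dims)
        if len(dims) != 3 or any(d < 1 for d in dims):
            raise ValueError(f"lattice dims must be three positive integers, got {dims}")
        if boundary not in (FIXED_MEDIUM, PERIODIC):
            raise ValueError(f"unknown boundary condition {boundary!r}")
        self.dims = dims
        self.boundary = boundary
        self.labels = np.zeros(dims, dtype=np.int32)
        cap = 64
        self.ctype = np.zeros(cap, dtype=np.int8)
        self.zone_code = np.zeros(cap, dtype=np.int8)
        self.volume = np.zeros(cap, dtype=np.int64)
        self.target_volume = np.zeros(cap, dtype=np.float64)
        self.alive = np.zeros(cap, dtype=bool)
        # inclusive bounding boxes [x0,y0,z0,x1,y1,z1]; empty = x0 > x1
        self.bbox = np.zeros((cap, 6), dtype=np.int32)
        self.bbox[:, :3] = np.iinfo(np.int32).max
        self.bbox[:, 3:] = -1
        self.n_ids = 1  # id 0 = medium
        self.alive[MEDIUM_ID] = True
        self.volume[MEDIUM_ID] = int(np.prod(dims))

    # -- registry ---------------------------------------------------------

    def _grow(self, need: int) -> None:
        cap = len(self.ctype)
        if need <= cap:
            return
        new = max(need, cap * 2)
        for name in ("ctype", "zone_code", "volume", "target_volume", "alive"):
            arr = getattr(self, name)
            ext = np.zeros(new, dtype=arr.dtype)
            ext[:cap] = arr
            setattr(self, name, ext)
        ext = np.zeros((new, 6), dtype=np.int32)
        ext[:, :3] = np.iinfo(np.int32).max
        ext[:, 3:] = -1
        ext[:cap] = self.bbox
        self.bbox = ext

    def new_compartment(self, ctype: CompartmentType, zone: Zone | str = Zone.NONE,
                        target_volume: float = 0.0) -> int:
        if ctype == CompartmentType.Medium:
            raise ValueError("medium is the singleton compartment id 0")
        cid = self.n_ids
        self._grow(cid + 1)
        self.n_ids += 1
        self.ctype[cid] = int(ctype)
        self.zone_code[cid] = _ZONE_CODE[Zone.coerce(zone)]
        self.volume[cid] = 0
        self.target_volume[cid] = target_volume
        self.alive[cid] = True
        return cid

    def compartment(self, cid: int) -> Compartment:
        if not (0 <= cid < self.n_ids) or not self.alive[cid]:
            raise KeyError(f"no registered compartment with id {cid}")
        return Compartment(
            id=cid,
            ctype=CompartmentType(int(self.ctype[cid])),
            zone=_CODE_ZONE[int(self.zone_code[cid])],
            volume=int(self.volume[cid]),
            target_volume=float(self.target_volume[cid]),
        )

    def compartments(self, ctype: CompartmentType | None = None) -> list[Compartment]:
        out = []
        for cid in range(self.n_ids):
            if not self.alive[cid]:
                continue
            if ctype is not None and self.ctype[cid] != int(ctype):
                continue
            out.append(self.compartment(cid))
        return out

    def ids_of_type(self, ctype: CompartmentType) -> np.ndarray:
        mask = self.alive[: self.n_ids] & (self.ctype[: self.n_ids] == int(ctype))
        return np.nonzero(mask)[0]

    def remove_compartment(self, cid: int) -> int:
        """Delete a compartment: its voxels become medium.  Returns freed voxels."""
        if cid == MEDIUM_ID:
            raise ValueError("cannot remove the medium")
        vox = self.voxels_of(cid)
        n = len(vox)
        if n:
            self.labels[vox[:, 0], vox[:, 1], vox[:, 2]] = MEDIUM_ID
            self.volume[MEDIUM_ID] += n
        self.volume[cid] = 0
        self.alive[cid] = False
        self.bbox[cid, :3] = np.iinfo(np.int32).max
        self.bbox[cid, 3:] = -1
        return n

    # -- geometry ---------------------------------------------------------

    def in_bounds(self, voxel: tuple[int, int, int]) -> bool:
        x, y, z = voxel
        nx, ny, nz = self.dims
        return 0 <= x < nx and 0 <= y < ny and 0 <= z < nz

    def label_at(self, voxel) -> int:
        return int(self.labels[tuple(voxel)])

    def place_block(self, cid: int, corner: tuple[int, int, int],
                    shape: tuple[int, int, int]) -> None:
        """Assign a solid axis-aligned block of voxels to compartment ``cid``."""
        x, y, z = corner
        sx, sy, sz = shape
        region = self.labels[x:x + sx, y:y + sy, z:z + sz]
        if region.shape != (sx, sy, sz):
            raise ValueError("block extends outside the lattice")
        if np.any(region != MEDIUM_ID):
            raise ValueError("block overlaps a non-medium compartment")
        region[...] = cid
        n = sx * sy * sz
        self.volume[cid] += n
        self.volume[MEDIUM_ID] -= n
        self._bbox_include(cid, (x, y, z), (x + sx - 1, y + sy - 1, z + sz - 1))

    def assign_voxels(self, cid: int, voxels: np.ndarray) -> None:
        """Relabel explicit medium voxels (n×3 array) to compartment ``cid``."""
        voxels = np.asarray(voxels)
        labs = self.labels[voxels[:, 0], voxels[:, 1], voxels[:, 2]]
        if np.any(labs != MEDIUM_ID):
            raise ValueError("assign_voxels requires medium voxels")
        self.labels[voxels[:, 0], voxels[:, 1], voxels[:, 2]] = cid
        self.volume[cid] += len(voxels)
        self.volume[MEDIUM_ID] -= len(voxels)
        self._bbox_include(cid, voxels.min(axis=0), voxels.max(axis=0))

    def _bbox_include(self, cid: int, lo, hi) -> None:
        b = self.bbox[cid]
        b[:3] = np.minimum(b[:3], lo)
        b[3:] = np.maximum(b[3:], hi)

    def voxels_of(self, cid: int) -> np.ndarray:
        """All voxels carrying ``cid``, as an (n, 3) array (bbox-limited scan)."""
        if cid == MEDIUM_ID:
            return np.argwhere(self.labels == MEDIUM_ID)
        b = self.bbox[cid]
        if b[0] > b[3]:
            return np.zeros((0, 3), dtype=np.int64)
        sub = self.labels[b[0]:b[3] + 1, b[1]:b[4] + 1, b[2]:b[5] + 1]
        vox = np.argwhere(sub == cid)
        vox += b[:3]
        return vox

    def refresh_bboxes(self) -> None:
        """Recompute tight bounding boxes (they only grow during dynamics)."""
        self.bbox[: self.n_ids, :3] = np.iinfo(np.int32).max
        self.bbox[: self.n_ids, 3:] = -1
        for axis in range(3):
            proj = np.moveaxis(self.labels, axis, 0)
            for i in range(proj.shape[0]):
                present = np.unique(proj[i])
                self.bbox[present, axis] = np.minimum(self.bbox[present, axis], i)
                self.bbox[present, 3 + axis] = np.maximum(self.bbox[present, 3 + axis], i)

    # -- integrity --------------------------------------------------------

    def recount_volumes(self) -> np.ndarray:
        counts = np.bincount(self.labels.ravel(), minlength=self.n_ids)
        return counts[: self.n_ids]

    def check_bookkeeping(self) -> None:
        """Raise if registry volumes disagree with the label field."""
        counts = self.recount_volumes()
        if not np.array_equal(counts, self.volume[: self.n_ids]):
            bad = np.nonzero(counts != self.volume[: self.n_ids])[0]
            raise AssertionError(f"volume bookkeeping mismatch for ids {bad.tolist()}")
        if counts.sum() != int(np.prod(self.dims)):
            raise AssertionError("voxel count not conserved")


def create_lattice(dims: tuple[int, int, int], boundary: str = FIXED_MEDIUM) -> VoxelLattice:
    """Create an all-medium lattice (medium volume = nx·ny·nz)."""
    return VoxelLattice(dims, boundary)


def neighbor_voxels(lattice: VoxelLattice, voxel: tuple[int, int, int],
                    neighborhood: Neighborhood = Neighborhood(1)) -> list[Site]:
    """Neighbor sites of ``voxel``.

    Under the fixed-medium boundary, out-of-range neighbors are reported as
    virtual medium-labeled sites (``inside=False``); under periodic wrap they
    are mapped back into the lattice.
    """
    if not lattice.in_bounds(voxel):
        raise ValueError(f"voxel {voxel} outside lattice {lattice.dims}")
    x, y, z = voxel
    nx, ny, nz = lattice.dims
    sites = []
    for dx, dy, dz in neighborhood.offsets:
        c = (x + dx, y + dy, z + dz)
        if lattice.in_bounds(c):
            sites.append(Site(c, True, lattice.label_at(c)))
        elif lattice.boundary == PERIODIC:
            c = (c[0] % nx, c[1] % ny, c[2] % nz)
            sites.append(Site(c, True, lattice.label_at(c)))
        else:
            sites.append(Site(c, False, MEDIUM_ID))
    return sites


def are_neighbors(lattice: VoxelLattice, a, b, neighborhood: Neighborhood) -> bool:
    return any(s.inside and s.coord == tuple(b)
               for s in neighbor_voxels(lattice, a, neighborhood))


def apply_index_copy(lattice: VoxelLattice, source_voxel, target_voxel) -> None:
    """Copy the source voxel's label onto the target voxel, with exact bookkeeping.

    The caller guarantees the voxels are neighbors; calling with identical
    labels is a caller logic error and raises.
    """
    src = lattice.label_at(source_voxel)
    tgt = lattice.label_at(target_voxel)
    if src == tgt:
        raise ValueError("index copy requested between voxels of the same compartment")
    lattice.labels[tuple(target_voxel)] = src
    lattice.volume[src] += 1
    lattice.volume[tgt] -= 1
    lattice._bbox_include(src, target_voxel, target_voxel)


def compartment_contact_area(lattice: VoxelLattice, id_a: int, id_b: int,
                             neighborhood: Neighborhood = Neighborhood(1)) -> int:
    """Number of unordered neighbor voxel pairs with labels (id_a, id_b).

    Virtual out-of-lattice medium sites count toward contact with the medium
    under the fixed-medium boundary.  ``id_a == id_b`` is 0 by definition.
    """
    for cid in (id_a, id_b):
        if not (0 <= cid < lattice.n_ids) or not lattice.alive[cid]:
            raise KeyError(f"unknown compartment id {cid}")
    if id_a == id_b:
        return 0
    pair = {id_a, id_b}
    count = 0
    mask = (lattice.labels == id_a) | (lattice.labels == id_b)
    for voxel in np.argwhere(mask):
        v = tuple(int(c) for c in voxel)
        lab_v = lattice.label_at(v)
        for site in neighbor_voxels(lattice, v, neighborhood):
            if site.inside:
                if {lab_v, site.label} == pair and v < site.coord:
                    count += 1
            elif lab_v != MEDIUM_ID and {lab_v, MEDIUM_ID} == pair:
                count += 1
    return count
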