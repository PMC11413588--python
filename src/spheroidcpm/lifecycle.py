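"""Cyclic cell and ECM behavior, executed once per MCS after the sweep.

Cells grow by increasing their *target* volume at v_g voxel³/MCS (the realized
volume follows through the volume constraint).  A cell whose realized volume
exceeds the action threshold V_A may, each MCS, divide (probability P_M) or
secrete an ECM compartment (P_ECMst, P_ECMv); by default a mitosis draw
pre-empts the secretion draws for that MCS.  Cells above V_Death are removed.

ECM compartments have no fixed target volume: their target starts at V_ECMInit
when created and decays at v_d voxel³/MCS; once the realized volume falls
below V_Delete the compartment is deleted and its voxels revert to medium.
"""

from __future__ import annotations

import numpy as np

from .lattice import MEDIUM_ID, CompartmentType, VoxelLattice
from .params import ParameterSet

_FACE_OFFSETS = np.array([(1, 0, 0), (-1, 0, 0), (0, 1, 0),
                          (0, -1, 0), (0, 0, 1), (0, 0, -1)], dtype=np.int64)


# -- single-compartment operations ---------------------------------------

def divide_cell(state, cid: int, params: ParameterSet | None = None,
                rng: np.random.Generator | None = None):
    """Split a cell by a random plane through its centroid.

    Both halves are cells of the same zone with target volume V_Cell/2; the
    daughter gets a fresh id.  A 1-voxel cell cannot split: the mitosis is
    skipped and logged.  Returns (parent_id, daughter_id) or None.
    """
    lat = state.lattice
    params = params or state.params
    rng = rng if rng is not None else state.rng
    vox = lat.voxels_of(cid)
    if len(vox) < 2:
        state.log_event("mitosis_skipped", cid)
        return None
    centroid = vox.mean(axis=0)
    normal = rng.standard_normal(3)
    norm = np.linalg.norm(normal)
    normal = normal / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    d = (vox - centroid) @ normal
    daughter_side = d > 0.0
    if daughter_side.all() or not daughter_side.any():
        # degenerate plane (e.g. coplanar voxels): split at the median instead
        order = np.argsort(d, kind="stable")
        daughter_side = np.zeros(len(vox), dtype=bool)
        daughter_side[order[len(vox) // 2:]] = True
    dvox = vox[daughter_side]
    zone = lat.compartment(cid).zone
    did = lat.new_compartment(CompartmentType.Cell, zone,
                              target_volume=params.V_daughter)
    lat.labels[dvox[:, 0], dvox[:, 1], dvox[:, 2]] = did
    lat.volume[did] = len(dvox)
    lat.volume[cid] -= len(dvox)
    lat._bbox_include(did, dvox.min(axis=0), dvox.max(axis=0))
    lat.target_volume[cid] = params.V_parent
    state.log_event("mitosis", cid)
    return cid, did


def secrete_ecm(state, cid: int, kind: CompartmentType,
                params: ParameterSet | None = None,
                rng: np.random.Generator | None = None):
    """Create a new ECM compartment at medium voxels adjacent to the cell.

    The seed is up to a 2×2×2 block of medium next to the cell boundary (the
    block with the most free medium wins, ties broken by RNG); the volume
    constraint then grows it toward its target V_ECMInit.  Returns the new id,
    or None (logged) when the cell has no adjacent medium.
    """
    if kind not in (CompartmentType.ECMst, CompartmentType.ECMv):
        raise ValueError("secreted compartment must be ECMst or ECMv")
    lat = state.lattice
    params = params or state.params
    rng = rng if rng is not None else state.rng
    vox = lat.voxels_of(cid)
    cand = _adjacent_medium(lat, vox)
    if len(cand) == 0:
        state.counters["secretions_blocked"] += 1
        state.log_event("secretion_blocked", cid)
        return None
    seed = cand[int(rng.integers(len(cand)))]
    block = _best_medium_block(lat, seed, rng)
    zone = lat.compartment(cid).zone
    eid = lat.new_compartment(kind, zone, target_volume=params.V_ECMInit)
    lat.assign_voxels(eid, block)
    name = "ECMst" if kind == CompartmentType.ECMst else "ECMv"
    state.counters[f"secretions_{name}"] += 1
    state.log_event(f"secrete_{name}", cid)
    return eid


def _adjacent_medium(lat: VoxelLattice, vox: np.ndarray) -> np.ndarray:
    """Medium voxels face-adjacent to any of ``vox``, lexicographically sorted."""
    if len(vox) == 0:
        return np.zeros((0, 3), dtype=np.int64)
    cand = (vox[:, None, :] + _FACE_OFFSETS[None, :, :]).reshape(-1, 3)
    ok = np.all((cand >= 0) & (cand < np.array(lat.dims)), axis=1)
    cand = cand[ok]
    cand = cand[lat.labels[cand[:, 0], cand[:, 1], cand[:, 2]] == MEDIUM_ID]
    if len(cand) == 0:
        return cand
    return np.unique(cand, axis=0)


def _best_medium_block(lat: VoxelLattice, seed: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    """Medium voxels of the best 2×2×2 block containing ``seed``."""
    best: list[np.ndarray] = []
    best_n = 0
    for dx in (0, -1):
        for dy in (0, -1):
            for dz in (0, -1):
                corner = seed + np.array([dx, dy, dz])
                if np.any(corner < 0) or np.any(corner + 2 > np.array(lat.dims)):
                    continue
                xs, ys, zs = corner
                sub = lat.labels[xs:xs + 2, ys:ys + 2, zs:zs + 2]
                block = np.argwhere(sub == MEDIUM_ID) + corner
                if len(block) > best_n:
                    best, best_n = [block], len(block)
                elif len(block) == best_n and best_n > 0:
                    best.append(block)
    if not best:
        return seed.reshape(1, 3)
    return best[int(rng.integers(len(best)))]


def update_cell(state, cid: int, params: ParameterSet | None = None,
                rng: np.random.Generator | None = None) -> None:
    """Per-MCS update of one live cell: growth, death check, gated actions."""
    lat = state.lattice
    params = params or state.params
    rng = rng if rng is not None else state.rng
    lat.target_volume[cid] += params.v_g
    vol = int(lat.volume[cid])
    if vol > params.V_Death:
        lat.remove_compartment(cid)
        state.counters["cell_deaths"] += 1
        state.log_event("cell_death", cid)
        return
    if vol > params.V_A:
        divided = rng.random() < params.prob_mitosis
        if divided and divide_cell(state, cid, params, rng) is not None:
            state.counters["mitoses"] += 1
        if not divided or state.independent_action_draws:
            if rng.random() < params.prob_ecmst:
                secrete_ecm(state, cid, CompartmentType.ECMst, params, rng)
            if rng.random() < params.prob_ecmv:
                secrete_ecm(state, cid, CompartmentType.ECMv, params, rng)


def update_ecm(state, cid: int, params: ParameterSet | None = None) -> None:
    """Per-MCS update of one ECM compartment: target decay and deletion check."""
    lat = state.lattice
    params = params or state.params
    if state.ecm_target_mode == "decay":
        lat.target_volume[cid] -= params.v_d
    if lat.volume[cid] < params.V_Delete:
        lat.remove_compartment(cid)
        state.counters["ecm_deletions"] += 1
        state.log_event("ecm_deleted", cid)


# -- per-MCS driver -------------------------------------------------------

def step(state) -> None:
    """One lifecycle pass over all live compartments.

    ECM is updated first (so freshly secreted blobs are not judged against the
    deletion threshold before they have had a sweep to grow), then cells.
    Growth and decay are vectorized; discrete events (death, deletion, mitosis,
    secretion) are applied in an RNG-shuffled order each MCS so that compartment
    ids carry no systematic advantage when competing for space.
    """
    lat = state.lattice
    p = state.params
    rng = state.rng
    n = lat.n_ids
    alive = lat.alive[:n]
    ctype = lat.ctype[:n]

    # --- ECM: decay targets, delete shrunken compartments ---
    ecm_mask = alive & ((ctype == int(CompartmentType.ECMst)) |
                        (ctype == int(CompartmentType.ECMv)))
    ecm_ids = np.nonzero(ecm_mask)[0]
    if state.ecm_target_mode == "decay" and len(ecm_ids):
        lat.target_volume[ecm_ids] -= p.v_d
    doomed = ecm_ids[lat.volume[ecm_ids] < p.V_Delete]
    for cid in rng.permutation(doomed):
        lat.remove_compartment(int(cid))
        state.counters["ecm_deletions"] += 1
        state.log_event("ecm_deleted", int(cid))

    # --- cells: grow targets, remove dead, draw and apply gated actions ---
    cell_mask = alive & (ctype == int(CompartmentType.Cell))
    cell_ids = np.nonzero(cell_mask)[0]
    if len(cell_ids) == 0:
        return
    lat.target_volume[cell_ids] += p.v_g
    vols = lat.volume[cell_ids]
    dead = cell_ids[(vols > p.V_Death) | (vols == 0)]
    for cid in dead:
        lat.remove_compartment(int(cid))
        state.counters["cell_deaths"] += 1
        state.log_event("cell_death", int(cid))
    eligible = cell_ids[(vols > p.V_A) & (vols <= p.V_Death)]
    if len(eligible) == 0:
        return
    draw_m = rng.random(len(eligible)) < p.prob_mitosis
    if state.independent_action_draws:
        can_secrete = np.ones(len(eligible), dtype=bool)
    else:
        can_secrete = ~draw_m
    draw_st = (rng.random(len(eligible)) < p.prob_ecmst) & can_secrete
    draw_v = (rng.random(len(eligible)) < p.prob_ecmv) & can_secrete
    events: list[tuple[int, str]] = []
    events += [(int(c), "M") for c in eligible[draw_m]]
    events += [(int(c), "st") for c in eligible[draw_st]]
    events += [(int(c), "v") for c in eligible[draw_v]]
    for idx in rng.permutation(len(events)):
        cid, ev = events[idx]
        if not lat.alive[cid] or lat.volume[cid] == 0:
            continue
        if ev == "M":
            if divide_cell(state, cid, p, rng) is not None:
                state.counters["mitoses"] += 1
        elif ev == "st":
            secrete_ecm(state, cid, CompartmentType.ECMst, p, rng)
        else:
            secrete_ecm(state, cid, CompartmentType.ECMv, p, rng)
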