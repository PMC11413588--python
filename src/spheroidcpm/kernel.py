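"""Compiled Metropolis sweep.

The index-copy attempt loop is the hot path (one sweep is ~10^5–10^6 attempts
and a 14-day run is 3120 sweeps), so it is JIT-compiled with numba.  The local
energy change computed here is the same quantity as :func:`energy.delta_h`;
tests cross-check the two routes move by move.

Randomness uses an inline xorshift128+ generator so the accept/reject stream
is bit-reproducible from the stored two-word state, independent of numpy
internals.  The modulo draw for voxel/neighbor selection carries a bias of
order m/2^64, far below anything observable.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .lattice import FIXED_MEDIUM


@njit(inline="always")
def _next_u64(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0
    s1 ^= s0 >> np.uint64(26)
    state[1] = s1
    return (state[0] + state[1]) & np.uint64(0xFFFFFFFFFFFFFFFF)


@njit(inline="always")
def _next_double(state):
    return float(_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


def seed_state(seed: int) -> np.ndarray:
    """Expand an integer seed into a nonzero xorshift128+ state (splitmix64)."""
    mask = (1 << 64) - 1
    out = np.empty(2, dtype=np.uint64)
    x = int(seed) & mask
    for i in range(2):
        x = (x + 0x9E3779B97F4A7C15) & mask
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & mask
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & mask
        out[i] = np.uint64(z ^ (z >> 31))
    if out[0] == 0 and out[1] == 0:
        out[0] = np.uint64(1)
    return out


@njit
def _neighbor_label(labels, x, y, z, periodic):
    nx, ny, nz = labels.shape
    if 0 <= x < nx and 0 <= y < ny and 0 <= z < nz:
        return labels[x, y, z]
    if periodic:
        return labels[x % nx, y % ny, z % nz]
    return np.int32(0)  # fixed-medium boundary: out-of-lattice sites are medium


@njit
def move_delta(labels, tx, ty, tz, new_label, class_of, volume, target_volume,
               constrained, jmat, lam, offsets, periodic):
    """Local ΔH of rewriting the target voxel's label to ``new_label``."""
    old = labels[tx, ty, tz]
    c_old = class_of[old]
    c_new = class_of[new_label]
    dh = 0.0
    for k in range(offsets.shape[0]):
        ln = _neighbor_label(labels, tx + offsets[k, 0], ty + offsets[k, 1],
                             tz + offsets[k, 2], periodic)
        cn = class_of[ln]
        if ln != new_label:
            dh += jmat[c_new, cn]
        if ln != old:
            dh -= jmat[c_old, cn]
    if constrained[new_label]:
        dv = float(volume[new_label]) - target_volume[new_label]
        dh += lam * ((dv + 1.0) ** 2 - dv ** 2)
    if constrained[old]:
        dv = float(volume[old]) - target_volume[old]
        dh += lam * ((dv - 1.0) ** 2 - dv ** 2)
    return dh


@njit
def metropolis_sweep(labels, class_of, volume, target_volume, constrained,
                     jmat, lam, tm, n_attempts, offsets, periodic, bbox,
                     rng_state):
    """Run ``n_attempts`` index-copy attempts in place.

    Each attempt samples a target voxel uniformly, then a source site uniformly
    among its neighbors (under the fixed-medium boundary an out-of-lattice
    source supplies the medium label and can never itself be overwritten).
    Same-label draws count as attempts but cost no energy evaluation.
    Returns (attempts, distinct-label attempts, accepted copies).
    """
    nx, ny, nz = labels.shape
    n_vox = np.uint64(nx * ny * nz)
    n_off = np.uint64(offsets.shape[0])
    n_distinct = 0
    n_accept = 0
    for _ in range(n_attempts):
        r = _next_u64(rng_state) % n_vox
        tz = np.int64(r % np.uint64(nz))
        r //= np.uint64(nz)
        ty = np.int64(r % np.uint64(ny))
        tx = np.int64(r // np.uint64(ny))
        k = np.int64(_next_u64(rng_state) % n_off)
        new_label = _neighbor_label(labels, tx + offsets[k, 0], ty + offsets[k, 1],
                                    tz + offsets[k, 2], periodic)
        old = labels[tx, ty, tz]
        if new_label == old:
            continue
        n_distinct += 1
        dh = move_delta(labels, tx, ty, tz, new_label, class_of, volume,
                        target_volume, constrained, jmat, lam, offsets, periodic)
        if dh > 0.0 and _next_double(rng_state) >= np.exp(-dh / tm):
            continue
        labels[tx, ty, tz] = new_label
        volume[new_label] += 1
        volume[old] -= 1
        if tx < bbox[new_label, 0]:
            bbox[new_label, 0] = tx
        if ty < bbox[new_label, 1]:
            bbox[new_label, 1] = ty
        if tz < bbox[new_label, 2]:
            bbox[new_label, 2] = tz
        if tx > bbox[new_label, 3]:
            bbox[new_label, 3] = tx
        if ty > bbox[new_label, 4]:
            bbox[new_label, 4] = ty
        if tz > bbox[new_label, 5]:
            bbox[new_label, 5] = tz
        n_accept += 1
    return n_attempts, n_distinct, n_accept


@njit
def tighten_bboxes(labels, bbox):
    """Recompute exact bounding boxes in one pass (they only grow in the sweep)."""
    n = bbox.shape[0]
    for i in range(n):
        bbox[i, 0] = bbox[i, 1] = bbox[i, 2] = 2147483647
        bbox[i, 3] = bbox[i, 4] = bbox[i, 5] = -1
    nx, ny, nz = labels.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                cid = labels[x, y, z]
                if x < bbox[cid, 0]:
                    bbox[cid, 0] = x
                if y < bbox[cid, 1]:
                    bbox[cid, 1] = y
                if z < bbox[cid, 2]:
                    bbox[cid, 2] = z
                if x > bbox[cid, 3]:
                    bbox[cid, 3] = x
                if y > bbox[cid, 4]:
                    bbox[cid, 4] = y
                if z > bbox[cid, 5]:
                    bbox[cid, 5] = z


def sweep_args(lattice, model):
    """Assemble the static kernel arguments for a lattice + energy model."""
    from .energy import lattice_class_codes
    codes = lattice_class_codes(lattice)
    constrained = model.constraint.constrained_mask(lattice)
    return dict(
        class_of=codes,
        constrained=constrained,
        jmat=np.nan_to_num(model.j_table.matrix, nan=np.inf),
        lam=float(model.constraint.lambda_vol),
        offsets=model.neighborhood.offsets,
        periodic=lattice.boundary != FIXED_MEDIUM,
    )
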