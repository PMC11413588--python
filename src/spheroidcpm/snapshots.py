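"""Checksummed snapshot archives and ASCII structured-points export.

A snapshot stores the label field, the compartment registry, the clock, both
RNG states and the cumulative counters, so that a resumed run continues
voxel-for-voxel identically to an uninterrupted one.  Archives are versioned;
readers reject unknown versions and corrupt payloads (SHA-256 mismatch).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np

from .dynamics import DomainParameters, SimulationClock, SimulationState
from .lattice import Neighborhood, VoxelLattice
from .params import ParameterSet, Zone

FORMAT_VERSION = 1

_ARRAYS = ("ctype", "zone_code", "volume", "target_volume", "alive", "bbox")


def _checksum(labels: np.ndarray, volume: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(labels).tobytes())
    h.update(np.ascontiguousarray(volume).tobytes())
    return h.hexdigest()


def state_hash(state: SimulationState) -> str:
    """Hash of the label field + registry volumes (trajectory fingerprint)."""
    return _checksum(state.lattice.labels, state.lattice.volume[: state.lattice.n_ids])


def write_snapshot(state: SimulationState, path, config: dict | None = None) -> None:
    lat = state.lattice
    n = lat.n_ids
    params_dict = dataclasses.asdict(state.params)
    params_dict["zone"] = state.params.zone.value
    meta = {
        "version": FORMAT_VERSION,
        "dims": list(lat.dims),
        "boundary": lat.boundary,
        "n_ids": n,
        "clock": dataclasses.asdict(state.clock),
        "params": params_dict,
        "domain": {
            "Tm": state.domain.Tm,
            "attempts_per_mcs": state.domain.attempts_per_mcs,
            "neighborhood_order": state.domain.neighborhood.order,
            "rng_seed": state.domain.rng_seed,
        },
        "ecm_target_mode": state.ecm_target_mode,
        "independent_action_draws": state.independent_action_draws,
        "counters": state.counters,
        "rng_state": state.rng.bit_generator.state,
        "event_log_offset": len(state.event_log),
        "checksum": _checksum(lat.labels, lat.volume[:n]),
        "config": config,
    }
    arrays = {name: getattr(lat, name)[:n] for name in _ARRAYS}
    np.savez_compressed(Path(path), labels=lat.labels,
                        kernel_state=state.kernel_state,
                        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                        **arrays)


def read_snapshot(path) -> SimulationState:
    with np.load(Path(path)) as npz:
        meta = json.loads(bytes(npz["meta"].tobytes()).decode())
        if meta.get("version") != FORMAT_VERSION:
            raise ValueError(f"unsupported snapshot format version "
                             f"{meta.get('version')!r} (expected {FORMAT_VERSION})")
        labels = npz["labels"]
        kernel_state = npz["kernel_state"].astype(np.uint64)
        arrays = {name: npz[name] for name in _ARRAYS}
    n = int(meta["n_ids"])
    if _checksum(labels, arrays["volume"]) != meta["checksum"]:
        raise ValueError(f"snapshot {path} failed its checksum: corrupt archive")
    lat = VoxelLattice(tuple(meta["dims"]), meta["boundary"])
    lat.labels = labels.astype(np.int32)
    lat._grow(n)
    lat.n_ids = n
    for name in _ARRAYS:
        getattr(lat, name)[:n] = arrays[name]
    pd = dict(meta["params"])
    pd["zone"] = Zone.coerce(pd["zone"])
    params = ParameterSet(**pd)
    dom = meta["domain"]
    domain = DomainParameters(Tm=dom["Tm"], attempts_per_mcs=dom["attempts_per_mcs"],
                              neighborhood=Neighborhood(dom["neighborhood_order"]),
                              rng_seed=dom["rng_seed"])
    state = SimulationState(lat, params, domain,
                            ecm_target_mode=meta["ecm_target_mode"],
                            independent_action_draws=meta["independent_action_draws"])
    state.clock = SimulationClock(**meta["clock"])
    state.counters.update(meta["counters"])
    rng_state = meta["rng_state"]
    state.rng.bit_generator.state = rng_state
    state.kernel_state = kernel_state
    lat.check_bookkeeping()
    return state


def export_structured_points(state_or_lattice, path) -> None:
    """ASCII legacy structured-points export of the label field (visualization)."""
    lat = state_or_lattice if isinstance(state_or_lattice, VoxelLattice) \
        else state_or_lattice.lattice
    nx, ny, nz = lat.dims
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("compartment labels\nASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\nSPACING 1 1 1\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        fh.write("SCALARS compartment_id int 1\nLOOKUP_TABLE default\n")
        # VTK structured points iterate x fastest
        flat = np.transpose(lat.labels, (2, 1, 0)).ravel()
        for i in range(0, len(flat), 20):
            fh.write(" ".join(map(str, flat[i:i + 20])) + "\n")
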