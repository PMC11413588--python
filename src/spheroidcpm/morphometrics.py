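"""Morphometric readouts: clusters, diameters, composition, radial profiles.

Two connectivity notions are reported, matching how spheroids are described:
*all-matter* components (cells + ECM) define "spheroids", while *cells-only*
components define "cell clusters".  Components use face (order-1) connectivity
and each compartment is assigned to the component containing the majority of
its voxels.

"Spheroid diameter" is the equivalent circular diameter of the cluster's XY
footprint, ``2·sqrt(A/π)`` — the projection a microscope camera sees; the
equivalent-sphere diameter ``(6V/π)^(1/3)`` is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .lattice import MEDIUM_ID, CompartmentType, VoxelLattice

ALL_MATTER = "all-matter"
CELLS_ONLY = "cells-only"

_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


@dataclass
class Cluster:
    """One connected component of compartments."""

    member_ids: list[int]
    voxel_count: int
    cell_count: int
    ecmst_count: int
    ecmv_count: int
    centroid: tuple[float, float, float]
    projected_diameter: float
    equivalent_diameter: float
    voxels: np.ndarray  # (n, 3), retained for radial profiling


@dataclass
class ClusterReport:
    mcs: int
    mode: str
    clusters: list[Cluster]

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def largest(self) -> Cluster:
        """Largest cluster by voxel count; ties go to the lowest centroid z
        (closest to the substrate)."""
        if not self.clusters:
            raise ValueError("report contains no clusters")
        return min(self.clusters, key=lambda c: (-c.voxel_count, c.centroid[2]))


@dataclass
class RadialProfile:
    """Concentric-shell composition around a cluster centroid.

    ``edges`` are shell boundaries in voxels from the centroid; fractions are
    per-shell voxel-type fractions (cell/ECMst/ECMv/medium), each row summing
    to 1 over the lattice voxels whose centers fall in the shell.
    """

    edges: np.ndarray
    fractions: pd.DataFrame  # columns: cell, ECMst, ECMv, medium


def projected_diameter(voxels: np.ndarray) -> float:
    """Equivalent circular diameter of the XY footprint, 2·sqrt(A/π)."""
    if len(voxels) == 0:
        raise ValueError("empty cluster has no diameter")
    area = len(np.unique(voxels[:, :2], axis=0))
    return 2.0 * float(np.sqrt(area / np.pi))


def equivalent_sphere_diameter(voxels: np.ndarray) -> float:
    if len(voxels) == 0:
        raise ValueError("empty cluster has no diameter")
    return float((6.0 * len(voxels) / np.pi) ** (1.0 / 3.0))


def find_clusters(state_or_lattice, mode: str = ALL_MATTER) -> ClusterReport:
    """Connected components of non-medium (or cell-only) voxels.

    Compartments are assigned to the component containing their majority
    voxel, so a compartment straddling two components is counted once.
    """
    lattice, mcs = _as_lattice(state_or_lattice)
    if mode not in (ALL_MATTER, CELLS_ONLY):
        raise ValueError(f"unknown cluster mode {mode!r}")
    labels = lattice.labels
    if mode == ALL_MATTER:
        mask = labels != MEDIUM_ID
    else:
        is_cell = lattice.ctype[: lattice.n_ids] == int(CompartmentType.Cell)
        mask = is_cell[labels]
    comp, n_comp = ndimage.label(mask, structure=_FACE_STRUCTURE)
    clusters: list[Cluster] = []
    if n_comp == 0:
        return ClusterReport(mcs, mode, clusters)
    # majority component per compartment id
    flat_ids = labels[mask]
    flat_comp = comp[mask]
    df = pd.DataFrame({"cid": flat_ids, "comp": flat_comp})
    counts = df.groupby(["cid", "comp"]).size().reset_index(name="n")
    counts = counts.sort_values(["cid", "n", "comp"])
    majority = counts.groupby("cid").last()["comp"]
    members: dict[int, list[int]] = {k: [] for k in range(1, n_comp + 1)}
    for cid, k in majority.items():
        members[int(k)].append(int(cid))
    slices = ndimage.find_objects(comp)
    for k in range(1, n_comp + 1):
        sl = slices[k - 1]
        vox = np.argwhere(comp[sl] == k)
        vox += np.array([s.start for s in sl])
        ids = sorted(members[k])
        types = lattice.ctype[ids] if ids else np.array([], dtype=np.int8)
        clusters.append(Cluster(
            member_ids=ids,
            voxel_count=len(vox),
            cell_count=int(np.sum(types == int(CompartmentType.Cell))),
            ecmst_count=int(np.sum(types == int(CompartmentType.ECMst))),
            ecmv_count=int(np.sum(types == int(CompartmentType.ECMv))),
            centroid=tuple(vox.mean(axis=0)),
            projected_diameter=projected_diameter(vox),
            equivalent_diameter=equivalent_sphere_diameter(vox),
            voxels=vox,
        ))
    clusters.sort(key=lambda c: (-c.voxel_count, c.centroid[2]))
    return ClusterReport(mcs, mode, clusters)


def diameter_ratio(report_t2: ClusterReport, report_t1: ClusterReport) -> float:
    """Projected-diameter ratio of the largest clusters at two snapshots."""
    return report_t2.largest().projected_diameter / \
        report_t1.largest().projected_diameter


def radial_profile(state_or_lattice, cluster: Cluster,
                   n_shells: int = 6) -> RadialProfile:
    """Equal-width concentric shells from the cluster centroid to its max radius."""
    lattice, _ = _as_lattice(state_or_lattice)
    if n_shells < 2:
        raise ValueError("need at least 2 shells")
    if cluster.voxel_count < 2:
        raise ValueError("radial profile undefined for a single-voxel cluster")
    center = np.array(cluster.centroid)
    r_max = float(np.linalg.norm(cluster.voxels - center, axis=1).max())
    if r_max == 0:
        raise ValueError("degenerate cluster with zero radius")
    edges = np.linspace(0.0, r_max, n_shells + 1)
    lo = np.maximum(np.floor(center - r_max).astype(int), 0)
    hi = np.minimum(np.ceil(center + r_max).astype(int) + 1, lattice.dims)
    sub = lattice.labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    coords = np.argwhere(np.ones_like(sub, dtype=bool)) + lo
    radii = np.linalg.norm(coords - center, axis=1)
    types = lattice.ctype[: lattice.n_ids][sub.ravel()]
    shell_idx = np.clip(np.searchsorted(edges, radii, side="right") - 1,
                        0, n_shells - 1)
    inside = radii <= r_max
    rows = []
    for s in range(n_shells):
        m = inside & (shell_idx == s)
        total = int(m.sum())
        if total == 0:
            rows.append({"cell": np.nan, "ECMst": np.nan, "ECMv": np.nan,
                         "medium": np.nan})
            continue
        t = types[m]
        rows.append({
            "cell": np.mean(t == int(CompartmentType.Cell)),
            "ECMst": np.mean(t == int(CompartmentType.ECMst)),
            "ECMv": np.mean(t == int(CompartmentType.ECMv)),
            "medium": np.mean(t == int(CompartmentType.Medium)),
        })
    return RadialProfile(edges=edges, fractions=pd.DataFrame(rows))


def core_shell_contrast(profile: RadialProfile) -> dict[str, float]:
    """Inner-third minus outer-third mean fraction, per voxel type.

    Positive values mean enrichment toward the core; the published SZ
    phenotype is ECMv-positive and cell-negative (cells at the rim).
    """
    n = len(profile.fractions)
    third = max(1, n // 3)
    inner = profile.fractions.iloc[:third].mean()
    outer = profile.fractions.iloc[-third:].mean()
    return {k: float(inner[k] - outer[k]) for k in ("cell", "ECMst", "ECMv", "medium")}


def summary_timeseries(snapshots) -> pd.DataFrame:
    """Per-snapshot morphometric summary table.

    ``snapshots`` is an iterable of SimulationState; one row per state with
    cluster counts (both modes), the largest spheroid's diameters, voxel and
    compartment totals, and cumulative lifecycle event counts.
    """
    rows = []
    for state in snapshots:
        lat = state.lattice
        all_matter = find_clusters(state, ALL_MATTER)
        cells_only = find_clusters(state, CELLS_ONLY)
        n = lat.n_ids
        alive = lat.alive[:n]
        ctype = lat.ctype[:n]
        vol = lat.volume[:n]
        row = {
            "mcs": state.clock.mcs,
            "day": state.clock.day,
            "n_clusters_all_matter": all_matter.n_clusters,
            "n_clusters_cells_only": cells_only.n_clusters,
            "largest_projected_diameter": (
                all_matter.largest().projected_diameter if all_matter.clusters
                else 0.0),
            "largest_equivalent_diameter": (
                all_matter.largest().equivalent_diameter if all_matter.clusters
                else 0.0),
            "cell_voxels": int(vol[alive & (ctype == int(CompartmentType.Cell))].sum()),
            "ecmst_voxels": int(vol[alive & (ctype == int(CompartmentType.ECMst))].sum()),
            "ecmv_voxels": int(vol[alive & (ctype == int(CompartmentType.ECMv))].sum()),
            "n_cells": int(np.sum(alive & (ctype == int(CompartmentType.Cell)))),
            "n_ecmst": int(np.sum(alive & (ctype == int(CompartmentType.ECMst)))),
            "n_ecmv": int(np.sum(alive & (ctype == int(CompartmentType.ECMv)))),
        }
        row.update({f"cum_{k}": v for k, v in state.counters.items()})
        rows.append(row)
    if not rows:
        raise ValueError("summary_timeseries needs at least one snapshot")
    return pd.DataFrame(rows)


def _as_lattice(state_or_lattice):
    if isinstance(state_or_lattice, VoxelLattice):
        return state_or_lattice, 0
    return state_or_lattice.lattice, state_or_lattice.clock.mcs
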