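"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from spheroidcpm import Neighborhood, make_fixture
from spheroidcpm.energy import lattice_class_codes
from spheroidcpm.lattice import FIXED_MEDIUM, MEDIUM_ID


def brute_force_contact_energy(lattice, j_matrix, order=1):
    """Independent oracle: enumerate every unordered neighbor pair by loops.

    Counts each in-lattice pair once (lexicographic dedup) and, under the
    fixed-medium boundary, each bond from an edge voxel to a virtual
    out-of-lattice medium site once.
    """
    codes = lattice_class_codes(lattice)
    offsets = [tuple(int(v) for v in o) for o in Neighborhood(order).offsets]
    nx, ny, nz = lattice.dims
    total = 0.0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                lab = int(lattice.labels[x, y, z])
                for dx, dy, dz in offsets:
                    w = (x + dx, y + dy, z + dz)
                    inside = 0 <= w[0] < nx and 0 <= w[1] < ny and 0 <= w[2] < nz
                    if inside:
                        if (x, y, z) < w:
                            lab_w = int(lattice.labels[w])
                            if lab_w != lab:
                                total += j_matrix[codes[lab], codes[lab_w]]
                    elif lattice.boundary == FIXED_MEDIUM and lab != MEDIUM_ID:
                        total += j_matrix[codes[lab], codes[MEDIUM_ID]]
    return total


def brute_force_volume_energy(lattice, lam):
    total = 0.0
    for comp in lattice.compartments():
        if comp.id == MEDIUM_ID or comp.ctype == 0:
            continue
        total += lam * (comp.volume - comp.target_volume) ** 2
    return total


def flood_fill_clusters(mask):
    """Independent face-connectivity component labelling by BFS."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    offs = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    for start in np.argwhere(mask):
        start = tuple(start)
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = []
        while queue:
            v = queue.pop()
            comp.append(v)
            for d in offs:
                w = (v[0] + d[0], v[1] + d[1], v[2] + d[2])
                if all(0 <= w[i] < mask.shape[i] for i in range(3)) \
                        and mask[w] and not seen[w]:
                    seen[w] = True
                    queue.append(w)
        comps.append(comp)
    return comps


def roughen(state, n_mcs=2):
    """A few hot sweeps to produce irregular compartment shapes."""
    from spheroidcpm import run_mcs
    run_mcs(state, n_mcs)
    state.lattice.check_bookkeeping()
    return state


@pytest.fixture
def isolated_cube():
    return make_fixture("isolated-cube")


@pytest.fixture
def two_cubes():
    return make_fixture("two-cube-contact")


@pytest.fixture
def dispersion():
    return make_fixture("random-dispersion", seed=7, n=8)
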