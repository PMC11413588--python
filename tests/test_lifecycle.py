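"""Cell growth, mitosis, secretion, ECM decay and deletion."""

import math

import numpy as np
import pytest

from spheroidcpm import build_parameter_set, run_mcs
from spheroidcpm.dynamics import DomainParameters, SimulationState
from spheroidcpm.lattice import MEDIUM_ID, CompartmentType, create_lattice
from spheroidcpm.lifecycle import (divide_cell, secrete_ecm, step, update_cell,
                                   update_ecm)


def quiet_params(zone="SZ", **extra):
    base = {"v_g": 0.0, "P_M": 0.0, "P_ECMst": 0.0, "P_ECMv": 0.0}
    base.update(extra)
    return build_parameter_set(zone, base)


def state_with(lattice, params, seed=0, **opts):
    return SimulationState(lattice, params,
                           DomainParameters(Tm=params.Tm, rng_seed=seed), **opts)


def add_box(lat, ctype, zone, corner, shape, target):
    cid = lat.new_compartment(ctype, zone, target_volume=target)
    lat.place_block(cid, corner, shape)
    return cid


class TestCellUpdate:
    def test_growth_raises_target_volume(self):
        lat = create_lattice((10, 10, 10))
        cid = add_box(lat, CompartmentType.Cell, "SZ", (3, 3, 3), (3, 3, 3), 30)
        st = state_with(lat, build_parameter_set("SZ"))
        update_cell(st, cid)
        assert lat.target_volume[cid] == pytest.approx(30.08)

    def test_below_action_threshold_no_events(self):
        # volume 18 < V_A = 20: even certain event draws cannot fire
        lat = create_lattice((12, 12, 12))
        cid = add_box(lat, CompartmentType.Cell, "SZ", (3, 3, 3), (3, 3, 2), 30)
        params = build_parameter_set(
            "SZ", {"P_M": 100.0, "P_ECMst": 100.0, "P_ECMv": 100.0})
        st = state_with(lat, params)
        update_cell(st, cid)
        assert st.counters["mitoses"] == 0
        assert len(lat.compartments()) == 2  # medium + the cell

    def test_oversized_cell_is_deleted(self):
        lat = create_lattice((12, 12, 12))
        cid = add_box(lat, CompartmentType.Cell, "SZ", (2, 2, 2), (4, 4, 4), 30)
        st = state_with(lat, quiet_params())
        update_cell(st, cid)  # volume 64 > V_Death = 60
        assert not lat.alive[cid]
        assert st.counters["cell_deaths"] == 1
        assert np.all(lat.labels == MEDIUM_ID)
        lat.check_bookkeeping()

    def test_all_probabilities_zero_keeps_cell_count(self):
        lat = create_lattice((14, 14, 8))
        for corner in ((1, 1, 1), (6, 6, 1), (10, 10, 1)):
            add_box(lat, CompartmentType.Cell, "SZ", corner, (3, 3, 3), 30)
        st = state_with(lat, quiet_params())
        for _ in range(50):
            step(st)
        assert len(st.lattice.compartments(CompartmentType.Cell)) == 3


class TestMitosis:
    def test_division_partitions_voxels_and_targets(self):
        lat = create_lattice((12, 12, 12))
        cid = add_box(lat, CompartmentType.Cell, "SZ", (3, 3, 3), (5, 3, 2), 30)
        st = state_with(lat, build_parameter_set("SZ"), seed=1)
        parent, daughter = divide_cell(st, cid)
        assert lat.volume[parent] + lat.volume[daughter] == 30
        assert lat.target_volume[parent] == 15.0
        assert lat.target_volume[daughter] == 15.0
        assert lat.compartment(daughter).zone == lat.compartment(parent).zone
        lat.check_bookkeeping()

    @pytest.mark.parametrize("seed", range(8))
    def test_centroid_plane_split_is_balanced_on_convex_cells(self, seed):
        lat = create_lattice((12, 12, 12))
        cid = add_box(lat, CompartmentType.Cell, "SZ", (3, 3, 3), (5, 3, 2), 30)
        st = state_with(lat, build_parameter_set("SZ"), seed=seed)
        parent, daughter = divide_cell(st, cid)
        assert abs(lat.volume[parent] - lat.volume[daughter]) <= 0.2 * 30

    def test_single_voxel_cell_skips_mitosis(self):
        lat = create_lattice((6, 6, 6))
        cid = add_box(lat, CompartmentType.Cell, "SZ", (2, 2, 2), (1, 1, 1), 30)
        st = state_with(lat, build_parameter_set("SZ"))
        assert divide_cell(st, cid) is None
        assert ("mitosis_skipped" in {e[1] for e in st.event_log})

    def test_repeated_division_conserves_cell_voxels(self):
        lat = create_lattice((12, 12, 12))
        add_box(lat, CompartmentType.Cell, "SZ", (3, 3, 3), (3, 3, 3), 30)
        st = state_with(lat, build_parameter_set("SZ"), seed=3)
        for cid in (1, 1, 2):
            if lat.alive[cid] and lat.volume[cid] >= 2:
                divide_cell(st, cid)
        total = sum(c.volume for c in lat.compartments(CompartmentType.Cell))
        assert total == 27
        lat.check_bookkeeping()

    def test_offspring_below_action_threshold(self):
        # both halves of a 30-voxel cell are below V_A = 20 after division
        lat = create_lattice((12, 12, 12))
        cid = add_box(lat, CompartmentType.Cell, "SZ", (3, 3, 3), (5, 3, 2), 30)
        st = state_with(lat, build_parameter_set("SZ"), seed=2)
        parent, daughter = divide_cell(st, cid)
        assert lat.volume[parent] <= 20 and lat.volume[daughter] <= 20


class TestSecretion:
    def test_secreted_ecm_properties(self):
        lat = create_lattice((12, 12, 12))
        cid = add_box(lat, CompartmentType.Cell, "MZ", (4, 4, 4), (3, 3, 3), 30)
        st = state_with(lat, build_parameter_set("MZ"), seed=1)
        eid = secrete_ecm(st, cid, CompartmentType.ECMv)
        comp = lat.compartment(eid)
        assert comp.ctype == CompartmentType.ECMv
        assert comp.target_volume == 30.0
        assert 1 <= comp.volume <= 8
        # seeded adjacent to the cell: some ECM voxel touches a cell voxel
        vox = lat.voxels_of(eid)
        adj = False
        for v in vox:
            for d in ((1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                      (0, 0, 1), (0, 0, -1)):
                w = tuple(v + np.array(d))
                if lat.in_bounds(w) and lat.label_at(w) == cid:
                    adj = True
        assert adj
        lat.check_bookkeeping()

    def test_enclosed_cell_secretion_blocked(self):
        lat = create_lattice((9, 9, 9))
        cid = add_box(lat, CompartmentType.Cell, "SZ", (3, 3, 3), (3, 3, 3), 30)
        shell = lat.new_compartment(CompartmentType.Cell, "SZ", target_volume=98)
        mask = np.zeros(lat.dims, dtype=bool)
        mask[2:7, 2:7, 2:7] = True
        mask[3:6, 3:6, 3:6] = False
        lat.assign_voxels(shell, np.argwhere(mask))
        st = state_with(lat, build_parameter_set("SZ"))
        assert secrete_ecm(st, cid, CompartmentType.ECMst) is None
        assert st.counters["secretions_blocked"] == 1


class TestEcmUpdate:
    def test_decay_arithmetic_dz(self):
        lat = create_lattice((10, 10, 10))
        eid = add_box(lat, CompartmentType.ECMv, "DZ", (3, 3, 3), (5, 3, 2), 30)
        st = state_with(lat, quiet_params("DZ"))
        for _ in range(100):
            update_ecm(st, eid)
        assert lat.target_volume[eid] == pytest.approx(30 - 100 * 0.097)

    def test_zero_decay_keeps_target(self):
        lat = create_lattice((10, 10, 10))
        eid = add_box(lat, CompartmentType.ECMst, "SZ", (3, 3, 3), (3, 3, 3), 30)
        st = state_with(lat, quiet_params("SZ", v_d=0.0))
        for _ in range(500):
            update_ecm(st, eid)
        assert lat.target_volume[eid] == 30.0

    def test_small_ecm_deleted_and_replaced_by_medium(self):
        lat = create_lattice((8, 8, 8))
        eid = add_box(lat, CompartmentType.ECMst, "SZ", (3, 3, 3), (2, 1, 1), 30)
        st = state_with(lat, build_parameter_set("SZ"))
        update_ecm(st, eid)  # volume 2 < V_Delete = 3
        assert not lat.alive[eid]
        assert np.all(lat.labels == MEDIUM_ID)
        assert st.counters["ecm_deletions"] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_quiescent_dz_ecm_deletion_time(self, seed):
        # target reaches V_Delete after (30−3)/0.097 ≈ 278 MCS; the realized
        # volume tracks it with lattice relaxation lag (±15%)
        lat = create_lattice((14, 14, 14))
        eid = add_box(lat, CompartmentType.ECMst, "DZ", (4, 4, 4), (5, 3, 2), 30)
        st = state_with(lat, quiet_params("DZ"), seed=seed)
        deleted_at = None
        for _ in range(400):
            run_mcs(st, 1)
            if st.counters["ecm_deletions"]:
                deleted_at = st.clock.mcs
                break
        expected = (30 - 3) / 0.097
        assert deleted_at is not None
        assert abs(deleted_at - expected) <= 0.15 * expected


class TestEventStatistics:
    def test_mitosis_counts_are_binomial(self):
        # eligibility widened to V_A=1 so lineages stay countable; the number
        # of divisions is then Binomial(Σ_t N_eligible(t), P_M)
        lat = create_lattice((42, 42, 6))
        params = build_parameter_set("SZ", {"V_A": 1.0, "v_g": 0.0,
                                            "P_ECMst": 0.0, "P_ECMv": 0.0})
        n_slots = 13
        for i in range(n_slots):
            for j in range(n_slots):
                if i * n_slots + j < 160:
                    add_box(lat, CompartmentType.Cell, "SZ",
                            (3 * i + 1, 3 * j + 1, 1), (3, 3, 3), 30)
        st = state_with(lat, params, seed=12)
        p = params.prob_mitosis
        n_draws = 0
        for _ in range(40):
            vols = lat.volume[: lat.n_ids]
            elig = (lat.alive[: lat.n_ids] &
                    (lat.ctype[: lat.n_ids] == int(CompartmentType.Cell)) &
                    (vols > params.V_A) & (vols <= params.V_Death))
            n_draws += int(elig.sum())
            step(st)
        mean = n_draws * p
        sigma = math.sqrt(n_draws * p * (1 - p))
        assert abs(st.counters["mitoses"] - mean) <= 3 * sigma

    def test_secretion_counts_are_binomial_at_mz_rate(self):
        # P(ECMv) = 9.3%: over 10⁴ eligible cell-MCS draws expect ≈ 930
        lat = create_lattice((66, 66, 6))
        params = build_parameter_set("MZ", {"P_M": 0.0, "P_ECMst": 0.0,
                                            "v_g": 0.0})
        count = 0
        for i in range(21):
            for j in range(21):
                add_box(lat, CompartmentType.Cell, "MZ",
                        (3 * i + 1, 3 * j + 1, 1), (3, 3, 3), 30)
                count += 1
        st = state_with(lat, params, seed=21)
        n_steps = 23  # ≈ 10⁴ eligible cell-MCS draws
        for _ in range(n_steps):
            step(st)  # no dynamics: volumes stay 27 > V_A, always eligible
        fired = (st.counters["secretions_ECMv"] +
                 st.counters["secretions_blocked"])
        n, p = count * n_steps, params.prob_ecmv
        assert abs(fired - n * p) <= 3 * math.sqrt(n * p * (1 - p))

    def test_lifecycle_conserves_voxels(self):
        st = state_with(create_lattice((20, 20, 12)),
                        build_parameter_set("DZ"), seed=5)
        for corner in ((2, 2, 2), (8, 8, 2), (14, 14, 2), (2, 14, 2)):
            add_box(st.lattice, CompartmentType.Cell, "DZ", corner, (3, 3, 3), 30)
        for _ in range(60):
            step(st)
        st.lattice.check_bookkeeping()
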