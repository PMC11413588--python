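"""Hamiltonian: hand-checkable energies, brute-force oracles, local ΔH."""

import numpy as np
import pytest

from spheroidcpm import (ContactEnergyTable, Neighborhood, VolumeConstraint,
                         build_parameter_set, contact_energy, create_lattice,
                         delta_h, make_fixture, total_energy, volume_energy)
from spheroidcpm.energy import (EnergyModel, bond_counts, delta_for_relabel,
                                lattice_class_codes)
from spheroidcpm.lattice import CompartmentType, neighbor_voxels
from conftest import (brute_force_contact_energy, brute_force_volume_energy,
                      roughen)

ORDER1 = Neighborhood(1)


class TestHandComputableEnergies:
    def test_all_medium_lattice_is_zero(self):
        lat = create_lattice((6, 6, 6))
        model = EnergyModel.from_parameters(build_parameter_set("SZ"), ORDER1)
        assert contact_energy(lat, model.j_table, ORDER1) == 0.0
        assert total_energy(lat, model) == 0.0

    def test_isolated_sz_cell(self, isolated_cube):
        lat = isolated_cube.lattice
        model = isolated_cube.model
        # 54 faces × J(medium-cell)=5.0; λ=10 · (27−30)²
        assert contact_energy(lat, model.j_table, ORDER1) == pytest.approx(270.0)
        assert volume_energy(lat, model.constraint) == pytest.approx(90.0)
        assert total_energy(lat, model, ORDER1) == pytest.approx(360.0)

    def test_two_touching_sz_cells(self, two_cubes):
        # 90 medium faces × 5.0 + 9 shared faces × 5.0
        hc = contact_energy(two_cubes.lattice, two_cubes.model.j_table, ORDER1)
        assert hc == pytest.approx(495.0)

    def test_volume_energy_cases(self):
        lat = create_lattice((12, 12, 6))
        c = VolumeConstraint(lambda_vol=10.0)
        for corner, target in (((0, 0, 0), 30), ((6, 6, 0), 27)):
            cid = lat.new_compartment(CompartmentType.ECMst, "MZ",
                                      target_volume=target)
            lat.place_block(cid, corner, (3, 3, 3))
        # one blob at 10·(27−30)², one exactly at target
        assert volume_energy(lat, c) == pytest.approx(90.0)
        lat.target_volume[1] = 27.0
        assert volume_energy(lat, c) == pytest.approx(0.0)

    def test_energy_independent_of_id_relabelling(self):
        # same geometry, compartments created in opposite order
        def build(order_swap):
            lat = create_lattice((10, 10, 6))
            corners = [(1, 1, 1), (6, 6, 1)]
            if order_swap:
                corners.reverse()
            for corner in corners:
                cid = lat.new_compartment(CompartmentType.Cell, "SZ",
                                          target_volume=30)
                lat.place_block(cid, corner, (3, 3, 3))
            model = EnergyModel.from_parameters(build_parameter_set("SZ"), ORDER1)
            return total_energy(lat, model)

        assert build(False) == pytest.approx(build(True))


class TestBruteForceOracles:
    @pytest.mark.parametrize("order", [1, 2])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_contact_energy_matches_pair_enumeration(self, seed, order):
        state = roughen(make_fixture("random-dispersion", seed=seed, n=6, side=15))
        nb = Neighborhood(order)
        expected = brute_force_contact_energy(state.lattice,
                                              state.model.j_table.matrix, order)
        assert contact_energy(state.lattice, state.model.j_table,
                              nb) == pytest.approx(expected)

    def test_volume_energy_matches_direct_sum(self):
        state = roughen(make_fixture("random-dispersion", seed=3, n=6, side=15))
        lam = state.model.constraint.lambda_vol
        expected = brute_force_volume_energy(state.lattice, lam)
        assert volume_energy(state.lattice,
                             state.model.constraint) == pytest.approx(expected)

    def test_bond_counts_reconcile_with_contact_energy(self, two_cubes):
        counts = bond_counts(two_cubes.lattice, ORDER1)
        j = two_cubes.model.j_table.matrix
        total = 0.0
        for a in range(counts.shape[0]):
            for b in range(a, counts.shape[1]):
                if counts[a, b]:
                    total += counts[a, b] * j[a, b]
        assert total == pytest.approx(
            contact_energy(two_cubes.lattice, two_cubes.model.j_table, ORDER1))


class TestDeltaH:
    def _admissible_moves(self, lattice, nb):
        for v in np.ndindex(lattice.dims):
            for s in neighbor_voxels(lattice, v, nb):
                if s.label != lattice.label_at(v):
                    yield v, s.label

    @pytest.mark.parametrize("order", [1, 2])
    def test_local_equals_global_difference(self, order):
        state = roughen(make_fixture("random-dispersion", seed=11, n=5, side=12))
        state.model.neighborhood = Neighborhood(order)
        lat, model = state.lattice, state.model
        checked = 0
        for v, new_label in self._admissible_moves(lat, model.neighborhood):
            before = total_energy(lat, model)
            dh = delta_for_relabel(lat, model, v, new_label)
            old = lat.label_at(v)
            lat.labels[v] = new_label
            lat.volume[new_label] += 1
            lat.volume[old] -= 1
            after = total_energy(lat, model)
            lat.labels[v] = old
            lat.volume[new_label] -= 1
            lat.volume[old] += 1
            assert abs((after - before) - dh) < 1e-9
            checked += 1
            if checked >= 150:
                break
        assert checked >= 100

    def test_reverse_move_is_antisymmetric(self, two_cubes):
        lat, model = two_cubes.lattice, two_cubes.model
        model.neighborhood = ORDER1
        v = (5, 6, 6)  # corner voxel of the first cube
        fwd = delta_for_relabel(lat, model, v, 0)
        old = lat.label_at(v)
        lat.labels[v] = 0
        lat.volume[0] += 1
        lat.volume[old] -= 1
        rev = delta_for_relabel(lat, model, v, old)
        assert fwd == pytest.approx(-rev)

    def test_volume_part_closed_form(self):
        # shrink a cell sitting exactly at target: ΔH_volume = λ·1² = +10
        lat = create_lattice((8, 8, 8))
        cid = lat.new_compartment(CompartmentType.Cell, "SZ", target_volume=27)
        lat.place_block(cid, (2, 2, 2), (3, 3, 3))
        model = EnergyModel.from_parameters(build_parameter_set("SZ"), ORDER1)
        v = (2, 2, 2)
        dh = delta_for_relabel(lat, model, v, 0)
        contact_part = dh - 10.0
        expected_contact = (brute_force_contact_after_move(lat, model, v, 0)
                            - brute_force_contact_energy(lat, model.j_table.matrix, 1))
        assert contact_part == pytest.approx(expected_contact)

    def test_same_label_rejected(self, isolated_cube):
        lat, model = isolated_cube.lattice, isolated_cube.model
        with pytest.raises(ValueError):
            delta_h(lat, model, (0, 0, 0), (0, 0, 1))

    def test_cube_at_target_is_local_minimum(self):
        # V = V_target = 27, J(medium-cell) > 0: every admissible copy uphill
        lat = create_lattice((9, 9, 9))
        cid = lat.new_compartment(CompartmentType.Cell, "SZ", target_volume=27)
        lat.place_block(cid, (3, 3, 3), (3, 3, 3))
        model = EnergyModel.from_parameters(build_parameter_set("SZ"), ORDER1)
        model.neighborhood = ORDER1
        for v, new_label in TestDeltaH()._admissible_moves(lat, ORDER1):
            assert delta_for_relabel(lat, model, v, new_label) > 0


def brute_force_contact_after_move(lattice, model, voxel, new_label):
    old = lattice.label_at(voxel)
    lattice.labels[voxel] = new_label
    try:
        return brute_force_contact_energy(lattice, model.j_table.matrix,
                                          model.neighborhood.order)
    finally:
        lattice.labels[voxel] = old


class TestContactTable:
    def test_symmetric_and_medium_zero(self):
        t = ContactEnergyTable.from_parameters(build_parameter_set("MZ"))
        assert np.allclose(t.matrix, t.matrix.T)
        assert t.j(0, 0) == 0.0

    def test_missing_entry_raises(self, isolated_cube):
        m = np.zeros((10, 10))
        m[0, 1] = m[1, 0] = np.nan
        table = ContactEnergyTable(m)
        with pytest.raises(KeyError):
            contact_energy(isolated_cube.lattice, table, ORDER1)

    def test_zone_specific_medium_ecm_row(self):
        sz = ContactEnergyTable.from_parameters(build_parameter_set("SZ"))
        codes_ecmst_sz = 4  # ECMst in SZ
        codes_ecmv_sz = 7
        assert sz.j(0, codes_ecmst_sz) == 20.0
        assert sz.j(0, codes_ecmv_sz) == 20.0
        mz = ContactEnergyTable.from_parameters(build_parameter_set("MZ"))
        assert mz.j(0, 5) == 2.5  # ECMst in MZ

    def test_cross_zone_cell_cell_is_mean(self):
        t = ContactEnergyTable.from_parameters(build_parameter_set("SZ"))
        # J(SZ cell, MZ cell) = (5.0 + 2.5)/2
        assert t.j(1, 2) == pytest.approx(3.75)

    def test_class_codes_require_zone(self):
        lat = create_lattice((4, 4, 4))
        lat.new_compartment(CompartmentType.Cell, "none", target_volume=1)
        with pytest.raises(ValueError):
            lattice_class_codes(lat)
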