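"""Potential-term forms, tables, and force-gradient consistency."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from protofibril.builder import _axis_angle
from protofibril.forcefield import (NeighborList, OverlappingAtomsError,
                                    angle_energy, bond_energy, bonded_params,
                                    dihedral_energy, load_tables, pair_energy,
                                    total_energy_forces)


class TestBondTerm:
    def test_zero_at_equilibrium(self, tables):
        kb, r0 = tables.bond_params["C_3:O_3"]
        assert bond_energy(r0, kb, r0) == 0.0

    def test_quadratic_symmetry(self, tables):
        kb, r0 = tables.bond_params["C_3:C_3"]
        for delta in (0.05, 0.2, 0.5):
            assert bond_energy(r0 + delta, kb, r0) == pytest.approx(
                bond_energy(r0 - delta, kb, r0))

    def test_force_matches_finite_difference(self, rng, tables):
        kb, r0 = tables.bond_params["C_3:O_3"]
        h = 1e-6
        for r in r0 + rng.uniform(-0.4, 0.6, size=10):
            force = -2.0 * kb * (r - r0)
            num = -(bond_energy(r + h, kb, r0)
                    - bond_energy(r - h, kb, r0)) / (2 * h)
            assert num == pytest.approx(force, rel=1e-6, abs=1e-8)

    def test_nonpositive_length_rejected(self, tables):
        kb, r0 = tables.bond_params["C_3:C_3"]
        with pytest.raises(ValueError):
            bond_energy(-0.1, kb, r0)


class TestAngleTerm:
    def test_zero_at_equilibrium_and_symmetry(self, tables):
        kv, t0 = tables.angle_params["C_3"]
        assert angle_energy(t0, kv, t0) == 0.0
        for d in (0.05, 0.3):
            assert angle_energy(t0 + d, kv, t0) == pytest.approx(
                angle_energy(t0 - d, kv, t0))

    def test_degenerate_angle_rejected(self, tables):
        kv, t0 = tables.angle_params["C_3"]
        with pytest.raises(ValueError):
            angle_energy(0.0, kv, t0)
        with pytest.raises(ValueError):
            angle_energy(np.pi, kv, t0)


class TestDihedralTerm:
    def test_printed_form_special_values(self):
        # A2-only term vanishes at 0; A1-only vanishes at pi and is A1 at 0
        assert dihedral_energy(0.0, 0.0, 5.0, 0.0) == 0.0
        assert dihedral_energy(np.pi, 3.0, 0.0, 0.0) == pytest.approx(0.0)
        assert dihedral_energy(0.0, 3.0, 0.0, 0.0) == pytest.approx(3.0)

    @given(theta=st.floats(-np.pi, np.pi),
           a1=st.floats(0, 5), a2=st.floats(0, 5), a3=st.floats(0, 5))
    @settings(max_examples=50, deadline=None)
    def test_periodicity(self, theta, a1, a2, a3):
        assert dihedral_energy(theta + 2 * np.pi, a1, a2, a3) == \
            pytest.approx(dihedral_energy(theta, a1, a2, a3), abs=1e-9)


class TestPairTerm:
    def test_analytic_minimum(self, rng):
        for _ in range(10):
            a = 10 ** rng.uniform(2, 6)
            c = 10 ** rng.uniform(0, 3)
            rstar = (2 * a / c) ** (1 / 6)
            assert pair_energy(rstar, a, c) == pytest.approx(
                -c * c / (4 * a), rel=1e-12)

    def test_numeric_minimum_matches_closed_form(self, rng):
        from scipy.optimize import minimize_scalar
        for _ in range(10):
            a = 10 ** rng.uniform(2, 6)
            c = 10 ** rng.uniform(0, 3)
            res = minimize_scalar(lambda r: pair_energy(r, a, c),
                                  bounds=(0.3, 50.0), method="bounded",
                                  options={"xatol": 1e-12})
            assert res.x == pytest.approx((2 * a / c) ** (1 / 6), abs=1e-6)
            assert res.fun == pytest.approx(-c * c / (4 * a), abs=1e-8)

    def test_truncation_beyond_cutoff(self, tables):
        a, c = 1e5, 1e2
        assert pair_energy(tables.cutoff + 0.1, a, c,
                           cutoff=tables.cutoff) == 0.0
        # continuous at the cutoff: shifted value just inside is ~0
        inside = pair_energy(tables.cutoff - 1e-6, a, c, cutoff=tables.cutoff)
        assert abs(inside) < 1e-8


class TestTables:
    def test_pair_table_symmetric_and_positive(self, tables):
        assert np.array_equal(tables.pair_A, tables.pair_A.T)
        assert np.array_equal(tables.pair_C, tables.pair_C.T)
        assert (tables.pair_A > 0).all()
        assert (tables.pair_C >= 0).all()

    def test_hbond_wells_deeper_than_plain(self, tables):
        """H-O, H-P, H-N donor pairs are deeper than the plain vdW pairs."""
        for acceptor in tables.hbond_acceptors:
            deep = tables.well_depth("H_HB", acceptor)
            plain = tables.well_depth("H_", acceptor)
            assert deep > plain

    def test_dump_lists_all_pairs(self, tables):
        text = tables.dump()
        n = len(tables.type_names)
        assert len(text.splitlines()) == 1 + n * (n + 1) // 2


class TestTotalEnergyForces:
    def _setup(self, system, topo, tables, coords=None):
        params = bonded_params(topo, tables)
        nl = NeighborList(system, topo, tables)
        nl.build(system.coords if coords is None else coords)
        return params, nl

    def test_bonded_diatomic_at_equilibrium_is_null(self, tables):
        from protofibril.fixtures import toy_diatomic
        system, topo = toy_diatomic()
        kb, r0 = tables.bond_params["C_3:C_3"]
        system.coords[1, 0] = r0
        params, nl = self._setup(system, topo, tables)
        e, f = total_energy_forces(system.coords, topo, params, nl)
        assert e.total == pytest.approx(0.0, abs=1e-12)
        assert np.abs(f).max() == pytest.approx(0.0, abs=1e-12)

    def test_whole_system_gradient_on_cellobiose(self, cellobiose, tables,
                                                 rng):
        """Analytic forces match central differences to < 1e-5 kcal/mol/A."""
        system, topo = cellobiose
        coords = system.coords + 0.05 * rng.standard_normal(
            system.coords.shape)
        params, nl = self._setup(system, topo, tables, coords)
        e, forces = total_energy_forces(coords, topo, params, nl)
        h = 1e-5
        for i in range(0, system.n_atoms):
            for d in range(3):
                cp = coords.copy()
                cp[i, d] += h
                ep, _ = total_energy_forces(cp, topo, params, nl)
                cp[i, d] -= 2 * h
                em, _ = total_energy_forces(cp, topo, params, nl)
                num = -(ep.total - em.total) / (2 * h)
                assert abs(num - forces[i, d]) < 1e-5

    def test_net_force_and_torque_vanish(self, cellobiose, tables, rng):
        system, topo = cellobiose
        coords = system.coords + 0.03 * rng.standard_normal(
            system.coords.shape)
        params, nl = self._setup(system, topo, tables, coords)
        _, forces = total_energy_forces(coords, topo, params, nl)
        assert np.abs(forces.sum(axis=0)).max() < 1e-9
        assert np.abs(np.cross(coords, forces).sum(axis=0)).max() < 1e-8

    def test_rigid_motion_invariance(self, cellobiose, tables, rng):
        system, topo = cellobiose
        params, nl = self._setup(system, topo, tables)
        e0, _ = total_energy_forces(system.coords, topo, params, nl)
        rot = _axis_angle(rng.standard_normal(3), rng.uniform(0, np.pi))
        moved = system.coords @ rot.T + rng.uniform(-5, 5, 3)
        nl2 = NeighborList(system, topo, tables)
        nl2.build(moved)
        e1, _ = total_energy_forces(moved, topo, params, nl2)
        assert e1.total == pytest.approx(e0.total, rel=1e-9)

    def test_overlap_raises(self, cellobiose, tables):
        system, topo = cellobiose
        coords = system.coords.copy()
        # slam the two termini together
        coords[-1] = coords[0] + [0.05, 0, 0]
        params, nl = self._setup(system, topo, tables, coords)
        with pytest.raises(OverlappingAtomsError):
            total_energy_forces(coords, topo, params, nl)

    def test_energy_decomposition_totals(self, cellobiose, tables):
        system, topo = cellobiose
        params, nl = self._setup(system, topo, tables)
        e, _ = total_energy_forces(system.coords, topo, params, nl)
        assert e.total == pytest.approx(
            e.bond + e.angle + e.dihedral + e.nonbonded, rel=1e-12)

    def test_membrane_energy_is_additive(self, tables):
        """E(with membrane) - E(without) equals the glucan-membrane pair sum."""
        from protofibril.builder import (attach_membrane, build_extended_glucan,
                                         build_membrane, build_topology)
        chain = build_extended_glucan(3)
        topo = build_topology(chain.system, chain.bonds)
        membrane = build_membrane((4.0, 4.0), density=8.0, seed=2, z0=-4.0)
        merged, mtopo = attach_membrane(chain.system, topo, membrane)
        params, nl = self._setup(chain.system, topo, tables)
        e_alone, _ = total_energy_forces(chain.system.coords, topo, params,
                                         nl)
        mparams = bonded_params(mtopo, tables)
        mnl = NeighborList(merged, mtopo, tables)
        mnl.build(merged.coords)
        e_with, _ = total_energy_forces(merged.coords, mtopo, mparams, mnl)

        # brute-force glucan-site pair sum under the same truncation rule
        ids = tables.type_id(merged.types)
        cross = 0.0
        ng = chain.system.n_atoms
        for i in range(ng):
            for j in range(ng, merged.n_atoms):
                r = np.linalg.norm(merged.coords[i] - merged.coords[j])
                a = tables.pair_A[ids[i], ids[j]]
                c = tables.pair_C[ids[i], ids[j]]
                cross += pair_energy(r, a, c, cutoff=tables.cutoff)
        assert e_with.total - e_alone.total == pytest.approx(cross, abs=1e-8)
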