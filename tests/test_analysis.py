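"""Observable estimators against constructed ground truth and brute force."""

import numpy as np
import pytest

from protofibril import analysis, fixtures
from protofibril.analysis import (CENSORED, bend_angle, correct_replica_diameter,
                                  cross_section, detect_hbonds,
                                  fibril_diameter_nm, first_contact_monomers,
                                  interacting_monomer_run, pairing_partition,
                                  stability_threshold)
from protofibril.builder import System, _axis_angle


def _simple_frame(coords, elements, names, chains, resids, roles=None,
                  types=None):
    n = len(coords)
    roles = roles or ["carbon"] * n
    types = types or ["C_3"] * n
    return System(np.asarray(coords, float), np.array(elements),
                  np.array(names), np.array(roles), np.array(types),
                  np.array(chains), np.array(resids), np.zeros(n, bool))


class TestHBonds:
    def _oh_o(self, d, angle_deg):
        """Donor O-H pointing at an acceptor O at distance d, given angle."""
        a = np.deg2rad(180.0 - angle_deg)
        acc = np.array([0.98 + np.cos(a) * (d - 0.98),
                        np.sin(a) * (d - 0.98), 0.0])
        # place acceptor so that the O...O distance is d exactly
        # (solve along the rotated direction from the donor O)
        u = acc / np.linalg.norm(acc)
        acc = u * d
        return _simple_frame(
            [[0, 0, 0], [0.98, 0, 0], list(acc)],
            ["O", "H", "O"], ["O2", "HO2", "O3"], [0, 0, 1], [0, 0, 0],
            roles=["hydroxyl-oxygen", "hydroxyl-hydrogen", "hydroxyl-oxygen"],
            types=["O_3", "H_HB", "O_3"])

    def test_textbook_geometry_detected(self):
        frame = self._oh_o(2.8, 180.0)
        records = detect_hbonds(frame)
        assert len(records) == 1
        assert records[0].distance == pytest.approx(2.8)
        assert records[0].cls == "glucan-glucan"

    def test_beyond_distance_cutoff_rejected(self):
        assert detect_hbonds(self._oh_o(6.0, 180.0)) == []

    def test_bent_geometry_rejected(self):
        frame = self._oh_o(2.8, 90.0)
        assert detect_hbonds(frame) == []

    def test_matches_brute_force_on_tower(self, hexamer_tower):
        from _oracles import brute_force_hbonds
        system, _ = hexamer_tower
        fast = detect_hbonds(system)
        slow = brute_force_hbonds(system)
        fast_keys = sorted((r.donor, r.hydrogen, r.acceptor) for r in fast)
        assert fast_keys == sorted(slow)


class TestPairing:
    def test_constructed_dimers(self):
        frame = fixtures.make_paired_dimers(4.0, 40.0)
        part = pairing_partition(frame)
        assert sorted(sorted(c) for c in part.clusters) == \
            [[0, 1], [2, 3], [4, 5]]

    def test_far_chains_are_singletons(self):
        frame = fixtures.make_paired_dimers(20.0, 60.0)
        part = pairing_partition(frame, contact_cut=4.5)
        assert part.cluster_sizes() == [1] * 6

    def test_all_close_is_one_cluster(self):
        frame = fixtures.make_straight_fibril(6, 6, spacing=5.5)
        part = pairing_partition(frame)
        assert part.cluster_sizes() == [6]

    def test_linkage_counts_symmetric_partition_is_partition(self):
        frame = fixtures.make_paired_dimers(4.0, 40.0)
        part = pairing_partition(frame)
        members = sorted(m for c in part.clusters for m in c)
        assert members == [0, 1, 2, 3, 4, 5]
        for (i, j) in part.linkage:
            assert i < j

    def test_matches_brute_force_components(self, rng):
        """Single-linkage clustering equals brute-force connected components."""
        for trial in range(5):
            centers = rng.uniform(0, 30, size=(6, 3))
            frames = []
            coords, chains = [], []
            for c, ctr in enumerate(centers):
                pts = ctr + rng.uniform(-2, 2, size=(8, 3))
                coords.extend(pts)
                chains.extend([c] * 8)
            frame = _simple_frame(coords, ["C"] * 48, ["C1"] * 48, chains,
                                  [0] * 48)
            part = pairing_partition(frame, contact_cut=6.0, min_contacts=1)
            # brute force over chain pairs
            adj = {c: set() for c in range(6)}
            arr = np.array(coords)
            for i in range(48):
                for j in range(i + 1, 48):
                    if chains[i] != chains[j] and \
                            np.linalg.norm(arr[i] - arr[j]) < 6.0:
                        adj[chains[i]].add(chains[j])
                        adj[chains[j]].add(chains[i])
            seen, comps = set(), []
            for c in range(6):
                if c in seen:
                    continue
                stack, comp = [c], set()
                while stack:
                    x = stack.pop()
                    if x in comp:
                        continue
                    comp.add(x)
                    stack.extend(adj[x])
                seen |= comp
                comps.append(frozenset(comp))
            assert sorted(map(sorted, part.clusters)) == \
                sorted(map(sorted, comps))


class TestBendAngle:
    @pytest.mark.parametrize("kink", [0.0, 5.0, 15.0, 30.0, 45.0, 60.0])
    def test_recovers_constructed_kink(self, kink):
        frame = fixtures.make_kinked_fibril(6, 15, kink)
        tol = 0.5 if kink == 0 else 1.0
        assert bend_angle(frame, 0.2) == pytest.approx(kink, abs=tol)

    def test_rigid_motion_invariance(self, rng):
        frame = fixtures.make_kinked_fibril(6, 15, 25.0)
        a0 = bend_angle(frame)
        rot = _axis_angle(rng.standard_normal(3), rng.uniform(0, np.pi))
        frame.coords = frame.coords @ rot.T + rng.uniform(-30, 30, 3)
        assert bend_angle(frame) == pytest.approx(a0, abs=1e-6)

    def test_insufficient_monomers_rejected(self):
        frame = fixtures.make_straight_fibril(6, 8)
        with pytest.raises(ValueError, match="3 monomers"):
            bend_angle(frame, 0.2)      # only 1 basal monomer

    def test_invalid_base_fraction(self):
        frame = fixtures.make_straight_fibril(6, 15)
        with pytest.raises(ValueError):
            bend_angle(frame, 0.0)


class TestCrossSection:
    def test_single_chain_bracket(self):
        frame = fixtures.make_straight_fibril(1, 12)
        assert 25.0 <= cross_section(frame) <= 45.0

    def test_homogeneous_under_similarity(self):
        """Radial x2 with the atom radius scaled alongside gives area x4."""
        frame = fixtures.make_straight_fibril(6, 12, spacing=6.0)
        a1 = cross_section(frame, inflation=1.5)
        axis = analysis._principal_axis(frame.coords[frame.heavy])
        center = frame.coords.mean(axis=0)
        rel = frame.coords - center
        radial = rel - np.outer(rel @ axis, axis)
        frame2 = frame.copy()
        frame2.coords = center + rel + radial
        a2 = cross_section(frame2, inflation=3.0)
        assert a2 == pytest.approx(4.0 * a1, rel=1e-4)

    def test_six_chain_additivity_at_crystal_packing(self):
        one = cross_section(fixtures.make_straight_fibril(1, 12))
        six = cross_section(fixtures.make_straight_fibril(
            6, 12, spacing=5.5, packing="lattice"))
        assert six == pytest.approx(6 * one, rel=0.25)

    def test_rigid_motion_invariance(self, rng):
        frame = fixtures.make_straight_fibril(6, 12, spacing=6.0)
        a0 = cross_section(frame)
        rot = _axis_angle(rng.standard_normal(3), rng.uniform(0, np.pi))
        frame.coords = frame.coords @ rot.T + rng.uniform(-30, 30, 3)
        assert cross_section(frame) == pytest.approx(a0, rel=1e-6)


class TestGrowthThresholds:
    @pytest.mark.parametrize("cycle", [1, 7, 10])
    def test_first_contact_reads_injected_cycle(self, cycle):
        traj = fixtures.make_growth_trace(cycle)
        assert first_contact_monomers(traj) == cycle

    def test_censored_when_no_contact(self):
        traj = fixtures.make_growth_trace(None)
        assert first_contact_monomers(traj) == CENSORED

    def test_stability_threshold_constructed_profile(self):
        profile = {3: (0, 5), 4: (1, 5), 5: (2, 5), 6: (4, 5), 7: (5, 5)}
        assert stability_threshold(profile) == 6

    def test_stability_threshold_boundaries(self):
        assert stability_threshold({4: (5, 5), 5: (5, 5)}) == 4
        assert stability_threshold({4: (0, 5), 5: (1, 5)}) == CENSORED

    def test_interacting_monomer_run_on_bundle(self):
        frame = fixtures.make_straight_fibril(6, 8, spacing=5.5)
        assert interacting_monomer_run(frame) == 8
        far = fixtures.make_paired_dimers(20.0, 60.0)
        assert interacting_monomer_run(far) == 0


class TestReplicaCorrection:
    def test_printed_rule(self):
        assert correct_replica_diameter(25.4, 0.75) == pytest.approx(23.9)

    def test_zero_thickness_is_identity(self):
        assert correct_replica_diameter(5.0, 0.0) == 5.0

    def test_guard_on_too_small_measurement(self):
        with pytest.raises(ValueError):
            correct_replica_diameter(1.0, 0.75)


def test_36_chain_fibril_diameter_arithmetic():
    """Six 205 A^2 protofibrils make a ~4 nm, 1230 A^2 fibril."""
    assert fibril_diameter_nm(205.0, 6) == pytest.approx(4.0, abs=0.1)
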