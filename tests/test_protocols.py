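"""Protocol contracts at small scale: convergence, composability, bookkeeping."""

import numpy as np
import pytest

from protofibril import analysis
from protofibril.protocols import (ProtocolConfig, build_protocol_membrane,
                                   build_scaled_system, extrusion_growth,
                                   membrane_assembly, preassembly, relaxation,
                                   stability_experiment, wall_bending)


def _small_config(**kw):
    base = dict(name="relaxation", n_residues=8, seed=3,
                preassembly_stage_steps=300, relaxation_steps=1500,
                report_every=300, membrane_extent_nm=(8.0, 8.0))
    base.update(kw)
    return ProtocolConfig(**base)


def test_config_validation():
    with pytest.raises(ValueError):
        ProtocolConfig(name="nonsense")
    with pytest.raises(ValueError):
        ProtocolConfig(relaxation_steps=0)


def test_preassembly_draws_tops_toward_axis(tables):
    """Top anchors end well inside 1 nm of the common axis at default spring."""
    cfg = ProtocolConfig(name="preassembly", n_residues=12, seed=1,
                         preassembly_stage_steps=600)
    system, topo = build_scaled_system(cfg)
    pre = preassembly(system, topo, tables, cfg)
    top = pre.residue_index == cfg.n_residues - 1
    radii = np.linalg.norm(pre.coords[top][:, :2], axis=1)
    assert radii.max() < 10.0


def test_preassembly_without_spring_does_not_converge(tables):
    cfg = _small_config(name="preassembly", spring_k=0.0,
                        preassembly_stage_steps=200)
    system, topo = build_scaled_system(cfg)
    top = system.residue_index == cfg.n_residues - 1
    r0 = np.linalg.norm(system.coords[top][:, :2], axis=1).mean()
    pre = preassembly(system, topo, tables, cfg)
    r1 = np.linalg.norm(pre.coords[top][:, :2], axis=1).mean()
    assert r1 > r0 - 2.0      # unchanged within thermal wobble


def test_preassembly_deterministic(tables):
    cfg = _small_config(name="preassembly")
    system, topo = build_scaled_system(cfg)
    a = preassembly(system, topo, tables, cfg)
    b = preassembly(system, topo, tables, cfg)
    assert np.array_equal(a.coords, b.coords)


def test_membrane_assembly_with_null_membrane_equals_relaxation(tables):
    """Protocol composability: an absent or empty membrane changes nothing."""
    cfg = _small_config()
    system, topo = build_scaled_system(cfg)
    t_plain = relaxation(system, topo, tables, cfg)
    t_none = membrane_assembly(system, topo, None, tables, cfg)
    empty = build_protocol_membrane(
        ProtocolConfig(name="membrane_assembly", membrane_density=0.0,
                       membrane_extent_nm=(8.0, 8.0), seed=cfg.seed))
    t_empty = membrane_assembly(system, topo, empty, tables, cfg)
    for f1, f2, f3 in zip(t_plain.frames, t_none.frames, t_empty.frames):
        assert np.array_equal(f1.coords, f2.coords)
        assert np.array_equal(f1.coords, f3.coords)


def test_membrane_contacts_form(tables):
    """Basal monomers hydrogen-bond the membrane O/P/N sites."""
    cfg = _small_config(name="membrane_assembly", n_residues=12, seed=1,
                        relaxation_steps=12000, preassembly_stage_steps=600)
    system, topo = build_scaled_system(cfg)
    pre = preassembly(system, topo, tables, cfg)
    membrane = build_protocol_membrane(cfg)
    traj = membrane_assembly(pre, topo, membrane, tables, cfg)
    final = traj.frame_system(len(traj) - 1)
    records = analysis.detect_hbonds(final)
    chains = {r.donor_chain for r in records
              if r.cls.startswith("glucan-membrane")}
    assert len(chains) >= 3
    classes = {r.cls for r in records if r.cls.startswith("glucan-membrane")}
    assert classes <= {"glucan-membrane:O", "glucan-membrane:P",
                       "glucan-membrane:N"}


def test_growth_bookkeeping(tables):
    """After k cycles each chain has exactly k free monomers, 5 A of rise each."""
    cfg = ProtocolConfig(name="extrusion_growth", n_residues=6, seed=2,
                         growth_cycle_steps=200, growth_post_steps=200,
                         report_every=200, membrane_extent_nm=(8.0, 8.0))
    traj, info = extrusion_growth(cfg, tables)
    seen = {}
    for frame in traj.frames:
        k = frame.annotations["free_monomers"]
        frozen = frame.annotations["frozen_mask"]
        seen[k] = frozen
    assert set(seen) == set(range(1, cfg.n_residues))
    s = traj.system
    for k, frozen in seen.items():
        for c in range(6):
            free = (~frozen) & (s.chain_index == c)
            n_free = len(set(s.residue_index[free].tolist()))
            assert n_free == k
    assert info["n_cycles"] == cfg.n_residues - 1


def test_growth_censored_when_chains_cannot_meet(tables):
    """Schedule exhausted without contact reports a censored outcome."""
    cfg = ProtocolConfig(name="extrusion_growth", n_residues=4, seed=2,
                         circle_diameter_nm=12.0, growth_cycles_per_approach=50,
                         growth_cycle_steps=150, growth_post_steps=150,
                         report_every=150, membrane_extent_nm=(16.0, 16.0))
    traj, info = extrusion_growth(cfg, tables)
    assert info["first_contact_monomers"] == analysis.CENSORED
    assert info["stability_verdict"] is None


def test_removing_membrane_atoms_preserves_interchain_bonds(tables):
    """Interchain H-bonds are a property of glucan coordinates alone."""
    cfg = ProtocolConfig(name="extrusion_growth", n_residues=6, seed=4,
                         growth_cycle_steps=250, growth_post_steps=500,
                         report_every=250, membrane_extent_nm=(8.0, 8.0))
    traj, _ = extrusion_growth(cfg, tables)
    final = traj.frame_system(len(traj) - 1)
    with_mem = {(r.donor, r.acceptor)
                for r in analysis.detect_hbonds(final)
                if r.cls == "glucan-glucan"}
    glucan_only_idx = np.where(final.chain_index >= 0)[0]
    from protofibril.builder import System
    stripped = System(*(np.array(getattr(final, f)[glucan_only_idx])
                        for f in ("coords", "elements", "names", "roles",
                                  "types", "chain_index", "residue_index",
                                  "frozen")))
    without = {(glucan_only_idx[r.donor], glucan_only_idx[r.acceptor])
               for r in analysis.detect_hbonds(stripped)}
    assert with_mem == without


def test_wall_bending_flattens_fibril(tables):
    """A standing anchored bundle is driven toward the membrane plane."""
    from protofibril import fixtures
    from protofibril.builder import build_topology
    cfg = ProtocolConfig(name="wall_bending", n_residues=8, seed=1,
                         report_every=300, wall_hold_steps=300)
    organized = fixtures.make_straight_fibril(6, 8, spacing=8.5)
    organized.frozen[organized.residue_index == 0] = True
    from protofibril.builder import build_extended_glucan
    bonds = []
    offset = 0
    for k in range(6):
        ch = build_extended_glucan(8, chain_index=k)
        bonds.append(ch.bonds + offset)
        offset += ch.n_atoms
    topo = build_topology(organized, np.vstack(bonds))
    traj, info = wall_bending(organized, topo, tables, cfg)
    assert info["initial_angle_deg"] > 60.0     # standing upright
    assert info["final_angle_deg"] < info["initial_angle_deg"]
    angles = info["stage_axis_angles_deg"]
    assert angles[-1] < angles[0]


def test_stability_experiment_emits_profile(tables):
    cfg = ProtocolConfig(name="membrane_assembly", seed=0,
                         membrane_extent_nm=(8.0, 8.0), report_every=200)
    profile = stability_experiment([4], replicates=2, steps=800,
                                   config=cfg, tables=tables)
    assert set(profile) == {4}
    stable, total = profile[4]
    assert 0 <= stable <= total == 2


def test_protocol_reports_are_serializable(tables, tmp_path):
    from protofibril import io
    cfg = _small_config(relaxation_steps=600)
    system, topo = build_scaled_system(cfg)
    traj = relaxation(system, topo, tables, cfg)
    report = analysis.summarize_trajectory(traj)
    io.write_report(report, tmp_path / "report.json")
    import json
    data = json.loads((tmp_path / "report.json").read_text())
    assert data["frame_range"] == [0, len(traj) - 1]
    assert "criteria" in data and data["criteria"]["hbond_dmax_A"] == 3.5
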