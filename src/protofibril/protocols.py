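"""Simulation protocols for protofibril assembly.

Four procedures compose the builders with the NVT engine:

* **preassembly** — chains anchored on the 4 nm circle are drawn together
  from the top in 0.5 nm spring-guided steps (force-guided, never
  teleported), producing the 'Eiffel tower' pre-organized state;
* **relaxation** — unrestrained NVT of the pre-organized tower (anchors stay
  frozen); interchain hydrogen bonds zip top-down, chains pair two by two,
  and a basal bend develops;
* **membrane_assembly** — the same run with the fibril base fixed at a frozen
  phospholipid-headgroup surface, adding glucan-membrane H-O/H-P/H-N
  interactions;
* **extrusion_growth** — de novo growth: each chain rises through the
  membrane in 5 A increments (one glucose per cycle), monomers are released
  one by one, and the first-produced monomers are drawn inward step by step;
  records the monomer count at first interchain contact and whether the
  nascent protofibril persists;
* **wall_bending** — a rigid one-sided wall descends onto an organized
  protofibril on a stage schedule, bending it toward the membrane plane.

All protocols are deterministic given (config, seed) and can emit an
:class:`~protofibril.analysis.AssemblyReport`.

Desk-scale defaults (short chains, tens of picoseconds) are chosen so the
whole protocol suite runs on a laptop; the full 60-mer, multi-nanosecond
protocol is reachable through configuration only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import analysis
from .builder import (MembraneSurface, System, Topology, TowerConfiguration,
                      attach_membrane, build_extended_glucan, build_membrane,
                      build_tower)
from .constants import NM_TO_A
from .dynamics import (CentroidRestraint, MDEngine, Trajectory,
                       WallConstraint)
from .forcefield import ForceFieldTables, load_tables

__all__ = [
    "ProtocolConfig", "ProtocolAbortError", "IntegrityFailureError",
    "build_scaled_system", "build_protocol_membrane", "preassembly",
    "relaxation", "membrane_assembly",
    "extrusion_growth", "wall_bending", "stability_experiment", "is_stable",
]

PROTOCOL_NAMES = ("preassembly", "relaxation", "membrane_assembly",
                  "extrusion_growth", "wall_bending")


class ProtocolAbortError(RuntimeError):
    """A protocol stage failed; carries the stage index."""

    def __init__(self, msg: str, stage: int):
        super().__init__(f"{msg} (stage {stage})")
        self.stage = stage


class IntegrityFailureError(RuntimeError):
    """Chain connectivity broken (bond overstretched); carries frame index."""

    def __init__(self, msg: str, frame: int):
        super().__init__(f"{msg} (frame {frame})")
        self.frame = frame


@dataclass
class ProtocolConfig:
    """Parameters of one protocol run; defaults are the desk-scale standard."""

    name: str = "relaxation"
    n_residues: int = 12
    n_chains: int = 6
    seed: int = 0
    temperature: float = 298.0
    dt: float = 1.0
    tau: float = 100.0
    report_every: int = 250
    # tower geometry
    circle_diameter_nm: float = 4.0
    approach_step_nm: float = 0.5
    spring_k: float = 20.0
    top_radius: float = 8.0
    # preassembly
    preassembly_stage_steps: int = 800
    preassembly_target_radius: float = 2.5
    # relaxation / membrane_assembly
    relaxation_steps: int = 15000
    # membrane
    membrane_enabled: bool = False
    membrane_extent_nm: tuple = (12.0, 12.0)
    membrane_density: float = 12.0
    #: membrane slab centre: sites span z0 +/- 1 A, immediately below the
    #: anchor plane (the fibril base is fixed at the membrane surface) while
    #: mobile basal atoms start outside steep 12-6 repulsion
    membrane_z0: float = -3.0
    membrane_ratio: dict = field(default_factory=dict)
    # extrusion growth
    growth_increment: float = 5.0     # A per cycle, one glucose monomer
    growth_cycle_steps: int = 800
    growth_post_steps: int = 4000
    growth_spring_k: float = 5.0
    #: growth cycles per 0.5 nm inward approach step; one step per two
    #: extruded monomers keeps the pulled segment's tilt within what chain
    #: stiffness allows (~0.5 nm lateral per 1 nm of new chain)
    growth_cycles_per_approach: int = 2
    #: the approach target never shrinks below this radius: six chains pack
    #: around the axis at contact distance, they cannot occupy a point
    growth_approach_floor: float = 4.5
    # wall bending: soft enough for 1 fs integration, still impenetrable
    # against thermal energy (penetration depth ~sqrt(kT/k_w) ~ 0.25 A)
    wall_stiffness: float = 10.0
    wall_hold_steps: int = 1000
    wall_step: float = 2.0            # A of descent per stage
    wall_final_height_fraction: float = 0.35

    def __post_init__(self):
        if self.name not in PROTOCOL_NAMES:
            raise ValueError(f"unknown protocol {self.name!r}")
        for attr in ("preassembly_stage_steps", "relaxation_steps",
                     "growth_cycle_steps", "wall_hold_steps"):
            if getattr(self, attr) < 1:
                raise ValueError(f"{attr} must be positive")

    @property
    def approach_step(self) -> float:
        return self.approach_step_nm * NM_TO_A

    def tower_config(self) -> TowerConfiguration:
        return TowerConfiguration(
            circle_diameter_nm=self.circle_diameter_nm,
            approach_step_nm=self.approach_step_nm,
            spring_k=self.spring_k,
            top_radius=self.top_radius)

    def as_dict(self) -> dict:
        return asdict(self)


def build_scaled_system(config: ProtocolConfig):
    """Tower of ``n_chains`` chains of ``n_residues`` on the anchor circle."""
    chains = [build_extended_glucan(config.n_residues, chain_index=i)
              for i in range(config.n_chains)]
    return build_tower(chains, config.tower_config())


def build_protocol_membrane(config: ProtocolConfig, holes=None,
                            hole_radius: float = 4.0) -> MembraneSurface:
    return build_membrane(
        extent_nm=config.membrane_extent_nm,
        density=config.membrane_density,
        ratio=config.membrane_ratio or None,
        seed=config.seed,
        z0=config.membrane_z0,
        holes=holes,
        hole_radius=hole_radius)


# ---------------------------------------------------------------------------
# Preassembly
# ---------------------------------------------------------------------------

def _top_anchor_atoms(system: System, chain: int) -> np.ndarray:
    """Heavy atoms of a chain's top residue (the preassembly handle)."""
    glucan = system.chain_index == chain
    top = int(system.residue_index[glucan].max())
    return np.where(glucan & (system.residue_index == top)
                    & system.heavy)[0]


def preassembly(system: System, topology: Topology,
                tables: ForceFieldTables | None = None,
                config: ProtocolConfig | None = None) -> System:
    """Draw the chain tops toward the common axis in spring-guided steps.

    Each chain's top residue is tethered to a target that moves inward in
    ``approach_step`` (default 0.5 nm) increments, with a short relaxation
    between increments; the tether exerts a force, it never displaces atoms
    directly.  Returns the pre-organized system (coordinates updated,
    topology unchanged).
    """
    config = config or ProtocolConfig(name="preassembly")
    tables = tables or load_tables()
    engine = MDEngine(system, topology, tables, dt=config.dt,
                      temperature=config.temperature, tau=config.tau,
                      seed=config.seed)

    chains = sorted(set(
        system.chain_index[system.chain_index >= 0].tolist()))
    tops = {c: _top_anchor_atoms(system, c) for c in chains}
    # per-chain azimuth and starting top radius
    info = {}
    for c in chains:
        centroid = engine.state.coords[tops[c]].mean(axis=0)
        r = float(np.hypot(centroid[0], centroid[1]))
        info[c] = (float(np.arctan2(centroid[1], centroid[0])), r,
                   float(centroid[2]))

    r_start = max(r for _, r, _ in info.values())
    radii = []
    r = r_start
    while r > config.preassembly_target_radius + 1e-9:
        r = max(r - config.approach_step, config.preassembly_target_radius)
        radii.append(r)
    if not radii:
        radii = [config.preassembly_target_radius]

    for stage, r in enumerate(radii):
        engine.restraints = [
            CentroidRestraint(atoms=tops[c],
                              target=np.array([r * np.cos(info[c][0]),
                                               r * np.sin(info[c][0]),
                                               info[c][2]]),
                              stiffness=config.spring_k)
            for c in chains]
        engine.refresh_forces()
        try:
            engine.run(config.preassembly_stage_steps,
                       report_every=config.preassembly_stage_steps)
        except RuntimeError as err:
            raise ProtocolAbortError(str(err), stage) from err

    out = system.copy()
    out.coords = engine.state.coords.copy()
    return out


# ---------------------------------------------------------------------------
# Relaxation and membrane assembly
# ---------------------------------------------------------------------------

def relaxation(system: System, topology: Topology,
               tables: ForceFieldTables | None = None,
               config: ProtocolConfig | None = None) -> Trajectory:
    """Unrestrained NVT of a pre-organized system (anchors stay frozen)."""
    config = config or ProtocolConfig(name="relaxation")
    tables = tables or load_tables()
    engine = MDEngine(system, topology, tables, dt=config.dt,
                      temperature=config.temperature, tau=config.tau,
                      seed=config.seed)
    return engine.run(config.relaxation_steps,
                      report_every=config.report_every)


def membrane_assembly(system: System, topology: Topology,
                      membrane: MembraneSurface | None,
                      tables: ForceFieldTables | None = None,
                      config: ProtocolConfig | None = None) -> Trajectory:
    """Relaxation with the fibril base fixed at the membrane surface.

    The membrane contributes only nonbonded glucan-site terms; with a null
    or empty membrane the run is identical to :func:`relaxation` at the same
    seed.
    """
    config = config or ProtocolConfig(name="membrane_assembly")
    tables = tables or load_tables()
    merged, topo = attach_membrane(system, topology, membrane)
    engine = MDEngine(merged, topo, tables, dt=config.dt,
                      temperature=config.temperature, tau=config.tau,
                      seed=config.seed)
    return engine.run(config.relaxation_steps,
                      report_every=config.report_every)


# ---------------------------------------------------------------------------
# Extrusion growth
# ---------------------------------------------------------------------------

def extrusion_growth(config: ProtocolConfig | None = None,
                     tables: ForceFieldTables | None = None,
                     membrane: MembraneSurface | None = None):
    """Monomer-by-monomer growth of six chains through the membrane.

    Each chain starts with only its first-produced (top) monomer free above
    the membrane plane; per growth cycle the chain is translated up by one
    monomer length (5 A), the next monomer is released, and the
    first-produced monomers are drawn inward by one approach step, followed
    by a relaxation.  Frames carry ``free_monomers`` annotations so
    first-contact and stability observables can be read off the trajectory.

    Returns ``(trajectory, info)`` where ``info`` holds the first-contact
    monomer count (or the censored marker) and the stability verdict.
    """
    config = config or ProtocolConfig(name="extrusion_growth")
    tables = tables or load_tables()

    n_res = config.n_residues
    radius = config.tower_config().circle_radius
    anchors = [(radius * np.cos(2 * np.pi * k / config.n_chains),
                radius * np.sin(2 * np.pi * k / config.n_chains))
               for k in range(config.n_chains)]
    if membrane is None:
        # exit ports wider than the chain's lateral extent (~4.5 A), so a
        # monomer released at the surface never lands on a site
        membrane = build_protocol_membrane(config, holes=anchors,
                                           hole_radius=6.5)

    chains = [build_extended_glucan(n_res, chain_index=k)
              for k in range(config.n_chains)]
    placed, bonds, offset = [], [], 0
    drop = (n_res - 1) * 5.19 - 2.0   # top monomer ~2 A above the plane
    for k, ch in enumerate(chains):
        s = ch.system.copy()
        s.coords = s.coords + np.array([anchors[k][0], anchors[k][1], -drop])
        s.frozen[:] = s.residue_index < n_res - 1
        placed.append(s)
        bonds.append(ch.bonds + offset)
        offset += s.n_atoms
    from .builder import build_topology, concat_systems
    system = placed[0]
    for s in placed[1:]:
        system = concat_systems(system, s)
    bonds = np.vstack(bonds)
    system, topo = attach_membrane(system, build_topology(system, bonds),
                                   membrane)

    engine = MDEngine(system, topo, tables, dt=config.dt,
                      temperature=config.temperature, tau=config.tau,
                      seed=config.seed)
    glucan = system.chain_index >= 0

    master = Trajectory(system=system)
    state = {"cycle": 1}

    def annotate(eng):
        return {"free_monomers": state["cycle"],
                "frozen_mask": eng.state.frozen.copy()}

    def run_stage(n_steps, stage):
        try:
            t = engine.run(n_steps, report_every=config.report_every,
                           annotate=annotate)
        except RuntimeError as err:
            raise ProtocolAbortError(str(err), stage) from err
        master.frames.extend(t.frames if not master.frames else t.frames[1:])

    def set_approach_restraints(cycle):
        engine.restraints = []
        n_steps_in = (cycle - 1) // config.growth_cycles_per_approach
        r_target = max(radius - n_steps_in * config.approach_step,
                       config.growth_approach_floor)
        for k in range(config.n_chains):
            sel = np.where((system.chain_index == k)
                           & (system.residue_index == n_res - 1)
                           & system.heavy)[0]
            ang = 2 * np.pi * k / config.n_chains
            z = float(engine.state.coords[sel, 2].mean())
            engine.restraints.append(CentroidRestraint(
                atoms=sel,
                target=np.array([r_target * np.cos(ang),
                                 r_target * np.sin(ang), z]),
                stiffness=config.growth_spring_k))
        engine.refresh_forces()

    set_approach_restraints(1)
    run_stage(config.growth_cycle_steps, 0)

    for cycle in range(2, n_res):
        state["cycle"] = cycle
        # extrude: whole chains rise one monomer length
        engine.state.coords[glucan, 2] += config.growth_increment
        # release the next monomer of each chain
        newly = glucan & (system.residue_index == n_res - cycle) \
            & engine.state.frozen
        engine.set_frozen(engine.state.frozen & ~newly)
        set_approach_restraints(cycle)
        run_stage(config.growth_cycle_steps, cycle)

    # post-growth relaxation with restraints released
    engine.restraints = []
    engine.refresh_forces()
    run_stage(config.growth_post_steps, n_res)

    first = analysis.first_contact_monomers(master)
    stable = is_stable(master) if first != analysis.CENSORED else None
    return master, {"first_contact_monomers": first,
                    "stability_verdict": stable,
                    "n_cycles": n_res - 1}


# ---------------------------------------------------------------------------
# Wall bending
# ---------------------------------------------------------------------------

def wall_bending(system: System, topology: Topology,
                 tables: ForceFieldTables | None = None,
                 config: ProtocolConfig | None = None,
                 schedule: list[tuple[float, int]] | None = None):
    """Lower a rigid impenetrable plane onto an organized protofibril.

    The wall descends in stages with relaxation holds; the protofibril bends
    at its flexible base toward the membrane plane.  Chain connectivity is
    checked each stage (no bond may stretch beyond 1.5x its rest length).

    Returns ``(trajectory, info)`` with per-stage body-axis-to-plane angles.
    """
    config = config or ProtocolConfig(name="wall_bending")
    tables = tables or load_tables()
    engine = MDEngine(system, topology, tables, dt=config.dt,
                      temperature=config.temperature, tau=config.tau,
                      seed=config.seed)
    glucan = system.chain_index >= 0
    z_top = float(engine.state.coords[glucan, 2].max())
    z_base = float(engine.state.coords[glucan, 2].min())
    if schedule is None:
        z_final = z_base + config.wall_final_height_fraction * (z_top - z_base)
        n_stages = max(int(np.ceil((z_top + 2.0 - z_final)
                                   / config.wall_step)) + 1, 2)
        heights = np.linspace(z_top + 2.0, z_final, n_stages)
        schedule = [(float(z), config.wall_hold_steps) for z in heights]

    engine.wall = WallConstraint(z_w=schedule[0][0],
                                 stiffness=config.wall_stiffness)
    master = Trajectory(system=system)
    angles = []

    from .forcefield import bonded_params
    params = engine.params
    r0 = params.bond_r0

    def check_integrity(frame_idx):
        c = engine.state.coords
        d = np.linalg.norm(c[topology.bonds[:, 0]] - c[topology.bonds[:, 1]],
                           axis=1)
        over = d > 1.5 * r0
        if over.any():
            b = int(np.argmax(over))
            raise IntegrityFailureError(
                f"bond {topology.bonds[b].tolist()} stretched to "
                f"{d[b]:.2f} A (limit {1.5 * r0[b]:.2f} A)", frame_idx)

    def annotate(eng):
        s = eng.system.copy()
        s.coords = eng.state.coords
        return {"axis_angle_deg": analysis.axis_angle_to_plane(s)}

    for stage, (z_w, hold) in enumerate(schedule):
        engine.wall.z_w = z_w
        engine.refresh_forces()
        try:
            t = engine.run(hold, report_every=config.report_every,
                           annotate=annotate)
        except RuntimeError as err:
            raise ProtocolAbortError(str(err), stage) from err
        master.frames.extend(t.frames if not master.frames else t.frames[1:])
        check_integrity(len(master.frames) - 1)
        angles.append(master.frames[-1].annotations["axis_angle_deg"])

    info = {"stage_axis_angles_deg": angles,
            "initial_angle_deg": master.frames[0].annotations[
                "axis_angle_deg"],
            "final_angle_deg": angles[-1]}
    return master, info


# ---------------------------------------------------------------------------
# Stability of short contact segments
# ---------------------------------------------------------------------------

def is_stable(trajectory: Trajectory, min_cluster: int = 5,
              window_fraction: float = 0.5) -> bool:
    """Stability criterion: a >=5-chain cluster persists over the final half.

    The protofibril counts as stable when a cluster of at least
    ``min_cluster`` chains is present in a majority of the frames of the
    final ``window_fraction`` of the run.
    """
    frames = trajectory.frames
    start = int(len(frames) * (1.0 - window_fraction))
    hits = total = 0
    for i in range(start, len(frames)):
        part = analysis.pairing_partition(trajectory.frame_system(i))
        total += 1
        hits += max(part.cluster_sizes(), default=0) >= min_cluster
    return total > 0 and hits > total / 2.0


def _bundle_on_membrane(m_monomers: int, config: ProtocolConfig,
                        spacing: float = 8.5):
    """Six parallel m-mer chains bundled above the membrane, bases free."""
    from scipy.spatial import cKDTree

    from .builder import BuildFailureError, build_topology, concat_systems
    placed, bonds, offset = [], [], 0
    ring_r = spacing / (2 * np.sin(np.pi / 6))
    for k in range(6):
        ang = 2 * np.pi * k / 6
        ch = build_extended_glucan(m_monomers, chain_index=k)
        s = ch.system.copy()
        # base low enough that basal hydroxyls reach membrane acceptors but
        # with ~2 A initial clearance above the site slab (the terminal
        # 4-OH hydrogen hangs ~2.6 A below the chain origin)
        s.coords = s.coords + np.array([ring_r * np.cos(ang),
                                        ring_r * np.sin(ang), 2.6])
        placed.append(s)
        bonds.append(ch.bonds + offset)
        offset += s.n_atoms
    system = placed[0]
    for s in placed[1:]:
        system = concat_systems(system, s)
    topo = build_topology(system, np.vstack(bonds))
    tree = cKDTree(system.coords)
    bonded = {tuple(sorted(b)) for b in topo.bonds.tolist()}
    for i, j in tree.query_pairs(r=1.6):
        if tuple(sorted((int(i), int(j)))) not in bonded:
            raise BuildFailureError(
                f"bundle spacing {spacing} A leaves atoms {i},{j} in clash")
    return system, topo


def stability_experiment(m_values, replicates: int = 3,
                         steps: int = 4000,
                         config: ProtocolConfig | None = None,
                         tables: ForceFieldTables | None = None
                         ) -> dict[int, tuple[int, int]]:
    """Persistence of six-chain bundles with m interacting monomers.

    For each m, a bundle of six m-mer chains rests (unanchored) just above
    the membrane, where glucan-membrane hydrogen bonds compete with the
    interchain ones; a run is stable per :func:`is_stable`.  Returns the
    profile mapping m to (n_stable, n_total), the input to
    :func:`~protofibril.analysis.stability_threshold`.
    """
    config = config or ProtocolConfig(name="membrane_assembly")
    tables = tables or load_tables()
    profile = {}
    for m in m_values:
        stable = 0
        for rep in range(replicates):
            system, topo = _bundle_on_membrane(m, config)
            membrane = build_protocol_membrane(config)
            merged, mtopo = attach_membrane(system, topo, membrane)
            engine = MDEngine(merged, mtopo, tables, dt=config.dt,
                              temperature=config.temperature, tau=config.tau,
                              seed=config.seed + 1000 * m + rep)
            traj = engine.run(steps, report_every=config.report_every)
            stable += is_stable(traj)
        profile[m] = (stable, replicates)
    return profile
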