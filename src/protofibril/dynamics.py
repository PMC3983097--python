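"""NVT dynamics: velocity-Verlet propagation with a Nosé-Hoover thermostat.

The integrator advances mobile atoms only; frozen atoms (chain anchors,
membrane sites) keep their exact positions and zero velocity for the whole
trajectory.  The instantaneous kinetic temperature and thermostat degrees of
freedom are defined over the mobile atoms.  The timestep is 1 fs by default,
as required by the explicit C-H vibrations of an all-atom description.

With the thermostat disabled the scheme reduces to plain velocity-Verlet
(NVE); with it enabled, a single Nosé-Hoover friction variable xi couples the
mobile atoms to a bath at the target temperature with relaxation time tau.
The extended-system conserved quantity

    H' = KE + PE + Q xi^2 / 2 + g kB T eta

(eta the time integral of xi, Q = g kB T tau^2, g the number of mobile
degrees of freedom) is reported each frame as an integration diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .builder import System, Topology
from .constants import ACC, KB
from .forcefield import (BondedParams, EnergyDecomposition, ForceFieldTables,
                         NeighborList, bonded_params, total_energy_forces)

__all__ = [
    "SystemState",
    "Restraint",
    "CentroidRestraint",
    "WallConstraint",
    "Trajectory",
    "Frame",
    "MDEngine",
    "NumericalBlowupError",
    "maxwell_boltzmann_velocities",
]


class NumericalBlowupError(RuntimeError):
    """Non-finite coordinate or velocity encountered during integration."""


@dataclass
class SystemState:
    """Dynamical variables of the full system."""

    coords: np.ndarray        # (N, 3) A
    velocities: np.ndarray    # (N, 3) A/fs
    frozen: np.ndarray        # (N,) bool
    masses: np.ndarray        # (N,) amu
    xi: float = 0.0           # thermostat friction, 1/fs
    eta: float = 0.0          # time integral of xi
    time: float = 0.0         # fs

    @property
    def n_free(self) -> int:
        return int((~self.frozen).sum())

    @property
    def dof(self) -> int:
        return 3 * self.n_free

    def kinetic_energy(self) -> float:
        m = ~self.frozen
        return 0.5 * float((self.masses[m] * (self.velocities[m] ** 2)
                            .sum(axis=1)).sum()) / ACC

    def temperature(self) -> float:
        g = self.dof
        if g == 0:
            return 0.0
        return 2.0 * self.kinetic_energy() / (g * KB)


def maxwell_boltzmann_velocities(state: SystemState, temperature: float,
                                 rng: np.random.Generator) -> None:
    """Draw velocities for mobile atoms at the target temperature (in place).

    The centre-of-mass drift of the mobile atoms is removed and the sample is
    rescaled to the exact target kinetic temperature.
    """
    m = ~state.frozen
    n = int(m.sum())
    if n == 0:
        return
    sigma = np.sqrt(KB * temperature * ACC / state.masses[m])[:, None]
    v = rng.standard_normal((n, 3)) * sigma
    v -= np.average(v, axis=0, weights=state.masses[m])
    state.velocities[:] = 0.0
    state.velocities[m] = v
    t = state.temperature() if n > 1 else 0.0
    # guard: a single free atom after COM removal has no kinetic energy
    if t > 0:
        state.velocities[m] *= np.sqrt(temperature / t)


@dataclass
class Restraint:
    """Harmonic tether ``U = k * sum_i |x_i - target|^2`` over an atom set."""

    atoms: np.ndarray            # indices
    target: np.ndarray           # (3,) A
    stiffness: float             # kcal/mol/A^2

    def __post_init__(self):
        if self.stiffness < 0:
            raise ValueError("restraint stiffness must be >= 0")
        self.atoms = np.asarray(self.atoms, dtype=int)
        self.target = np.asarray(self.target, dtype=float)

    def energy_forces(self, coords: np.ndarray, forces: np.ndarray) -> float:
        d = coords[self.atoms] - self.target
        forces[self.atoms] -= 2.0 * self.stiffness * d
        return float(self.stiffness * (d ** 2).sum())


@dataclass
class CentroidRestraint:
    """Harmonic tether on the centroid of an atom set.

    ``U = k |mean(x) - target|^2``; the force is shared equally by the
    attached atoms, so the group is pulled without being deformed.
    """

    atoms: np.ndarray
    target: np.ndarray
    stiffness: float

    def __post_init__(self):
        if self.stiffness < 0:
            raise ValueError("restraint stiffness must be >= 0")
        self.atoms = np.asarray(self.atoms, dtype=int)
        self.target = np.asarray(self.target, dtype=float)

    def energy_forces(self, coords: np.ndarray, forces: np.ndarray) -> float:
        d = coords[self.atoms].mean(axis=0) - self.target
        forces[self.atoms] -= 2.0 * self.stiffness * d / len(self.atoms)
        return float(self.stiffness * (d ** 2).sum())


@dataclass
class WallConstraint:
    """One-sided repulsive plane descending from above.

    Atoms above the plane (z > z_w) feel ``U = k_w (z - z_w)^2``; the wall is
    purely repulsive, never attractive, and effectively impenetrable at the
    default stiffness.  ``schedule`` is a sequence of (z_w, hold_steps)
    stages; between stages the height jumps instantaneously.
    """

    z_w: float = np.inf
    stiffness: float = 100.0     # kcal/mol/A^2
    schedule: list[tuple[float, int]] = field(default_factory=list)

    def energy_forces(self, coords: np.ndarray, forces: np.ndarray) -> float:
        dz = coords[:, 2] - self.z_w
        over = dz > 0
        if not over.any():
            return 0.0
        forces[over, 2] -= 2.0 * self.stiffness * dz[over]
        return float(self.stiffness * (dz[over] ** 2).sum())


@dataclass
class Frame:
    time: float
    coords: np.ndarray
    energy: EnergyDecomposition
    temperature: float
    kinetic: float
    conserved: float
    wall_z: float = np.inf
    annotations: dict = field(default_factory=dict)


@dataclass
class Trajectory:
    """Time-ordered frames plus the (static) per-atom metadata."""

    system: System
    frames: list[Frame] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i) -> Frame:
        return self.frames[i]

    def scalars(self) -> pd.DataFrame:
        rows = []
        for f in self.frames:
            row = {"time_fs": f.time, "temperature_K": f.temperature,
                   "kinetic": f.kinetic, "conserved": f.conserved,
                   "wall_z": f.wall_z}
            row.update(f.energy.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def frame_system(self, i: int) -> System:
        s = self.system.copy()
        s.coords = self.frames[i].coords.copy()
        return s


class MDEngine:
    """Propagates a built system under the four-term potential.

    Parameters
    ----------
    temperature:
        Thermostat target (K).  ``thermostat=False`` runs NVE.
    tau:
        Nosé-Hoover relaxation time (fs).
    """

    def __init__(self, system: System, topology: Topology,
                 tables: ForceFieldTables, dt: float = 1.0,
                 temperature: float = 298.0, thermostat: bool = True,
                 tau: float = 100.0, seed: int = 0,
                 check_overlap: bool = True):
        if dt <= 0:
            raise ValueError("dt must be positive")
        self.system = system
        self.topology = topology
        self.tables = tables
        self.params: BondedParams = bonded_params(topology, tables)
        self.nlist = NeighborList(system, topology, tables)
        self.dt = dt
        self.temperature = temperature
        self.thermostat = thermostat
        self.tau = tau
        self.rng = np.random.default_rng(seed)
        self.check_overlap = check_overlap
        #: per-step displacement above which integration counts as diverged
        self.max_step_displacement = 1.0  # A

        self.state = SystemState(
            coords=system.coords.copy(),
            velocities=np.zeros_like(system.coords),
            frozen=system.frozen.copy(),
            masses=system.masses,
        )
        if thermostat:
            maxwell_boltzmann_velocities(self.state, temperature, self.rng)
        self._mobile = ~self.state.frozen
        self._inv_m = np.zeros(len(self.state.masses))
        self._inv_m[self._mobile] = ACC / self.state.masses[self._mobile]
        self.restraints: list[Restraint] = []
        self.wall: WallConstraint | None = None
        self._energy, self._forces = self._evaluate(self.state.coords)

    # -- force evaluation ---------------------------------------------------
    def _evaluate(self, coords):
        self.nlist.update(coords)
        e, forces = total_energy_forces(coords, self.topology, self.params,
                                        self.nlist,
                                        check_overlap=self.check_overlap)
        for r in self.restraints:
            e.restraint += r.energy_forces(coords, forces)
        if self.wall is not None and np.isfinite(self.wall.z_w):
            e.wall += self.wall.energy_forces(coords, forces)
        return e, forces

    def refresh_forces(self) -> None:
        """Re-evaluate forces (call after mutating restraints or the wall)."""
        self.nlist._ref = None   # coordinates may have been edited in place
        self._energy, self._forces = self._evaluate(self.state.coords)

    def set_frozen(self, frozen: np.ndarray, thermalize: bool = True) -> None:
        """Change the mobility mask mid-protocol (e.g. releasing monomers).

        Newly mobile atoms receive Maxwell-Boltzmann velocities at the
        target temperature; newly frozen atoms are stopped.
        """
        frozen = np.asarray(frozen, dtype=bool)
        newly_free = self.state.frozen & ~frozen
        self.state.frozen = frozen.copy()
        self.system.frozen = frozen.copy()
        self._mobile = ~frozen
        self._inv_m = np.zeros(len(self.state.masses))
        self._inv_m[self._mobile] = ACC / self.state.masses[self._mobile]
        self.state.velocities[frozen] = 0.0
        if thermalize and newly_free.any():
            sigma = np.sqrt(KB * self.temperature * ACC
                            / self.state.masses[newly_free])[:, None]
            self.state.velocities[newly_free] = (
                self.rng.standard_normal((int(newly_free.sum()), 3)) * sigma)
        self.nlist.frozen = frozen.copy()
        self.refresh_forces()

    @property
    def Q(self) -> float:
        g = self.state.dof
        return g * KB * self.temperature * self.tau ** 2

    def conserved_quantity(self) -> float:
        h = self.state.kinetic_energy() + self._energy.total
        if self.thermostat:
            g = self.state.dof
            h += (0.5 * self.Q * self.state.xi ** 2
                  + g * KB * self.temperature * self.state.eta)
        return h

    def _nh_half(self, dt: float) -> None:
        """Trotter half-step of the Nosé-Hoover friction variable.

        Updates xi by a quarter step, rescales mobile velocities over a half
        step, advances eta, and updates xi by another quarter step — the
        standard factorization whose full step conserves the extended
        Hamiltonian to high order.
        """
        st = self.state
        mob = self._mobile
        g = st.dof
        gkt = g * KB * self.temperature * ACC          # amu A^2/fs^2
        q = g * KB * self.temperature * self.tau ** 2 * ACC
        ke2 = float((st.masses[mob]
                     * (st.velocities[mob] ** 2).sum(axis=1)).sum())
        st.xi += 0.25 * dt / q * (ke2 - gkt)
        scale = np.exp(-0.5 * dt * st.xi)
        st.velocities[mob] *= scale
        st.eta += 0.5 * dt * st.xi
        ke2 *= scale * scale
        st.xi += 0.25 * dt / q * (ke2 - gkt)

    # -- one velocity-Verlet / Nosé-Hoover step -----------------------------
    def step(self) -> None:
        st = self.state
        dt = self.dt
        mob = self._mobile
        acc = self._forces * self._inv_m[:, None]

        if self.thermostat:
            self._nh_half(dt)
        st.velocities[mob] += 0.5 * dt * acc[mob]
        step_disp = dt * st.velocities[mob]
        st.coords[mob] += step_disp
        self._energy, self._forces = self._evaluate(st.coords)
        acc = self._forces * self._inv_m[:, None]
        st.velocities[mob] += 0.5 * dt * acc[mob]
        if self.thermostat:
            self._nh_half(dt)

        st.time += dt
        disp2 = (step_disp ** 2).sum(axis=1)
        limit2 = self.max_step_displacement ** 2
        if not np.isfinite(st.coords[mob]).all() \
                or not np.isfinite(st.velocities[mob]).all() \
                or not np.isfinite(disp2).all() or bool((disp2 > limit2).any()):
            mob_idx = np.where(mob)[0]
            bad = ~np.isfinite(st.coords[mob]).all(axis=1) \
                | ~np.isfinite(st.velocities[mob]).all(axis=1) \
                | ~np.isfinite(disp2) | (disp2 > limit2)
            first = int(mob_idx[np.argmax(bad)]) if bad.any() else -1
            raise NumericalBlowupError(
                f"non-finite or runaway position/velocity at atom {first}, "
                f"t = {st.time} fs")

    # -- trajectory driver --------------------------------------------------
    def run(self, n_steps: int, report_every: int = 100,
            annotate=None) -> Trajectory:
        """Advance ``n_steps`` and collect frames every ``report_every`` steps.

        ``annotate(engine) -> dict`` attaches per-frame bookkeeping (e.g.
        growth-cycle counters) to each reported frame.  The initial state is
        reported as frame 0.
        """
        if n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        traj = Trajectory(system=self.system)
        self._report(traj, annotate)
        for i in range(1, n_steps + 1):
            self.step()
            if i % report_every == 0 or i == n_steps:
                self._report(traj, annotate)
        return traj

    def _report(self, traj, annotate) -> None:
        st = self.state
        traj.frames.append(Frame(
            time=st.time,
            coords=st.coords.copy(),
            energy=EnergyDecomposition(**{
                k: v for k, v in self._energy.as_dict().items()
                if k != "total"}),
            temperature=st.temperature(),
            kinetic=st.kinetic_energy(),
            conserved=self.conserved_quantity(),
            wall_z=self.wall.z_w if self.wall is not None else np.inf,
            annotations=dict(annotate(self)) if annotate else {},
        ))
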