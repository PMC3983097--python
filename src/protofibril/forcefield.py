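"""Potential energy terms and forces.

The potential has exactly four contributions, summed over a fixed topology:

* bond:      ``U_b = k_b (r - r_o)^2``
* angle:     ``U_v = k_v (theta - theta_o)^2``
* dihedral:  ``U_d = 0.5 [A1(1 + cos t) + A2(1 - cos 2t) + A3(1 + cos 3t)]``
* nonbonded: ``U_LJ = A_ij / r^12 - C_ij / r^6``

with no electrostatics.  Hydrogen bonds are folded into the 12-6 form as
deepened wells for hydroxyl-hydrogen/acceptor (H-O, H-P, H-N) pairs.
Parameters are generic Dreiding constants loaded from a shipped YAML file;
1-2 and 1-3 pairs are excluded, 1-4 kept at full strength; the 12-6 term is
truncated at a cutoff and shifted to zero there so that energy is conserved.

Nonbonded sums run over pairs with at least one mobile atom: interactions
among permanently frozen atoms (membrane-membrane, anchor-membrane) are
constant over any trajectory and are excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from numba import njit
from scipy.spatial import cKDTree

from .builder import System, Topology

__all__ = [
    "ForceFieldTables",
    "EnergyDecomposition",
    "NeighborList",
    "OverlappingAtomsError",
    "load_tables",
    "bond_energy",
    "angle_energy",
    "dihedral_energy",
    "pair_energy",
    "total_energy_forces",
]

HARD_FLOOR = 0.1  # A; any closer nonbonded approach is an error


class OverlappingAtomsError(RuntimeError):
    """Two nonbonded atoms closer than the hard floor."""


@dataclass
class EnergyDecomposition:
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    nonbonded: float = 0.0
    restraint: float = 0.0
    wall: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.nonbonded
                + self.restraint + self.wall)

    def as_dict(self) -> dict[str, float]:
        return {"bond": self.bond, "angle": self.angle,
                "dihedral": self.dihedral, "nonbonded": self.nonbonded,
                "restraint": self.restraint, "wall": self.wall,
                "total": self.total}


@dataclass
class ForceFieldTables:
    """Materialized parameter tables for a fixed set of atom types."""

    type_names: list[str]
    pair_A: np.ndarray           # (nt, nt) kcal/mol A^12
    pair_C: np.ndarray           # (nt, nt) kcal/mol A^6
    bond_params: dict[str, tuple[float, float]]   # "T1:T2" -> (k_b, r_o)
    angle_params: dict[str, tuple[float, float]]  # center type -> (k_v, th_o)
    torsion_barrier: float
    cutoff: float
    skin: float
    hbond_donor: str
    hbond_acceptors: list[str]
    hbond_depth: float
    source: dict = field(repr=False, default_factory=dict)

    def type_id(self, names) -> np.ndarray:
        lut = {t: i for i, t in enumerate(self.type_names)}
        return np.array([lut[t] for t in names], dtype=np.int64)

    def well_depth(self, t1: str, t2: str) -> float:
        i, j = self.type_id([t1, t2])
        a, c = self.pair_A[i, j], self.pair_C[i, j]
        return c * c / (4.0 * a)

    def dump(self) -> str:
        """Human-readable dump of the active pair table (for audit)."""
        lines = ["# pair  A_ij[kcal/mol A^12]  C_ij[kcal/mol A^6]  "
                 "r*[A]  depth[kcal/mol]"]
        for i, t1 in enumerate(self.type_names):
            for j, t2 in enumerate(self.type_names[i:], start=i):
                a, c = self.pair_A[i, j], self.pair_C[i, j]
                rstar = (2 * a / c) ** (1 / 6)
                lines.append(f"{t1}:{t2}  {a:.6g}  {c:.6g}  "
                             f"{rstar:.4f}  {c * c / (4 * a):.6g}")
        return "\n".join(lines)


def load_tables(hbond_depth: float | None = None,
                cutoff: float | None = None,
                skin: float | None = None) -> ForceFieldTables:
    """Load the shipped Dreiding-style parameter file into explicit tables.

    Cross pairs combine with a geometric mean on well depth and an arithmetic
    mean on the 12-6 minimum position; hydroxyl-hydrogen/acceptor pairs
    (H-O, H-P, H-N) are then replaced by deepened short-range wells of
    ``hbond_depth`` (default from the file) at H-bond geometry, the 12-6
    representation of hydrogen bonding.
    """
    raw = yaml.safe_load(
        resources.files("protofibril.data").joinpath("dreiding.yaml")
        .read_text())

    vdw = raw["vdw"]
    types = list(vdw.keys())
    r0 = np.array([vdw[t]["r0"] for t in types])
    d0 = np.array([vdw[t]["d0"] for t in types])
    rstar = 0.5 * (r0[:, None] + r0[None, :])
    depth = np.sqrt(d0[:, None] * d0[None, :])

    hb = raw["hbond"]
    hb_depth = float(hbond_depth if hbond_depth is not None else hb["depth"])
    donor = hb["donor_hydrogen"]
    acceptors = list(hb["acceptors"])
    for a_name, spec in hb["acceptors"].items():
        i, j = types.index(donor), types.index(a_name)
        depth[i, j] = depth[j, i] = hb_depth
        rstar[i, j] = rstar[j, i] = float(spec["rstar"])

    pair_A = depth * rstar ** 12
    pair_C = 2.0 * depth * rstar ** 6

    radii = raw["covalent_radii"]
    kb = float(raw["bond_k"])
    bond_params = {}
    for t1 in radii:
        for t2 in radii:
            key = ":".join(sorted((t1, t2)))
            bond_params[key] = (kb, radii[t1] + radii[t2] - 0.01)

    angle_params = {t: (float(v["k"]), float(np.deg2rad(v["theta0_deg"])))
                    for t, v in raw["angle"].items()}

    nb = raw["nonbonded"]
    return ForceFieldTables(
        type_names=types,
        pair_A=pair_A, pair_C=pair_C,
        bond_params=bond_params,
        angle_params=angle_params,
        torsion_barrier=float(raw["torsion"]["barrier"]),
        cutoff=float(cutoff if cutoff is not None else nb["cutoff"]),
        skin=float(skin if skin is not None else nb["skin"]),
        hbond_donor=donor, hbond_acceptors=acceptors, hbond_depth=hb_depth,
        source=raw,
    )


# ---------------------------------------------------------------------------
# Analytic single-term forms (scalar or vectorized)
# ---------------------------------------------------------------------------

def bond_energy(r, k_b: float, r_o: float):
    """Harmonic bond energy ``k_b (r - r_o)^2``; force is -2 k_b (r - r_o)."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("bond length must be positive")
    return k_b * (r - r_o) ** 2


def angle_energy(theta, k_v: float, theta_o: float):
    """Harmonic valence-angle energy ``k_v (theta - theta_o)^2`` (radians)."""
    theta = np.asarray(theta, dtype=float)
    if np.any((theta <= 0) | (theta >= np.pi)):
        raise ValueError("valence angle must lie in (0, pi)")
    return k_v * (theta - theta_o) ** 2


def dihedral_energy(theta, a1: float, a2: float, a3: float):
    """Three-cosine torsion, periodic in 2*pi."""
    theta = np.asarray(theta, dtype=float)
    return 0.5 * (a1 * (1 + np.cos(theta))
                  + a2 * (1 - np.cos(2 * theta))
                  + a3 * (1 + np.cos(3 * theta)))


def pair_energy(r, a: float, c: float, cutoff: float | None = None):
    """12-6 energy ``A/r^12 - C/r^6``, truncated and shifted at ``cutoff``.

    The minimum sits at r* = (2A/C)^(1/6) with depth -C^2/(4A).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("pair distance must be positive")
    u = a / r ** 12 - c / r ** 6
    if cutoff is not None:
        shift = a / cutoff ** 12 - c / cutoff ** 6
        u = np.where(r < cutoff, u - shift, 0.0)
    return u


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _bond_kernel(coords, bonds, kb, r0, forces):
    e = 0.0
    for n in range(bonds.shape[0]):
        i, j = bonds[n, 0], bonds[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dr = r - r0[n]
        e += kb[n] * dr * dr
        f = -2.0 * kb[n] * dr / r
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    return e


@njit(cache=True)
def _angle_kernel(coords, angles, kv, t0, forces):
    e = 0.0
    for n in range(angles.shape[0]):
        i, j, k = angles[n, 0], angles[n, 1], angles[n, 2]
        ax = coords[i, 0] - coords[j, 0]
        ay = coords[i, 1] - coords[j, 1]
        az = coords[i, 2] - coords[j, 2]
        bx = coords[k, 0] - coords[j, 0]
        by = coords[k, 1] - coords[j, 1]
        bz = coords[k, 2] - coords[j, 2]
        lij = np.sqrt(ax * ax + ay * ay + az * az)
        lkj = np.sqrt(bx * bx + by * by + bz * bz)
        ct = (ax * bx + ay * by + az * bz) / (lij * lkj)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        st = np.sqrt(1.0 - ct * ct)
        if st < 1e-8:
            st = 1e-8
        dth = theta - t0[n]
        e += kv[n] * dth * dth
        coef = 2.0 * kv[n] * dth / st
        c1 = 1.0 / (lij * lkj)
        ca = ct / (lij * lij)
        cb = ct / (lkj * lkj)
        fix = coef * (bx * c1 - ax * ca)
        fiy = coef * (by * c1 - ay * ca)
        fiz = coef * (bz * c1 - az * ca)
        fkx = coef * (ax * c1 - bx * cb)
        fky = coef * (ay * c1 - by * cb)
        fkz = coef * (az * c1 - bz * cb)
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[k, 0] += fkx
        forces[k, 1] += fky
        forces[k, 2] += fkz
        forces[j, 0] -= fix + fkx
        forces[j, 1] -= fiy + fky
        forces[j, 2] -= fiz + fkz
    return e


@njit(cache=True)
def _dihedral_kernel(coords, dihedrals, a1, a2, a3, forces):
    e = 0.0
    for n in range(dihedrals.shape[0]):
        i, j, k, l = (dihedrals[n, 0], dihedrals[n, 1],
                      dihedrals[n, 2], dihedrals[n, 3])
        b1x = coords[j, 0] - coords[i, 0]
        b1y = coords[j, 1] - coords[i, 1]
        b1z = coords[j, 2] - coords[i, 2]
        b2x = coords[k, 0] - coords[j, 0]
        b2y = coords[k, 1] - coords[j, 1]
        b2z = coords[k, 2] - coords[j, 2]
        b3x = coords[l, 0] - coords[k, 0]
        b3y = coords[l, 1] - coords[k, 1]
        b3z = coords[l, 2] - coords[k, 2]
        n1x = b1y * b2z - b1z * b2y
        n1y = b1z * b2x - b1x * b2z
        n1z = b1x * b2y - b1y * b2x
        n2x = b2y * b3z - b2z * b3y
        n2y = b2z * b3x - b2x * b3z
        n2z = b2x * b3y - b2y * b3x
        lb2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        sn1 = n1x * n1x + n1y * n1y + n1z * n1z
        sn2 = n2x * n2x + n2y * n2y + n2z * n2z
        if sn1 < 1e-12 or sn2 < 1e-12:
            continue
        x = n1x * n2x + n1y * n2y + n1z * n2z
        crx = n1y * n2z - n1z * n2y
        cry = n1z * n2x - n1x * n2z
        crz = n1x * n2y - n1y * n2x
        y = (crx * b2x + cry * b2y + crz * b2z) / lb2
        phi = np.arctan2(y, x)
        e += 0.5 * (a1[n] * (1 + np.cos(phi))
                    + a2[n] * (1 - np.cos(2 * phi))
                    + a3[n] * (1 + np.cos(3 * phi)))
        dudphi = 0.5 * (-a1[n] * np.sin(phi)
                        + 2 * a2[n] * np.sin(2 * phi)
                        - 3 * a3[n] * np.sin(3 * phi))
        ci = dudphi * lb2 / sn1
        cl = -dudphi * lb2 / sn2
        fix = ci * n1x
        fiy = ci * n1y
        fiz = ci * n1z
        flx = cl * n2x
        fly = cl * n2y
        flz = cl * n2z
        d12 = (b1x * b2x + b1y * b2y + b1z * b2z) / (lb2 * lb2)
        d32 = (b3x * b2x + b3y * b2y + b3z * b2z) / (lb2 * lb2)
        svx = d12 * fix - d32 * flx
        svy = d12 * fiy - d32 * fly
        svz = d12 * fiz - d32 * flz
        forces[i, 0] += fix
        forces[i, 1] += fiy
        forces[i, 2] += fiz
        forces[j, 0] += -fix - svx
        forces[j, 1] += -fiy - svy
        forces[j, 2] += -fiz - svz
        forces[k, 0] += -flx + svx
        forces[k, 1] += -fly + svy
        forces[k, 2] += -flz + svz
        forces[l, 0] += flx
        forces[l, 1] += fly
        forces[l, 2] += flz
    return e


@njit(cache=True)
def _pair_kernel(coords, pairs, pa, pc, cutoff, shifts, forces):
    e = 0.0
    rmin = 1e30
    c2 = cutoff * cutoff
    for n in range(pairs.shape[0]):
        i, j = pairs[n, 0], pairs[n, 1]
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= c2:
            continue
        if r2 < rmin:
            rmin = r2
        inv6 = 1.0 / (r2 * r2 * r2)
        inv12 = inv6 * inv6
        e += pa[n] * inv12 - pc[n] * inv6 - shifts[n]
        f = (12.0 * pa[n] * inv12 - 6.0 * pc[n] * inv6) / r2
        forces[i, 0] += f * dx
        forces[i, 1] += f * dy
        forces[i, 2] += f * dz
        forces[j, 0] -= f * dx
        forces[j, 1] -= f * dy
        forces[j, 2] -= f * dz
    return e, np.sqrt(rmin)


# ---------------------------------------------------------------------------
# Parameter materialization per topology
# ---------------------------------------------------------------------------

@dataclass
class BondedParams:
    bond_kb: np.ndarray
    bond_r0: np.ndarray
    angle_k: np.ndarray
    angle_t0: np.ndarray
    dih_a1: np.ndarray
    dih_a2: np.ndarray
    dih_a3: np.ndarray


def bonded_params(topology: Topology, tables: ForceFieldTables) -> BondedParams:
    nb = len(topology.bonds)
    bond_kb = np.empty(nb)
    bond_r0 = np.empty(nb)
    for n, key in enumerate(topology.bond_types):
        bond_kb[n], bond_r0[n] = tables.bond_params[key]
    na = len(topology.angles)
    angle_k = np.empty(na)
    angle_t0 = np.empty(na)
    for n, t in enumerate(topology.angle_types):
        angle_k[n], angle_t0[n] = tables.angle_params[t]
    nd = len(topology.dihedrals)
    dih_a3 = (tables.torsion_barrier
              / np.maximum(topology.dihedral_mult, 1)).astype(float) \
        if nd else np.empty(0)
    zeros = np.zeros(nd)
    return BondedParams(bond_kb, bond_r0, angle_k, angle_t0,
                        zeros, zeros.copy(), dih_a3)


# ---------------------------------------------------------------------------
# Neighbor list
# ---------------------------------------------------------------------------

class NeighborList:
    """Verlet pair list with a skin; pairs among frozen atoms are dropped.

    Rebuilds are triggered when any mobile atom has moved more than half the
    skin since the last build.
    """

    def __init__(self, system: System, topology: Topology,
                 tables: ForceFieldTables):
        self.topology = topology
        self.tables = tables
        self.frozen = system.frozen.copy()
        self.type_ids = tables.type_id(system.types)
        self.cutoff = tables.cutoff
        self.skin = tables.skin
        self._ref = None
        self.pairs = np.empty((0, 2), dtype=np.int64)
        self.pair_a = np.empty(0)
        self.pair_c = np.empty(0)
        self.pair_shift = np.empty(0)

    def needs_rebuild(self, coords: np.ndarray) -> bool:
        if self._ref is None:
            return True
        mobile = ~self.frozen
        if not mobile.any():
            return False
        disp = np.abs(coords[mobile] - self._ref[mobile]).max()
        return bool(disp > 0.5 * self.skin)

    def build(self, coords: np.ndarray) -> None:
        tree = cKDTree(coords)
        pairs = tree.query_pairs(r=self.cutoff + self.skin,
                                 output_type="ndarray").astype(np.int64)
        if len(pairs):
            both_frozen = self.frozen[pairs[:, 0]] & self.frozen[pairs[:, 1]]
            pairs = pairs[~both_frozen]
        if len(pairs):
            n = self.topology.n_atoms
            lo = np.minimum(pairs[:, 0], pairs[:, 1])
            hi = np.maximum(pairs[:, 0], pairs[:, 1])
            keys = lo * n + hi
            pos = np.searchsorted(self.topology.exclusion_keys, keys)
            pos = np.clip(pos, 0, max(len(self.topology.exclusion_keys) - 1, 0))
            excluded = (len(self.topology.exclusion_keys) > 0) \
                & (self.topology.exclusion_keys[pos] == keys)
            pairs = pairs[~excluded]
        self.pairs = pairs
        ti = self.type_ids[pairs[:, 0]] if len(pairs) else np.empty(0, np.int64)
        tj = self.type_ids[pairs[:, 1]] if len(pairs) else np.empty(0, np.int64)
        self.pair_a = self.tables.pair_A[ti, tj]
        self.pair_c = self.tables.pair_C[ti, tj]
        rc = self.cutoff
        self.pair_shift = self.pair_a / rc ** 12 - self.pair_c / rc ** 6
        self._ref = coords.copy()

    def update(self, coords: np.ndarray) -> None:
        if self.needs_rebuild(coords):
            self.build(coords)


# ---------------------------------------------------------------------------
# Total energy and forces
# ---------------------------------------------------------------------------

def total_energy_forces(coords: np.ndarray, topology: Topology,
                        params: BondedParams, nlist: NeighborList,
                        check_overlap: bool = True):
    """Evaluate the full potential and per-atom forces.

    Forces on frozen atoms are reported (Newton's third law is respected in
    the returned array) but the integrator never applies them.
    """
    forces = np.zeros_like(coords)
    e = EnergyDecomposition()
    if len(topology.bonds):
        e.bond = _bond_kernel(coords, topology.bonds, params.bond_kb,
                              params.bond_r0, forces)
    if len(topology.angles):
        e.angle = _angle_kernel(coords, topology.angles, params.angle_k,
                                params.angle_t0, forces)
    if len(topology.dihedrals):
        e.dihedral = _dihedral_kernel(coords, topology.dihedrals,
                                      params.dih_a1, params.dih_a2,
                                      params.dih_a3, forces)
    if len(nlist.pairs):
        e.nonbonded, rmin = _pair_kernel(coords, nlist.pairs, nlist.pair_a,
                                         nlist.pair_c, nlist.cutoff,
                                         nlist.pair_shift, forces)
        if check_overlap and rmin < HARD_FLOOR:
            raise OverlappingAtomsError(
                f"nonbonded distance {rmin:.3f} A below {HARD_FLOOR} A")
    return e, forces
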