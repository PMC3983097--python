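"""All-atom construction of glucan chains, the six-chain tower, and the membrane.

A cellulose protofibril precursor is modelled as six beta-1,4-linked
glucopyranose polymers.  Each residue is built as an idealized 4C1 chair with
all heavy substituents equatorial (the beta-D-glucopyranose substitution
pattern) and explicit hydrogens; the internal geometry follows standard
cellulose crystallography (chair ring, ~1.52 A C-C, ~1.42 A C-O bonds, 2-fold
screw symmetry along the chain axis with 10.38 A per cellobiose, i.e. a rise
of 5.19 A per glucose).  One residue carries 21 atoms; the two chain termini
add a 4-OH hydrogen (non-reducing end) and an anomeric O1-H (reducing end),
so an n-mer has 21*n + 3 atoms (a 60-mer has 1263).

This module also owns system topology: bond, angle and dihedral lists plus the
1-2/1-3 nonbonded exclusion set over which the force field is summed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import cKDTree

from .constants import ATOMIC_MASSES, NM_TO_A

__all__ = [
    "GlucanChain",
    "System",
    "Topology",
    "MembraneSurface",
    "TowerConfiguration",
    "BuildFailureError",
    "build_extended_glucan",
    "build_tower",
    "build_membrane",
    "attach_membrane",
    "build_topology",
    "RISE_PER_RESIDUE",
]

#: Rise per glucose residue along the chain axis (A); half the cellulose
#: fibre repeat of 10.38 A per cellobiose.  One extruded monomer corresponds
#: to ~5 A of chain.
RISE_PER_RESIDUE = 5.19

GLYCOSIDIC_BOND_LENGTH = 1.42  # C1-O4' (A)

_TET = np.deg2rad(109.471)


class BuildFailureError(RuntimeError):
    """A built configuration violates a hard geometric contract."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class System:
    """Flat per-atom arrays for a (multi-chain, optionally membrane) system.

    ``chain_index`` is -1 for membrane sites; ``frozen`` atoms are immobile
    during dynamics and their positions are never updated.
    """

    coords: np.ndarray          # (N, 3) float64, A
    elements: np.ndarray        # (N,) unicode
    names: np.ndarray           # (N,) atom names, e.g. "C1", "HO6"
    roles: np.ndarray           # (N,) role labels
    types: np.ndarray           # (N,) force-field type names
    chain_index: np.ndarray     # (N,) int
    residue_index: np.ndarray   # (N,) int, per-chain residue number
    frozen: np.ndarray          # (N,) bool

    def __post_init__(self) -> None:
        n = len(self.coords)
        for name in ("elements", "names", "roles", "types",
                     "chain_index", "residue_index", "frozen"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"array length mismatch for {name!r}")
        if not set(np.unique(self.elements)) <= {"C", "H", "O", "N", "P"}:
            raise ValueError("elements restricted to C, H, O, N, P")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[e] for e in self.elements])

    @property
    def heavy(self) -> np.ndarray:
        return self.elements != "H"

    def copy(self) -> "System":
        return System(*(np.array(getattr(self, f.name), copy=True)
                        for f in self.__dataclass_fields__.values()))

    def n_chains(self) -> int:
        idx = self.chain_index[self.chain_index >= 0]
        return int(idx.max()) + 1 if idx.size else 0


def concat_systems(a: System, b: System) -> System:
    return System(
        np.vstack([a.coords, b.coords]),
        np.concatenate([a.elements, b.elements]),
        np.concatenate([a.names, b.names]),
        np.concatenate([a.roles, b.roles]),
        np.concatenate([a.types, b.types]),
        np.concatenate([a.chain_index, b.chain_index]),
        np.concatenate([a.residue_index, b.residue_index]),
        np.concatenate([a.frozen, b.frozen]),
    )


@dataclass
class GlucanChain:
    """One beta-1,4-glucan in extended (2-fold screw) conformation.

    Residue 0 is the non-reducing end (chain base); the reducing end with the
    anomeric O1-H hydroxyl sits at the top, matching the polarity of a chain
    extruded from a membrane-embedded synthase.
    """

    system: System
    n_residues: int
    chain_index: int
    reducing_end_last: bool = True
    bonds: np.ndarray = field(default_factory=lambda: np.empty((0, 2), int))

    @property
    def n_atoms(self) -> int:
        return self.system.n_atoms


@dataclass
class Topology:
    """Bonded terms and nonbonded exclusions, immutable during dynamics.

    ``exclusions`` holds sorted (i, j) pairs for every 1-2 and 1-3
    relationship encoded as i * n_atoms + j keys (sorted array, searchable).
    """

    n_atoms: int
    bonds: np.ndarray          # (nb, 2) int
    bond_types: np.ndarray     # (nb,) param key strings like "C_3:O_3"
    angles: np.ndarray         # (na, 3) int, center second
    angle_types: np.ndarray    # (na,) center type name
    dihedrals: np.ndarray      # (nd, 4) int
    dihedral_mult: np.ndarray  # (nd,) number of dihedrals sharing the bond
    exclusion_keys: np.ndarray  # sorted int64 keys

    def is_excluded(self, i: int, j: int) -> bool:
        lo, hi = (i, j) if i < j else (j, i)
        key = np.int64(lo) * self.n_atoms + hi
        pos = np.searchsorted(self.exclusion_keys, key)
        return bool(pos < len(self.exclusion_keys)
                    and self.exclusion_keys[pos] == key)


@dataclass
class MembraneSurface:
    """Frozen O/P/N interaction sites emulating a phospholipid headgroup face.

    Only the hydrogen-bond-capable species of a phosphoethanolamine headgroup
    are represented; all sites are immobile and lie in a thin slab about z0.
    """

    system: System
    extent: tuple[float, float]   # (A, A)
    z0: float
    thickness: float
    density: float                # sites / nm^2
    ratio: dict[str, int]

    @property
    def n_sites(self) -> int:
        return self.system.n_atoms


@dataclass
class TowerConfiguration:
    """Geometry of the pre-assembly 'Eiffel tower' initial configuration."""

    circle_diameter_nm: float = 4.0
    approach_step_nm: float = 0.5
    spring_k: float = 5.0          # kcal/mol/A^2 per restrained atom
    top_radius: float = 8.0        # A, radius at which chain tops start
    min_separation: float = 1.0    # A, hard clash floor at build time

    @property
    def circle_radius(self) -> float:
        return 0.5 * self.circle_diameter_nm * NM_TO_A


# ---------------------------------------------------------------------------
# Residue template geometry
# ---------------------------------------------------------------------------

def _perp(u: np.ndarray) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(u, ref)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t = np.cross(u, ref)
    return t / np.linalg.norm(t)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _vacant_directions(center, nb1, nb2):
    """Two remaining tetrahedral directions at an atom with two neighbours."""
    u = _unit(nb1 - center)
    v = _unit(nb2 - center)
    bisec = -_unit(u + v)
    w = _unit(np.cross(u, v))
    # half-angle between the two vacant bonds of a tetrahedral centre
    half = 0.5 * _TET
    d1 = _unit(np.cos(half) * bisec + np.sin(half) * w)
    d2 = _unit(np.cos(half) * bisec - np.sin(half) * w)
    return d1, d2


def _hydroxyl_h(o_pos, c_pos, plane_hint):
    """Place a hydroxyl hydrogen at 0.98 A with a ~107.5 deg C-O-H angle."""
    u = _unit(c_pos - o_pos)
    t = np.cross(u, plane_hint)
    nt = np.linalg.norm(t)
    t = _perp(u) if nt < 1e-6 else t / nt
    ang = np.deg2rad(107.5)
    return o_pos + 0.98 * (np.cos(ang) * u + np.sin(ang) * t)


_CC = 1.52   # C-C bond (A)
_CO = 1.42   # C-O bond (A)
_CH = 1.09   # C-H bond (A)

#: intra-residue connectivity by atom name (21-atom repeat unit)
RESIDUE_BONDS = [
    ("C1", "C2"), ("C2", "C3"), ("C3", "C4"), ("C4", "C5"),
    ("C5", "O5"), ("O5", "C1"),
    ("C1", "H1"),
    ("C2", "O2"), ("C2", "H2"), ("O2", "HO2"),
    ("C3", "O3"), ("C3", "H3"), ("O3", "HO3"),
    ("C4", "O4"), ("C4", "H4"),
    ("C5", "C6"), ("C5", "H5"),
    ("C6", "O6"), ("C6", "H61"), ("C6", "H62"), ("O6", "HO6"),
]

_ROLE_BY_NAME = {
    "O5": "ring-oxygen", "O4": "glycosidic-oxygen",
    "O2": "hydroxyl-oxygen", "O3": "hydroxyl-oxygen", "O6": "hydroxyl-oxygen",
    "O1": "anomeric-oxygen",
}


def _role_of(name: str) -> str:
    if name in _ROLE_BY_NAME:
        return _ROLE_BY_NAME[name]
    if name.startswith("HO"):
        return "hydroxyl-hydrogen"
    if name.startswith("H"):
        return "aliphatic-hydrogen"
    return "carbon"


def _type_of(name: str) -> str:
    if name.startswith("HO"):
        return "H_HB"
    if name.startswith("H"):
        return "H_"
    if name.startswith("O"):
        return "O_3"
    return "C_3"


def _raw_residue() -> dict[str, np.ndarray]:
    """Idealized 4C1 chair glucopyranose with explicit hydrogens.

    Ring atoms sit on a puckered hexagon; OH/CH2OH substituents equatorial,
    ring hydrogens axial.  Returned in an arbitrary local frame.
    """
    ring_names = ["C1", "C2", "C3", "C4", "C5", "O5"]
    q = 0.25
    radius = np.sqrt(_CC ** 2 / 4.0 * 3.0 - 0.0)  # placeholder, fixed below
    # choose radius so that adjacent ring atoms are ~1.5 A apart with the pucker
    bond = 1.50
    radius = np.sqrt((bond ** 2 - (2 * q) ** 2) / (2 * (1 - np.cos(np.pi / 3))))
    pos: dict[str, np.ndarray] = {}
    for k, name in enumerate(ring_names):
        ang = -k * np.pi / 3.0
        pos[name] = np.array([radius * np.cos(ang), radius * np.sin(ang),
                              q * (-1.0) ** k])

    nbrs = {ring_names[k]: (ring_names[k - 1], ring_names[(k + 1) % 6])
            for k in range(6)}
    normal = np.array([0.0, 0.0, 1.0])

    def place_pair(center_name, heavy_name, heavy_len):
        c = pos[center_name]
        d1, d2 = _vacant_directions(c, pos[nbrs[center_name][0]],
                                    pos[nbrs[center_name][1]])
        # axial = more aligned with the ring normal
        if abs(np.dot(d1, normal)) >= abs(np.dot(d2, normal)):
            ax, eq = d1, d2
        else:
            ax, eq = d2, d1
        h_name = "H" + center_name[1]
        pos[h_name] = c + _CH * ax
        if heavy_name is not None:
            pos[heavy_name] = c + heavy_len * eq
        return eq

    anomeric_dir = place_pair("C1", None, 0.0)       # vacant slot for O4'/O1
    place_pair("C2", "O2", _CO)
    place_pair("C3", "O3", _CO)
    place_pair("C4", "O4", _CO)
    place_pair("C5", "C6", _CC)

    # exocyclic CH2OH: three tetrahedral slots on C6 around the C6->C5 bond
    u5 = _unit(pos["C5"] - pos["C6"])
    t1 = _perp(u5)
    t2 = np.cross(u5, t1)
    for name, phi in (("O6", 0.0), ("H61", 2 * np.pi / 3),
                      ("H62", 4 * np.pi / 3)):
        d = (np.cos(_TET) * u5
             + np.sin(_TET) * (np.cos(phi) * t1 + np.sin(phi) * t2))
        ln = _CO if name == "O6" else _CH
        pos[name] = pos["C6"] + ln * d

    for o_name, c_name in (("O2", "C2"), ("O3", "C3"), ("O6", "C6")):
        pos["H" + o_name] = _hydroxyl_h(pos[o_name], pos[c_name], normal)

    pos["_anomeric_dir"] = anomeric_dir
    # vacant direction on O4 (where HO4 / the incoming C1' sits): tetrahedral
    # continuation of the C4-O4 bond, bent away in the ring plane
    u = _unit(pos["C4"] - pos["O4"])
    t = _perp(u)
    ang = np.deg2rad(113.0)
    pos["_o4_dir"] = np.cos(ang) * u + np.sin(ang) * t
    return pos


def _apply_rt(params, pts):
    """Rotate (xyz Euler angles) then translate a set of points."""
    a, b, c, tx, ty, tz = params
    ca, sa, cb, sb, cc, sc = np.cos(a), np.sin(a), np.cos(b), np.sin(b), \
        np.cos(c), np.sin(c)
    rx = np.array([[1, 0, 0], [0, ca, -sa], [0, sa, ca]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz = np.array([[cc, -sc, 0], [sc, cc, 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    return pts @ rot.T + np.array([tx, ty, tz])


def _screw(pts: np.ndarray) -> np.ndarray:
    """Cellulose 2-fold screw: rotate 180 deg about z, rise one residue."""
    out = np.array(pts, copy=True, dtype=float)
    out[..., 0] *= -1.0
    out[..., 1] *= -1.0
    out[..., 2] += RISE_PER_RESIDUE
    return out


@lru_cache(maxsize=1)
def residue_template() -> dict[str, np.ndarray]:
    """21-atom glucopyranose template oriented in the chain screw frame.

    The orientation is solved (deterministically) so that the screw image of
    this residue's O4 lies one glycosidic bond along the anomeric direction of
    C1, i.e. successive residues are joined by a single, well-formed C1-O4'
    bond while the chain repeats by the 2-fold screw.
    """
    raw = _raw_residue()
    names = [n for n in raw if not n.startswith("_")]
    pts = np.array([raw[n] for n in names])
    ano = raw["_anomeric_dir"]
    o4d = raw["_o4_dir"]
    i_c1 = names.index("C1")
    i_o4 = names.index("O4")
    i_c4 = names.index("C4")

    # pairs between a residue and its screw image that are 1-2/1-3 through
    # the glycosidic bond and therefore legitimately short
    near_bond = {("C1", "O4"), ("C1", "C4"), ("C2", "O4"), ("O5", "O4"),
                 ("H1", "O4")}
    clash_mask = np.ones((len(names), len(names)), dtype=bool)
    for a, nm_a in enumerate(names):
        for b, nm_b in enumerate(names):
            if (nm_a, nm_b) in near_bond:
                clash_mask[a, b] = False

    def residuals(p):
        moved = _apply_rt(p, pts)
        # directions rotate only
        ano_r = _apply_rt(np.concatenate([p[:3], [0, 0, 0]]), ano[None])[0]
        c1 = moved[i_c1]
        o4_next = _screw(moved[i_o4])
        c4_next = _screw(moved[i_c4])
        v = o4_next - c1
        d = np.linalg.norm(v)
        r = [10.0 * (d - GLYCOSIDIC_BOND_LENGTH)]
        # the new bond should leave C1 along its vacant anomeric direction
        r.append(2.0 * (1.0 - float(np.dot(v / d, ano_r))))
        # glycosidic valence angle C1-O4'-C4' near its tetrahedral-ether value
        u1 = _unit(c1 - o4_next)
        u2 = _unit(c4_next - o4_next)
        cos_t = float(np.dot(u1, u2))
        r.append(2.0 * (cos_t - np.cos(np.deg2rad(116.0))))
        # keep the ring centred on the screw axis
        center = moved.mean(axis=0)
        r.extend(0.3 * center[:2])
        # soft repulsion between residue i and residue i+1 atoms so the fit
        # cannot trade bond geometry for interpenetrating neighbours
        nxt = _screw(moved)
        dm = np.linalg.norm(moved[:, None, :] - nxt[None, :, :], axis=-1)
        overlap = np.clip(1.9 - dm, 0.0, None)[clash_mask]
        r.extend(3.0 * overlap)
        return np.array(r)

    best = None
    for a0 in (0.0, 0.7, 1.4, 2.1, 2.8):
        for b0 in (0.0, 1.0, 2.0):
            x0 = np.array([a0, b0, 0.1, 0.0, 0.0, 0.0])
            sol = least_squares(residuals, x0=x0, xtol=1e-14, ftol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol
    sol = best
    moved = _apply_rt(sol.x, pts)
    out = {n: moved[i] for i, n in enumerate(names)}

    # sanity: glycosidic bond length within 15% of target
    d = np.linalg.norm(_screw(out["O4"]) - out["C1"])
    if not (0.85 * GLYCOSIDIC_BOND_LENGTH < d < 1.15 * GLYCOSIDIC_BOND_LENGTH):
        raise BuildFailureError(
            f"screw-frame fit failed: glycosidic distance {d:.3f} A")
    # terminal substituent directions in the screw frame
    rot_only = np.concatenate([sol.x[:3], [0, 0, 0]])
    out["_anomeric_dir"] = _apply_rt(rot_only, ano[None])[0]
    out["_o4_dir"] = _apply_rt(rot_only, o4d[None])[0]
    return out


# ---------------------------------------------------------------------------
# Chain builder
# ---------------------------------------------------------------------------

def _rotation_to(axis) -> np.ndarray:
    """Rotation matrix taking +z onto ``axis``."""
    axis = _unit(np.asarray(axis, dtype=float))
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    s = np.linalg.norm(v)
    c = float(np.dot(z, axis))
    if s < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s ** 2)


def build_extended_glucan(n_residues: int, axis=(0.0, 0.0, 1.0),
                          chain_index: int = 0) -> GlucanChain:
    """Build one extended beta-1,4-glucan of ``n_residues`` glucose units.

    The chain runs along ``axis`` from the non-reducing end (residue 0, at the
    origin end) to the reducing end, with successive residues related by the
    cellulose 2-fold screw (rise 5.19 A, 180 deg twist).  Atom count is
    21 * n_residues + 3 (a 60-mer has 1263 atoms).
    """
    if not isinstance(n_residues, (int, np.integer)) or n_residues < 1:
        raise ValueError("n_residues must be a positive integer")

    tmpl = residue_template()
    names21 = [n for n in tmpl if not n.startswith("_")]

    names, coords, roles, types, elements, resids = [], [], [], [], [], []
    for i in range(n_residues):
        for n in names21:
            p = tmpl[n]
            for _ in range(i):
                p = _screw(p)
            names.append(n)
            coords.append(p)
            resids.append(i)

    def screw_n(p, k):
        for _ in range(k):
            p = _screw(p)
        return p

    # non-reducing end: residue 0's O4 is a free hydroxyl -> HO4
    o4 = tmpl["O4"]
    ho4 = o4 + 0.98 * _unit(tmpl["_o4_dir"])
    names.append("HO4")
    coords.append(ho4)
    resids.append(0)

    # reducing end: last residue's C1 carries the anomeric O1-H
    c1_last = screw_n(tmpl["C1"], n_residues - 1)
    ano = tmpl["_anomeric_dir"] * np.array(
        [(-1.0) ** (n_residues - 1)] * 2 + [1.0])
    o1 = c1_last + _CO * _unit(ano)
    names.append("O1")
    coords.append(o1)
    resids.append(n_residues - 1)
    names.append("HO1")
    coords.append(_hydroxyl_h(o1, c1_last, np.array([0.0, 0.0, 1.0])))
    resids.append(n_residues - 1)

    coords = np.array(coords)
    rot = _rotation_to(axis)
    coords = coords @ rot.T

    elements = np.array([n[0] for n in names])
    roles = np.array([_role_of(n) for n in names])
    types = np.array([_type_of(n) for n in names])

    sys_ = System(
        coords=coords,
        elements=elements,
        names=np.array(names),
        roles=roles,
        types=types,
        chain_index=np.full(len(names), chain_index, dtype=int),
        residue_index=np.array(resids, dtype=int),
        frozen=np.zeros(len(names), dtype=bool),
    )

    bonds = _chain_bonds(sys_, n_residues)
    return GlucanChain(system=sys_, n_residues=n_residues,
                       chain_index=chain_index, bonds=bonds)


def _chain_bonds(sys_: System, n_residues: int) -> np.ndarray:
    """Bond list (local indices) for one chain from named connectivity."""
    index: dict[tuple[int, str], int] = {}
    for i, (res, name) in enumerate(zip(sys_.residue_index, sys_.names)):
        index[(int(res), str(name))] = i
    bonds = []
    for res in range(n_residues):
        for a, b in RESIDUE_BONDS:
            bonds.append((index[(res, a)], index[(res, b)]))
        if res + 1 < n_residues:  # glycosidic C1(i)-O4(i+1)
            bonds.append((index[(res, "C1")], index[(res + 1, "O4")]))
    bonds.append((index[(0, "O4")], index[(0, "HO4")]))
    last = n_residues - 1
    bonds.append((index[(last, "C1")], index[(last, "O1")]))
    bonds.append((index[(last, "O1")], index[(last, "HO1")]))
    return np.array(bonds, dtype=int)


# ---------------------------------------------------------------------------
# Topology enumeration
# ---------------------------------------------------------------------------

def build_topology(system: System, bonds: np.ndarray) -> Topology:
    """Enumerate angles, dihedrals and 1-2/1-3 exclusions from the bond graph."""
    n = system.n_atoms
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))

    angles = []
    for j in range(n):
        nb = sorted(adj[j])
        for x in range(len(nb)):
            for y in range(x + 1, len(nb)):
                angles.append((nb[x], j, nb[y]))

    dihedrals = []
    for j, k in bonds:
        j, k = int(j), int(k)
        for i in adj[j]:
            if i == k:
                continue
            for l in adj[k]:
                if l == j or l == i:
                    continue
                dihedrals.append((i, j, k, l))

    # torsion multiplicity: dihedrals sharing the same central bond
    central: dict[tuple[int, int], int] = {}
    for i, j, k, l in dihedrals:
        key = (j, k) if j < k else (k, j)
        central[key] = central.get(key, 0) + 1
    mult = np.array([central[(j, k) if j < k else (k, j)]
                     for _, j, k, _ in dihedrals], dtype=int) \
        if dihedrals else np.empty(0, dtype=int)

    excl = set()
    for i, j in bonds:
        i, j = int(i), int(j)
        excl.add((min(i, j), max(i, j)))
    for i, j, k in angles:
        excl.add((min(i, k), max(i, k)))
    keys = np.sort(np.array([np.int64(a) * n + b for a, b in excl],
                            dtype=np.int64)) if excl else np.empty(0, np.int64)

    types = system.types
    bond_types = np.array([":".join(sorted((types[i], types[j])))
                           for i, j in bonds])
    angle_types = np.array([types[j] for _, j, _ in angles]) \
        if angles else np.empty(0, dtype="U8")

    return Topology(
        n_atoms=n,
        bonds=np.asarray(bonds, dtype=int).reshape(-1, 2),
        bond_types=bond_types,
        angles=np.array(angles, dtype=int).reshape(-1, 3),
        angle_types=angle_types,
        dihedrals=np.array(dihedrals, dtype=int).reshape(-1, 4),
        dihedral_mult=mult,
        exclusion_keys=keys,
    )


# ---------------------------------------------------------------------------
# Tower and membrane
# ---------------------------------------------------------------------------

def build_tower(chains, config: TowerConfiguration | None = None):
    """Assemble six equal chains into the 'Eiffel tower' start configuration.

    Chain bases are anchored (all atoms of residue 0 frozen) at six equally
    spaced points on a circle of the configured diameter (default 4 nm, the
    footprint of one synthase-complex globule); each chain is tilted about its
    base so the chain tops converge toward the common axis.

    Returns ``(system, topology)`` with global atom indexing.
    """
    config = config or TowerConfiguration()
    chains = list(chains)
    if len(chains) != 6:
        raise ValueError(f"exactly six chains required, got {len(chains)}")
    n_res = {c.n_residues for c in chains}
    if len(n_res) != 1:
        raise ValueError("all chains must have equal length")
    n_res = n_res.pop()

    radius = config.circle_radius
    length = (n_res - 1) * RISE_PER_RESIDUE if n_res > 1 else RISE_PER_RESIDUE
    # tilt so the top lands at top_radius from the axis
    inward = max(radius - config.top_radius, 0.0)
    tilt = np.arctan2(inward, length)

    placed, all_bonds, offset = [], [], 0
    for k, chain in enumerate(chains):
        ang = 2 * np.pi * k / 6.0
        anchor = np.array([radius * np.cos(ang), radius * np.sin(ang), 0.0])
        s = chain.system.copy()
        s.chain_index[:] = k
        # tilt axis: horizontal, perpendicular to the inward direction
        inward_dir = -anchor / np.linalg.norm(anchor)
        tilt_axis = np.cross(np.array([0.0, 0.0, 1.0]), inward_dir)
        rot = _axis_angle(tilt_axis, tilt)
        base = s.coords[s.residue_index == 0].mean(axis=0)
        s.coords = (s.coords - base) @ rot.T + anchor
        s.frozen[s.residue_index == 0] = True
        placed.append(s)
        all_bonds.append(chain.bonds + offset)
        offset += s.n_atoms

    system = placed[0]
    for s in placed[1:]:
        system = concat_systems(system, s)
    bonds = np.vstack(all_bonds)

    # hard clash floor
    tree = cKDTree(system.coords)
    pairs = tree.query_pairs(r=config.min_separation, output_type="ndarray")
    if len(pairs):
        bonded = {(min(int(i), int(j)), max(int(i), int(j)))
                  for i, j in bonds}
        for i, j in pairs:
            key = (min(int(i), int(j)), max(int(i), int(j)))
            if key not in bonded:
                raise BuildFailureError(
                    f"steric clash: atoms {i} and {j} closer than "
                    f"{config.min_separation} A")

    return system, build_topology(system, bonds)


def _axis_angle(axis, angle) -> np.ndarray:
    axis = _unit(np.asarray(axis, dtype=float))
    x, y, z = axis
    c, s = np.cos(angle), np.sin(angle)
    cc = 1 - c
    return np.array([
        [c + x * x * cc, x * y * cc - z * s, x * z * cc + y * s],
        [y * x * cc + z * s, c + y * y * cc, y * z * cc - x * s],
        [z * x * cc - y * s, z * y * cc + x * s, c + z * z * cc],
    ])


POPE_SITE_RATIO = {"O": 8, "P": 1, "N": 1}
"""Hydrogen-bond-capable sites per phosphoethanolamine headgroup: four
phosphate oxygens, four ester/glycerol oxygens, one phosphorus, one amine
nitrogen."""


def build_membrane(extent_nm=(12.0, 12.0), density: float = 12.0,
                   ratio: dict[str, int] | None = None, seed: int = 0,
                   z0: float = 0.0, thickness: float = 2.0,
                   min_extent_nm: float = 0.0,
                   holes=None, hole_radius: float = 4.0) -> MembraneSurface:
    """Frozen quasi-random O/P/N site slab emulating a POPE headgroup face.

    Sites are jittered on a regular grid (seeded, deterministic), assigned
    elements at the headgroup O:P:N stoichiometry, and frozen.  ``holes``
    (list of xy points) carve site-free discs, e.g. chain extrusion ports.
    """
    ratio = dict(ratio or POPE_SITE_RATIO)
    ex, ey = (float(extent_nm[0]) * NM_TO_A, float(extent_nm[1]) * NM_TO_A)
    if ex <= 0 or ey <= 0:
        raise ValueError("membrane extent must be positive")
    if min(ex, ey) < min_extent_nm * NM_TO_A:
        raise ValueError("membrane extent smaller than required coverage")

    n_sites = int(round(ex * ey / 100.0 * density))
    rng = np.random.default_rng(seed)
    # jittered grid for quasi-random, clash-free coverage
    nx = max(int(np.ceil(np.sqrt(n_sites * ex / ey))), 1)
    ny = max(int(np.ceil(n_sites / nx)), 1)
    gx, gy = ex / nx, ey / ny
    cells = [(i, j) for i in range(nx) for j in range(ny)]
    keep = rng.permutation(len(cells))[:n_sites]
    pts = []
    for idx in keep:
        i, j = cells[idx]
        x = (i + 0.5) * gx - ex / 2 + rng.uniform(-0.3, 0.3) * gx
        y = (j + 0.5) * gy - ey / 2 + rng.uniform(-0.3, 0.3) * gy
        z = z0 + rng.uniform(-0.5, 0.5) * thickness
        pts.append((x, y, z))
    pts = np.array(pts).reshape(-1, 3)

    if holes is not None and len(pts):
        mask = np.ones(len(pts), dtype=bool)
        for h in holes:
            h = np.asarray(h, dtype=float)[:2]
            d = np.linalg.norm(pts[:, :2] - h, axis=1)
            mask &= d > hole_radius
        pts = pts[mask]

    total = sum(ratio.values())
    elems = []
    for el, w in ratio.items():
        elems.extend([el] * int(round(len(pts) * w / total)))
    while len(elems) < len(pts):
        elems.append("O")
    elems = np.array(elems[:len(pts)])
    rng.shuffle(elems)

    role = {"O": "headgroup-oxygen", "P": "headgroup-phosphorus",
            "N": "headgroup-nitrogen"}
    typ = {"O": "O_M", "P": "P_M", "N": "N_M"}
    sys_ = System(
        coords=pts,
        elements=elems,
        names=np.array([f"M{e}" for e in elems]),
        roles=np.array([role[e] for e in elems]),
        types=np.array([typ[e] for e in elems]),
        chain_index=np.full(len(pts), -1, dtype=int),
        residue_index=np.full(len(pts), -1, dtype=int),
        frozen=np.ones(len(pts), dtype=bool),
    )
    return MembraneSurface(system=sys_, extent=(ex, ey), z0=z0,
                           thickness=thickness, density=density, ratio=ratio)


def attach_membrane(system: System, topology: Topology,
                    membrane: MembraneSurface | None):
    """Merge membrane sites into a glucan system (no new bonded terms)."""
    if membrane is None or membrane.n_sites == 0:
        return system, topology
    merged = concat_systems(system, membrane.system)
    topo = build_topology(merged, topology.bonds)
    return merged, topo
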