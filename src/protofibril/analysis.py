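"""Derived observables of protofibril assembly.

Estimators operate on single frames (a :class:`~protofibril.builder.System`
with per-atom labels) or whole trajectories and quantify the observables that
characterize early protofibril formation: the hydrogen-bond inventory
(glucan-glucan and glucan-membrane H-O/H-P/H-N contacts), the pairing
partition of the six chains, the basal bend angle, the fibril cross-section,
the first-contact and stability thresholds of extrusion growth, and the
shadowing-metal correction applied to replica diameters measured in
freeze-fracture electron micrographs.

Default criteria (config-exposed):

* hydrogen bond: donor-acceptor distance <= 3.5 A and donor-H-acceptor
  angle >= 120 deg (a standard geometric criterion; results always carry the
  criterion used);
* interchain heavy-atom contact: < 4.5 A;
* a monomer counts as *interacting* if it shares >= 1 interchain H-bond or
  >= 2 heavy-atom contacts with another chain.

The basal segment of a fibril is identified by residue number (each chain's
lowest-index monomers are its base, anchored at the synthesis site), which
makes every estimator invariant under rigid motions of the frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

__all__ = [
    "HBondRecord", "PairingPartition", "AssemblyReport",
    "detect_hbonds", "pairing_partition", "bend_angle", "cross_section",
    "first_contact_monomers", "stability_threshold",
    "correct_replica_diameter", "fibril_diameter_nm",
    "interacting_monomer_run", "axis_angle_to_plane", "summarize_trajectory",
    "CENSORED",
]

HBOND_DMAX = 3.5       # A, donor-acceptor
HBOND_ANGLE_MIN = 120.0  # deg, donor-H-acceptor
CONTACT_CUT = 4.5      # A, interchain heavy-atom contact

#: sentinel for censored (no-event) outcomes
CENSORED = "censored"


@dataclass
class HBondRecord:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float
    frame: int
    cls: str               # "glucan-glucan" | "glucan-membrane:O|P|N"
    donor_chain: int = -2
    acceptor_chain: int = -2


@dataclass
class PairingPartition:
    frame: int
    clusters: list[frozenset]
    linkage: dict[tuple[int, int], int]

    def cluster_sizes(self) -> list[int]:
        return sorted((len(c) for c in self.clusters), reverse=True)


@dataclass
class AssemblyReport:
    """Machine-readable summary of one protocol run."""

    frame_range: tuple[int, int]
    criteria: dict = field(default_factory=dict)
    bend_angle_deg: float | None = None
    cross_section_A2: float | None = None
    hbond_counts: list[int] = field(default_factory=list)
    interchain_hbond_counts: list[int] = field(default_factory=list)
    membrane_hbond_counts: list[int] = field(default_factory=list)
    pairing_history: list[list[int]] = field(default_factory=list)
    first_contact_monomers: object = None
    stability_verdict: object = None
    corrected_replica_diameters_nm: list[float] = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "frame_range": list(self.frame_range),
            "criteria": self.criteria,
            "bend_angle_deg": self.bend_angle_deg,
            "cross_section_A2": self.cross_section_A2,
            "hbond_counts": self.hbond_counts,
            "interchain_hbond_counts": self.interchain_hbond_counts,
            "membrane_hbond_counts": self.membrane_hbond_counts,
            "pairing_history": self.pairing_history,
            "first_contact_monomers": self.first_contact_monomers,
            "stability_verdict": self.stability_verdict,
            "corrected_replica_diameters_nm":
                self.corrected_replica_diameters_nm,
            "extras": self.extras,
        }


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _donor_map(system) -> tuple[np.ndarray, np.ndarray]:
    """Indices of hydroxyl hydrogens and their covalently bound oxygens."""
    h_idx, o_idx = [], []
    lookup = {}
    for i in range(system.n_atoms):
        key = (int(system.chain_index[i]), int(system.residue_index[i]),
               str(system.names[i]))
        lookup[key] = i
    for i in np.where(system.roles == "hydroxyl-hydrogen")[0]:
        o_name = str(system.names[i])[1:]   # "HO6" -> "O6"
        key = (int(system.chain_index[i]), int(system.residue_index[i]), o_name)
        if key in lookup:
            h_idx.append(int(i))
            o_idx.append(lookup[key])
    return np.array(h_idx, dtype=int), np.array(o_idx, dtype=int)


def detect_hbonds(system, d_max: float = HBOND_DMAX,
                  angle_min: float = HBOND_ANGLE_MIN,
                  frame: int = 0) -> list[HBondRecord]:
    """Geometric hydrogen-bond detection on one frame.

    Donors are hydroxyl O-H groups; acceptors any O, N or P atom in a
    different residue (or a membrane site).  A bond is recorded when the
    donor-acceptor distance is at most ``d_max`` and the donor-H-acceptor
    angle at least ``angle_min`` degrees.
    """
    known_roles = {"ring-oxygen", "glycosidic-oxygen", "hydroxyl-oxygen",
                   "anomeric-oxygen", "hydroxyl-hydrogen",
                   "aliphatic-hydrogen", "carbon", "headgroup-oxygen",
                   "headgroup-phosphorus", "headgroup-nitrogen"}
    if system.n_atoms and not np.isin(system.roles,
                                      sorted(known_roles)).any():
        raise ValueError("frame lacks role labels for donor detection")
    h_idx, d_idx = _donor_map(system)
    acc_mask = np.isin(system.elements, ("O", "N", "P"))
    acc_idx = np.where(acc_mask)[0]
    if len(h_idx) == 0 or len(acc_idx) == 0:
        return []

    tree = cKDTree(system.coords[acc_idx])
    neighbors = tree.query_ball_point(system.coords[d_idx], r=d_max)
    records = []
    cos_min = np.cos(np.deg2rad(angle_min))
    for n, (hi, di) in enumerate(zip(h_idx, d_idx)):
        for a_local in neighbors[n]:
            ai = int(acc_idx[a_local])
            if ai == di:
                continue
            same_unit = (system.chain_index[ai] == system.chain_index[di]
                         and system.residue_index[ai]
                         == system.residue_index[di])
            if same_unit:
                continue
            d = float(np.linalg.norm(system.coords[ai] - system.coords[di]))
            v1 = system.coords[di] - system.coords[hi]
            v2 = system.coords[ai] - system.coords[hi]
            denom = np.linalg.norm(v1) * np.linalg.norm(v2)
            if denom == 0:
                continue
            cos_a = float(np.dot(v1, v2) / denom)
            # angle >= angle_min  <=>  cos(angle) <= cos(angle_min)
            if cos_a > cos_min + 1e-12:
                continue
            ang = float(np.degrees(np.arccos(np.clip(cos_a, -1, 1))))
            if int(system.chain_index[ai]) < 0:
                cls = f"glucan-membrane:{system.elements[ai]}"
            else:
                cls = "glucan-glucan"
            records.append(HBondRecord(
                donor=int(di), hydrogen=int(hi), acceptor=ai, distance=d,
                angle=ang, frame=frame, cls=cls,
                donor_chain=int(system.chain_index[di]),
                acceptor_chain=int(system.chain_index[ai])))
    return records


def count_hbonds(records, interchain_only=False, membrane_only=False) -> int:
    n = 0
    for r in records:
        if membrane_only:
            n += r.cls.startswith("glucan-membrane")
        elif interchain_only:
            n += (r.cls == "glucan-glucan"
                  and r.donor_chain != r.acceptor_chain)
        else:
            n += 1
    return n


# ---------------------------------------------------------------------------
# Pairing partition
# ---------------------------------------------------------------------------

def pairing_partition(system, contact_cut: float = CONTACT_CUT,
                      min_contacts: int = 2, frame: int = 0
                      ) -> PairingPartition:
    """Cluster chains by single linkage over interchain heavy-atom contacts.

    Two chains are linked when at least ``min_contacts`` distinct monomer
    pairs are in heavy-atom contact below ``contact_cut``.
    """
    glucan = system.chain_index >= 0
    heavy = glucan & system.heavy
    idx = np.where(heavy)[0]
    chains = sorted(set(system.chain_index[idx].tolist()))
    linkage: dict[tuple[int, int], int] = {}
    if len(idx):
        tree = cKDTree(system.coords[idx])
        pairs = tree.query_pairs(r=contact_cut, output_type="ndarray")
        seen: dict[tuple[int, int], set] = {}
        for a, b in pairs:
            i, j = int(idx[a]), int(idx[b])
            ci, cj = int(system.chain_index[i]), int(system.chain_index[j])
            if ci == cj:
                continue
            key = (min(ci, cj), max(ci, cj))
            mono = ((ci, int(system.residue_index[i])),
                    (cj, int(system.residue_index[j])))
            seen.setdefault(key, set()).add(mono)
        linkage = {k: len(v) for k, v in seen.items()}

    n = len(chains)
    pos = {c: i for i, c in enumerate(chains)}
    rows, cols = [], []
    for (ci, cj), cnt in linkage.items():
        if cnt >= min_contacts:
            rows.append(pos[ci])
            cols.append(pos[cj])
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    clusters = [frozenset(chains[i] for i in range(n) if labels[i] == c)
                for c in range(n_comp)]
    return PairingPartition(frame=frame, clusters=clusters, linkage=linkage)


# ---------------------------------------------------------------------------
# Geometry: bend angle, cross-section
# ---------------------------------------------------------------------------

def _principal_axis(points: np.ndarray) -> np.ndarray:
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[0]


def _monomer_split(system, base_fraction: float):
    glucan = system.chain_index >= 0
    n_res = int(system.residue_index[glucan].max()) + 1
    n_base = int(np.floor(base_fraction * n_res))
    basal = glucan & (system.residue_index < n_base)
    body = glucan & (system.residue_index >= n_base)
    return basal, body, n_base, n_res


def bend_angle(system, base_fraction: float = 0.2) -> float:
    """Basal bend of the fibril, in degrees.

    The basal segment of each chain is its lowest ``base_fraction`` of
    monomers (by residue number, counted from the anchored base; the base of
    an assembling protofibril is radially splayed, so the basal axis is a
    per-chain quantity).  The estimator returns the mean over chains of the
    angle between the chain's basal principal axis and the principal axis of
    the fibril body (all chains' remaining monomers).  It is 0 for a
    perfectly straight fibril and recovers a rigid kink exactly.

    Requires at least 3 monomers in each segment.
    """
    if not 0 < base_fraction <= 0.5:
        raise ValueError("base_fraction must lie in (0, 0.5]")
    basal, body, n_base, n_res = _monomer_split(system, base_fraction)
    if n_base < 3 or n_res - n_base < 3:
        raise ValueError("fewer than 3 monomers per segment")
    pt = system.coords[body & system.heavy]
    if len(pt) < 3:
        raise ValueError("insufficient atoms in the body segment")
    v = _principal_axis(pt)
    glucan = system.chain_index >= 0
    angles = []
    for c in sorted(set(system.chain_index[glucan].tolist())):
        sel = basal & system.heavy & (system.chain_index == c)
        pb = system.coords[sel]
        if len(pb) < 3:
            raise ValueError("insufficient atoms in a basal segment")
        u = _principal_axis(pb)
        cos = abs(float(np.dot(u, v)))
        angles.append(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))
    return float(np.mean(angles))


def cross_section(system, base_fraction: float = 0.2, slab_width: float = 5.0,
                  inflation: float = 1.5) -> float:
    """Mean cross-sectional area (A^2) of the fibril body.

    Heavy atoms of the body (basal ``base_fraction`` excluded) are projected
    onto the plane perpendicular to the body principal axis in axial slabs of
    ``slab_width``; each slab contributes the area of the convex hull of its
    projected points inflated by a per-atom radius; empty or degenerate slabs
    are skipped.
    """
    _, body, _, _ = _monomer_split(system, base_fraction)
    pts = system.coords[body & system.heavy]
    if len(pts) < 4:
        raise ValueError("too few heavy atoms for a cross-section")
    axis = _principal_axis(pts)
    center = pts.mean(axis=0)
    rel = pts - center
    t = rel @ axis
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    proj = np.column_stack([rel @ e1, rel @ e2])

    edges = np.arange(t.min(), t.max() + slab_width, slab_width)
    areas = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (t >= lo) & (t < hi)
        if sel.sum() < 3:
            warnings.warn(f"axial slab [{lo:.1f}, {hi:.1f}) has fewer than "
                          "3 atoms; skipped", stacklevel=2)
            continue
        hull = MultiPoint(proj[sel]).convex_hull.buffer(inflation)
        areas.append(hull.area)
    if not areas:
        raise ValueError("no slab had enough atoms")
    return float(np.mean(areas))


def axis_angle_to_plane(system, base_fraction: float = 0.2,
                        normal=(0.0, 0.0, 1.0)) -> float:
    """Angle (deg) between the fibril body axis and a plane (default z=0)."""
    _, body, _, _ = _monomer_split(system, base_fraction)
    pts = system.coords[body & system.heavy]
    axis = _principal_axis(pts)
    normal = np.asarray(normal, float)
    normal = normal / np.linalg.norm(normal)
    sin = abs(float(np.dot(axis, normal)))
    return float(np.degrees(np.arcsin(np.clip(sin, -1.0, 1.0))))


# ---------------------------------------------------------------------------
# Growth thresholds
# ---------------------------------------------------------------------------

def _has_interchain_contact(system, contact_cut, only_free=True) -> bool:
    mask = (system.chain_index >= 0) & system.heavy
    if only_free:
        mask &= ~system.frozen
    idx = np.where(mask)[0]
    if len(idx) < 2:
        return False
    tree = cKDTree(system.coords[idx])
    for a, b in tree.query_pairs(r=contact_cut):
        if system.chain_index[idx[a]] != system.chain_index[idx[b]]:
            return True
    return False


def first_contact_monomers(trajectory, contact_cut: float = CONTACT_CUT):
    """Free-monomer count at the first frame with an interchain contact.

    Frames must carry a ``free_monomers`` annotation (growth-cycle
    bookkeeping).  Returns :data:`CENSORED` when no contact ever occurs.
    """
    for i, frame in enumerate(trajectory.frames):
        if "free_monomers" not in frame.annotations:
            raise ValueError("trajectory lacks growth-cycle annotations")
        s = trajectory.frame_system(i)
        s.frozen = frame.annotations.get("frozen_mask", s.frozen)
        if _has_interchain_contact(s, contact_cut):
            return int(frame.annotations["free_monomers"])
    return CENSORED


def stability_threshold(profile: dict[int, tuple[int, int]]):
    """Smallest interacting-monomer count whose runs are majority-stable.

    ``profile`` maps a monomer count m to ``(n_stable, n_total)`` over
    replicate runs.  The threshold is the smallest m such that every tested
    m' >= m is majority-stable; :data:`CENSORED` when no such m exists.
    """
    ms = sorted(profile)
    if not ms:
        raise ValueError("empty stability profile")

    def majority(m):
        s, tot = profile[m]
        return s > tot / 2.0

    threshold = None
    for m in reversed(ms):
        if majority(m):
            threshold = m
        else:
            break
    return CENSORED if threshold is None else int(threshold)


def interacting_monomer_run(system, hbonds=None,
                            contact_cut: float = CONTACT_CUT,
                            min_contacts: int = 2) -> int:
    """Longest consecutive run of interacting monomers over all chains.

    A monomer interacts when it shares at least one interchain H-bond or at
    least ``min_contacts`` interchain heavy-atom contacts.
    """
    if hbonds is None:
        hbonds = detect_hbonds(system)
    glucan = system.chain_index >= 0
    chains = sorted(set(system.chain_index[glucan].tolist()))
    n_res = int(system.residue_index[glucan].max()) + 1
    interacting = {c: np.zeros(n_res, dtype=bool) for c in chains}

    for r in hbonds:
        if r.cls == "glucan-glucan" and r.donor_chain != r.acceptor_chain:
            interacting[r.donor_chain][
                system.residue_index[r.donor]] = True
            interacting[r.acceptor_chain][
                system.residue_index[r.acceptor]] = True

    heavy = glucan & system.heavy
    idx = np.where(heavy)[0]
    counts: dict[tuple[int, int], int] = {}
    tree = cKDTree(system.coords[idx])
    for a, b in tree.query_pairs(r=contact_cut):
        i, j = int(idx[a]), int(idx[b])
        ci, cj = int(system.chain_index[i]), int(system.chain_index[j])
        if ci == cj:
            continue
        for c, res in ((ci, int(system.residue_index[i])),
                       (cj, int(system.residue_index[j]))):
            counts[(c, res)] = counts.get((c, res), 0) + 1
    for (c, res), n in counts.items():
        if n >= min_contacts:
            interacting[c][res] = True

    best = 0
    for c in chains:
        run = cur = 0
        for flag in interacting[c]:
            cur = cur + 1 if flag else 0
            run = max(run, cur)
        best = max(best, run)
    return best


# ---------------------------------------------------------------------------
# Worked-example arithmetic
# ---------------------------------------------------------------------------

def correct_replica_diameter(measured_nm: float,
                             metal_thickness_nm: float = 0.75) -> float:
    """Subtract twice the shadowing-metal thickness from a replica diameter."""
    correction = 2.0 * metal_thickness_nm
    if measured_nm <= correction:
        raise ValueError(
            f"measured diameter {measured_nm} nm not above the "
            f"{correction} nm metal correction")
    return measured_nm - correction


def fibril_diameter_nm(cross_section_A2: float, n_protofibrils: int = 6
                       ) -> float:
    """Diameter (nm) of a fibril built from ``n_protofibrils`` protofibrils.

    The combined cross-section is ``n * A`` and the diameter that of the
    equivalent circle: six 205 A^2 protofibrils give 1230 A^2, a 4 nm fibril.
    """
    area = n_protofibrils * cross_section_A2
    return 2.0 * np.sqrt(area / np.pi) / 10.0


# ---------------------------------------------------------------------------
# Trajectory summary
# ---------------------------------------------------------------------------

def summarize_trajectory(trajectory, base_fraction: float = 0.2,
                         hbond_dmax: float = HBOND_DMAX,
                         hbond_angle: float = HBOND_ANGLE_MIN,
                         contact_cut: float = CONTACT_CUT,
                         stride: int = 1,
                         final_frame_only_geometry: bool = True
                         ) -> AssemblyReport:
    """Assemble the standard AssemblyReport for a finished run."""
    n = len(trajectory.frames)
    report = AssemblyReport(
        frame_range=(0, n - 1),
        criteria={"hbond_dmax_A": hbond_dmax,
                  "hbond_angle_min_deg": hbond_angle,
                  "contact_cut_A": contact_cut,
                  "base_fraction": base_fraction})
    for i in range(0, n, stride):
        s = trajectory.frame_system(i)
        hb = detect_hbonds(s, hbond_dmax, hbond_angle, frame=i)
        report.hbond_counts.append(len(hb))
        report.interchain_hbond_counts.append(
            count_hbonds(hb, interchain_only=True))
        report.membrane_hbond_counts.append(
            count_hbonds(hb, membrane_only=True))
        part = pairing_partition(s, contact_cut, frame=i)
        report.pairing_history.append(part.cluster_sizes())
    final = trajectory.frame_system(n - 1)
    try:
        report.bend_angle_deg = bend_angle(final, base_fraction)
    except ValueError:
        report.bend_angle_deg = None
    try:
        report.cross_section_A2 = cross_section(final, base_fraction)
    except ValueError:
        report.cross_section_A2 = None
    return report
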