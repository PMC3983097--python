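"""Synthetic ground-truth systems for testing every analysis stage.

Fixtures reuse the chain builder's chemistry (so they are valid force-field
inputs, not bare point clouds) but encode exact geometric ground truth:
straight or kinked rigid fibrils of prescribed angle, pre-paired chain
dimers, annotated growth traces with a known first-contact cycle, and toy
two-atom systems for integrator and force oracles.  They encode geometry
only, with no claim of thermodynamic realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import (System, Topology, _axis_angle, build_extended_glucan,
                      build_topology, concat_systems)
from .dynamics import Frame, Trajectory
from .forcefield import EnergyDecomposition

__all__ = [
    "FixtureSpec", "make_straight_fibril", "make_kinked_fibril",
    "make_paired_dimers", "make_growth_trace", "make_stability_profile",
    "toy_diatomic", "toy_oscillator",
]

FIXTURE_KINDS = ("straight_fibril", "kinked_fibril", "paired_dimers",
                 "toy_diatomic", "toy_oscillator", "growth_trace",
                 "stability_profile")


@dataclass
class FixtureSpec:
    kind: str
    kink_deg: float = 0.0
    spacing: float = 6.0
    n_chains: int = 6
    n_residues: int = 12
    base_fraction: float = 0.2
    contact_cycle: object = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}")

    def build(self):
        if self.kind == "straight_fibril":
            return make_straight_fibril(self.n_chains, self.n_residues,
                                        self.spacing)
        if self.kind == "kinked_fibril":
            return make_kinked_fibril(self.n_chains, self.n_residues,
                                      self.kink_deg, self.base_fraction)
        if self.kind == "paired_dimers":
            return make_paired_dimers(self.spacing,
                                      n_residues=self.n_residues)
        if self.kind == "toy_diatomic":
            return toy_diatomic()[0]
        if self.kind == "toy_oscillator":
            return toy_oscillator()[0]
        if self.kind == "growth_trace":
            return make_growth_trace(self.contact_cycle)
        raise ValueError(f"{self.kind} has no frame representation")


def make_straight_fibril(n_chains: int = 6, n_residues: int = 12,
                         spacing: float = 6.0, packing: str = "ring"
                         ) -> System:
    """Parallel extended chains at the given spacing.

    ``packing="ring"`` places chains on a circle (the radial motif of an
    assembling protofibril); ``packing="lattice"`` packs them in staggered
    close-packed rows like a crystalline sheet pair.
    """
    if packing == "ring":
        if n_chains == 1:
            ring_r = 0.0
        else:
            ring_r = spacing / (2 * np.sin(np.pi / n_chains))
        offsets = [(ring_r * np.cos(2 * np.pi * k / max(n_chains, 1)),
                    ring_r * np.sin(2 * np.pi * k / max(n_chains, 1)))
                   for k in range(n_chains)]
    elif packing == "lattice":
        row_sep = spacing * np.sqrt(3) / 2
        offsets = []
        for k in range(n_chains):
            row, col = divmod(k, (n_chains + 1) // 2)
            offsets.append((col * spacing + 0.5 * spacing * row,
                            row * row_sep))
    else:
        raise ValueError("packing must be 'ring' or 'lattice'")
    systems = []
    for k in range(n_chains):
        ch = build_extended_glucan(n_residues, chain_index=k)
        s = ch.system
        s.coords = s.coords + np.array([offsets[k][0], offsets[k][1], 0.0])
        systems.append(s)
    out = systems[0]
    for s in systems[1:]:
        out = concat_systems(out, s)
    return out


def make_kinked_fibril(n_chains: int = 6, n_residues: int = 15,
                       kink_deg: float = 30.0,
                       base_fraction: float = 0.2) -> System:
    """Rigid fibril with an exact kink at the base-fraction boundary.

    The basal monomers (residue index below ``floor(base_fraction * n)``)
    are rotated as a rigid block by ``kink_deg`` about a horizontal axis
    through the boundary plane, so the angle between basal and body principal
    axes equals ``kink_deg`` by construction.
    """
    if not 0 <= kink_deg < 90:
        raise ValueError("kink angle must lie in [0, 90) degrees")
    s = make_straight_fibril(n_chains, n_residues)
    n_base = int(np.floor(base_fraction * n_residues))
    if kink_deg == 0 or n_base < 1:
        return s
    basal = s.residue_index < n_base
    pivot = s.coords[basal].mean(axis=0)
    rot = _axis_angle([1.0, 0.0, 0.0], np.deg2rad(kink_deg))
    s.coords[basal] = (s.coords[basal] - pivot) @ rot.T + pivot
    return s


def make_paired_dimers(intra_spacing: float = 4.0,
                       inter_spacing: float = 40.0,
                       n_residues: int = 6) -> System:
    """Three chain pairs: intra-pair contact, inter-pair far separation."""
    if intra_spacing <= 0:
        raise ValueError("spacing must be positive")
    systems = []
    for pair in range(3):
        cx = pair * inter_spacing
        for sub in range(2):
            k = 2 * pair + sub
            ch = build_extended_glucan(n_residues, chain_index=k)
            s = ch.system
            s.coords = s.coords + np.array(
                [cx + sub * intra_spacing, 0.0, 0.0])
            systems.append(s)
    out = systems[0]
    for s in systems[1:]:
        out = concat_systems(out, s)
    return out


def make_growth_trace(contact_cycle, n_cycles: int = 12, n_chains: int = 6,
                      lateral: float = 40.0) -> Trajectory:
    """Annotated synthetic growth trajectory with a known contact cycle.

    Chains are single-carbon-per-monomer stalks 5 A apart axially; at cycle
    ``contact_cycle`` (1-based) two chains are brought into heavy-atom
    contact.  ``contact_cycle=None`` yields a censored (no-contact) trace.
    """
    if contact_cycle is not None and contact_cycle < 1:
        raise ValueError("contact_cycle must be >= 1 or None")
    frames = []
    n_atoms = n_chains * n_cycles
    elements = np.array(["C"] * n_atoms)
    chain_idx = np.repeat(np.arange(n_chains), n_cycles)
    resid = np.tile(np.arange(n_cycles), n_chains)
    sys0 = System(
        coords=np.zeros((n_atoms, 3)),
        elements=elements,
        names=np.array(["C1"] * n_atoms),
        roles=np.array(["carbon"] * n_atoms),
        types=np.array(["C_3"] * n_atoms),
        chain_index=chain_idx,
        residue_index=resid,
        frozen=np.ones(n_atoms, dtype=bool),
    )
    for cycle in range(1, n_cycles + 1):
        coords = np.zeros((n_atoms, 3))
        frozen = np.ones(n_atoms, dtype=bool)
        for c in range(n_chains):
            ang = 2 * np.pi * c / n_chains
            x0 = lateral * np.cos(ang)
            y0 = lateral * np.sin(ang)
            for r in range(n_cycles):
                i = c * n_cycles + r
                above = r >= n_cycles - cycle
                z = 5.0 * (r - (n_cycles - cycle))
                coords[i] = [x0, y0, z]
                frozen[i] = not above
        if contact_cycle is not None and cycle >= contact_cycle:
            # bring the top monomers of chains 0 and 1 into contact
            i0 = 0 * n_cycles + (n_cycles - 1)
            i1 = 1 * n_cycles + (n_cycles - 1)
            mid = 0.5 * (coords[i0] + coords[i1])
            coords[i0] = mid + [1.5, 0, 0]
            coords[i1] = mid - [1.5, 0, 0]
        frames.append(Frame(
            time=float(cycle), coords=coords,
            energy=EnergyDecomposition(), temperature=0.0, kinetic=0.0,
            conserved=0.0,
            annotations={"free_monomers": cycle, "frozen_mask": frozen}))
    return Trajectory(system=sys0, frames=frames)


def make_stability_profile(spec: dict[int, tuple[int, int]]
                           ) -> dict[int, tuple[int, int]]:
    """Validate and return a constructed stability profile."""
    for m, (s, tot) in spec.items():
        if not (0 <= s <= tot):
            raise ValueError(f"bad profile entry {m}: {s}/{tot}")
    return dict(spec)


def toy_diatomic(elements=("C", "C"), r: float = 1.60
                 ) -> tuple[System, Topology]:
    """Two bonded free atoms, the NVE-conservation and period oracle system."""
    s = System(
        coords=np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]]),
        elements=np.array(elements),
        names=np.array(["C1", "C2"]),
        roles=np.array(["carbon", "carbon"]),
        types=np.array(["C_3", "C_3"]),
        chain_index=np.array([0, 0]),
        residue_index=np.array([0, 0]),
        frozen=np.zeros(2, dtype=bool),
    )
    topo = build_topology(s, np.array([[0, 1]]))
    return s, topo


def toy_oscillator(r: float = 1.60) -> tuple[System, Topology]:
    """Diatomic with one atom frozen: a one-body harmonic oscillator."""
    s, topo = toy_diatomic(r=r)
    s.frozen[0] = True
    return s, topo
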