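"""Readers and writers: PDB/XYZ coordinates, CSV scalar logs, YAML configs.

Glucan atoms are written as ATOM records (one chain ID per glucan chain,
residue name GLC); membrane sites as HETATM records (chain M, residue MEM).
Trajectories become multi-model PDB or concatenated XYZ frames.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import yaml

from .builder import System

__all__ = [
    "write_pdb", "write_xyz", "read_xyz", "read_pdb",
    "write_trajectory_pdb", "write_trajectory_xyz", "write_scalars_csv",
    "load_config", "save_config", "write_report",
]


def _chain_letter(idx: int) -> str:
    return "M" if idx < 0 else chr(ord("A") + (idx % 26))


def _pdb_atom_lines(system: System, serial_start: int = 1) -> list[str]:
    lines = []
    serial = serial_start
    for i in range(system.n_atoms):
        hetatm = system.chain_index[i] < 0
        record = "HETATM" if hetatm else "ATOM  "
        resname = "MEM" if hetatm else "GLC"
        resseq = (1 if hetatm else int(system.residue_index[i]) + 1) % 10000
        name = str(system.names[i])[:4]
        x, y, z = system.coords[i]
        lines.append(
            f"{record}{serial % 100000:5d} {name:<4s}{resname:>4s} "
            f"{_chain_letter(int(system.chain_index[i]))}{resseq:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{str(system.elements[i]):>2s}")
        serial += 1
    return lines


def write_pdb(system: System, path) -> None:
    lines = _pdb_atom_lines(system) + ["END"]
    Path(path).write_text("\n".join(lines) + "\n")


def write_trajectory_pdb(trajectory, path) -> None:
    lines = []
    for m, frame in enumerate(trajectory.frames, start=1):
        s = trajectory.system.copy()
        s.coords = frame.coords
        lines.append(f"MODEL     {m:4d}")
        lines.extend(_pdb_atom_lines(s))
        lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(system: System, path, comment: str = "", append: bool = False):
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write(f"{system.n_atoms}\n{comment}\n")
        for el, (x, y, z) in zip(system.elements, system.coords):
            fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def write_trajectory_xyz(trajectory, path) -> None:
    s = trajectory.system
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"{s.n_atoms}\nt= {frame.time} fs\n")
            for el, (x, y, z) in zip(s.elements, frame.coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path):
    """Read one or more XYZ frames; returns (elements, list of coord arrays)."""
    text = Path(path).read_text().splitlines()
    frames, elements = [], None
    i = 0
    while i < len(text):
        if not text[i].strip():
            i += 1
            continue
        n = int(text[i].strip())
        block = text[i + 2:i + 2 + n]
        els, xyz = [], []
        for line in block:
            parts = line.split()
            els.append(parts[0])
            xyz.append([float(p) for p in parts[1:4]])
        elements = np.array(els)
        frames.append(np.array(xyz))
        i += 2 + n
    return elements, frames


def read_pdb(path) -> System:
    """Parse one model of a package-written PDB back into a System."""
    coords, elements, names, chains, resids = [], [], [], [], []
    for line in Path(path).read_text().splitlines():
        if line.startswith(("ATOM", "HETATM")):
            names.append(line[12:16].strip())
            ch = line[21]
            chains.append(-1 if ch == "M" else ord(ch) - ord("A"))
            resids.append(int(line[22:26]) - 1)
            coords.append([float(line[30:38]), float(line[38:46]),
                           float(line[46:54])])
            elements.append(line[76:78].strip() or line[12:16].strip()[0])
        elif line.startswith("ENDMDL"):
            break
    from .builder import _role_of, _type_of
    roles, types = [], []
    for nm, el, ch in zip(names, elements, chains):
        if ch < 0:
            roles.append({"O": "headgroup-oxygen", "P": "headgroup-phosphorus",
                          "N": "headgroup-nitrogen"}[el])
            types.append({"O": "O_M", "P": "P_M", "N": "N_M"}[el])
        else:
            roles.append(_role_of(nm))
            types.append(_type_of(nm))
    chains = np.array(chains)
    return System(
        coords=np.array(coords),
        elements=np.array(elements),
        names=np.array(names),
        roles=np.array(roles),
        types=np.array(types),
        chain_index=chains,
        residue_index=np.array(resids),
        frozen=chains < 0,
    )


def write_scalars_csv(trajectory, path) -> None:
    trajectory.scalars().to_csv(path, index=False)


def load_config(path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}


def save_config(cfg: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def write_report(report, path) -> None:
    """Serialize an AssemblyReport (or any dataclass/dict) as JSON."""
    if hasattr(report, "as_dict"):
        report = report.as_dict()

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(type(o))

    Path(path).write_text(json.dumps(report, indent=2, default=default))
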