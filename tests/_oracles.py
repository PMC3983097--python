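"""Independent brute-force oracles shared across test modules."""

import numpy as np


def brute_force_hbonds(system, d_max=3.5, angle_min=120.0):
    """O(N^2) hydrogen-bond scan; returns (donor, hydrogen, acceptor) keys."""
    from protofibril.analysis import _donor_map
    h_idx, d_idx = _donor_map(system)
    out = []
    for hi, di in zip(h_idx, d_idx):
        for ai in range(system.n_atoms):
            if system.elements[ai] not in ("O", "N", "P") or ai == di:
                continue
            if (system.chain_index[ai] == system.chain_index[di]
                    and system.residue_index[ai] == system.residue_index[di]):
                continue
            d = np.linalg.norm(system.coords[ai] - system.coords[di])
            if d > d_max:
                continue
            v1 = system.coords[di] - system.coords[hi]
            v2 = system.coords[ai] - system.coords[hi]
            cos = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
            if ang >= angle_min:
                out.append((int(di), int(hi), int(ai)))
    return out
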