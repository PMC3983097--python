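# Generic Dreiding-style force-field constants (Mayo, Olafson & Goddard,
# J. Phys. Chem. 94 (1990) 8897): harmonic bonds/angles by hybridization,
# threefold sp3 torsions, 12-6 van der Waals by element.  Energies kcal/mol,
# lengths A, angles deg.  Hydrogen bonds are represented as deepened 12-6
# wells on hydroxyl-hydrogen / acceptor pairs (H-O, H-P, H-N).
version: 1

# bond r0 = R_i + R_j - 0.01 A;  U_b = bond_k * (r - r0)^2
bond_k: 350.0
covalent_radii:
  C_3: 0.77
  O_3: 0.66
  H_: 0.33
  H_HB: 0.33

# U_v = k * (theta - theta0)^2, keyed by the central atom type
angle:
  C_3: {k: 50.0, theta0_deg: 109.471}
  O_3: {k: 50.0, theta0_deg: 104.51}

# threefold sp3 torsion: U_d = 0.5 * A3 * (1 + cos 3*theta); the barrier is
# shared equally among the dihedrals crossing one central bond
torsion:
  barrier: 2.0

# 12-6 pairs: U = A/r^12 - C/r^6 with A = d0*r0^12, C = 2*d0*r0^6
# (well of depth d0 at r0); O_M/P_M/N_M are frozen membrane headgroup sites
vdw:
  C_3:  {r0: 3.8983, d0: 0.0951}
  O_3:  {r0: 3.4046, d0: 0.0957}
  H_:   {r0: 3.1950, d0: 0.0152}
  H_HB: {r0: 3.1950, d0: 0.0152}
  O_M:  {r0: 3.4046, d0: 0.0957}
  P_M:  {r0: 4.1500, d0: 0.3200}
  N_M:  {r0: 3.6621, d0: 0.0774}

# deepened wells for donor-hydrogen / acceptor pairs, replacing the combined
# 12-6 entry: depth is the H-bond strength (kcal/mol, the same for O, P and N
# acceptors, whose well depths are comparable), rstar the H...acceptor
# minimum position consistent with a ~2.8 A donor-acceptor distance
hbond:
  donor_hydrogen: H_HB
  depth: 4.0
  acceptors:
    O_3: {rstar: 1.90}
    O_M: {rstar: 1.90}
    P_M: {rstar: 2.40}
    N_M: {rstar: 2.10}

nonbonded:
  cutoff: 10.0
  skin: 2.0
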