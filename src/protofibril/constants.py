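"""Physical constants and unit conventions.

Internal units throughout the package: length in angstrom (A), time in
femtoseconds (fs), energy in kcal/mol, mass in atomic mass units (amu),
temperature in kelvin.  Lengths given in nm at configuration boundaries are
converted on entry.
"""

# Boltzmann constant, kcal/mol/K
KB = 0.0019872041

# Converts force [kcal/mol/A] divided by mass [amu] into acceleration [A/fs^2]:
#   1 kcal/mol/A / 1 amu = 4.184e-4 A/fs^2
ACC = 4.184e-4

ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
}

NM_TO_A = 10.0
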