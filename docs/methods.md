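# Methods

## The model

Six β-1,4-glucan chains are represented at all-atom resolution with explicit
hydrogens.  One glucopyranose residue carries 21 atoms; the non-reducing
terminus adds a 4-OH hydrogen and the reducing terminus an anomeric O1–H, so
an n-mer has 21n + 3 atoms (1263 for the 60-mer used at full scale; six
chains total 7578 atoms).  Residue geometry is an idealized ⁴C₁ chair with
all heavy substituents equatorial — the β-D-glucopyranose substitution
pattern — and successive residues are related by the cellulose 2-fold screw
(180° twist, 5.19 Å rise, half the 10.38 Å fibre repeat), so the extended
chain rises ≈ 5 Å per glucose, matching the equivalence of one extruded
monomer with 5 Å of chain.  The screw-frame orientation of the template
residue is solved once, deterministically, so that consecutive residues are
joined by a single well-formed C1–O4′ glycosidic bond (1.42 Å, ether valence
angle ≈ 116°) with no steric overlap between neighbours.

The potential has exactly four terms — harmonic bonds and valence angles, a
three-cosine dihedral, and a 12-6 pair term — and no electrostatics.
Parameters are generic Dreiding constants (bond k = 350 kcal/mol/Å² in the
U = k(r−r₀)² convention, r₀ from covalent radii; angle k = 50 kcal/mol/rad²
with sp³ and ether equilibrium angles; one 2 kcal/mol threefold barrier per
sp³ central bond, shared among the dihedrals crossing it; element-wise 12-6
wells) stored in `src/protofibril/data/dreiding.yaml`.  Cross pairs combine
with a geometric mean on well depth and an arithmetic mean on r*.

**Hydrogen bonds** are folded into the 12-6 form: every
hydroxyl-hydrogen/acceptor pair (H–O, H–P, H–N) is replaced by a deepened
well of 4.0 kcal/mol — the scale of a hydroxyl hydrogen bond, and equal for
O, P and N acceptors, whose well depths are comparable — positioned at
H···acceptor hydrogen-bond geometry (r* = 1.9/2.4/2.1 Å for O/P/N,
consistent with a ~2.8 Å donor–acceptor distance).  A multiplicative
"4–5 × plain vdW" prescription was rejected: the plain Dreiding H···O well
is 0.038 kcal/mol, so any small multiple of it lies far below k_BT and
cannot drive assembly at 298 K, and the combined r* (3.3 Å for H···O) puts
the minimum outside hydrogen-bond geometry altogether.  The depth remains
config-exposed (`load_tables(hbond_depth=...)`).

Nonbonded interactions exclude 1-2 and 1-3 pairs (1-4 kept at full
strength), are truncated at 10 Å with an energy shift to zero at the cutoff,
and use a Verlet pair list with a 2 Å skin rebuilt when any mobile atom has
moved more than half the skin.  Pairs in which both atoms are permanently
frozen (membrane–membrane, anchor–membrane) contribute a constant and are
excluded by construction.  Any nonbonded approach below 0.1 Å raises an
overlapping-atoms error.

## Dynamics

Velocity-Verlet integration at dt = 1 fs (required by the explicit C–H
vibrations) with a single Nosé–Hoover friction variable, applied as the
standard Trotter-factorized half-step (quarter-step ξ update, half-step
velocity rescale, quarter-step ξ update) around the Verlet core; this
conserves the extended Hamiltonian to ≈ 5 × 10⁻⁴ relative over 10⁵ steps on
a cellobiose test system, versus a few 10⁻³ for the textbook explicit
coupling.  The thermostat relaxation time defaults to 100 fs; initial
velocities are Maxwell–Boltzmann at the target temperature from a seeded
generator, and every protocol is bitwise reproducible from (config, seed) on
one platform.  Frozen atoms (chain anchors, membrane sites) keep their exact
coordinates and zero velocity; kinetic temperature and thermostat mass are
defined over mobile degrees of freedom only.  A step that moves any mobile
atom more than 1 Å raises a blow-up error naming the first offending atom —
velocity-based guards are unreliable because the thermostat's exponential
rescale can annihilate runaway velocities after positions have already
diverged.

Restraints are harmonic; protocol pulls use *centroid* restraints (force
distributed equally over the attached heavy atoms) because a point-target
restraint over a whole residue crushes it and destabilizes integration.
The "impenetrable wall" is a one-sided quadratic U = k_w(z−z_w)² acting only
on atoms above the plane; k_w = 10 kcal/mol/Å² makes thermal penetration
~0.25 Å (impenetrable in practice) while remaining integrable at 1 fs.
Internally the membrane plane is z = 0 and the wall descends from +z; a
published depiction of the same experiment directs the z-axis downward from
the wall plane, i.e. our convention is sign-flipped relative to that figure.

## Membrane

The external face of a phosphoethanolamine (POPE) monolayer enters only
through the species that hydrogen-bond to glucan: O, P and N sites at
headgroup stoichiometry (8:1:1 — four phosphate plus four ester oxygens, one
phosphorus, one amine nitrogen per lipid) placed by a seeded jittered grid
at 12 sites/nm² in a 2 Å slab, all frozen.  The slab centre sits 3 Å below
the anchor plane so that sites are immediately below the fibril base while
mobile basal atoms start ≈ 2 Å clear of the steep 12-6 repulsion.  There are
no periodic boundaries: the system is an open cluster on a finite slab with
enough lateral margin that chains cannot escape it.

## Protocols

* **Preassembly**: all atoms of each chain's base residue are frozen on a
  4 nm circle (six equally spaced anchors); chains are tilted so their tops
  start 8 Å from the common axis; centroid springs (20 kcal/mol/Å² total per
  chain) draw the top residues inward in 0.5 nm stages with 800 relaxation
  steps per stage.  The spring acts by force — atoms are never teleported.
* **Relaxation**: unrestrained NVT (anchors stay frozen).  Desk-scale
  standard: 10–25 ps.
* **Membrane assembly**: identical, with the membrane's nonbonded terms
  added; with a null or empty membrane the trajectory is bit-identical to
  plain relaxation at the same seed.
* **Extrusion growth**: chains start with one free monomer above the
  membrane (the rest frozen below, the membrane perforated at the six exit
  ports); each cycle translates the chains up 5 Å (one glucose), releases
  the next monomer with fresh thermal velocities, and advances an inward
  centroid restraint on the first-produced monomers by 0.5 nm per two
  cycles — a rate chosen so the pulled segment's tilt stays within what
  chain stiffness allows (0.5 nm lateral per 1 nm of new chain, ≈ 30°).
  Frames carry free-monomer annotations; exhausting the schedule without
  contact is a censored outcome, not an error.
* **Wall bending**: the wall descends in 2 Å stages with relaxation holds
  onto an organized fibril; chain integrity is checked each stage (no bond
  may stretch past 1.5 × its rest length).

## Estimators

* **H-bond**: donor–acceptor ≤ 3.5 Å and donor–H–acceptor ≥ 120°
  (config-exposed); donors are hydroxyl O–H groups, acceptors any O/N/P in a
  different residue; classified glucan–glucan vs glucan–membrane:O/P/N.
* **Pairing partition**: single-linkage over chains, linking two chains when
  ≥ 2 distinct monomer pairs are in heavy-atom contact < 4.5 Å.
* **Bend angle**: mean over chains of the angle between each chain's basal
  principal axis (lowest `base_fraction` of monomers, by residue number
  from the anchored base) and the principal axis of the fibril body.  The
  base of an assembling protofibril is radially splayed, so the basal axis
  is per-chain; identifying basal monomers by residue number rather than by
  height makes every estimator rigid-motion invariant.  Requires ≥ 3
  monomers per segment, hence the 15-mer desk-scale standard for
  base_fraction 0.2 (12-mers use 0.25).  Recovers constructed 5–60° kinks
  within 1°.
* **Cross-section**: slab-averaged (5 Å slabs) convex-hull area of body
  heavy atoms projected perpendicular to the body axis, inflated by a 1.5 Å
  per-atom radius, basal 20% excluded.  Exactly homogeneous of degree 2
  under similarity transforms that scale the inflation radius with the
  coordinates.
* **Interacting monomers**: a monomer interacts when it shares ≥ 1
  interchain H-bond or ≥ 2 interchain heavy-atom contacts; the protofibril
  counts as *stable* when a ≥ 5-chain cluster is present in a majority of
  the final half of the run.
* **Replica-diameter correction**: measured diameter minus twice the
  shadowing-metal thickness (default 0.75 nm).
* Worked-example arithmetic: a fibril of six protofibrils has six times the
  cross-section and the equivalent-circle diameter (6 × 205 Å² = 1230 Å² →
  4.0 nm).

## Desk-scale standards and what they show

Full-scale runs (60-mers, 3–9 ns) are supported through configuration but
are hours-long; the shipped tests and the acceptance script use the largest
sizes that keep the whole suite tractable on one CPU: six 15-mers with 20 ps
of relaxation (five seeded replicates) for the bend-angle observables, six
12-mers with 10 ps (ten replicates) for the emergence properties, 12-mer
extrusion growth, and m-mer bundles (m = 3…8) for the stability experiment.

At this scale the qualitative phenomenology reproduces: top-down zipping by
interchain hydrogen bonds, two-by-two pairing before larger clusters,
H-O/H-P/H-N membrane contacts, a nonzero basal bend that the membrane
reduces, wall-driven bending to near-horizontal with intact connectivity.
Three quantitative observables do **not** converge within picosecond runs
and are reported as such rather than tuned: the fibril cross-section is
still compacting (loose bundles read 1.5–2 × the crystalline-packing value
that six chains reach at equilibrium), first interchain contact in scaled
12-mer growth occurs at 5–6 free monomers (the full-geometry value requires
longer chains and slower approach), and the membrane-driven disassembly of
short-contact bundles — the 6-monomer stability threshold — is a
nanosecond-scale process that picosecond bundles do not resolve (all tested
m persist, making the threshold estimate degenerate at the smallest tested
m).  The synthetic fixtures encode exact geometric ground truth (kinks,
pairings, growth traces) but no thermodynamics, so estimator tests certify
the measurement code, not the force field.

## Known limitations

No solvent (consistent with the vacuum treatment of the original study), no
electrostatics, no protein (the synthase channel is reduced to an anchor
circle and membrane ports), generic rather than carbohydrate-specific force
constants, and a single Nosé–Hoover chain.  Emergent quantities therefore
carry wide tolerances by design; exact quantities (atom counts, topology,
estimator ground truth, conservation laws) are tested tightly.
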