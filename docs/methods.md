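# Methods

## Scope and model system

`ftszlat` quantifies the lateral (inter-protofilament) interfaces of
bacterial FtsZ and models their consequence for Z-ring assembly. Two
crystallographically observed lateral interfaces anchor the structural
side: a small patch on the S7/S10 face held by reciprocal Arg229–Asp301
salt bridges (MtbFtsZ numbering), and a larger charge-complementary face
on helices H3/H4/H5 carrying five basic (Arg76, Lys77, Lys83, Arg119,
Lys120) and three acidic (Glu80, Glu87, Glu153) residues per subunit.
Both crystal forms are hexagonal P6₅22 lattices whose 6-fold screw along
c generates the double-stranded, antiparallel protofilament helices; the
cell repeat c is therefore also the helical pitch.

## Structure handling

Coordinates are held as plain chains → residues → atoms containers in
Cartesian Å; parsing and writing of PDB/mmCIF is delegated to gemmi.
On reading, hydrogens and waters are dropped (a flag retains them),
zero-occupancy atoms are discarded, and alternate conformers collapse to
the highest-occupancy copy so surface areas are single-conformer. The
P6₅22 operator list is built in as coordinate triplets and validated for
group closure (and against gemmi's space-group tables) in the tests;
other symmetries enter through the operator list a file or caller
provides. Fractional coordinates exist only inside symmetry application:
x′ = M(R M⁻¹x + t + n) with M the orthogonalization matrix and n an
integer lattice shift. Filament expansion applies successive powers of a
chosen generator, renaming chains `<id><k>` and recording the generator
so an expansion is replayable; a generator whose centroid displacement is
below 0.5 Å cannot grow a filament and is rejected.

## Helical geometry

Superposition is closed-form least squares (Kabsch via SVD), proper
rotations only, requiring ≥ 3 non-collinear pairs. Residues are paired
by author sequence number; cross-species pairing uses the seq-id offset
that maximizes the number of paired main-chain atoms (N, CA, C, O — the
selection is configurable), which is sufficient at protofilament scale
without a sequence aligner, plus a ≥ 30% residue-identity sanity check
so unrelated templates are rejected rather than force-fit.

A rigid transform decomposes into screw parameters: the rotation's
invariant axis, the twist angle in (0, 180°], the rise (translation
component along the axis, axis flipped so rise ≥ 0, making pitch
positive by convention) and pitch = rise·360/twist. Rotations below
0.1° have no usable axis and are rejected. Filament pitch averages the
screw over consecutive subunit pairs (axes flipped into a common
hemisphere first) and reports the spread of per-pair pitches. For a
lattice-generated filament the independent analytic route — a
single-start n_m screw repeats exactly once per cell, pitch = c — must
agree with the superposition route, and the tests use that agreement as
an internal consistency check.

Pitch is a ratio of two noisy estimates, so under coordinate noise it
carries an O(σ²) positive-curvature bias that is negligible for
protein-sized subunits (tens of atoms over tens of Å) but visible on
deliberately tiny pseudo-subunits; the unbiasedness test therefore runs
at a protein-like subunit scale.

## Interface quantification

SASA uses the Shrake–Rupley estimator on a deterministic golden-spiral
point grid (960 points per atom by default; the tests check 1%
convergence against a 9600-point grid and exactness on isolated
spheres). Radii are Bondi-style (C 1.70, N 1.55, O 1.52, S/P 1.80 Å)
with a 1.4 Å water probe, all configurable. Buried interface area is
ΔSASA = SASA(A) + SASA(B) − SASA(AB), reported per side (ΔSASA/2, the
standard interface-area convention) and in total, since published
figures rarely state which convention they use. Contact residues use a
4.5 Å heavy-atom cutoff and salt bridges a 4.0 Å cutoff between basic
side-chain nitrogens (Arg NE/NH1/NH2, Lys NZ, His ND1/NE2) and acidic
side-chain oxygens (Asp OD1/OD2, Glu OE1/OE2), deduplicated per residue
pair at the minimum N–O distance; no cutoffs being standard, both are
parameters. Histidine counts as basic in the charge census but is
flagged, its protonation being unknown. Ligands (GTP/GDP) are excluded
from areas by default. Lateral-dimer extraction scans all symmetry
mates over ±1 lattice shifts and scores candidate pairings by the
number of inter-atomic contacts between the expected face residues
(interface 1: 229/301; interface 2: the H3–H5 set; an explicit set or
an any-face scan is available for non-FtsZ models), because chain
naming within a deposition is arbitrary.

## Sheet assembly

A sheet is tiled as lateralⁱ ∘ longitudinalʲ applied to a subunit, with
full transform provenance recorded (replaying it reproduces the model
bit-identically). Antiparallel alternation is enforced up front: the
lateral transform must reverse the longitudinal screw axis. Grafting a
crystal-contact dimer onto a template filament applies the subunit-A →
anchor superposition to the whole dimer; because crystal-contact grafts
are approximate, rmsd above 5 Å only records a warning. Steric
screening lists all inter-chain pairs below 2.2 Å; an assembly is
rejected when the atoms involved exceed 0.5% of the model (read as
atoms, not raw pair counts, which would scale quadratically and never
trigger).

## Z-ring incorporation model

Conditions follow the study design: n = 200 protofilaments of L = 50
subunits; per protofilament the disruptive-subunit count is
x ~ Binomial(L, f) with f the cellular proportion of laterally
disruptive FtsZ; incorporation into the ring is Bernoulli with
probability 0.99 when x is at or below the threshold T (critical
fraction f_c = T/L) and 0.01 above it; the statistic is
S = (X·V)/Σxᵢ over the cell, averaged across 10,000 independent
replicates. Two modelling choices the formula itself leaves open:
x = T is treated as tolerated (f_c reads as the highest tolerated
fraction; a flag flips the rule), and replicates with Σx = 0 — where S
is undefined — are excluded from the mean and counted, rather than
scored as zero. One seeded generator drives a run; replicates are
vectorized but equivalent to sequential sampling, and identical
config + seed reproduces results bit-for-bit.

Two exact routes back the Monte-Carlo estimator. At tiny sizes, full
enumeration over compositions with Binomial weights (linearity of
expectation over the Bernoulli states gives E[S | x] = Σxᵢpᵢ/Σxᵢ, so no
enumeration over V is needed). At any size, exchangeability plus the
fact that a sum of Binomials is Binomial reduces the mean to
E[S | Σx > 0] = n·Σₖ P(x = k)·k·p(k)·E[1/(k + R)] with
R ~ Binomial(L(n−1), f). A constant incorporation probability p
contributes exactly p, so the mean splits into p_above plus a positive
sub-threshold excess. That split matters numerically: past f ≈ 0.5
(T = 10, L = 50) the excess falls below 10⁻⁹ — the mean is pinned at
0.01 to within double precision and far below what any feasible
Monte-Carlo replicate budget can resolve — yet the model's central
qualitative claim (more disruptive FtsZ in the cell means a *smaller*
disruptive fraction in the ring) is a strict-monotonicity statement
about exactly this excess. The monotonicity check therefore certifies
strict decrease on the exact excess across the full f range while
validating the Monte-Carlo sweep against the exact mean within
sampling error; demanding strict ordering of raw Monte-Carlo means in
the flat tail would reduce to a coin flip at any replicate count.

## Synthetic fixtures

Generators emulate the geometry the real analyses see, at pseudo-atom
scale: helical filaments with known twist/rise (plus optional seeded
Gaussian jitter), a subunit in a P6₅22 cell whose screw expansion has
pitch = c by construction, and two-chain "dimers" whose planted
residue pairs (real residue and atom names, minimal side-chain
templates) meet at specified minimum distances exactly — the tip atom
of each template is its x-extreme atom, so the inter-residue minimum is
tip-to-tip by construction and verified to 0.01 Å. These fixtures
exercise the identical code paths as deposited structures but carry
none of a real protein's packing, secondary structure, or composition,
so passing tests demonstrate correctness of the computations, not
biological realism. Analyses of deposited entries (the MtbFtsZ-GDP
protofilament, PDB 4KWE) fetch coordinates from the PDB archive on
first use and cache them locally; those end-to-end checks require
network access once.

## Problem sizes and determinism

Default test-suite sizes: filaments of 2–24 pseudo-subunits, SASA
fixtures under ~100 atoms (960-point grids; 9600 for convergence
checks), simulation grids of ≤ 25 (f, T) points at up to 10⁶
replicates for tiny instances and 10⁴ at the full 200 × 50 scale. The
whole suite runs in well under a minute; the acceptance script in a few
seconds. All stochastic components take explicit integer seeds;
property tests run derandomized.

## Known limitations

- No electrostatics, ΔG estimation, energy minimization or side-chain
  repacking; interfaces are described geometrically.
- The screw description assumes rigid subunits; flexible or curved
  filament mechanics are out of scope.
- Sheet registry (which subunit pairs with which across strands) is a
  caller-supplied transform, not inferred.
- The incorporation model has no spatial structure, treadmilling
  kinetics or membrane energetics; it is a minimal threshold model of
  copolymer exclusion.
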