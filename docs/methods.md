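# Methods

This note documents the models implemented in `capscan`, the defaults and
conventions chosen where the design was open, and what the synthetic fixtures
do and do not establish.

## Coordinate and unit conventions

All coordinates are Cartesian Ångströms, right-handed; charges are in
elementary charges, energies in kcal/mol, forces in kcal/(mol·Å). The
Coulomb constant is 332.0636 kcal·Å/(mol·e²). PDB residue numbering is kept
as-is; atoms default to unit mass, so centers of mass are geometric centers
(element masses are available behind a flag — at capsomer scale the
difference is negligible for the pose constructions, which only use the
center and the symmetry axis). Angles follow the right-hand rule about the
scan-plane normal and are given in degrees at every user-facing interface.

## Charge assignment

The default scheme places integer formal charges at pH 7 on one
representative side-chain heavy atom per titratable residue: Asp CG −1,
Glu CD −1, Lys NZ +1, Arg CZ +1, His neutral by default (NE2 +1 when
protonated), and ±1 on free chain termini (N; OXT or C) when included.
No hydrogens are added and no pKa prediction is attempted; users with
force-field charges supply PQR files, which pass through untouched.
Unknown residues get charge 0 with a logged warning. Radii missing from the
input (plain PDB) default to 1.7 Å; they matter only to the
Poisson–Boltzmann and surface-area paths.

## Pose operations

A scan is defined by a fixed and a moving capsomer, a plane normal
(defaulting to the fixed capsomer's pseudo-3-fold axis, since capsomers sit
normal to the capsid surface) and the native axis — the COM-to-COM vector
projected into that plane. The four operations are exact isometries:

* *shift away*: translate along the native axis; the scan parameter is the
  displacement **added** to the native pose (the alternative reading, absolute
  COM separation, is not used — the operation describes relative motion);
* *shift perpendicular*: a fixed standoff along the axis, then an in-plane
  offset along `normal × axis`; the sign of "+60 Å" follows that cross
  product;
* *spin*: rotation about the plane normal through the moving capsomer's own
  (displaced) center, which is therefore invariant across the series;
* *rotate around*: one rigid rotation about the plane normal through the
  fixed center — position and orientation co-rotate, keeping the COM
  separation constant. An orientation-locked orbit is deliberately not the
  default: "rotating around" one body describes a single isometry.

The printed scan grids are 5–40 Å in 1 Å steps (36 poses), −60 to +60 Å in
5 Å steps (25), and −30° to +30° in 2° steps (31) for spin and
rotate-around. Spin ranges out to ±60° are supported; the ±30° grid is the
one used by the funnel analyses and the pose-count contract.

## Electrostatics

The default force model is a screened Coulomb (Debye–Hückel) sum over atom
pairs in a uniform solvent dielectric: the force term carries
`exp(−κr)(1+κr)` and the energy term `exp(−κr)`, with κ derived from the
ionic strength (0.15 M, 298.15 K, ε = 80 → Debye length ≈ 7.9 Å). Attraction
is reported as a positive projection of the force onto the fixed→moving
axis. Bodies closer than 0.5 Å at any atom pair are rejected.

The finite-difference linearized PB solver uses a 7-point stencil on a
node-centered cubic grid (default 1.0 Å spacing, 15 Å padding), dielectric
ε_protein = 2 inside the atom radii and ε_solvent = 80 outside
(face-harmonic averaging), ionic screening only outside the protein region,
trilinear charge deposition, Debye–Hückel Dirichlet boundary values summed
over all charges, and red-black successive over-relaxation (ω = 1.5,
convergence when the largest update falls below 1e-4 kT/e, at most 10,000
sweeps). The exterior potential of a single ion reproduces the analytic
screened-Coulomb (Born-ion) form within ~1% when the ion radius is resolved
by 3 grid cells; forces interpolated from a solved grid agree with the
direct Coulomb sum to better than 10%. Nonlinear PB, dielectric-boundary
pressure and ionic-pressure force terms are out of scope. Grids export to
OpenDX for visualization; grid potentials are in kT/e (a grid may also be
labelled kcal/(mol·e), in which case forces pass through unconverted).

## Funnels, effective range, salt bridges

A funnel is the maximal contiguous run of scan records sharing the sign of
the dominant extremum of the axial force; ties between equal extrema break
toward the native parameter, then the smaller parameter. The effective range
of a shift-away scan is the largest distance up to which every record keeps
a minimum magnitude (default 1e-3 kcal/(mol·Å)) and axial coherence
(axial/magnitude ≥ 0.5); beyond it directions are considered random.

Salt bridges are heavy-atom contacts (≤ 4.0 Å) between acidic oxygens
(OD1/OD2/OE1/OE2/OXT) and basic nitrogens (NZ, NH1/NH2/NE, ND1/NE2) across
the two capsomers, deduplicated to one bridge per residue pair at the
minimum distance. Hydrogens are not considered. The production search uses a
k-d tree; tests assert equivalence with an all-pairs scan. Formation
frequency over a frame ensemble is the fraction of frames containing the
residue pair; the per-frame bridge count distribution and its mean summarize
the population.

## Energy decomposition

`binding_energy` is a **single-snapshot** decomposition sharing the term
structure of trajectory MM/PBSA averages: a molecular-mechanics Coulomb
cross term (dielectric 1), a 12-6 Lennard-Jones cross term with
Lorentz–Berthelot combination (uniform defaults ε = 0.1 kcal/mol,
σ = 3.4 Å when per-atom parameters are not supplied), a
generalized-Born-style pairwise polar-solvation cross term screening from
ε_protein to ε_solvent with atom radii as Born radii, and a nonpolar term
γ·ΔSASA + b (γ = 0.00542 kcal/(mol·Å²), b = 0 by default, so the term
vanishes for separated bodies; SASA via Shrake–Rupley). The total is the
sum of the four terms. Ensemble averages over frames report per-term means
and sample standard deviations. No entropy term, no per-residue
decomposition, and no claim to reproduce ensemble values from long MD —
those require the trajectories themselves.

## Symmetron combinatorics

For the giant-virus family (h = 7, three capsomer layers per pentasymmetron
asymmetric unit) the trisymmetron edge length is n = k + 3 and the
pentasymmetron holds 31 capsomers. Inside a planar trisymmetron of n rows
every adjacent pair is a mode-1 contact, `3n(n−1)/2` in total; across each
of the 30 boundary edges there are n mode-2 and n mode-3 contacts,
alternating along the edge. Whole-virion counts are therefore
`N₁ = (k+3)(k+2)·30` and `N₂ = N₃ = (k+3)·30`; for PBCV-1 (k = 8, n = 11)
this gives 3300, 330 and 330. Every closed form is cross-checked against
enumeration on an explicitly built planar lattice. Two conventions are
deliberate: the geometry is flat (the analysis targets the flat 2-fold
region, not a spherical embedding), and the 2n-th boundary contact at an
edge end involves the corner dot contributed by the adjoining symmetron,
assigned to the lower-indexed edge. Pentasymmetron-internal (spiral)
contacts are not modelled.

## The synthetic capsomer

The toy capsomer is a flat C3-symmetric disc of nine charge sites: +1 at the
six pseudo-hexagon vertices and −2 in the three alternating grooves (net
charge 0), each site a short stack of atoms across the disc thickness with
the charge on a titratable head atom (LYS NZ / GLU OE1), so salt-bridge
machinery works on it. Groove charges line the groove mouths at the
edge-midpoint radius (cos 30° × 30 Å ≈ 26 Å); vertex charges sit slightly
recessed (0.92 × 30 Å ≈ 27.6 Å). That recession keeps the native
complementary contacts of the binding-mode pairs the closest interactions
throughout all four pose scans, which is what makes the funnel pattern
deterministic.

The three mode geometries are: mode 1 — same orientation, the moving
capsomer's groove capping a fixed vertex, approached 10° past the vertex
normal so that ±30° orbits stay on the uncharged-groove side; mode 2 — 60°
rotated, placed at the point where the "groove caps vertex" and "vertex caps
groove" ideal centers coincide, giving two complementary contacts at the gap
distance; mode 3 — 60° rotated, edge-on across the uncharged edges, so two
positive vertex pairs face head-on with no charged groove in the interface.
With the default 5 Å gap and the 0.15 M screened-Coulomb model, modes 1 and
2 are attractive with funnels containing the native pose in all four scans,
mode 2 is the stronger, and mode 3 is repulsive.

What passing these fixtures shows — and does not show: the toy reproduces
the *qualitative* electrostatic steering pattern (signs, funnel existence
and centering, C3 periodicity of spin profiles) with fully deterministic
arithmetic. It does not reproduce protein-scale magnitudes or ratios: with
nine point charges the mode-2/mode-1 strength ratio is ~12 (a dense protein
interface gives ~1.2–2), and the repulsive mode-3 magnitude is not small
relative to mode 1. Real-structure force magnitudes, funnel endpoints and
trajectory-ensemble energies are outside what a point-charge disc can
establish.

Synthetic frame ensembles apply Gaussian jitter to a mode pair and can plant
named salt bridges in an exact fraction of frames (3.5 Å in planted frames,
pushed beyond twice the cutoff elsewhere), so recovered formation
frequencies are exact at zero jitter and binomial otherwise.

## Problem sizes

The shipped analyses run on desk-scale inputs: 27-atom toy capsomers,
force scans of 25–36 poses, PB grids up to ~50³ nodes, and salt-bridge
ensembles of 4000 frames — the full suite completes in seconds on one CPU.

## Known limitations

* The charging scheme is formal-integer; reproducing a specific deposited
  structure's net charge depends on its resolved residues and termini and is
  a calibration check, not ground truth.
* The PB solver is linear, with a hard protein/solvent dielectric boundary
  on the grid; no Stern layer beyond the protein region itself.
* The energy decomposition is a static snapshot with crude Born radii;
  its value is the term structure and its invariants, not absolute numbers.
* The planar lattice ignores curvature and pentasymmetron spirals.
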