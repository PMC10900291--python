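# Methods

## Coarse-grained representation and cross-link geometry

A protein chain is reduced to two sites per residue: the Cα position and the
side-chain center (SC), taken as the centroid of the side-chain heavy atoms
(Cβ and beyond). Glycine has no side-chain heavy atoms and gets `sc = ca` by
convention; alanine's SC is its Cβ. Residues with partially missing side
chains use the centroid of whatever side-chain atoms are present (falling
back to the glycine convention with a warning), the highest-occupancy altloc
is kept, and author numbering — the currency of cross-link tables — is
preserved alongside internal sequential indices.

A cross-link between residues i and j is anchored at points X_i, X_j on the
Cα→SC axes, at offsets d_Xi, d_Xj that approximate where the reagent
attaches to the side chain; offsets beyond the SC center are allowed, since
reagent attachment sites can sit past the side-chain centroid. The link's
internal coordinates are the anchor distance d_XiXj, the two virtual-bond
angles θ_Xi (Cα_i···X_i···X_j) and θ_Xj, and the virtual-bond dihedral
γ (Cα_i···X_i···X_j···Cα_j), computed with the right-handed IUPAC sign
convention and reported in (−π, π]. When either bonded triple is collinear
(cross-product norm below 1e-8 Å²) the dihedral is undefined and a NaN
sentinel is returned; angles are still reported. All of these quantities
are exactly invariant under rigid motions, and mirroring negates every
dihedral — both asserted as property tests.

## Restraint potentials

All restraint energies are in kcal/mol, distances in Å, angles in radians
internally (degrees at the CLI/config boundary). Every potential returns its
analytic first derivative; the test suite verifies each against central
finite differences.

**Flat-bottom Lorentz-like wall** (on the SC–SC distance). With excess
x = d − d_u above the bottom (or d_l − d below it),

    V(d) = A · x⁴ / (x⁴ + σ⁴),      V = 0 on [d_l, d_u].

This bounded quartic-Lorentzian form satisfies the family's defining
contract: zero inside the flat bottom, continuous and once differentiable at
the boundaries, strictly increasing in the excess, bounded above by the well
depth A with gradient → 0 at gross violation. The sub-d_l wall mirrors the
upper wall; nothing in the family's specification fixes the sub-lower-bound
shape, and the symmetric choice prevents side-chain fusion while keeping the
flat-bottom contract. σ is a true wall thickness: V(d_u + σ) = A/2. Defaults
d_l = 2.5 Å; d_u per reagent (TATA 4, SDA 5, ABAS/DSG 6, DSA 7, BS³ 12,
disulfide 4.5 Å with σ = 5, A = 10); presets LR(σ,A) for
(σ, A) ∈ {5, 15} × {8, 20}.

**Statistical potential** (on the Cα–Cα distance). Cross-link-specific
distance distributions are modeled as a skew normal — amplitude a, location
b, scale σ, shape c, exactly the four shape parameters this family carries —
and the energy is the Boltzmann-weighted negative log density,

    V(d) = −A·RT·ln[ 2a·φ((d−b)/σ)·Φ(c(d−b)/σ) ]    (up to a constant),

with RT = 0.591 kcal/mol (T = 298 K) and the confidence weight A = 15 by
default. Φ is evaluated through `log_ndtr`, so the energy and gradient stay
finite and stable over (0, 100] Å even deep in the tail; no large-d
truncation is applied. The energy is exactly linear in A, which is how
cross-link confidence enters.

**MD-based potential** (on the full cross-link geometry). The energy is a
sum of independent one-coordinate components,

    V = V_d(d_XiXj) + V_θ(θ_Xi) + V_θ(θ_Xj) + V_γ(γ),

with Gaussian basis terms (coefficient, center, width) for the distance and
angle components and a cosine series (coefficient, phase, integer order) for
the dihedral, which is therefore exactly 2π-periodic. These bases mirror the
shapes of PMFs of cross-linked model compounds (localized wells in distance
and angle, periodic structure in the dihedral) and are closed under the
fitting pipeline below. Since the equations' printed coefficient tables are
supplementary data, nothing numeric is hard-coded: coefficient sets load
from versioned JSON parameter files.

**Dihedral window restraint.** Backbone virtual-bond dihedrals are
restrained by a flat-bottom quartic, zero inside [γ_l, γ_u] (modulo 360°)
and w_dih·Δγ⁴ outside, with Δγ the excess in radians along the shorter
angular path to the window — the radian choice follows directly from
w_dih's units, kcal/(mol·rad⁴). Defaults: w_dih = 50, helical window
(30°, 70°), extended window (120°, 240°).

**Composite energy.** `total_restraint_energy` sums cross-link terms (each
scaled by its link's confidence) and dihedral terms, returning a per-term
breakdown that sums to the total exactly. The physical force-field term of
a full modeling energy is deliberately out of scope; the toy refiner
substitutes a per-site harmonic tether (below).

## PMF derivation and fitting

Coordinate samples are histogrammed (defaults: 50 distance bins, 36 angle
bins ≈ 5°, 72 dihedral bins = 5°; dihedrals wrapped into (−π, π], making
the edge bins periodic neighbors) and inverted,

    W_i = −RT ln h_i,   R = 1.9872×10⁻³ kcal/(mol·K),  T = 300 K default,

then shifted so min W = 0. Empty bins are masked rather than pseudo-counted:
the inversion is undefined at h = 0 and invented counts would bias the fit.
Two bins with counts in ratio e therefore differ by exactly RT
(0.596 kcal/mol at 300 K), and renormalized exp(−W/RT) reproduces the
empirical bin frequencies identically — both are tests.

Fitting minimizes Σᵢ wᵢ (V(xᵢ) − Wᵢ)², weights uniform by default with
per-bin (Boltzmann) count weighting exposed as an option, and always
includes an additive constant since the PMF zero point is arbitrary. The
cosine series is linear in its coefficients for fixed harmonic orders
1..N, so the dihedral fit is solved exactly by linear least squares and
converted back to (amplitude, phase, order) triples. The Gaussian forms are
fitted by variable projection: amplitudes and offset are profiled out
exactly, and a bounded trust-region least-squares solver (widths constrained
away from zero) works on the (center, width) parameters only, started from
an exhaustive linear-subfit scan over a candidate grid plus matching-pursuit
and spread heuristics, with a deterministic perturbation polish (width
rescaling, one-width center nudges) to escape the shallow basins created by
strongly overlapping terms. This multi-start-with-polish scheme replaces a
plain fixed-count multi-start because near-degenerate Gaussian pairs
(overlapping centers, opposite signs) otherwise trap local optimizers;
noiseless synthetic PMFs from random parameter draws are recovered to
residual < 1e-4 in ≥ 95 of 100 seeded trials (97–99 observed across seeds).
The accepted-descent cost trace is recorded and is non-increasing;
convergence is reported at the 1e-8 gradient-norm tolerance.

`derive_mdbased_params` runs histogram → PMF → fit per coordinate and
assembles the result, storing per-coordinate residuals and convergence in
provenance. The fitted constants are dropped on assembly (restraint
potentials are defined up to an additive constant), so round-trip
comparisons align offsets first. In the original workflow the samples come
from all-atom MD of cross-linked model compounds; here the package's own
Metropolis sampler generates samples from known potentials for testing, and
real trajectories can be ingested as plain TSV tables of the four internal
coordinates.

## Cross-link planning and violation analysis

Topological length is L = |j − i| (the index-difference convention; the
inclusive loop-size convention |j − i| + 1 is exposed as an option because
"a loop of N residues" is ambiguous between the two). ΣL sums L over a set;
classification is strictly ΣL > 150 for high improvement capacity. ΣL is
additive, order-invariant and invariant under uniform renumbering — all
property-tested.

Cross-linkable pairs must be (a) allowed by the reagent's residue-type
specificity (Lys–Lys for the NHS homobifunctionals DSG/DSA/BS³; Lys paired
with Ser/Cys/Met/Thr/Glu for SDA, whose diazirine chemistry is characterized
for those partners; Lys–any for ABAS's aryl azide; unrestricted for TATA;
Cys–Cys for disulfides), (b) within the reagent's d_u in SC–SC distance, and
(c) surface-exposed. Exposure is a Shrake–Rupley-style fraction computed
directly on the CG sphere model: 256 golden-spiral test points on the
probe-inflated SC sphere (r_SC = 3.0 Å, r_Cα = 2.0 Å, probe 1.4 Å),
normalized by the accessibility of the same sphere occluded only by its own
residue's Cα sphere, with default threshold 0.2. This is a deliberately
coarse criterion — a two-sphere model has no atomic detail — but it cleanly
separates core from surface side chains in the fixtures, which is its job.

The violation census compares each link's Cα–Cα distance with the reagent's
maximum Cα span, d_u plus both residues' Cα→side-chain-end reaches (6.4 Å
for lysine; a small per-type table covers the other linkable residues), and
counts excesses above 5 and 10 Å. Over-length links are false restraints —
capturable only through fluctuation or distortion — and are reported, never
removed: with bounded restraint walls, false restraints are tolerable, and
curation would require knowing the structure one is trying to determine.

## Scoring

Cα RMSD uses an in-package Kabsch superposition (SVD with the proper-
rotation correction), cross-checked in tests against an independent
solver. GDT_TS is the average over cutoffs {1, 2, 4, 8} Å of the maximal
fraction of corresponding Cα atoms superposable within the cutoff, ×100.
The exact maximum is combinatorial, so a standard seeded heuristic is used:
candidate superpositions from every contiguous fragment of lengths 3, 5, 7
plus the global fit, each refined by superpose-on-inliers iteration to a
fixed point, with every candidate scored at all four cutoffs (which also
guarantees cutoff-monotone fractions). Distances after optimal subset
superposition are symmetric in the two structures, so the score is symmetric
for full mappings. The heuristic can differ from an exhaustive LGA-style
search by up to a couple of GDT_TS units on ambiguous decoys; validation
therefore uses constructed fixtures with unambiguous scores (rigid
transforms → 100.0, a half-displaced rigid block → exactly 50.0) and the
guarantee that the heuristic never scores below the single global
superposition. Residue correspondence is by author-index intersection; no
sequence alignment is attempted, since models of the same sequence are
compared.

## Toy restrained refinement

`restrained_minimize` minimizes tether + restraint energy by gradient
descent with Armijo backtracking (trace monotone by construction), where the
tether is a per-site harmonic to the starting coordinates, weight in
kcal/(mol·Å²). The tether isolates restraint-gradient behavior without
reimplementing a force field: satisfied flat-bottom links exert zero force,
a moderately violated link pulls side chains to just outside d_u at the
1-D wall/tether balance point (checked against a closed-form 1-D
minimization), and a grossly violated link on the plateau leaves the
structure unchanged to < 1e-3 Å. Cartesian gradients are analytic
throughout, chain-ruled through the anchor-point geometry
(∂X/∂sc = (d_X/|v|)(I − ûûᵀ), v = sc − ca), with distance, angle and
dihedral point-gradients in closed form; all are finite-difference-tested.

## Synthetic data generators

The fixture generators define the conditions under which everything above
is validated.

- `ideal_helix`: Cα on a helical lattice (rise 1.5 Å/residue, twist
  100°/residue, radius 2.3 Å — consecutive Cα distance 3.83 Å and backbone
  virtual-bond dihedrals +50°, i.e. realistic α-helix values inside the
  helical restraint window), SC 2.0 Å radially outward, all-lysine sequence
  by default so every residue is linkable by the Lys-specific reagents.
- `perturb`: hinge rotations about random axes plus Gaussian coordinate
  noise, deterministic per seed — enough to make decoys with controlled
  global/local error for scoring tests.
- `boltzmann_sample`: single-chain Metropolis on one coordinate, uniform
  ±step proposals, 10% burn-in discarded, acceptance rate logged. On a
  harmonic potential the sample variance matches RT/k within 5% at
  n = 50000, and histogram → inversion recovers the generating potential
  within 0.2 kcal/mol RMS over the central 90% of the mass.
- `make_xlink_fixture`: draws n_true satisfied pairs and n_false pairs
  over-length by > 5 Å (the false-restraint fraction is a generator knob,
  reflecting that uncurated experimental lists contain such links; the
  toolkit itself never filters them).
- `write_pdb` emits CA plus a single CB record at the SC position, so the
  centroid convention reproduces `sc` exactly on re-reading and the I/O
  loop closes through the package's own parser.

What these fixtures do *not* emulate: real side-chain rotamer geometry,
sequence-dependent SC sizes and reaches beyond the small built-in table,
solvent effects on exposure, correlated coordinates in the MD-based
ensembles (the four internal coordinates are sampled independently, matching
the potential's additive form), and realistic decoy energy landscapes.
Passing tests therefore demonstrate correctness of the restraint machinery
and its contracts, not modeling accuracy on real proteins.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the checks
sharp but quick: 20–60-residue helices, 5000-sample dihedral recovery
(matching the snapshot count used for PMF derivation in the source
workflow), 50000-sample harmonic calibration, 100-trial fit-recovery rates,
and 1000 random decoys for the GDT heuristic's dominance property.
Degenerate inputs are handled explicitly: collinear dihedrals return a NaN
sentinel (and the MD-based potential refuses it), zero-length anchor axes
require a fallback, empty histogram bins are masked, under-determined fits
raise, and duplicate or self cross-links are rejected at construction.

## Known limitations

Single chain per analysis (no inter-protein links), pairs only (TATA's
third arm is not modeled), no mmCIF, no Hessians, no replica-temperature
weighting. The statistical potential's published per-reagent shape
parameters and the MD-based coefficient tables are supplementary data to be
loaded from JSON, not bundled. GDT_TS is a documented heuristic, not
exhaustive LGA.
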