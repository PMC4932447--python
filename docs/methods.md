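# Methods

## The ECD descriptor chain

The analysis operates on one trajectory segment at a time.  Frames are
optionally (and by default) superposed onto the segment-mean structure by
least-squares rigid-body fitting (batched Kabsch via SVD of the 3×3
cross-covariance; the mean is re-fit iteratively to a fixed point, which
makes the operation idempotent).  The 3N×3N coordinate covariance is then
formed with plain population normalisation (1/T — at the usual 2000 frames
per segment the difference from 1/(T−1) is immaterial, but fixing it makes
runs bit-reproducible) and decomposed by dense symmetric eigendecomposition.

Atom images are built from the top k_max eigenvectors: image of atom i =
concatenated triplets of that atom's x/y/z components in each retained
eigenvector.  Orthonormality forces Σᵢ|r⃗ᵢ|² = k_max, which the tests use as
a conservation check, together with trace(C) = Σλ.  Flexibility F_Cα(i) is
the distance of a Cα image from the centroid of the Cα images (centroid over
Cα only); pair correlations d_ij are Euclidean distances between images and
therefore satisfy the metric axioms exactly.

Numerical conventions that matter:

* **Eigenvector sign** is arbitrary; each eigenvector is flipped so its
  largest-magnitude component is positive (ties → lowest index).  A global
  sign flip reflects all triplets at once, so d_ij and F are unaffected; the
  convention exists purely for reproducibility, and a property test asserts
  descriptor neutrality.
* **Degenerate eigenvalues.**  Exactly degenerate clusters are ordered
  lexicographically by their sign-fixed eigenvectors.  d_ij is invariant
  under any orthogonal rotation *within* the retained set of eigenvectors
  (images transform as B_i → B_iQ), so descriptors are stable as long as
  k_max does not split a degenerate (or near-degenerate) cluster; a warning
  is emitted when it does.  Isotropic harmonic networks have exactly
  three-fold degenerate spectra, which makes this visible in practice.
* **Superposition before PCA** is on by default (standard essential-dynamics
  practice) and can be disabled (`fit=False`, CLI `--no-fit`) for
  sensitivity checks; the synthetic generator produces no rigid-body motion,
  so both settings are meaningful there.
* **No mass- or eigenvalue-weighting** of images: raw eigenvector
  components are used.

Default protocol parameters: 200-ps segments, 0.1-ps frame spacing (2000
conformations/segment), k_max = 20, PCA over all heavy atoms, descriptors
over Cα, averaging over the trailing 10 ns in 50 segments.  Segment averages
are unweighted elementwise means; the per-element segment-to-segment
standard deviation is retained.

## Constructs

Chains are built fully extended with every Cα exactly on a straight line,
3.7537 Å apart.  Bond lengths are ideal (N–CA 1.458 Å, CA–C 1.525 Å, peptide
C–N 1.329 Å); the price of exact Cα collinearity is an opened N–CA–C angle
(~147° instead of ~111°).  That trade was chosen deliberately: the axis *is*
the definition used for HH/HT classification, axis-to-axis separations, and
the 180° "roll" of the #2 dimer variants (which then provably leaves Cα
positions unchanged and moves only the backbone pleat and side chains).
Carbonyl and side-chain heavy atoms come from idealized CCD residue
templates rigidly superposed on each built N/CA/C frame, so their internal
geometry is exact.  These are synthetic starting geometries for fluctuation
synthesis and classification — not physical conformers, and no energy
minimisation or force-field treatment is attempted.

Dimers translate the second chain 14 Å along +y (axis-to-axis); HT variants
reverse the second chain's N→C direction by a 180° rotation about a vertical
axis through the Cα midpoint.  The tetramer stacks two copies of the base
dimer (default HT2) along +z at the same separation, a 2×2 bundle with equal
nearest-neighbour spacings; the published six-pair HH/HT table is reproduced
by axis-direction dot products alone.  The cross-section geometry (square
bundle rather than planar ribbon) is the one design choice the source
figures leave open; it is asserted only through the pair classification.

## The synthetic generator

One site per Cα; potential E = ½ Σ k_ij|u_i − u_j|² over displacements from
the reference geometry.  The Hessian is the weighted graph Laplacian L ⊗ I₃,
so the stationary covariance of the overdamped dynamics is kT·L⁺ per axis —
a closed form used as the oracle throughout the tests.  Because the energy
penalises |u_i − u_j| isotropically, only the three translations are free;
they are projected out, removing rigid-body drift by construction (and
leaving superposition code independently testable).  A connected spring
graph therefore has exactly one zero Laplacian mode per axis; anything else
raises a model error.

Block plans assign springs: dense k_block springs between all site pairs of
a rigid block within a 1.0-nm cutoff, chain-sequential k_linker springs for
linkers (and any residue not covered by a block), and explicit all-pairs
couplings between named residue ranges of two chains (no cutoff — these
model persistent inter-chain contacts).  Optional "satellite" decoration
puts every heavy atom of the source construct on its residue's Cα site plus
small independent Gaussian jitter (σ = 0.005 nm).  This exercises the
all-heavy-atom PCA path; it is a fixture feature, not side-chain physics.

The default integrator samples each Laplacian eigenmode as an exact
Ornstein–Uhlenbeck process (AR(1) recursion evaluated with a linear filter),
which is unconditionally stable, has the exact stationary law, and lets the
initial condition be drawn from stationarity — trajectories are equilibrated
from frame 0 and burn-in defaults to 0.  A plain Euler–Maruyama integrator
(`method="euler"`) is kept for cross-checks; its sub-step count is chosen so
h·λ_max/ζ ≤ 0.05, bounding the discretisation bias of the stationary
variance below ~3 %, and coordinate blow-up raises a stability error.

Parameters and units: stiffnesses in kJ·mol⁻¹·nm⁻², kT = 2.577 kJ·mol⁻¹
(310 K, the simulation temperature of the source protocol), and a friction
(drag) coefficient ζ in kJ·mol⁻¹·nm⁻²·ps so that the relaxation time of a
mode with Laplacian eigenvalue λ is ζ/λ (default ζ = 50 → a few ps for the
soft collective modes).

**Default two-chain plan** (the package's reference conditions): two
40-residue chains (the N-terminal stretch of the packaged α-synuclein
sequence), HH1 at 14 Å; per chain, rigid blocks at residues 1–16 and 25–40
joined by a linker at 17–24; inter-chain coupling between residues 5–12 of
both chains at 10 kJ·mol⁻¹·nm⁻²; k_block = 1000, k_linker = 50; heavy-atom
decoration on.  These values were fixed by examining the model's closed-form
spectrum before any trajectory was sampled: they put the network in the
collective regime the analysis assumes, with a handful of soft block/linker
modes carrying ~97 % of the population displacement variance, so a 20-
component PCA of a sampled 2000-frame segment lands in the 90–95 % coverage
band expected of equilibrated protein fluctuation segments.

## What the generator does and does not emulate

It produces stationary Gaussian fluctuations around a fixed reference with
controllable correlation structure — rigid blocks, flexible linkers,
inter-chain coupling, heavy-atom decoration — which is exactly what the
descriptor chain consumes.  It does **not** fold, drift between
conformational basins, form or break β-sheets, or carry solvent/force-field
anharmonicity.  Passing tests therefore demonstrate that the analysis
recovers planted correlation structure correctly and reproduces its own
closed forms; they do not re-derive any all-atom MD results (stable β-sheet
residue ranges, folding events), which require the full solvated
simulations and are out of scope here.

## Test-fixture regimes

The Monte-Carlo consistency check of the segment-averaging protocol (fifty
200-ps segments versus one 10-ns segment) is only statistically well-posed
when each segment is genuinely equilibrated and every segment retains the
same principal subspace.  Its fixture therefore uses mode relaxation times
of ~1 ps (≪ 200 ps), sub-nanometre fluctuation amplitudes, and a component
cut placed at the leading spectral gap of the closed-form covariance.  With
a cut inside a quasi-continuum, segment-to-segment subspace selection
fluctuates and the short-segment maps acquire a genuine bias relative to the
long-segment map — a property of the estimator worth knowing when applying
the method, not an implementation artifact.

Problem sizes used by the tests and the acceptance script — 10–40 residues
per chain, 2 000–100 000 frames, full heavy-atom PCA up to ~1 700 degrees of
freedom — were chosen as the smallest systems that exhibit each property
being checked.

## Known limitations

* The DSSP-style secondary-structure tables are parsed, never computed;
  assignment quality is the caller's responsibility.
* Stability statistics are per-residue (a residue is "stable β" if its E
  occupancy exceeds 80 % of the window, strictly); whole-sheet simultaneous
  occupancy is not tracked.
* PDB insertion codes are rejected; only the first altloc is kept.
* The distance-map atom set defaults to heavy atoms and is selectable, but
  no periodic-boundary handling exists — inputs are expected to be whole,
  protein-only trajectories.
* Dense eigendecomposition limits single-segment PCA to a few times 10⁴
  degrees of freedom in practice.
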