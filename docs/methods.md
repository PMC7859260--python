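# Methods

This note records how each quantity is defined, the defaults and why, what
the synthetic generator does and does not emulate, and the numerical
choices made where the procedure was genuinely open.

## Coordinate model

A bundle frame is an orthorhombic box plus an (H, N, 3) array of backbone
bead positions — H helices of one peptide variant, N residues each, in
nanometres. Trajectory times are nanoseconds. Frames from NMR ensembles
carry no physical box; they are flagged non-periodic, distance code then
uses plain Euclidean distances, and model ordinals stand in for times.
When an NMR model is read, the CA atom proxies the BB bead: the Martini
backbone bead sits at the backbone centre of mass, within about 0.07 nm of
CA, which is negligible against every cut-off used here (0.4–1.5 nm).

## Contact matrices

A contact between residue i of helix K and residue j of helix H (K ≠ H)
exists when the bead distance is ≤ the cut-off, boundary inclusive, under
the minimum-image convention in all three dimensions for periodic frames.
Counts accumulate over every frame of the window and over *ordered* helix
pairs. The double sum over (K, H) and (H, K) makes the matrix symmetric by
construction; it doubles raw totals relative to an unordered convention,
which is immaterial because matrices are reported normalised to their
largest entry. An all-zero matrix is returned unchanged from
normalisation, flagged rather than divided.

Defaults: paired cut-offs 0.5 and 0.8 nm (tight crossing-point contacts
vs. looser three-fold interfaces — at single-bead resolution 0.4 nm
detects nothing and 1 nm loses specificity); window opening at 3000 ns,
after membrane convergence; every stored frame within the window.

The implementation is a vectorised all-pairs distance evaluation per
frame. At the scale this package targets (36 helices × ≤ 35 residues ≈
1,260 beads) this is a few tens of milliseconds per frame; correctness is
pinned to an explicit quadruple-loop oracle in the test suite, so any
future acceleration must reproduce it exactly.

## Body frames and radial maps

Per helix and frame: centroid = mean of beads i−1, i, i+1 around the
reference residue i; orientation = the in-plane projection of the bisector
(r<sub>i−1</sub> − r<sub>i</sub>) + (r<sub>i+1</sub> − r<sub>i</sub>),
normalised. On a regular helix the bisector points from the surface bead
toward the helix axis, so the X-axis of the body frame points "inward
across" the reference residue; the sign choice is fixed and consistent
everywhere, which is all that matters for relative angles. If the
projected bisector norm falls below 10⁻³ nm (beads collinear in Z, or a
helix lying essentially flat) the descriptor is invalid; such references
are skipped and counted rather than contributing a garbage frame.

Widening the centroid window to two beads per side moves the centroid by
about 0.11 nm for canonical helix geometry (a fraction of the 0.23 nm
helix radius, with identical axial position). That is negligible against
the 1.5 nm first orbit, so the three-bead default stands.

Radial maps accumulate each neighbour centroid's minimum-image XY position
rotated into the reference body frame, for every ordered (reference,
neighbour) pair, at a 100 ns stride (nearest stored frame at or after each
tick). The density map is a fixed-grid Gaussian kernel estimate
(bandwidth 0.1 nm, grid step 0.05 nm, extent ±3 nm); each kernel
integrates to one so the grid mass approximates the point count. The map
is for visualisation only — every census quantity works on the raw points,
so no result depends on the bandwidth.

## Census: pairs, trimers, lifetimes

For an ordered pair of valid body frames, the analysis keeps three
numbers: the XY minimum-image centroid distance, the angular position α of
the neighbour in the reference frame, and the relative orientation β = the
counterclockwise in-plane angle from the reference orientation to the
neighbour's, mod 360°. For an ideal C<sub>n</sub>-symmetric assembly,
adjacent protomers satisfy β = 360°/n exactly and independently of global
pose: 180° for C2, 120°/240° for C3.

Classification defaults: first orbit d ≤ 1.5 nm; angular tolerance 25°,
chosen so the three windows 120/180/240 are disjoint (gaps of 60° > 2×25°)
— a pair can never be C2 and C3-compatible at once, and the two categories
are counted independently. β is kept signed (mod 360) so 120° and 240°
remain distinguishable.

A closed trimer is a 3-cycle of C3-compatible pairs whose directed betas
around the cycle sum to 0 mod 360° within 3× the tolerance. The closure
test is this package's construction: it is what separates a genuine
three-fold ring from three accidentally co-oriented pairs, and because
orientation errors telescope around a cycle it costs no sensitivity on
noisy but genuine trimers.

Association records open an interval when a member set first qualifies in
its category and close it when the set fails for more than
`gap_tolerance` consecutive strides (default 0 — strict, no bridging;
bridged gaps count toward the interval when the tolerance is raised).
Summaries report accumulated, longest and mean lifetimes plus the number
of distinct member sets and distinct helices involved.

First-orbit spots are isolated with DBSCAN (ε = 0.25 nm, minimum cluster
seed max(5, 1% of in-orbit points)). The Markov matrix assigns each
ordered pair per strided frame to its spot label or "outside", counts
transitions between consecutive strides, and normalises rows; rows with no
outgoing counts are flagged, never fabricated. The matrix is descriptive —
no rate estimation, no lag-time analysis.

## Structure comparison

Kabsch superposition by SVD with the determinant correction (rotations
only, det = +1); collinear bead sets are rejected. Oligomer matching tries
every chain permutation (assemblies here have ≤ 6 protomers, ≤ 720
correspondences) and reports the winner, so protomer labelling never
biases an RMSD. Ensemble averages superpose every model onto the first and
report per-bead RMS spread about the mean.

The C<sub>n</sub> axis of an assembly passes through its bead centroid
along the principal direction most aligned with the membrane normal; when
the assembly holds more than n helices, consecutive equal-sized groups
form the protomers (e.g. the two trimer units of a dimer of trimers under
n = 2). Deviation is the worst |azimuth gap − 360/n|. The R/T/A
decomposition expresses each per-bead deviation vector in the orthonormal
cylindrical basis at the reference bead (radial from the axis, tangential,
axial), so the Pythagorean identity R² + T² + A² = RMSD² holds to
round-off on every input; beads on the axis have no radial direction and
are excluded and counted. This decomposition is a reconstruction of how a
symmetric assembly's error budget is usually presented; no external
symmetry software is involved.

All comparisons are CG-backbone-level. Absolute values are therefore not
interchangeable with all-atom RMSDs; both nm and Å are reported.

## Membrane diagnostics

Area per lipid is the projected box area divided by lipids per leaflet,
with no protein-area correction — the simplest defensible estimator; in a
patch crowded with 36 helices it overestimates slightly, which the output
documents. For the reference geometry (25 × 25 nm, 1,700 lipids) it gives
2·625/1700 = 0.735 nm², the standard fluid-bilayer value. Thickness is the
difference of mean head-bead z between leaflets (leaflets split at the
median z); a density-profile estimator was considered and rejected as
noisier on small patches. The convergence check chops a series into
windows and reports the earliest time from which k = 3 consecutive window
means agree within 2% relative — an operational criterion standing in for
the usual by-eye judgement that a bilayer has settled before the analysis
window opens.

## Synthetic bundles

The generator emulates the *geometry* of the simulated systems: a
25 × 25 × 10 nm box, 36 helices on an even 6×6 grid (spacing box/√N ≈
4.17 nm), randomly re-oriented about Z each frame, with planted assemblies
built from ideal helices (rise 0.15 nm/residue, twist 100°, radius
0.23 nm — canonical α-helix constants, 30 residues by default to match
single-span TM lengths). C2 members are related by a 180° rotation about
the vertical axis through their midpoint; C3 members by 120° rotations
(adjacent axis separation 1.0 nm by default, comfortably inside the first
orbit); a dimer of trimers is two C3 units related by a 180° rotation with
the facing protomers at the C2 separation. Noise is per-frame rigid-body:
Gaussian displacement (σ default 0) plus a uniform bounded rotation about
the helix axis — bounded, not Gaussian, so an orientation-noise setting of
10° can never push β outside a 25° window on its own. Optional "wanderer"
pairs stay within the first orbit of each other but re-orient at random
and wobble radially every frame, emulating unassigned neighbour spots that
drift rather than bind. Assemblies may follow on/off frame schedules;
while off, members sit at their own grid slots. Placements closer than
0.5 nm between helix axes are rejected with the offending ids.

Everything is deterministic given the spec (seed included), and the
generator emits the exact planted census per frame, so recovery tests
compare against ground truth rather than against tuned expectations. What
the generator does *not* emulate: interactions, diffusion, membrane
undulations, helix flexibility, or assembly kinetics. Passing recovery
tests therefore demonstrates that the analysis chain measures what it
claims on known geometry — not that any force field forms these
assemblies.

## Problem sizes and determinism

Test and demonstration runs use bundles of 16–36 helices, 10–30 residues
and up to 200 frames — ample to exercise every code path while keeping the
full suite under a minute of compute. All stochastic fixtures are seeded;
the acceptance script threads its `--seed` through every random draw, and
the quantities it reports (ideal-assembly betas, closed-form area per
lipid) are pose-randomised but analytically forced, so they are identical
for every seed up to round-off.
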