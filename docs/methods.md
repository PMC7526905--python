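# Methods

## Model and assumptions

The pipeline models a molecular crystal as identical ellipsoids packed at
the molecular centroids. It rests on three assumptions: (i) a molecule can
be reduced to a single centroid (orientation, conformation and Z′ > 1
effects are outside the model); (ii) the densest packings of identical
ellipsoids are affine images of densest sphere packings, so only centroid
arrangements that are affine transformations of the four basic cubic
lattices P, C, I, F are modelled (the hexagonal family is excluded);
(iii) the ellipsoids are in tight contact along nearest-neighbour
directions, which fixes their size completely once the lattice type and the
affine map are known.

### Normalization

A cell with lengths a, b, c (nm) and angles α, β, γ (degrees) defines the
cell matrix `A` (columns = cell vectors; fixed Cartesian convention: **a**
along x, **b** in the xy-plane — persistence diagrams are rotation
invariant, so the convention cannot affect classification). The
normalization map is `W = alpha_side · A⁻¹` with `alpha_side = 0.1` nm. All
fractional centroids are re-centred on the first centroid; for true lattice
motifs the resulting cloud is independent of that choice (verified by a
translation-invariance property test). Centroids whose wrapped fractional
coordinate lies within `boundary_tol = 1e-6` of 0 (fractional) receive
periodic images, so corner/face/body positions appear with all their images:
8 points for P, 10 for C, 9 for I, 14 for F.

### Persistence

Diagrams are computed under the exact Čech filtration on the ball-radius
scale: a simplex enters at the radius of the minimal enclosing ball of its
vertices, so two points at distance d merge at d/2. Simplices are
enumerated to dimension 3, which is exact for homology degrees q ≤ 2.
Minimal enclosing balls of up to four points are computed per support subset
(diametral pairs, triangle circumballs, circumsphere, filtered by
containment), which is well defined for the cocircular/cospherical
configurations of the symmetric motifs — no symmetry-breaking perturbation
is needed. Pairing is by standard boundary-matrix reduction over Z/2;
zero-persistence pairs are culled at relative tolerance 1e-9.

The cost of the simplex enumeration grows as n⁴; the implementation is
intended for motif-sized clouds (tens of points), which is the regime of the
method: one unit cell contributes at most 14 reference points, and clouds
larger than 22 points (largest motif plus one full corner-image set) are
short-circuited to OTHER.

Reference diagrams are **computed** from the exact motif point sets rather
than hard-coded, because bottleneck comparison needs multiplicities. The
analytic single-cell values they must (and do) reproduce, in units of the
cube side: q = 0 deaths 1/2 (P), 1/(2√2) and 1/2 (C), √3/4 (I), 1/(2√2)
(F); the full P diagram {q1: (1/2, 1/√2), q2: (1/√2, √3/2)}; the full F
diagram {q1: (1/(2√2), 1/√6), q2: (1/√6, √3/4) and (1/√6, 1/2)}. The
higher-degree classes of C and I that exist in the *infinite* periodic
lattice (e.g. a cavity dying at the body-centred covering radius √5/4) are
not realised by a one-cell cloud: the enclosing cycles need points of
neighbouring cells. Since the pipeline compares one-cell clouds with
one-cell references built identically, this has no effect on assignments,
but it is the reason the C and I reference diagrams have empty q = 2
components.

### Bottleneck distance

`d_B` is the infimum over partial matchings of the sup L∞ transport cost;
unmatched finite points pay their distance to the diagonal (death−birth)/2.
Essential (infinite-death) classes must match each other at cost |b_X−b_Y|,
and the distance is +∞ when the essential counts differ. The implementation
binary-searches the sorted candidate costs with a Hopcroft–Karp feasibility
check on the standard augmented bipartite graph; the test suite pins it to a
brute-force matching enumeration on diagrams with up to six off-diagonal
points.

### Classification criterion

A type is accepted when the aggregated bottleneck distance over q = 0, 1, 2
is below ε = 0.001 nm. Two aggregations are provided:

- `min` (default): a match in any single informative degree suffices. A
  degree is *informative* when at least one of the two diagrams is
  nonempty; empty-vs-empty comparisons are vacuous (bottleneck distance 0
  with no topological content) and are skipped. Without this rule every
  cloud with an empty q = 2 diagram would "match" the C and I references
  perfectly, which would make the criterion meaningless for finite motifs.
- `max` (strict): all three degrees must match. This is the right mode for
  screening negatives, and is what the negative-control tests use; the
  permissive `min` can accept a jittered cloud whose spurious features have
  persistence below 2ε.

Ties below 1e-12 are broken in the fixed order P, C, I, F. The three C
centring orientations have congruent motifs and hence identical diagrams, so
the centring axis (needed to orient the reference spheroid) is detected
geometrically, by the Hausdorff distance between the normalized cloud and
the three C reference motifs.

### Ellipsoid estimation

Reference forms in cube coordinates (side α): P → sphere radius α/2; I →
sphere √3α/4 (contact along the body diagonal); F → sphere √2α/4 (contact
along face diagonals); C → spheroid (√2α/4, √2α/4, α/2) with the α/2 axis on
the centring axis. The crystal-coordinate form is `Q = Wᵀ R_Z W`; radii are
reciprocal square roots of its eigenvalues, sorted r₁ ≥ r₂ ≥ r₃, with
eigenvectors as principal axes. For degenerate radii (spheres, spheroids)
the eigenbasis is not unique; tests compare radii only in those cases.
Packing fractions Z·(4/3)π r₁r₂r₃/V_cell are affine invariants: π/6 (P),
√3π/8 (I), π/√18 ≈ 0.74048 (C and F).

### Fingerprint regression

Targets are the estimated radii triples; inputs are hashed circular (Morgan)
fingerprints, by default 2048 bits at bond radius 2 (ECFP4-equivalent), used
raw as binary vectors. The regressor is a single hidden layer of 64 tanh
units with linear 3-wide output, trained with Adam (learning rate 0.001,
mini-batch 32) to minimise the mean squared error, with 10 % of the training
data held out for early stopping (patience 20 epochs, cap 2000). Evaluation
is k-fold cross validation (default 4) with seeded, deterministic fold
assignment; both RMSE and MAE are reported, per radius and overall. The
training backend is scikit-learn's multilayer perceptron, which implements
exactly this protocol.

## Synthetic data: what it emulates, what it does not

`generate_crystal` draws cells with lengths in [0.3, 1.2] nm and angles in
[70°, 110°] — representative of small-molecule organic cells — rejecting
cell matrices with condition number above 10 to keep the normalization
well posed. It places the exact fractional motif of the requested type,
optionally jittered by η (uniform in [−η, η] per fractional coordinate, one
draw per base centroid so boundary images stay consistent), and returns the
planted ellipsoid computed analytically from the same pull-back the
estimator uses — so at η = 0 recovery must be exact to round-off.

`generate_ml_dataset` draws molecules from a built-in pool of two dozen
small aromatics and aliphatics and produces targets from a seeded sparse
linear map of fingerprint bits (64 active bits per radius drawn from the
substructures realised in the pool, weights N(0, 0.05²) nm around base radii
0.55/0.40/0.28 nm) plus Gaussian noise, sorted descending. The base radii
and spread mimic the magnitude and ordering of radii estimated for real
polyaromatic crystals.

What passing tests therefore show: the geometry, topology and optimisation
machinery are correct on exactly the structures the model assumes. What they
do not show: performance on real crystals — real centroids are not exact
affine lattice images, real radii are not a linear function of fingerprint
bits, and a handful of pool molecules cannot stand in for thousands of
distinct structures.

## Numerical choices

- `boundary_tol = 1e-6` fractional: far above double-rounding noise, far
  below physical displacements; decides when a coordinate "is" on the cell
  boundary and earns a periodic image.
- Ball-containment and zero-persistence tolerances: 1e-9 relative.
- Exact-tie margin in classification: 1e-12 nm.
- Degenerate quadruples (coplanar/cospherical) in the miniball: handled by
  support-subset enumeration with containment filtering, no perturbation.
- Eigen-decomposition of Q uses the symmetric solver after explicit
  symmetrization, guarding against round-off asymmetry in Wᵀ R W.

## Known limitations

- A centroid sitting exactly on a cell face (C, F motifs) loses its
  periodic images under any jitter, because the boundary test is a sharp
  tolerance: classification degrades discontinuously for boundary motifs,
  continuously for interior ones (I). The monotone-robustness property is
  therefore stated and tested on the body-centred motif.
- The permissive `min` aggregation can accept near-diagonal spurious
  features against empty reference diagrams; use `max` when false positives
  are costly.
- Only the cubic crystal families are covered; hexagonal arrangements and
  orientation motifs (herringbone) are out of scope.
- Persistence computation enumerates all ≤ 4-point subsets and is not meant
  for clouds beyond a few dozen points.
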