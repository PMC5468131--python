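# Methods

## The estimation problem

A population's *realized niche* is modelled as a region of an
orthogonal climate space; the package estimates that region's volume,
its overlap with other populations' regions, and its geographic
footprint, from presence-only records and gridded environmental layers.
All statistics are defined on the *k* principal axes retained from a
correlation-matrix PCA of the environmental variables, so "volume" is
in PC-units^k and depends on the fitted transform; comparisons are only
meaningful between hypervolumes built in the same fitted space (the
pipeline guarantees this by construction).

## Climate space

- **Standardized (correlation) PCA**, not covariance: the eigenvalue > 1
  retention rule presupposes variables on unit variance, and the
  loadings table reports variable-component Pearson correlations, which
  for this PCA equal eigenvector x sqrt(eigenvalue).
- **Fit sample.** The PCA is fitted on all valid cells of the analysis
  extent (the union of the groups' 200-km buffers in the pipeline), not
  on occurrences: the axes should describe available climate, against
  which occupancy is compared.  The fit sample and any subsampling cap
  (default 50,000 cells, seeded) are recorded in the transform's
  provenance.
- **Determinism.** Eigenvector signs are fixed by requiring each
  component's largest-|loading| variable to load positive; ties resolve
  to the lowest variable index.
- **Cell assignment** of records is half-open, [west, east) x
  [south, north), with records exactly on the global east/north edge
  assigned to the last column / top row.  At most one record per cell
  and group is kept (first by input order): a cheap, deterministic
  guard against spatial pseudo-replication at grid resolution.

## Hypervolume delineations

Two supports are built from a group's score cloud:

- **bdw** (bandwidth 0.5 PC units by default): the union of hyperboxes
  {z : max_axis |z − x_i| ≤ 0.5} around the records — a hard Chebyshev
  kernel.  The volume of the union is estimated by drawing a source box
  uniformly, a point uniformly within it, and weighting each draw by
  1/multiplicity (the number of boxes covering the point):
  `volume = n_boxes · (2·bw)^d · mean(1/m)`, an unbiased estimator whose
  standard error is reported.  Accepting draws with probability 1/m
  yields points exactly uniform over the union; these form the
  hypervolume's point cloud.  Defaults: n_mc = max(1e5, 1000·n_boxes)
  (the pipeline caps this at 2e6 to bound runtime), cloud size 10,000.
  Multiplicities come from a Chebyshev-metric k-d tree and are exact.
- **mcp**: the convex hull of the scores.  Volume is exact (sum of
  |det|/d! over a Delaunay triangulation; cross-checked against qhull's
  own volume).  Uniform points are drawn by volume-weighted simplex
  choice and flat-Dirichlet barycentric coordinates — exactly uniform.
  Rank-deficient clouds raise an error naming the rank rather than
  silently collapsing a dimension, because a degenerate hull would make
  volume comparisons meaningless.

Membership tests (`contains`) use the same geometry (nearest-source
Chebyshev distance; facet half-spaces) with an absolute tolerance of
1e-9, scaled by the coordinate magnitude for mcp.

## Overlap statistics

The intersection of two hypervolumes is estimated symmetrically:
`I = ½·[frac(A-cloud ∈ B)·|A| + frac(B-cloud ∈ A)·|B|]`, with binomial
standard errors propagated.  Because each cloud is exactly uniform,
each term is unbiased; symmetry holds by construction, and disjoint
supports give exactly zero.  The Soerensen index 2I/(|A|+|B|) is
clipped to [0, 1] only when Monte Carlo noise overshoots, and the clip
is recorded.  Centroid distance is the Euclidean distance between cloud
means.  "Per-axis contribution" — not a standardized quantity in the
literature — is implemented as the cloud's span along each axis divided
by the span along the first axis, so the first axis always reads 1.00;
the definition is deliberately simple and isolated in one function so
it can be swapped.

Univariate density profiles use a Gaussian kernel with the
normal-reference bandwidth h = 1.06·σ·n^(−1/5) per group, evaluated on
a shared grid spanning the pooled range ± 3 bandwidths.

## Geography

Buffers are great-circle: a cell belongs to a group's background if its
center lies within radius (200 km default) of the nearest record on a
sphere of radius 6371.0088 km.  Cell centers and records are compared
via unit-sphere chord lengths (monotone in the central angle, hence
exact for thresholding); ellipsoidal corrections (< 0.5%) are ignored
as irrelevant at a 200-km scale.  Background points are drawn uniformly
over masked cells, without replacement when possible (the branch is
recorded), and presence cells are excluded by default.

Projection scores every valid cell's environment with the PCA and tests
hypervolume membership, yielding a {0, 1, nodata} raster; crosswise
projection emits every train x target region combination.  Evaluation
drops (and counts) points on nodata cells, then computes the
tie-corrected rank AUC, the point-biserial correlation (defined as 0
for a constant prediction), and Cohen's kappa.  Binary predictions make
the ROC a single operating point, so AUC = (sensitivity+specificity)/2
identically — the code asserts this identity in its tests rather than
inventing a graded score.

## The synthetic world and what it does (not) show

`synthetic.default_world()` builds the standing test bed: a 100x100
grid (0.25-degree cells), six climate layers, two longitude-half
regions.  Layers come in three pairs; each pair shares one latent field
(SD ~1) plus independent per-layer noise (SD 0.03), so within-pair
correlation is ~0.999 and the correlation PCA retains exactly one axis
per pair (eigenvalues ~{2, 2, 2, ~0}) — k = 3 deterministically.  The
latents are a latitudinal gradient and two seeded random fields with
uniform marginals (plus a small sinusoid for spatial texture).  Two of
the three latents must be random: any set of deterministic fields over
a 2-D map lies on a 2-D manifold in climate space, and a climate cloud
that cannot fill 3-D volumes would make volume estimation meaningless.
Uniform marginals keep the corners of niche boxes populated with cells.

A group's true niche is an axis-aligned box in stack-standardized
environment space.  The native box (half-width 1.2 z-units, centered)
admits ~1,600 of the 5,000 western cells; the invaded truth is the
native box rescaled by 0.65 and shifted by (0.2, 0.2, 0.15, 0.15, 0.1,
0.1) — a strict subset, emulating an introduced population occupying
part of the source climate envelope, which is also what makes the
crosswise "area of origin" check well-defined (the truth-box
intersection *is* the invaded box).  Occurrences are sampled uniformly
without replacement from qualifying cells: 1,200 native, 360 invaded.
The sizes are near-balanced deliberately: the Soerensen estimate is
sensitive to the *difference* in convex-hull coverage between the two
groups, and hull coverage of a box-truncated cloud rises from ~0.80 at
120 points to ~0.95 at 800 in three dimensions.

Ground truth for estimates made in PC space is the *image* of a truth
box under the fitted affine standardize-rotate-truncate map: the convex
hull of the 2^6 mapped box corners (exact, since affine maps take boxes
to polytopes spanned by corner images).  Image-image intersection
volumes are computed exactly by stacking both half-space systems,
finding a Chebyshev-center interior point by LP, and taking the hull of
the half-space intersection.  These oracles share no code path with the
Monte Carlo estimators they check.

What the synthetic world does **not** emulate: real spatial
autocorrelation ranges, anisotropy or climate-variable skew;
observation bias (records are uniform over suitable cells); niches with
soft boundaries (truth is a hard box); coastlines/nodata structure.
Passing tests therefore demonstrate estimator correctness under ideal
sampling, not robustness to survey bias.

Known, quantified estimator behaviour on this world: the mcp volume
under-recovers the image volume by ~9% (1,200 records at ~140 cells per
PC-unit³), and the native-invaded Soerensen estimate sits ~0.04 below
its analytic 0.431 — the hull-rim deficit enters numerator and
denominator asymmetrically.  The bdw estimate brackets truth from
above (kernel padding).  Both behaviours are properties of the
delineations themselves, shared with their R-ecosystem counterparts,
not implementation artifacts.

`synthetic.evaluation_world()` is a second configuration for
evaluation metrics: one group, whole-domain region, box half-width 0.7,
300 records.  Its niche covers ~5% of available climate, giving a
truth-matched model sensitivity 1 and specificity ~0.95 — a regime
where kappa is informative.  On the invasion world itself the native
niche fills ~25% of its buffer's climate space, which caps kappa near
0.6 *regardless of model quality*; prevalence, not skill, is the
binding constraint there, which is why evaluation sanity checks use the
rare-niche world.

## Numerical choices

- All randomness flows from explicit integer seeds; pipeline stages
  derive child seeds from the master seed via `SeedSequence([master,
  stage, index])` and record them in the manifest.  Reruns are
  byte-identical (no output carries a timestamp).
- Monte Carlo draws with n_mc below 100 per source box are accepted but
  flagged in `mc_meta["warnings"]`.
- Multiplicity at a sampled point is guarded to ≥ 1 (floating-point
  round-off in `x + u − x` could otherwise miss the generating box).
- Serialized hypervolumes print floats at 17 significant digits so the
  JSON + CSV round trip is exact.
- Polytope intersections treat LP radii below 1e-12 as empty.

## Limitations

- No reprojection: inputs must share a geographic lon/lat grid.
- The bdw kernel is a hard hyperbox at fixed bandwidth; Gaussian or
  adaptive kernels, and graded (non-binary) suitability surfaces, are
  out of scope.
- Hull-based volumes are negatively biased at small sample sizes (see
  above); no small-sample correction is applied.
- Density-profile background curves are cell-count weighted; no
  latitude area weighting (cells are near-equal-area at the package's
  intended scales).
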