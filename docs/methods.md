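# Methods

## Model

A cell is represented by (i) an ordered, implicitly closed, simple
polygonal contour in pixel or micron coordinates and (ii) the centre of
mass of its nucleus, required to lie strictly inside the contour.  The
contour becomes a cyclic degree-2 graph; the filtration function assigns
each vertex its Euclidean distance to the nucleus centre, and each edge
the maximum of its endpoint values (cell-wise constant sub-level sets, not
piecewise-linear interpolation).  Pixel coordinates are treated as points
of the real plane (pixel centres); only Euclidean distances are used, so
no half-open pixel convention is needed.  Pixel-to-micron conversion is a
uniform scaling d = n × s.

Connected components of the sub-level graphs are tracked with a union-find
sweep over edges sorted by entry value; merges follow the elder rule (the
component whose canonical representative — the vertex of lowest function
value — is older survives).  The resulting dimension-0 diagram is made
finite by *essential pairing*: the one essential component, born at
min f, is paired with the birth of the essential 1-cycle, which equals
max f because the cycle closes only when the last vertex enters.  A
generic radial function on a cycle with m local minima therefore yields
exactly m diagram points.

### Numerical conventions

* **Ties.**  When two merging components have canonical representatives
  with equal values, the one containing the lower vertex index survives;
  simultaneous events at one filtration value are processed vertices first,
  then edges in index order.  Real radial values are generic almost
  surely, so these choices only pin down determinism on degenerate input.
* **Zero persistence.**  A vertex entering an existing component (or two
  components merging at their common birth value) contributes no diagram
  point; the essential point is kept even when min f = max f (constant
  function → diagram {(c, c)}).
* **Cleaning.**  Maximal runs of consecutive vertices sharing the same x
  or the same y coordinate are collapsed to their two endpoints before
  filtering.  Only axis-aligned runs are collapsed — general collinearity
  is left alone — because staircase runs are an artefact of rasterised
  boundaries while oblique collinearity is genuine geometry.  Cleaning can
  shift component births upward by at most the removed vertices' value
  span; diagram stability bounds the effect on distances.  Cleaning is
  applied after micron conversion (uniform scaling preserves shared
  coordinates, so the order is immaterial).
* **Validity checks.**  Simplicity is verified at construction through
  shapely's segment test; a self-intersecting polyline is rejected rather
  than silently producing a graph with more than one cycle.  Boundary
  points count as *outside* in the point-in-polygon test, so a jittered
  nucleus centre is always strictly interior.

## Wasserstein distance between diagrams

Diagrams of different sizes are balanced by augmenting each with ghost
points: a point (b, d) may match the diagonal at Euclidean cost
(d − b)/√2 (its orthogonal projection), and ghost–ghost matches are free.
This is the standard persistence-diagram convention; an arbitrary constant
ghost cost would break the triangle inequality.  The assignment is solved
exactly with the Hungarian algorithm (scipy's `linear_sum_assignment`) on
the (n₁+n₂)² cost matrix of p-th power Euclidean costs; diagrams here have
at most a few hundred points, so no entropic or sliced approximation is
needed and results are deterministic.  Default p = 2.

## Baseline distances

* **Aspect ratio** — eigenvalues λ₁ ≥ λ₂ of the covariance of the centred
  vertices; A = λ₁/λ₂ ≥ 1, compared as |log A₁ − log A₂| because
  elongation is multiplicative.  A √(λ₁/λ₂) variant (ratio of standard
  deviations) is available behind a flag; the two differ by a factor 2 in
  log space and give identical rankings.
* **Fourier descriptors** — the contour is resampled to 256
  equal-arc-length points traversed counterclockwise (a common sampling
  convention is needed to compare cells with different vertex counts),
  centred so F₀ = 0, phase-normalised by arg F₁, and summarised by the
  harmonic magnitudes E₁..E_M (default M = 10).  Size is informative for
  cells, so no scale normalisation is applied.  The distance is the
  Euclidean norm of the magnitude difference (the root of the summed
  squared differences, so the measure is a metric).  Start-point
  invariance is exact up to the start-dependence of arc-length resampling,
  i.e. to ~10⁻⁴ on coarse polygons and to machine precision on
  equal-segment contours.
* **Elastic (SRVF) distance** — both contours are resampled to a uniform
  grid (default 128), centred, oriented counterclockwise and mapped to
  square-root-velocity samples q = c′/√‖c′‖.  The L2 distance is minimised
  over rotation (closed-form 2×2 Procrustes), the starting point (search
  over all cyclic grid shifts under rotation-only alignment), and
  reparameterisation (dynamic programming over monotone lattice paths with
  local slopes 1/3..3 and the √γ̇ weighting), alternating rotation and
  warping for at most 20 iterations or until the relative improvement
  falls below 10⁻⁶.  This is a deliberately simplified grid aligner, not a
  full Riemannian geodesic solver; because DP alignment is directional,
  the reported distance is the average of both directions, which restores
  exact symmetry.

## Clustering and purity

Agglomerative clustering operates purely on the distance matrix with four
linkages: average (UPGMA), single, complete, and a Ward variant in which a
cluster's SSE is the sum of squared distances to its *medoid* (the member
with least total distance to the rest) — centroids do not exist in a
general metric space such as diagram space.  Medoid-Ward merge heights are
not guaranteed monotone and are reported as computed.  Ties are broken
deterministically: medoids by smallest index, merge pairs lexicographically
by cluster id.

A dendrogram is cut into k clusters by removing the k−1 highest merges
(ties by merge order) and taking the connected leaf components; clusters
are named A, B, … by decreasing size.  The purity of a cluster C₁ within
another linkage's tree is (N − |O|)/(N − |C₁|), where O is the leaf set of
the subtree rooted at the lowest common ancestor of C₁.  This closed form
is the fixed point of the iterative definition — grow from a seed leaf by
absorbing each parent's subtree until C₁ is covered — and is therefore
seed-independent; a literal seed-walk is kept in the test suite and
checked against the closed form from every admissible seed.  A cluster
that is exactly a subtree (in particular any cluster scored against its
own tree, and any singleton) has purity 1; a cluster whose LCA is the root
has purity 0.

## Evaluation

* **cMDS** squares the distances, double-centres, and eigendecomposes
  B = −½ J D J; coordinates come from the top p positive eigenpairs.  The
  explained-variance denominator sums *positive* eigenvalues only:
  Wasserstein matrices are generally non-Euclidean and produce negative
  eigenvalues that would make the fractions uninterpretable.
* **ROC** treats every unordered pair of cells as a trial, positive when
  both share a group.  Thresholds sweep the sorted unique distances with
  pairs at the threshold counted positive (ties collapse to a single ROC
  vertex); AUC is the trapezoidal area and pAUC10 the unnormalised
  trapezoidal area up to a false-positive rate of 0.1 (maximum 0.1).  AUC
  is a rank statistic, hence invariant under monotone transforms of the
  distances.
* **Sensitivity** jitters every nucleus centre uniformly in [−s, s] per
  axis, rejection-sampling (up to 10 000 draws) until the point is
  strictly inside the contour, then recomputes all diagrams and the
  distance matrix.  Reported per noise level: the relative Frobenius
  change δ(s) = ‖D(s) − D(0)‖_F/‖D(0)‖_F and the ROC AUC of each supplied
  labelling, as mean ± SD over repeats (default 20).  One integer seed
  governs the whole experiment; each (repeat, level, cell) triple derives
  its own counter-based stream, so results are independent of iteration
  order.

## Synthetic data

The generator emulates segmented fluorescence outlines as star-shaped
polygons r(θ) = mid + amp·cos(lobes·θ), stretched along x by an elongation
factor, with radial Gaussian boundary noise truncated at 3 SD and capped
below r_in/4 — radial noise preserves star-shapedness about the origin, so
every generated contour is simple by construction and the origin is always
a valid interior base point.  Optional pixelation rasterises the polygon
(a pixel is foreground when its centre is inside), regularises the mask
(largest 8-connected component; diagonal-only 2×2 checkerboards filled),
traces the outer boundary with the Moore neighbourhood from the
lexicographically smallest boundary pixel, and prunes one-pixel spurs so
the trace is a simple cycle of pixel centres with realistic axis-aligned
staircase runs for the cleaning step.

The bundled demo pair (`example_populations`) contrasts large 4–6-lobed
stars (radii ~8–30 µm, emulating spread star-shaped primary cells) with
small smooth ellipses (radii ~2–7 µm, elongation 1.3–1.8, emulating a
compact epithelial-like line).  Population sizes, lobe counts, radii and
noise are drawn per cell from per-index substreams of the population seed,
so generation is bit-reproducible and order-independent.

What the generator does **not** model: boundary texture and filopodia-like
fine protrusions, segmentation errors, nucleus off-centring (the base
point is the star centre), correlations between size and shape, or image
noise.  Tests passing on these fixtures demonstrate the correctness and
invariances of the machinery and its behaviour on cleanly separated versus
exchangeable populations — not performance on real micrographs.

## Problem sizes

Default analysis scales were chosen to match the intended population sizes
(tens to a few hundred cells): contours of 64–128 vertices, diagrams of
tens of points, 60-cell populations for the clustering/purity and ROC
demonstrations, 20 repeats for the sensitivity experiment, and 50 random
matrices of 100 objects for the label-independent ROC baseline.  All
property suites (Wasserstein vs brute-force assignment on ≤5-point
diagrams, persistence vs a level-by-level union oracle, linkage vs naive
re-scan and scipy, cMDS round-trips) run at these scales in seconds.

## Known limitations

* The elastic aligner restricts γ to monotone lattice paths on the grid
  and searches starting points coarsely; it approximates, and slightly
  overestimates, the continuum elastic distance (reparameterisation
  residuals ≲10⁻² on 128-point grids).
* Medoid-Ward heights can invert, so its dendrograms are interpreted
  through cuts and purity rather than heights.
* Purity compares one flat clustering against trees; it does not measure
  tree-to-tree similarity globally.
* The pipeline consumes contours; extracting contours and nucleus
  centroids from images is out of scope.
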