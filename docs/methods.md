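# Methods

## Problem and approach

Street trees scanned from a moving vehicle (mobile laser scanning, MLS)
arrive as dense, ground-removed 3D point clouds in which individual trees
must be isolated before any inventory parameter — height, diameter at
breast height (DBH), crown diameter, crown area — can be measured.  Two
failure modes dominate naive density clustering of such scenes:

* **over-segmentation** — occlusion by foliage or traffic deletes a band of
  trunk returns, so one tree falls apart into a trunk stub and a floating
  crown fragment;
* **under-segmentation** — adjacent crowns touch, so two or more trees fuse
  into one cluster.

The pipeline is hierarchical: a deliberately permissive pre-segmentation
followed by two topology-driven correction passes, then morphometry.

### Pre-segmentation

DBSCAN (defaults `eps = 0.6 m`, `min_pts = 10`) clusters the scene by
density reachability.  Each cluster is then classified *linear* or
*nonlinear* with a RANSAC two-point line fit at a 0.4 m point-to-line
distance threshold (clusters of ≤ 50 points are searched exhaustively over
all point pairs, larger ones with 200 seeded random pairs; a cluster is
linear when ≥ 90% of its points are inliers).  Small clusters are discarded
by the one-third rule: with *m* the mean point count of the *nonlinear*
clusters, any nonlinear cluster with fewer than *m*/3 points is noise.
Linear clusters are exempt from this rule — that is the point of the
linearity check.  A trunk stub left under an occlusion gap is both small
and line-like; dropping it would turn an over-segmented tree into a
truncated one.  Stubs stay alive for the merge pass, and linear clusters
that no merge absorbs (lamp posts, sign posts) are discarded afterwards as
pole-like interference.

### Over-segmentation: footprint-overlay merging

Fragments of one tree stack vertically, so their XOY (horizontal-plane)
convex footprints nest.  For each cluster pair the *containment* —
area(∩) / min(area₁, area₂) — is computed with exact polygon clipping; pairs
with containment ≥ 0.9 are merged, and the relation is closed transitively
with union-find so any number of fragments collapse at once.  Containment
rather than IoU is used because a small fragment inside a large crown has
near-zero IoU but containment ≈ 1.  Degenerate (collinear) footprints fall
back to a point-in-polygon fraction.

### Interference removal: trunk Z-voxel skeleton

Each merged cluster is sliced into 0.25 m Z slabs.  The radially tightest
slab (95th-percentile distance about its own centroid) is taken as a pure
trunk cross-section; its centroid fixes the trunk axis.  The crown base is
the top of the highest *narrow* slab below the widest slab, where narrow
means a 95th-percentile radius within max(2×, +0.2 m) of the tightest
slab's.  Width, not point count, marks the crown onset: an ellipsoidal
crown widens immediately above its base while its point count ramps up
only gradually, and a count-jump criterion was found to place the base a
meter or more too high, after which the interference filter clipped crown
points (per-tree F1 fell to ≈ 0.91 on clean synthetic trees).  Below the
crown base, points farther than a radius cutoff (2 × fitted breast-height
radius + 0.2 m by default) from the axis are rejected as trunk-hugging
distractors; above the crown base nothing is ever rejected, and the
kept/rejected sets always partition the cluster.

### Localization and under-segmentation splitting

Within each cluster, the breast-height slab — points 1.25–1.35 m above the
cluster's lowest point, the root-collar proxy after ground removal — is
split into XY connected components (single linkage, 0.5 m) and each
component is fitted with the algebraic least-squares circle: minimize
Σ(x² + y² + Ax + By + C)², recover center (a, b) = (−A/2, −B/2) and radius
r = √(a² + b² − C).  The fit is linear, exact on noiseless circles, and its
center is the tree's planimetric position; 2r is the DBH.  Fits with radius
outside [0.03, 1.5] m are discarded (sign posts at breast height produce
near-collinear slabs whose fitted radii are enormous, so the gate also
rejects them).

A cluster with ≥ 2 accepted fits holds several trees.  Its XY coordinates
are rotated about Z so the trunk-connection line (for > 2 trunks, the first
principal direction of the centers) lies along +u, point counts are binned
into 0.5 m voxels along u — the lattice anchored at the first trunk so bin
edges are tied to the trunk geometry, not to whichever crown tail reaches
farthest — and between each adjacent trunk pair the cluster is cut at the
center of the minimum-count voxel (ties resolved toward the pair's
midpoint; fewer than two whole voxels between trunks falls back to the
midpoint with a warning).  Splitting conserves points exactly.

### Morphometry

Per tree: height H = max z − min z; stand average height = arithmetic mean;
DBH = 2r of the breast-height circle fit; crown extent from the 2D convex
hull of the whole tree's XY projection, built with the quickhull recursion
(X-extreme chord, recursive farthest-point promotion) and cross-checked in
tests against an independent brute-force hull; crown diameter = maximum
vertex spacing (equal to the max pairwise distance over all points); crown
area = shoelace area of the hull.  The hull is computed on the whole tree
rather than crown-only points — trunk points are interior and do not move
it.  Quantities that cannot be computed (a crown-only fragment has no
breast-height slab) are NaN with a flag, never fabricated.

### Evaluation

Point-level, per matched tree: P = tp/(tp+fp), R = tp/(tp+tn),
F1 = 2PR/(P+R), where tp counts shared points, fp extra points claimed, and
the quantity written tn — the symbol kept from the reporting convention of
the segmentation literature — counts the truth tree's points the prediction
*missed* (false negatives in standard confusion-matrix terms; literal true
negatives would make R meaningless).  Predictions are matched to truth
trees greedily by overlap, each truth tree claimed at most once;
truth-noise points are excluded from denominators; scene averages are
unweighted.  Tree-level: a truth tree is detected (tp) when > 80% of its
points land in its matched prediction, failed (fp) below 50%, partial (tn)
between.  Crown polygons are compared by area IoU (AIoU).

## Synthetic scenes

The generator emulates the geometry the pipeline assumes: trunks as
cylinder-*surface* samples (2000 pts/m²), crowns as ellipsoid-*volume*
samples (500 pts/m³ — MLS crowns return points throughout the canopy),
isotropic Gaussian jitter σ = 0.01 m, trees planted 8 m apart along a
street axis with heights 6–13 m, trunk radii 0.05–0.15 m, crown radii
1.8–3.0 m, crown bases 2.2–3.5 m.  Optional content: a flat ground plane,
and pole-like distractors (sign 0.5×0.05×1 m at 1–2 m height, lamp-post,
box) placed 0.5–1 m from trunks.  Defects: `trunk_gap` deletes a ~1 m
z-band of trunk returns (the over-segmentation case) and `glued_pair`
plants trees 0 and 1 at 4 m with crown radii of gap/2 + 0.15 m, i.e.
crowns interpenetrating by ~0.3 m (the under-segmentation case).

The touching-crowns default is deliberate.  For uniform-density ellipsoid
crowns the 1D marginal along the trunk axis is parabolic, so when two
crowns interpenetrate deeply the mixture's density minimum sits at the
*sparser crown's support edge*, not between the trees, and any planar cut
at a density valley must misassign the larger crown's overhang.  The
density-valley split targets the planted-street situation of crowns that
touch; heavily fused canopies are outside its operating envelope, and
scenes are generated accordingly.

What the generator does not emulate: scanner trajectory and view-dependent
occlusion (the trunk gap is carved geometrically), intensity/RGB, foliage
clumping and branch structure, wind-blown asymmetric crowns, understory
vegetation.  Passing the recovery tests therefore shows the pipeline's
geometric logic is correct under its stated assumptions, not that the
default parameters transfer to every real scanner or species.

## Numerical choices

* Circle fit: normal equations solved by `lstsq`; collinear slabs detected
  by rank and reported as errors, as are fits with r² ≤ 0.
* RANSAC: exhaustive for ≤ 50 points (deterministic regardless of seed),
  seeded `default_rng` sampling otherwise; all stochastic steps accept a
  seed and defaults are fixed in the config.
* Noise-rule ties at exactly m/3 are retained (the rule drops strictly
  "below").
* Boundary-voxel ties go to the voxel nearest the trunk midpoint.
* Ground filter: 1 m grid-minimum with 0.3 m margin — simple plumbing, not
  a cloth simulation; pre-filtered clouds are first-class inputs.
* DBSCAN, single-linkage sub-clustering, polygon clipping and hull oracles
  are delegated to scikit-learn, SciPy and Shapely; the circle fit, the
  quickhull construction, the skeleton and the density-valley split are
  implemented here.

## Problem sizes

Default scenes run ≈ 400 k points (10 trees); the test suite exercises the
full pipeline on 6-tree scenes at reduced crown density (150 pts/m³) and
reserves default density for the acceptance checks, which process one
10-tree defect scene end-to-end in under a minute on one core.

## Known limitations

* Breast-height slabs are referenced to the cluster minimum z; on sloped
  streets a single z-reference per tree is coarse, and a DTM-based height
  normalization should precede the pipeline.
* The density-valley split cuts with a plane; interlocking crown lobes are
  assigned to the wrong tree near the cut.
* Trees shorter than ~1.4 m have no breast-height slab and are reported
  located-by-centroid with DBH flagged unavailable.
* A pole glued to a trunk and reaching into the crown defeats the
  radial-width crown-base rule (every slab looks wide); such clusters pass
  through uncleaned.
* LAS/LAZ I/O is not included; ASCII XYZ and PLY are.
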