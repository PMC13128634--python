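# Methods

This note records the models, parameter choices and numerical conventions
behind `splatphen`, and what the synthetic test suite does and does not
demonstrate.

## Scene model and projection

A 3DGS scene is a set of Gaussian primitives (μ, Σ, ω, c) with
Σ = R_q·diag(exp(ℓ))²·R_qᵀ from per-axis log-scales ℓ and a unit
quaternion q, opacity α = σ(ω), and color taken from the spherical-harmonic
DC band only (rgb = 0.5 + 0.2821·c, clipped to [0,1]). Higher-order SH is
preserved through PLY round trips but never evaluated: every stage that
uses color needs one color per Gaussian.

Projection follows the EWA splatting linearization: cov2d = J W Σ Wᵀ Jᵀ
with W the world-to-camera rotation and J the perspective Jacobian at μ.
Pixels are 0-based with centers at integer coordinates; a footprint is the
set of pixel centers inside the k_σ Mahalanobis ellipse (k_σ = 3 by
default, matching common rasterizer truncation), and the kernel is the 2D
Gaussian density at pixel centers renormalized to sum to one. Evaluating
at pixel centers rather than integrating over pixels is a deliberate
simplification; at the footprint sizes the pipeline operates on (several
pixels across) the difference is absorbed by the renormalization. A
singular projected covariance is dilated by 0.3 px² on the diagonal, the
standard 3DGS regularization.

## Lifting

The support score S(g) is the w-weighted mean of opacity-weighted masked
footprint fractions over seeded views (1–5 views in practice; the
synthetic suite uses 3). Choices worth recording:

* **Visibility proxy ᾱ(g,v).** Default is the splat's own opacity —
  deterministic and cheap. An optional mode composites a per-view
  accumulated-opacity map at quarter resolution front-to-back and averages
  it over the footprint; it accounts for occlusion but depends on the
  compositing approximation. Neither mode models inter-splat occlusion
  exactly.
* **Orientation term.** θ is measured against the eigenvector of the
  smallest eigenvalue of Σ — for flattened foliage splats this is the leaf
  surface normal. Eigenvectors have no sign, so |cos θ| is used before the
  max(·, 0) clamp; when the two smallest log-scales agree within 1e-9 the
  orientation is uninformative and the term is set to 1.
* **Foreground threshold.** τ is the ⌊qN⌋-th order statistic of S rather
  than an interpolated quantile, so |F| = N − ⌊qN⌋ plus ties, any q below
  1/N keeps the whole scene, and the selected set is always a subset of
  observed score levels. Default q = 0.88 (top 12%).
* Views where a splat is behind the camera or fully clipped contribute to
  neither the numerator nor the denominator; if no view is valid, S = 0.
* Multiple masks with the same view index are OR-combined before scoring:
  they are fragments of one target.

## Clustering

Descriptors are per-axis robust standardizations Z(s) = (s − median)/MAD
of x, y, z and the mean camera distance r̄ over the views whose frustum
contains the splat (no occlusion test; a splat seen by no camera falls
back to all views, logged). MAD = 0 maps to all zeros with a degenerate
flag. Note that per-axis standardization is equivariant to translation,
uniform scaling and axis permutations, but not to arbitrary rotations —
descriptors assume a roughly axis-aligned, gravity-consistent scene frame,
which SfM reconstructions of row crops deliver.

OPTICS runs with ξ = 0.1 and min_samples = max(15, 0.005·|F|). Two
departures from the most literal reading of the ξ-method are deliberate:

* **Coarse hierarchy extraction.** The ξ-method produces a hierarchy of
  reachability valleys. Leaf-level labels over-segment a plant into
  organ-scale micro-valleys and can leave most of the foreground as noise;
  the maximal non-nested spans of the hierarchy are used instead. The span
  covering the entire ordering counts as a cluster unless its child spans
  already partition ≥ 50% of the ordering (then it only bridges them).
* **min_samples floor of 15.** At desk-scale foreground sizes (hundreds of
  splats) a floor of a few points lets single leaves become clusters.

The plant cluster is the one with maximal summed lift score (ties: larger
cluster, then lowest id) — cue mass, not size, identifies the target.
Merging uses the 90th percentile of the selected cluster's
point-to-centroid distances and a 15% relative median-depth window; noise
(label −1) is never merged. If ξ-extraction yields no cluster at all, the
fallback cluster is the contiguous ordering segment around the global
reachability minimum with reachability below the median (logged; not
observed on the default suite).

NN-retain restores scene splats (including lift-rejected ones) within
r_nr = β·d̃_1NN of the kept set, β = 2, computed in raw world coordinates
in a single pass — restored splats do not extend the search radius.

## Chromatic refinement

A full-covariance GMM (k = 1..4 by BIC, k-means init, fixed seed,
reg_covar = 1e-6) models the kept set's Lab colors; sets above 50,000
points are subsampled by quantile-cell stratification (8 quantile bins per
channel, proportional allocation with largest-remainder rounding). The
window τ(ζ) is the ζ-quantile of squared Mahalanobis distances of the
dominant-assigned points, and the D² ≤ τ test is applied to *all* kept
points — a point assigned to another component but chromatically
compatible with the dominant one survives. ζ = 0.80 by default, 0.90 in
relaxed mode for recall-sensitive training-data export.

Two properties of this empirical-quantile window matter in practice. On a
continuous color distribution it removes exactly (1 − ζ) of the
dominant-assigned points — the coverage-calibration test verifies
ζ ± 0.05 on 10,000 Gaussian Lab points. On a distribution with a heavy
color atom (many splats sharing nearly one color, as converged DC colors
of a homogeneous canopy do) the quantile lands inside the tie mass and the
window keeps the entire atom while still removing chromatic outliers; this
is what makes the filter nearly lossless on real foliage. Re-estimating τ
on the filter's own output would cut again; idempotence holds at a fixed
window, so `chroma_filter` accepts an explicit `tau`.

Point-cloud export samples n_i = max(1, round(density·α_i)) points per
Gaussian from N(μ, Σ) truncated at 2σ per principal axis (unbounded tails
would corrupt nearest-neighbor spacing statistics downstream).

## Organ grouping and remapping

Grouping operates in the density-normalized frame x′ = c + (x − c)·Δ/s
(c = per-axis median, s = median mean-8-NN spacing, Δ = 0.02) with linking
radius r = γΔ, γ = 2.5, min_points = 30; components are exact connected
components of the radius graph (KD-tree pair enumeration + union-find;
verified against a brute-force all-pairs oracle). Semantics are an input
contract — per-point class + logits from any upstream segmenter; a toy
geometric classifier (linearity×verticality vs planarity of local
neighborhoods) ships for end-to-end demos only.

Remapping assigns each visible splat (α > τ_op = 0.05, strict) the labels
of its nearest labeled point within r_assign = α_r·d_med (α_r = 3, d_med =
median NN spacing of visible splats, world frame, labels carried back
through the inverse normalization), then reapplies the strict ζ = 0.80
chromatic window to the assigned set. γ, Δ, α_r and τ_op are fixed-scale
parameters calibrated on the synthetic suite and exposed in the config.

## Metric frame and traits

The similarity transform x′ = sRx + t takes its scale from a reference
pair of known length (default 0.42 m, a rack-width-style calibration
object) and its rotation from a robust plane fit (iterative 2.5σ clipping)
to the lowest 10% of points, rotated to +z and shifted to z = 0; under 50
candidate points or inliers the alignment falls back to identity with a
warning.

* **Height** is the maximum of a top-down per-cell max-z raster (cell =
  median NN spacing) after a grayscale morphological filter with a
  2-cell-radius disc. The default operator is closing; closing preserves
  bright peaks, so a separate `opening` mode exists for suppressing
  isolated spurious apex artifacts — the two readings of "suppress
  spurious peaks" are one flag apart, and the tests exercise both.
* **Leaf area** fits an opacity-weighted PCA plane per leaf instance,
  projects each member ellipsoid to a 2D covariance B·Σ·Bᵀ, discretizes
  the k_σ ellipse (k_σ = 2.0, calibrated on synthetic discs — area scales
  quadratically with it, so it is exposed) as 16 boundary points + center,
  and takes the α-shape area (Delaunay triangles with circumradius ≤
  alpha_len, default 4·d_med) of the pooled points. Collinear instances
  get area 0 with a flag. LAI divides the summed area by A_plot
  (default 0.036 m² = π(0.214/2)²).
* **Leaf count** merges instances whose centroids fall within one median
  NN spacing (single-link, transitive) and drops merged areas below 1 cm².
* **Skeleton.** The stem centerline comes from kNN-mean Laplacian
  contraction (λ = 0.5, k = 12, 8 iterations) of the dense sampled stem
  cloud — contracting the sparse splat centers instead collapses them into
  blobs, and more iterations over-contract and fuse attachment branches of
  nodes ~2 cm apart. The contraction has a radial noise floor of order
  r/√k, so centerline nodes sit near, not on, the true axis. Nodes are a
  farthest-point subsample at 2·d_med spacing.
* **Internodes.** A complete-graph MST with weights
  ‖e‖·(2 − |cos∠(e, d_local)|), d_local the principal direction of each
  node's 6-neighborhood (the two endpoint terms are averaged — "the
  incident node" is ambiguous for an edge); main axis = tree path between
  the lowest and highest node (which maximizes |Δz| over endpoint pairs);
  junctions = axis vertices of degree ≥ 3 whose side branch is at least
  3× the median MST edge long (shorter twigs are residual-thickness
  artifacts), plus attachment hints snapped to their nearest skeleton node
  and walked along the tree to the axis; junctions closer than one median
  edge along the axis merge. Internode j is the along-path arc length
  between consecutive junctions. A stem with no side branches reports 0
  nodes and no internodes.

## The synthetic generator

`synth.make_scene` emulates: plant grids at 0.72 m within-row spacing;
node counts ~ round(N(6.9, 2.1)), internode spacings ~ N(3.7, 0.9) cm and
disc-leaf areas ~ N(74.9, 22.8) cm², each truncated to the observed
cohort ranges (3–16 nodes, 1.9–6.1 cm, 39–122 cm²); stems as elongated
Gaussians along an arc-length-parameterized wobbly vertical path with a
short petiole per junction; leaves as patches of flattened Gaussians
(short axis = disc normal) with a rim ring so the realized extent matches
the nominal disc; ground/pot/trellis background (≥ 60% of splats); two
10-pose camera passes at 0.5 m and 1.5 m height; a 0.42 m calibration pair;
a global fake reconstruction scale (1.19) so metric alignment is
non-trivial; cue masks as unions of 2σ projected ellipses with dilation,
clutter rectangles and dropout as noise controls. Ground-truth internodes
are exact arc lengths (the path is built at 2 mm arc steps), ground-truth
LSA is the exact sum of nominal disc areas, and ground-truth height is the
realized apex height after position jitter.

Colors are sampled in CIELAB and converted to DC coefficients. Each
material carries one exact per-scene color; a 3% "color-bleed" fraction
receives continuous Lab jitter. This reflects how converged DC colors of a
homogeneous material concentrate, and it is load-bearing: with a dominant
color atom the ζ-window keeps essentially all plant splats (see above),
which is the regime in which the refinement stage is nearly lossless. What
the generator does *not* emulate: view-dependent color, illumination
gradients and shadows (which spread real DC colors), occlusion between
plants, SfM pose error beyond the global scale, floaters, and the long-tail
splat-size distribution of real reconstructions. Passing the suite
therefore demonstrates the algorithmic contracts of each stage and their
composition — not performance on real greenhouse reconstructions, whose
color spread in particular would make the ζ-window trade recall for
precision as the coverage calibration predicts.

Default problem sizes (scenes of ~2,500–3,000 splats, three plants,
20 cameras at 200×150 px, five suite seeds) were chosen so the entire
suite — including the staged precision-recall sweeps and trait recovery —
runs in a few minutes on one CPU; all stages are O(N) to O(N log N) in the
splat count except OPTICS (quadratic worst case), so the pipeline scales
to full reconstructions without structural change.

## Evaluation conventions

Extraction metrics are splat-level target-vs-rest counts; neighbor plants
count as background; mIoU averages the plant-class and background-class
IoU (the two-class reading; plant-only IoU is recoverable from the
confusion counts). Empty predictions report precision 0 with a flag.
Instance AP50/AR50 uses confidence-ordered greedy one-to-one matching at
point-set IoU ≥ 0.5 and all-point interpolation of the P-R curve; classes
with no ground-truth instances are skipped in the mean. P-R sweeps vary
the lift quantile over the top 2–20% and re-run whichever stages are
enabled downstream.

## Known limitations

* Cue quality bounds everything: the lift stage cannot recover a plant
  part absent from every seeded mask unless clustering/retain pull it in
  geometrically.
* The descriptor standardization assumes a gravity-consistent frame (see
  above); heavily tilted reconstructions should be aligned first.
* Junction detection resolves internodes down to roughly the centerline
  node spacing; internodes shorter than ~2 cm at the default sampling
  merge into their neighbors.
* The chromatic window assumes the plant is the dominant color mode of the
  kept set; a scene where background dominates the kept set after
  clustering would invert the filter's effect.
* Per-leaf area depends quadratically on the projected-ellipse extent
  k_σ; the default 2.0 is a synthetic-disc calibration, not a measured
  constant of real foliage.
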