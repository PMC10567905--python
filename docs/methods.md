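# Methods

This note documents the models, algorithms and design choices behind
`crownfit`, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Geometry model and units

All geometry is carried in millimetres; fit metrics are converted to
micrometres (×1000) only at reporting time, matching how marginal and
internal discrepancies are conventionally tabulated. STL files carry no
units, so the unit label is a configuration field defaulting to mm and is
logged on every load. Meshes are cleaned on load: vertices within 1e-6 mm
are merged (well below scanner noise; removes STL facet duplication) and
faces with area ≤ 1e-12 mm² are dropped.

## Exact surface distance queries

Every distance to a mesh is an exact point-to-triangle minimum. The
accelerated path prunes candidates with the bound
`|p − centroid_f| − r_f ≤ d_vertex`, where `r_f` is the face bounding-sphere
radius and `d_vertex` the k-d-tree distance to the nearest vertex; the true
minimizing face always survives the pruning, so the result provably equals a
brute-force scan over all faces (the suite asserts bit-level agreement,
including the chosen face, with ties broken by lowest face index). Faces
whose bounding radius exceeds 3× the median are kept aside and checked
exactly against every query, so a few oversized triangles cannot inflate the
pruning radius for the whole mesh.

## Margin curves

Margin landmarks (50 by convention) are ordered by projecting onto their
best-fit plane (SVD principal axes with deterministic sign fixing) and
sorting by polar angle about the projected centroid. This assumes the margin
is a near-planar ring — true for the molar-like geometry modelled here — and
the failure modes are detected explicitly: collinearity, ring-radius spread
above 90% of the mean, or angular collisions below 1e-6 rad all raise an
ordering error advising manually ordered input.

Resampling places n points at equal arc length along the closed polyline.
Note that resampling a polyline can only shorten it (samples cut corners);
the length is reproduced exactly when every original vertex is itself a
sample and to well under 1% once curves are densified (n = 500 default).

The marginal ROI band (faces within 0.5 mm of the margin curve, the
alignment region) measures distance point-to-polyline in 3D rather than
along the surface; at the 0.5 mm scale the difference is below faceting
error on the fixtures used here. A face with a vertex exactly on the curve
always counts as inside, so a zero-height band degenerates to the ring of
faces touching the margin.

## Marginal fit

The absolute marginal discrepancy is the unsigned symmetric Hausdorff
distance between the abutment and crown margin curves: the larger of the two
directed maxima of nearest-point distances. The default evaluates densified
curves (500 samples each) with exact point-to-segment distances, so the
metric is stable under further densification; a point-set mode evaluates the
raw annotated landmarks instead (max–min over points), which is also the
semantics used for degenerate inputs too small to form a curve. The
under/over-extension direction is exposed only as a signed diagnostic (the
radial sign at the attaining point); it never enters the headline metric.
The per-crown statistic is the single maximum; a mean-gap diagnostic is
reported alongside for context.

## Registration

`kabsch_align` is the standard SVD solution restricted to proper rotations;
configurations whose cross-covariance is rank-deficient (collinear points)
are refused. `trimmed_icp` implements the reference best-fit principle:
correspondences are source-vertex → target-surface (exact point-to-triangle,
more accurate than vertex-to-vertex at unequal resolutions), pairs beyond
the inlier threshold are discarded, and a Kabsch update follows. The
threshold is a visible knob defaulting to 0.5 mm; iteration stops when the
trimmed RMS changes by less than `tol` (1e-5 mm default) or after `max_iter`
(100 default). Because the inlier set can grow as alignment improves, the
RMS over inliers is not a strictly monotone quantity; the implementation
therefore tracks the best objective seen, returns that state, and reports
the accepted (improving) history, which is non-increasing by construction.
Ties in closest-face selection go to the lowest face index, making the whole
procedure deterministic. No scale is ever estimated: fit discrepancies must
not be absorbed by scaling.

Crown placement in the pipeline uses cyclic-correspondence Kabsch between
the crown and abutment margin curves: both are resampled to 50 points and
every cyclic shift in both traversal directions is tried. A near-planar ring
matches its mirror image almost as well as itself, so candidates that map
the crown interior to the wrong side of the reference margin plane are
rejected. ICP refinement of the crown against the abutment is available
behind a flag but is off in the measurement pipeline: ICP minimizes exactly
the distances being measured, and on the synthetic fixtures it measurably
pulled the crown into its own cement gap (several μm low). Trimmed ICP is
instead exercised where reference best-fit belongs — registering the
abutment margin ROI onto the reference mesh.

## Internal fit

Poisson-disk sampling is plain dart throwing: a candidate face is drawn with
probability proportional to area, a uniform barycentric point is drawn on
it, and the candidate is accepted iff no accepted sample lies within the
disk radius (exact check via a spatial hash with cell size equal to the
radius). Sampling stops after 1000 consecutive rejections, which in practice
saturates the surface: the suite checks that no vertex is farther than two
radii from a sample. The default radius of 0.15 mm yields thousands of
samples on a molar-scale crown; the seed is mandatory.

The gap at each sample is, by default, the exact shortest Euclidean distance
to the opposing abutment surface — the standard cement-gap reading — signed
by the side of the closest outward-oriented abutment triangle (+ open space,
− interpenetration; inconsistent winding is refused). A literal
graph-shortest-path mode (`edge_graph_geodesic`: Dijkstra over the union of
both vertex adjacency graphs plus bridging edges from each sample to its 3
nearest abutment vertices) is provided for sensitivity analysis; it can
never undercut the Euclidean minimum. Histograms use 50 equal bins from 0 to
the 99.5th percentile, with out-of-range values clipped into the edge bins
so counts always conserve the sample count. Colour-deviation maps
interpolate per-vertex scalars from the 8 nearest samples by inverse
distance and use a blue-white-red diverging ramp symmetric about zero,
clipped at ±300 μm by default.

The pipeline measures the internal-fit field over the intaglio region at
least 0.6 mm above the margin plane — the designed spacer region, above the
0.5 mm seal zone plus the 0.1 mm spacer onset blend. Measuring over the
whole intaglio would fold the near-zero seal-zone gaps into the mean and
understate the designed spacer; restricting to the spacer-active region
makes the mean gap directly comparable to the design parameter (the
parameter-recovery tests rely on this, and the 0.5 mm boundary mirrors the
ROI convention used for alignment).

## Synthetic study conditions

The generator stands in for scan data with an idealized prepared molar: a
body of revolution with a concave chamfer margin band (1.0 mm wide), an
axial wall (vertical at the default radii: base 4.5 mm, top 3.5 mm, height
5 mm), and a flat occlusal table with a 0.5 mm edge fillet. Anatomy is
deliberately not modelled — metric correctness is what is under test, and
analytic gap oracles require simple geometry. Target edge length defaults to
0.1 mm; the chamfer must be resolved by at least two edges.

The crown intaglio offsets the abutment along outward vertex normals by the
cementation spacer (default 40 μm), engaging 0.5 mm above the finish line
with a 0.1 mm smoothstep blend — the standard CAD spacer convention.
Distortions emulating sintering misfit are applied in a fixed order: an
occlusal doming lift (radial falloff equal to 1 over the table and decaying
across a 0.2 mm transition on the fillet, so labelled regions see either the
full lift or none), uniform shrinkage about the centroid, margin extension
(the margin curve and the rim vertices move radially outward, fading over
0.3 mm of height so the curve stays on the surface), isotropic Gaussian
vertex noise, and finally a seating transform. Ground truth is captured
before noise, so it records the noise-free nominal gap; distortion
distributions in cohorts are truncated at ±3 SD and clipped to physical
bounds. Per-crown seeds derive from the master seed through a spawned seed
sequence, making whole file trees byte-reproducible.

The two-cohort demo configuration gives the conventionally sintered group
larger occlusal doming (180 ± 25 μm vs 120 ± 15 μm) and margin extension
(0.30 ± 0.03 mm vs 0.25 ± 0.03 mm) than the high-speed group, with 5 μm
scanner noise and small random seating displacements (1° / 0.2 mm SD) —
the direction expected if conventional sintering shrinks more. These are
plausibility-scaled study conditions for exercising the pipeline, not a
calibration to any measured cohort; the synthetic group means and t values
carry no claim beyond internal consistency.

What the generator does *not* emulate: real tooth anatomy, physically based
sintering shrinkage fields, scanner artifacts beyond isotropic noise
(striping, holes, resolution anisotropy), soft-tissue or neighbouring-tooth
occlusion of the scan, and annotation error on landmarks. Passing tests
therefore demonstrate that the measurement chain recovers known geometric
ground truth through alignment, sampling and distance computation — not that
any particular clinical effect size would be detected in real scans.

## Statistics

The pooled (Student) two-sample t test is computed from first principles:
`sp² = ((n1−1)s1² + (n2−1)s2²)/(n1+n2−2)`,
`t = (m2 − m1)/(sp·√(1/n1+1/n2))`, `df = n1+n2−2`, and the two-sided p-value
through the regularized incomplete beta `p = I_{df/(df+t²)}(df/2, 1/2)`
(`scipy.special.betainc`); an independent scipy.stats oracle cross-checks
both routes in the tests, and a 10,000-pair Monte-Carlo confirms the null
rejection rate sits at α. The pooled form is the default because group
comparisons of this kind report `df = n1+n2−2`; Welch is available behind a
flag. The sign convention (group2 − group1, group1 first-listed) is recorded
in every report. p-values are stored at full precision and rounded only at
rendering. Normality is assumed, not screened; reports carry that note.

## Problem sizes and tolerances

The test suite and the acceptance script run the synthetic study at a target
edge length of 0.2–0.3 mm and n = 30 crowns per cohort (tests use 2–8), which
keeps a full run to about a minute while holding mesh-faceting error in the
recovered gap to ~0.3% — far inside the 2% recovery tolerances asserted.
Registration tests use an asymmetric ellipsoid rather than the frustum
because a body of revolution leaves azimuthal rotation as a gauge freedom,
making "transform recovery" ill-posed there; RMS-based checks hold on either
fixture. Noise-bearing assertions keep tolerances at or above three standard
errors of the corresponding estimate.
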