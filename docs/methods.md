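# Methods

This note documents the models implemented in morphopatch, the parameter
defaults and why they were chosen, what the synthetic fixtures emulate, and
the numerical choices a maintainer should know about.

## Thin-plate splines in 3D

The interpolant between source points X (k×3) and targets Y is
`f(p) = a₀ + A p + Σⱼ wⱼ U(|p − xⱼ|)` with the 3D kernel `U(r) = r` and the
non-affine weights W constrained to be orthogonal to the affine subspace
(`PᵀW = 0`, `P = [1 X]`).  Fitting solves the bordered linear system
`[[K − λI, P], [Pᵀ, 0]]`; note the **minus** sign on the regularization:
`U(r) = r` is conditionally *negative* definite, so the smoothing penalty
must oppose `−wᵀKw`.  With λ = 0 (the default, used for template warping)
the fit interpolates exactly; λ > 0 gives a smoothing fit whose residual is
monotone in λ, useful to rescue configurations with near-duplicate points.

The bending-energy quadratic form B is the upper-left k×k block of the
inverse bordered matrix, symmetrized, with its overall sign fixed at build
time so the form is positive semidefinite — conventions for the 3D kernel
differ across references, and the governing contracts here are: B is PSD,
annihilates affine configurations (rank ≤ k − 4), and
`tr(YᵀBY) = |tr(WᵀKW)|`.  Fewer than 5 points, or a coplanar source,
degrade gracefully to an affine-only fit with zero bending energy; this
also means configurations whose points are all collinear/coplanar have no
bending-energy signal, and sliding such fixtures requires the
Procrustes-distance criterion or out-of-plane anchor landmarks.

Linear solves use an LU factorization of the bordered system; the condition
number is checked and a warning logged above 1e12.

## Patching

`place_patch` fits the TPS from atlas fixed points (landmarks + resampled
curve points) to the specimen's, warps atlas surface points and the atlas
mesh (the intermediate model), displaces each warped point by
`inflate × n̂` along the warped template's normal at the nearest
intermediate-model face, then projects back by casting the line through the
inflated point along ∓n̂ against the specimen mesh.  Among all
intersections the hit with smallest |signed distance| wins, ties broken
toward the outward side; if the line misses entirely, the globally nearest
surface point is used (the route taken is reported per point).

*Inflate* is in absolute mesh units by default, because useful values are
specimen- and region-dependent; `inflate_relative=True` scales by the
specimen's fixed-point centroid size, which is the recommended mode for
samples with large size variation.  Patch failure — fixed points farther
from the specimen surface than 5×10⁻³ of the bounding-box diagonal, the
classic "floating curve point" — is returned as a value (`failed=True` with
the offending labels), not an exception, so batch runs complete and report.

`relax_to_atlas` optionally slides the placed points toward the atlas
configuration (fixed-reference bending-energy sliding in the tangent
plane, followed by re-projection).  It defaults to off: relaxation against
a template whose shape differs strongly from the specimen can move points
off their intended region, and the plain projection is already exact on the
fixtures tested.

The off-region diagnostic is a planar proxy: a region's warped boundary
points (its landmarks and curve points) are projected onto their best-fit
plane and a placed point is flagged when it falls outside the boundary's
convex hull by more than 5% of the region scale.  This is deliberately a
proxy — true containment is geodesic — and it is only computed for regions
with ≥3 boundary points.

Piecemeal patching runs `place_patch` per region with that region's atlas
and merges the results (fixed points first, then each region's surface
points in region order).  Extra fixed labels from neighboring regions can
be added as warp anchors without being patched; this is the remedy for face
inversion (points landing on the reverse side of the polygons), which is
detected by the per-point normal-agreement sign.

## Sliding

For a reference X with bending-energy matrix B and a specimen Y, the
tangential displacement minimizing `tr((Y+Δ)ᵀB(Y+Δ))` is solved exactly:
with sliding directions dⱼ at points p(j), the system is
`M t = −g, M = B[p,p] ∘ (DDᵀ), gⱼ = (BY)ₚ₍ⱼ₎·dⱼ`.  Because bending energy
ignores the affine part of Y, no superimposition is needed for this
criterion.  The Procrustes-distance criterion first maps the reference onto
the specimen by the least-squares similarity transform and projects the
deviation onto each point's tangent subspace.  Singular systems fall back
to a logged ridge (λ = 1e−8 × mean diagonal).

Tangents: curve points use the central difference of their neighbors along
the curve (anchor landmarks serve as terminal neighbors; closed fences
wrap); surface points use an orthonormal pair spanning the tangent plane of
the nearest mesh face; landmarks never slide.  Degenerate tangents demote a
point to fixed with a warning.

The damped update `Y ← Y + stepsize·Δ` (default stepsize 0.1) is followed
by re-projection of curve points onto their originally digitized polylines
and surface points onto their meshes **after every step**, not only at
convergence: undamped tangent moves leave the geometry, and projection
frequency is the safeguard.  Stepsize applies to curve and surface points
alike (separately disengageable via `slide_curves` / `slide_surfaces`).
The outer loop recomputes the GPA mean each iteration (or keeps a fixed
reference), stopping when the relative change in mean Procrustes distance
falls below 1e−6 or after 50 iterations; with stepsize 1 the pre-projection
criterion value is non-increasing by construction.

## Alignment, distance, PCA

GPA centers each configuration, scales it to unit centroid size, and
alternates rotating every shape onto the current reference with replacing
the reference by the renormalized mean; both half-steps are exact
minimizers, so the summed squared distance to the mean is non-increasing
(recorded for tests).  Convergence tolerance 1e−10 on the mean.
Reflections are excluded from the rotation solve by default (anatomy is
chiral); a flag allows them.  The Procrustes distance is the full form
`sin ρ = √(1 − cos²ρ)` after optimal translation, scale, and rotation.
PCA is the SVD of the centered, vectorized aligned coordinates, covariance
scaled by 1/(n − 1).

## Mirroring

The midline plane is the least-squares plane through the midline landmarks
(SVD; an error is raised when they are collinear).  Missing-side partners
are exact reflections of the present side; midline points are untouched,
and on symmetric data the operation is an involution.  The practical
warning baked into the tests: the imputation error grows with the lever arm
from the plane and with how thin the midline point cloud is in its second
in-plane direction — midline landmarks should be spread in two directions.
`midline_variance_fraction` is the ratio of summed per-coordinate aligned
variances of the midline points to those of a reference (right-side) point
set; aligning one-sided data inflates it, mirroring before alignment
deflates it.

## Evaluation statistics

The fit between two specimen score matrices is the Procrustean correlation:
both are column-centered, scaled to unit total sum of squares, and
optimally rotated; fit = Σ singular values of XᵀY = √(1 − m²).  This is a
reconstruction of the "0–1 Procrustes sum-of-squares fit" convention: it
satisfies the stated range and fit(full, full) = 1 exactly.  Sampling
curves redraw k = 3 … n points uniformly without replacement and re-align
each subsample with a fresh GPA (a cheaper subset-without-realign variant
is available via `realign=False`); medians over iterations and the smallest
k reaching fits of 0.90/0.95/0.99 are reported.  Random skewers draws
selection vectors uniformly on the sphere (normalized Gaussians; no
distribution is canonical) and reports the mean cosine of the two response
vectors; the p-value compares against cosines of independent unit-vector
pairs of the same dimension.

## Synthetic fixtures — what they do and do not show

The pyramid experiment generates 10 pyramids with base aspect ratio drawn
uniformly from 0.6–1.6, height 0.5–2.0, and base-corner skew ±0.15
(ranges chosen so the four generative factors dominate the PCA); 4 carry a
circular fossa (radius 0.07–0.13 in mesh units, realized as a spherical-cap
depression of depth 0.3 × radius so fossa size is a real shape signal).
The template is a near-median pyramid with 90 surface points in 9 rows of
10 on one face and a negligible-size fence (diameter 0.1, about one
surface-point spacing) at the fossa position.  Specimen meshes use ~2,400
faces and patching uses inflate 0.05; the whole 16-configuration experiment
runs in seconds on one CPU.  Real templates for vertebrate skulls should be
far denser — the atlas validator warns below 10,000 faces, with ~18,000 a
proven working resolution — but flat-faced pyramids warp accurately at much
lower resolution.

The bilateral dataset (20 specimens; 12 bilateral point pairs spanning all
three point classes; 5 midline landmarks) applies a random smooth
symmetric deformation field per specimen (scale 0.05), optional directional
asymmetry, and isotropic digitization noise (0.01), exporting the
one-sided, +left-landmarks, +mirrored-curves, and fully mirrored variants.
The two-group dataset (30 + 10) warps a hemisphere template by seeded
smooth TPS fields with a group-level mean offset, keeping every
configuration exactly on its mesh.

These fixtures are deliberately minimal geometry.  Passing tests shows the
algorithms are implemented correctly — exact projection, monotone
objectives, workflow equivalences, the direction and robustness of the
mirroring artifact — but not that any particular inflate value, template
shape, or point density is right for real anatomy; those remain empirical,
per-dataset decisions.

## Numerical choices and degenerate inputs

- Internal indexing is 0-based; file formats keep native conventions.
- ASCII PLY is written with full-precision float repr and parsed to
  float64, so write/read round trips are exact; binary PLY stores float32.
  STL import welds duplicate vertices within 1e−8 × bounding-box diagonal.
- Ray intersections deduplicate hits on shared edges within
  1e−9 × mesh scale; projection ties break toward the outward side.
- Vertex normals are area-weighted averages of incident face normals;
  winding is made globally consistent at load (non-orientable meshes are
  kept as loaded, flagged, and logged).
- Empty configurations, zero-length polylines, collinear midlines,
  duplicate TPS sources at λ = 0, and infeasible curve-point budgets all
  raise informative errors rather than producing NaNs.

## Known limitations

- No mesh repair, hole filling, decimation, or automatic detection of
  internal/non-manifold geometry: meshes are assumed preprocessed, with
  `extract_submesh` available for manual removal of interfering parts.
- The off-region test is a planar convex-hull proxy, not a geodesic test.
- Bending energy is blind to deformations of degenerate (coplanar/collinear)
  configurations (affine fallback).
- The sampling-curve fit statistic is a reconstruction of a 0–1 Procrustes
  fit convention, not a bit-compatible reimplementation of any existing
  package.
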