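# Methods

## Scope and assumptions

`fruitmap` reconstructs a single equirectangular surface map from an
ordered sequence of views of a fruit rotating under a fixed camera.
The method assumes:

- **Spheroidal fruit.** The geometry model is an ellipsoid of
  revolution; the distinct axis is the fruit *y*-axis by construction
  and is approximately the rotation axis. Generic revolution solids
  (pears, avocados) are out of scope.
- **Orthographic projection.** View coordinates are treated as surface
  coordinates (scaled parallel projection). This is accurate when the
  camera distance is large relative to the fruit radius, as in
  overhead inspection machines; no lens model is applied.
- **Near-vertical rotation axis.** The machine's rollers spin fruit
  about an approximately vertical axis; the synthetic generator allows
  tilts up to ~15° and the estimators tolerate them, but the axis is
  assumed roughly known in direction (upward) and the rotation
  direction fixed.
- **Visible surface texture.** Rotation is estimated from image
  content only; a texture-free surface makes the pairwise estimation
  fail by design (this is reported, not papered over).
- **Inter-view rotations of roughly 20–40°.** Enough overlap to match
  features, few enough views to keep one turn cheap.

## Coordinate conventions

View-centric: *x* rightward, *y* upward, *z* toward the camera, origin
at the fruit's center of mass; raster row/column indices are converted
at the I/O boundary (`x = col − cx`, `y = cy − row`). Fruit-centric:
the orthonormal triad (vx, vy, vz), right-handed, with vy along the
distinct/rotation axis. Longitude φ and latitude λ parametrize the
surface as X = rx cosλ cosφ, Y = ry sinλ, Z = rz cosλ sinφ; the view
center of an identity-frame view sits at φ = 90°.

## Geometry estimation

Silhouette ellipses come from central second moments of the solid
mask (semi-axis a = 2√λ₁ of the covariance eigenvalue). Classification
uses the observation that the semi-axis aligned with the near-vertical
rotation axis is stable across views while the orthogonal one
oscillates: spherical if every view is circular within `tol_spherical`
(default 0.03 relative), otherwise oblate/prolate by comparing the
median near-vertical semi-axis against the median near-horizontal one.
Radii: the common radii rx = rz are the median across views of the
near-horizontal semi-axis (robust to segmentation noise); ry is the
near-vertical semi-axis at the reference view, where the distinct axis
lies in the image plane and is seen at full length. The reference view
is the first view (spherical), the shortest minor axis (oblate) or the
longest major axis (prolate), ties to the earliest index.

Frame initialization sets vz = (0,0,1); for non-spherical fruit vy is
the silhouette principal direction making the smaller angle with the
image vertical (ties at exactly 45° go to the major axis), signed
upward, and vx = vy × vz. A nearly circular reference silhouette for a
non-spherical class falls back to a vertical vy with a warning.

## Surface height

The visible height above view point (x, y) solves the quadric
v'Av = 1 with A = M diag(1/r²) Mᵀ (M the frame matrix) along the
orthographic ray (x, y, t), taking the camera-side (largest) root.
A missed ray returns NaN — a signal, not an error — so callers can
distinguish "outside the silhouette" from invalid input. Note that
z > 0 alone does not imply a point is the visible intersection for
tilted non-spherical fruit; where an exact visibility decision is
needed (tests, point sampling) the outward-normal criterion
(M·∇F)_z > 0 is used.

## Rotation estimation

Pairwise rotations are estimated without any rotation sensor:

1. ORB keypoints (default 500 targets, FAST threshold 0.05) on the
   grayscale views, kept only if deeper than max(4 px, 8% of R) inside
   the silhouette (distance transform). The margin matters: silhouette
   edge corners are image features that do *not* rotate with the
   fruit and otherwise bias the fit toward identity.
2. Binary descriptor matching with cross-checking.
3. Back-projection of both keypoint sets to 3D with the spheroid
   model. The reference frame's quadric orientation serves both views:
   rotation happens about the fruit's near-symmetry axis, which leaves
   the view-space quadric essentially unchanged. Points whose height
   is below 12% of R (near the limb, ill-conditioned) are dropped.
4. Orthogonal Procrustes about the origin (no centroid removal — both
   sets are already centroid-relative) inside a 3-point random-sample
   consensus (300 trials, inlier tolerance max(3 px, 0.03 R)), then
   two refit/re-gate passes on the inliers. Fewer than 6 inliers is an
   estimation failure.

The consensus sampler is seeded (default 0) so runs are reproducible.
A failed pair is substituted by the geodesic (chordal) mean of its
successful neighbors and logged; an unsubstitutable failure aborts.
Chained products re-project onto SO(3) by polar decomposition whenever
orthogonality drift exceeds 1e-9, preventing accumulation over ~15
links.

## Map construction

Central longitudes L_i are the (φ of the) surface point seen at each
view's centroid; since the rotation direction is known, any
non-increasing step gets +360° (applied cumulatively), yielding a
strictly increasing schedule. Map longitudes between L_i and L_{i+1}
blend views i and i+1 linearly (weights sum to 1); longitudes before
L_1 and after L_N (pre/post-roll, default 45°) use one end view. At
most two views are touched per pixel — the efficiency contract that
makes per-fruit mapping cheap.

The grid is equirectangular: uniform angular step β in both axes,
rows from +90° down to −90° (row 0 north), column 0 at L_1 − preroll
so early views appear on the left. β = 1/R gives 1-pixel resolution
at the equator; map dimensions round half-away-from-zero on span/β.
Rows with |λ| ≥ λmax (default 60°) are background gray (128,128,128),
matching the unexplored polar bands. View sampling is bilinear
(nearest available via config for exactness tests). A scheduled
contribution with z ≤ 0 or outside the mask is dropped and the
surviving weight renormalized; if both drop, the pixel is background
with coverage 0 and counted in a QC tally. Because blended weights
are renormalized by their sum, weight conservation at two-view pixels
is exact by construction.

## Measurement

Each map pixel's true surface area integrates |∂φ r × ∂λ r| over its
patch — closed form r²β(sin(λ+β) − sinλ) for spheres, 2-point Gauss
per axis otherwise (relative error far below the 0.1% conservation
tolerance at practical β). Surface fractions weight the class mask by
these areas over covered pixels, excluding longitudes beyond the
first full turn so re-seen surface is not double counted. Spot
counting thresholds the map, takes connected components of at least
4 px, and merges detections whose positions agree modulo 360° (the
longitude difference is scaled by cos λ before comparison).

## Synthetic generator

The generator emulates the acquisition machine: orthographic views of
a textured spheroid, 12–16 views of 20–40° steps totaling about one
turn, near-vertical axis (optional tilt), optional per-step slip
jitter, all under a single seed. Defaults — 13 views, 30°/step,
radius 125 px, 300 px frames — mirror orange-sized fruit in typical
machines. Rendering is per-pixel ray–quadric intersection with
bilinear texture lookup, flat-shaded so photometric effects never
confound geometric tests, with 2×2 supersampling at the silhouette
and optional additive Gaussian noise (fruit only). Ground truth
(per-step rotation matrices, per-view frames, per-pixel (φ,λ)
rasters, defect positions) is retained for every stage.

Textures: `checker` (analytic color at any angle), `noise`
(two-scale band-limited color noise — coarse blobs plus fine grain,
like real fruit skin; the fine scale is what gives ORB distinctive
corners), and `spots` (countable dark defects of known angular
diameter on a light base). `paint_hemisphere` tints the φ ∈ (0°,180°)
half green while preserving luminance texture, producing a
ground-truth 50% surface fraction that still satisfies the texture
condition for rotation estimation. What the generator does *not*
emulate: shading and specularities, roller-bar occlusions, motion
blur, perspective, soft or miscalibrated segmentation. Passing tests
therefore demonstrate geometric and algorithmic correctness under
clean imaging, not robustness to photometric nuisances.

## Numerical and design choices

- "Mercator-like" intuition aside, a uniform angular step defines an
  equirectangular (plate carrée) grid — linear in λ — and that is
  what is implemented.
- Longitude from atan2 lives in (−180°, 180°]; unwrapping is solely
  the schedule's responsibility.
- Problem sizes in the test suite: unit fixtures use 60 px fruit in
  150 px frames with texture band-limited to the render resolution
  (so reconstruction error measures geometry, not texture aliasing);
  whole-method acceptance checks run at the realistic 125 px / 300 px
  scale.
- The seam check is statistical: boundary-column jumps are compared
  per row against the 95th-percentile gradient of single-view
  regions; absence of artifact means exceedances at the ~5% chance
  rate (a negative control with an injected 15-level step confirms
  detection power).
- Determinism: texture, jitter, noise, and the consensus sampler all
  derive from explicit seeds; identical inputs, config and seed give
  byte-identical maps.

## Known limitations

- Radii estimation from silhouettes degrades when the rotation axis
  is strongly tilted (the distinct radius is foreshortened in every
  view).
- The quadric-orientation approximation in pairwise estimation
  assumes rotation near the symmetry axis; large off-axis rotations
  would require per-view frame refinement.
- Surface-fraction exclusion beyond 360° keeps the *first* sighting
  of re-seen surface; no averaging across the overlap is attempted.
- Only RGB channels are wired through the blending, though the
  operation itself is channel-agnostic.
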