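# fruitmap

Seamless longitude–latitude surface maps of rotating spheroidal fruit,
built from nothing but an ordered sequence of camera views.

## The problem

Industrial fruit-inspection machines roll each piece of fruit under a
fixed camera, capturing 12–16 views as it turns through roughly a full
revolution. Grading from those views directly is awkward: small defects
are seen — and counted — in several overlapping views, large defects
are never fully visible in any single view, and global quantities such
as the fraction of green (unripe) surface are hard to define across
overlapping images. `fruitmap` fuses the whole view collection into
**one** equirectangular surface map of the fruit, on which defects
appear exactly once and every pixel has a well-defined surface area.

Crucially, the 3D rotation between consecutive views is estimated from
the images alone — fruit slip on the rollers, so encoder or conveyor
information is unreliable, and no extra sensors are assumed.

## The model

A fruit is a spheroid with principal radii $r_x, r_y, r_z$, where the
revolution (and approximate rotation) axis is the fruit $y$-axis, so
$r_x = r_z$ and the geometry class follows from $r_y$: oblate
($r_y < r_x$, e.g. mandarins), spherical, or prolate ($r_y > r_x$).
A surface point at longitude $\phi$ and latitude $\lambda$ sits at

$$X = r_x\cos\lambda\cos\phi,\qquad Y = r_y\sin\lambda,\qquad
Z = r_z\cos\lambda\sin\phi$$

in fruit-centric coordinates. With the orthonormal fruit-axis triad
$v_x(i), v_y(i), v_z(i)$ at view $i$, the view-centric position is
$(x_i,y_i,z_i) = X v_x(i) + Y v_y(i) + Z v_z(i)$, visible when
$z_i > 0$; conversely a view pixel is lifted to 3D by intersecting its
orthographic ray with the spheroid and projected back onto the fruit
axes to recover $(\phi, \lambda)$.

The pipeline:

1. **Geometry** — silhouette second-moment ellipses per view classify
   the geometry, select the reference view (shortest minor axis for
   oblate, longest major axis for prolate), estimate the radii, and
   initialize the fruit frame.
2. **Rotation** — ORB texture keypoints matched between consecutive
   views are back-projected onto the spheroid; a robust orthogonal
   Procrustes fit (3-point consensus sampling) yields each pairwise
   rotation matrix $R_i^{i+1}$; chaining propagates the fruit frame to
   every view.
3. **Mapping** — each view's central longitude $L_i$ (unwrapped to a
   strictly increasing schedule) drives a linear cross-fade: map
   longitudes between $L_i$ and $L_{i+1}$ blend exactly those two
   views with weights $w_i = (L_{i+1}-\phi)/(L_{i+1}-L_i)$,
   $w_{i+1} = 1 - w_i$; a pre-roll/post-roll extension (45° by
   default) uses a single end view. The angular step is
   $\beta = 1/R$ (radians/pixel) for 1-pixel resolution at the
   equator — an $R = 125$ px orange yields a map of about 800 × 400
   pixels for a full turn.
4. **Measurement** — every map pixel has an exact surface area from
   the spheroid's first fundamental form, so surface fractions (e.g.
   green surface) are single image-mask sums, with the region beyond
   the first 360° excluded to avoid double counting.

## Worked example

Simulate an oblate fruit (radii 125, 95, 125 px) turning 30° per view
for 13 views, rebuild its surface map from the images alone, and
measure a surface fraction:

```
$ fruitmap simulate demo/bundle --n-views 13 --step-deg 30 \
      --geometry oblate --texture noise --seed 42
wrote 13 views to demo/bundle

$ fruitmap build-map demo/bundle demo/map.png --seed 0
wrote 983x393 map to demo/map.png (oblate)

$ fruitmap measure demo/map.png --rule dark:60
{
 "rule": "dark:60",
 "fraction": 0.00010120156462732341,
 "covered_pixels": 257546,
 "matched_pixels": 25
}
```

The map is 393 rows (latitude −90°…+90° at β = 1/125 rad/px; rows
beyond ±60° are gray background) by 983 columns (the 360° turn plus
45° pre- and post-roll). The QC sidecar `map.qc.json` records the
estimated radii (125.1, 95.2, 125.1 px against the true 125, 95, 125),
the per-view central longitudes (30.03° first step against the true
30°), and per-pair inlier counts. The measured dark fraction ~1e-4 is
the false-positive floor of the threshold rule on this defect-free
fruit; on a hemisphere tinted green, `--rule green` returns 0.506
(truth: 0.500).

The same API is available from Python (`fruitmap.synthetic` renders,
`fruitmap.pipeline.build_map` fuses, `fruitmap.mapping` measures).

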