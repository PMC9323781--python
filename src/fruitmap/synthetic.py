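"""Synthetic rotating-spheroid renderer with known ground truth.

Emulates the acquisition geometry of a roller-conveyor inspection
machine: orthographic views of a textured spheroid rotating 20-40
degrees per step about a near-vertical axis, 12-16 views totaling
about one full turn. Every stage of the pipeline can be tested against
the renderer's ground truth: the source texture, the per-step rotation
matrices, the fruit frames at every view, and per-pixel (longitude,
latitude) rasters.

Rendering is flat (texture color only, no shading) so photometric
effects never confound geometric tests; optional additive Gaussian
noise exercises estimator robustness. Silhouettes are anti-aliased by
2x2 supersampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .geometry import FruitFrame, SpheroidModel, fit_silhouette, surface_height
from .mapping import _xyz_to_lonlat

__all__ = [
    "SyntheticScene",
    "GroundTruthBundle",
    "make_texture",
    "make_scene",
    "render_view",
    "generate_sequence",
]

TEXTURE_SHAPE = (360, 720)  # 0.5 degree per texel


@dataclass
class SyntheticScene:
    """A fruit, its surface texture, and the rotation script."""

    model: SpheroidModel
    texture: np.ndarray  # (H, W, 3) uint8 equirectangular, row 0 = lat +90
    rotation_axis: np.ndarray  # unit vector, near-vertical
    step_angles: np.ndarray  # degrees per step, typically 20-40
    seed: int = 0
    image_size: int = 300
    noise_sigma: float = 0.0
    spots: list = field(default_factory=list)  # ground-truth defect list

    def __post_init__(self) -> None:
        self.rotation_axis = np.asarray(self.rotation_axis, dtype=float)
        self.rotation_axis /= np.linalg.norm(self.rotation_axis)
        self.step_angles = np.atleast_1d(np.asarray(self.step_angles, dtype=float))

    @property
    def n_views(self) -> int:
        return len(self.step_angles) + 1

    def initial_frame(self) -> FruitFrame:
        """Fruit frame at view 0: vy along the rotation axis."""
        vy = self.rotation_axis
        if abs(vy @ np.array([0.0, 1.0, 0.0]) - 1.0) < 1e-12:
            return FruitFrame.identity()
        vz = np.array([0.0, 0.0, 1.0]) - vy[2] * vy
        vz /= np.linalg.norm(vz)
        vx = np.cross(vy, vz)
        return FruitFrame(vx, vy, vz)

    def cumulative_rotations(self) -> list[np.ndarray]:
        """World rotation applied to the fruit at each view (view 0 = I)."""
        mats = [np.eye(3)]
        total = 0.0
        for step in self.step_angles:
            total += step
            mats.append(
                Rotation.from_rotvec(np.deg2rad(total) * self.rotation_axis).as_matrix()
            )
        return mats

    def frame_at(self, i: int) -> FruitFrame:
        return FruitFrame.from_matrix(
            self.cumulative_rotations()[i] @ self.initial_frame().matrix
        )


@dataclass
class GroundTruthBundle:
    """Rendered sequence plus everything needed as an oracle."""

    scene: SyntheticScene
    views: list  # ViewObservation, silhouette-fitted, with images
    frames: list  # true FruitFrame per view
    pairwise_rotations: list  # true R_i^{i+1}
    cumulative_rotations: list
    lonlat_rasters: list  # per-view (H, W, 2) float arrays, NaN off-fruit


def make_texture(
    kind: str, params: dict | None = None, seed: int = 0
) -> tuple[np.ndarray, list]:
    """Build an equirectangular texture; returns (texture, spot list).

    Kinds
    -----
    checker
        Squares of ``square_deg`` (default 30) in two colors; the color
        at any (phi, lam) is analytic.
    noise
        Band-limited smooth color noise (``sigma_px`` texels smoothing,
        default 6) — the "moderate texture" a real fruit skin offers.
    spots
        A light base with ``n_spots`` (default 7) dark circular defects
        of angular diameter ``diameter_deg`` (default 10) at recorded
        positions with ``|lam| <= lat_max`` (default 40); the returned
        list carries one ``{"phi", "lam", "diameter_deg"}`` per spot.

    Deterministic for a given seed.
    """
    params = dict(params or {})
    h, w = params.pop("shape", TEXTURE_SHAPE)
    rng = np.random.default_rng(seed)
    lam = 90.0 - (np.arange(h) + 0.5) * 180.0 / h
    phi = -180.0 + (np.arange(w) + 0.5) * 360.0 / w
    spots: list = []
    if kind == "checker":
        sq = params.pop("square_deg", 30.0)
        c0 = np.array(params.pop("color0", (230, 140, 40)), dtype=np.uint8)
        c1 = np.array(params.pop("color1", (40, 90, 200)), dtype=np.uint8)
        par = (np.floor(phi[None, :] / sq) + np.floor(lam[:, None] / sq)) % 2 == 0
        tex = np.where(par[:, :, None], c0[None, None, :], c1[None, None, :])
    elif kind == "noise":
        # two-scale band-limited noise: coarse blobs plus fine grain,
        # like the multi-scale detail of real fruit skin
        sigma = params.pop("sigma_px", 6.0)
        fine_sigma = params.pop("fine_sigma_px", 1.5)
        coarse = np.stack(
            [
                ndimage.gaussian_filter(rng.uniform(size=(h, w)), sigma, mode="wrap")
                for _ in range(3)
            ],
            axis=-1,
        )
        fine = ndimage.gaussian_filter(rng.uniform(size=(h, w)), fine_sigma, mode="wrap")
        sm = coarse + 0.6 * fine[:, :, None]
        lo, hi = sm.min(), sm.max()
        tex = (30 + (sm - lo) / (hi - lo) * 195).astype(np.uint8)
    elif kind == "spots":
        n_spots = params.pop("n_spots", 7)
        diam = params.pop("diameter_deg", 10.0)
        lat_max = params.pop("lat_max", 40.0)
        base = np.array(params.pop("base_color", (210, 170, 90)), dtype=np.uint8)
        dark = np.array(params.pop("spot_color", (25, 25, 25)), dtype=np.uint8)
        tex = np.tile(base, (h, w, 1)).astype(np.uint8)
        centers: list[tuple[float, float]] = []
        guard = 0
        while len(centers) < n_spots and guard < 10000:
            guard += 1
            p = rng.uniform(-180.0, 180.0)
            l = rng.uniform(-lat_max, lat_max)
            # keep spots disjoint so each is countable
            if all(_angular_distance(p, l, q, m) > 2.5 * diam for q, m in centers):
                centers.append((p, l))
        lam_g, phi_g = np.meshgrid(lam, phi, indexing="ij")
        for p, l in centers:
            d = _angular_distance(phi_g, lam_g, p, l)
            tex[d <= diam / 2.0] = dark
            spots.append({"phi": float(p), "lam": float(l), "diameter_deg": float(diam)})
    else:
        raise ValueError(f"unknown texture kind {kind!r}")
    if params:
        raise ValueError(f"unused texture params: {sorted(params)}")
    return np.ascontiguousarray(tex, dtype=np.uint8), spots


def paint_hemisphere(texture: np.ndarray, boundary_phi: float = 0.0) -> np.ndarray:
    """Tint one longitude hemisphere green, keeping luminance texture.

    The half with ``phi`` in ``(boundary_phi, boundary_phi + 180)`` is
    recolored so the green channel dominates while the spatial
    luminance variation survives — a ripeness pattern with exactly 50%
    surface fraction that still offers the texture the rotation
    estimator needs.
    """
    h, w = texture.shape[:2]
    phi = -180.0 + (np.arange(w) + 0.5) * 360.0 / w
    rel = (phi - boundary_phi) % 360.0
    half = (rel > 0) & (rel < 180.0)
    out = texture.astype(float)
    lum = out.mean(axis=2)
    green = np.stack([0.25 * lum, 30.0 + lum, 0.25 * lum], axis=-1)
    out[:, half] = green[:, half]
    return np.clip(out, 0, 255).astype(np.uint8)


def _angular_distance(phi1, lam1, phi2, lam2):
    """Great-circle distance (degrees) between (phi, lam) points."""
    p1, l1, p2, l2 = (np.deg2rad(a) for a in (phi1, lam1, phi2, lam2))
    c = np.sin(l1) * np.sin(l2) + np.cos(l1) * np.cos(l2) * np.cos(p1 - p2)
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def make_scene(
    geometry: str = "spherical",
    radius: float = 125.0,
    distinct_radius: float | None = None,
    n_views: int = 13,
    step_deg: float = 30.0,
    jitter_deg: float = 0.0,
    tilt_deg: float = 0.0,
    texture_kind: str = "noise",
    texture_params: dict | None = None,
    seed: int = 0,
    image_size: int = 300,
    noise_sigma: float = 0.0,
) -> SyntheticScene:
    """Convenience scene factory with machine-like defaults.

    The defaults — 13 views, 30 degrees per step (one full turn), a
    125 px fruit — mirror typical acquisition conditions: 12-15 views
    per fruit, 20-40 degree steps, orange-sized fruit at ~125 px.
    ``jitter_deg`` adds per-step slip (uniform in +/- jitter) and
    ``tilt_deg`` tips the rotation axis away from the image vertical.
    """
    if n_views < 2:
        raise ValueError("need at least 2 views")
    if geometry == "spherical":
        model = SpheroidModel(radius, radius, radius, "spherical")
    elif geometry == "oblate":
        ry = distinct_radius if distinct_radius is not None else 0.76 * radius
        model = SpheroidModel(radius, ry, radius, "oblate")
    elif geometry == "prolate":
        ry = distinct_radius if distinct_radius is not None else radius / 0.76
        model = SpheroidModel(radius, ry, radius, "prolate")
    else:
        raise ValueError(f"unknown geometry {geometry!r}")
    rng = np.random.default_rng(seed)
    steps = np.full(n_views - 1, step_deg)
    if jitter_deg > 0:
        steps = steps + rng.uniform(-jitter_deg, jitter_deg, size=n_views - 1)
    tilt = np.deg2rad(tilt_deg)
    axis = np.array([np.sin(tilt), np.cos(tilt), 0.0])
    texture, spots = make_texture(texture_kind, texture_params, seed=seed)
    return SyntheticScene(
        model=model,
        texture=texture,
        rotation_axis=axis,
        step_angles=steps,
        seed=seed,
        image_size=image_size,
        noise_sigma=noise_sigma,
        spots=spots,
    )


def _sample_texture(texture: np.ndarray, phi, lam):
    """Bilinear texture lookup with longitude wraparound."""
    h, w = texture.shape[:2]
    rows = (90.0 - lam) * h / 180.0 - 0.5
    cols = ((phi + 180.0) * w / 360.0 - 0.5) % w
    padded = np.concatenate([texture, texture[:, :1]], axis=1).astype(float)
    coords = np.stack([np.clip(rows, 0, h - 1), cols])
    return np.stack(
        [
            ndimage.map_coordinates(padded[:, :, c], coords, order=1, mode="nearest")
            for c in range(3)
        ],
        axis=-1,
    )


def render_view(
    scene: SyntheticScene,
    cumulative_rotation: np.ndarray,
    image_size: int | None = None,
    noise_rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one orthographic view of the rotated, textured spheroid.

    Returns ``(image, mask, lonlat)``: an (S, S, 3) uint8 image, an
    (S, S) uint8 mask (255 = fruit), and an (S, S, 2) float raster of
    ground-truth (longitude, latitude) in degrees per pixel center
    (NaN off the fruit). Per-pixel color comes from intersecting the
    viewing ray with the rotated ellipsoid and looking up the texture
    at the intersection's surface coordinates; 2x2 supersampling
    anti-aliases the silhouette.
    """
    size = image_size or scene.image_size
    frame = FruitFrame.from_matrix(cumulative_rotation @ scene.initial_frame().matrix)
    model = scene.model

    # supersampled grid (2x per axis), pixel centers at half-steps
    c = (size - 1) / 2.0
    sub = (np.arange(2 * size) - 0.5) / 2.0  # raster coords of subsamples
    xs = sub - c
    ys = c - sub
    x = np.broadcast_to(xs[None, :], (2 * size, 2 * size))
    y = np.broadcast_to(ys[:, None], (2 * size, 2 * size))
    z = surface_height(x, y, model, frame)
    hit = np.isfinite(z)
    zf = np.where(hit, z, 0.0)
    m = frame.matrix
    X = m[0, 0] * x + m[1, 0] * y + m[2, 0] * zf
    Y = m[0, 1] * x + m[1, 1] * y + m[2, 1] * zf
    Z = m[0, 2] * x + m[1, 2] * y + m[2, 2] * zf
    phi, lam = _xyz_to_lonlat(X, Y, Z, model)
    rgb = _sample_texture(scene.texture, phi, lam)
    rgb[~hit] = 0.0

    # average the 2x2 subsamples
    img = rgb.reshape(size, 2, size, 2, 3).mean(axis=(1, 3))
    frac = hit.reshape(size, 2, size, 2).mean(axis=(1, 3))
    mask = (frac >= 0.5).astype(np.uint8) * 255
    img[frac > 0] /= np.maximum(frac[frac > 0], 1e-9)[:, None]
    img[mask == 0] = 0.0
    if scene.noise_sigma > 0:
        rng = noise_rng or np.random.default_rng(scene.seed)
        noise = rng.normal(0.0, scene.noise_sigma, img.shape)
        img = img + noise * (mask[:, :, None] > 0)  # background stays clean
    image = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    # ground-truth angles at pixel centers (no supersampling)
    xc = np.broadcast_to((np.arange(size) - c)[None, :], (size, size))
    yc = np.broadcast_to((c - np.arange(size))[:, None], (size, size))
    zc = surface_height(xc, yc, model, frame)
    hitc = np.isfinite(zc)
    zcf = np.where(hitc, zc, 0.0)
    Xc = m[0, 0] * xc + m[1, 0] * yc + m[2, 0] * zcf
    Yc = m[0, 1] * xc + m[1, 1] * yc + m[2, 1] * zcf
    Zc = m[0, 2] * xc + m[1, 2] * yc + m[2, 2] * zcf
    phic, lamc = _xyz_to_lonlat(Xc, Yc, Zc, model)
    lonlat = np.stack([phic, lamc], axis=-1)
    lonlat[~hitc] = np.nan
    return image, mask, lonlat


def generate_sequence(
    scene: SyntheticScene, n_views: int | None = None
) -> GroundTruthBundle:
    """Render the whole view sequence with its ground-truth bundle.

    Deterministic for a given scene (seeded noise per view). The
    bundle carries the true pairwise and cumulative rotations, the
    true fruit frame at every view, and per-view (phi, lam) rasters.
    """
    if n_views is not None and n_views != scene.n_views:
        raise ValueError("n_views disagrees with scene.step_angles")
    if scene.n_views < 2:
        raise ValueError("need at least 2 views")
    cum = scene.cumulative_rotations()
    pairwise = [
        Rotation.from_rotvec(np.deg2rad(a) * scene.rotation_axis).as_matrix()
        for a in scene.step_angles
    ]
    frames = [scene.frame_at(i) for i in range(scene.n_views)]
    views = []
    rasters = []
    for i, R in enumerate(cum):
        rng = np.random.default_rng([scene.seed % (2**31), i])
        image, mask, lonlat = render_view(scene, R, noise_rng=rng)
        obs = fit_silhouette(mask)
        obs.image = image
        views.append(obs)
        rasters.append(lonlat)
    return GroundTruthBundle(
        scene=scene,
        views=views,
        frames=frames,
        pairwise_rotations=pairwise,
        cumulative_rotations=cum,
        lonlat_rasters=rasters,
    )
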