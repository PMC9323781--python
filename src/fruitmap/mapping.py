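"""Longitude-latitude surface map construction and measurement.

A point on the fruit surface is addressed by longitude ``phi`` and
latitude ``lam`` through the spheroid parametrization::

    X = rx * cos(lam) * cos(phi)
    Y = ry * sin(lam)
    Z = rz * cos(lam) * sin(phi)

in fruit-centric coordinates, with the pole-pole axis (fruit y) aligned
to the rotation axis. The map is an equirectangular grid — linear in
both angles with a uniform angular step ``beta`` — so most view content
sits near the map equator where distortion is smallest. Each map pixel
is synthesized from at most two views, the ones whose central longitude
brackets the pixel's, with linearly cross-faded weights; a pre-roll and
post-roll extension at the two ends is filled from a single view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import FruitFrame, SpheroidModel, ViewObservation, surface_height

__all__ = [
    "LongitudeSchedule",
    "SurfaceMap",
    "SurfacePoint",
    "lonlat_to_surface",
    "surface_to_view",
    "view_to_lonlat",
    "compute_longitude_schedule",
    "blend_weights",
    "angular_step",
    "map_dimensions",
    "fill_map",
    "pixel_area",
    "surface_fraction",
]

BACKGROUND_RGB = (128, 128, 128)  # gray pole bands / unexplored surface


@dataclass(frozen=True)
class SurfacePoint:
    """A fruit-surface point in both angular and Cartesian form."""

    X: float
    Y: float
    Z: float
    phi: float  # longitude, degrees
    lam: float  # latitude, degrees


@dataclass
class LongitudeSchedule:
    """Per-view central longitudes, strictly increasing after unwrap."""

    L: np.ndarray  # degrees, one per view
    preroll: float = 45.0
    postroll: float = 45.0

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        if self.L.size == 0:
            raise ValueError("empty longitude schedule")
        if self.L.size > 1 and not np.all(np.diff(self.L) > 0):
            raise ValueError("longitudes must be strictly increasing (unwrap first)")
        if self.preroll < 0 or self.postroll < 0:
            raise ValueError("pre/post-roll must be non-negative")

    @property
    def lon_start(self) -> float:
        return float(self.L[0] - self.preroll)

    @property
    def lon_end(self) -> float:
        return float(self.L[-1] + self.postroll)

    @property
    def span(self) -> float:
        return self.lon_end - self.lon_start


@dataclass
class SurfaceMap:
    """Equirectangular surface map with per-pixel provenance.

    Row 0 is latitude +90 (north up); column 0 is ``lon_start``
    (= L1 - preroll), so the first views appear on the left. Rows with
    ``|lam| >= lambda_max`` and pixels no view can see are background.
    """

    pixels: np.ndarray  # (rows, cols, 3) uint8
    coverage: np.ndarray  # (rows, cols) uint8, number of contributing views
    beta: float  # rad / pixel
    lambda_max: float  # degrees
    lon_start: float  # degrees
    lon_end: float  # degrees
    schedule: LongitudeSchedule | None = None
    unseen_pixels: int = 0  # scheduled-but-invisible pixel count (QC)
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    def lat_centers(self) -> np.ndarray:
        """Latitude (deg) of each row center, decreasing from +90."""
        step = math.degrees(self.beta)
        rows = self.pixels.shape[0]
        return 90.0 - (np.arange(rows) + 0.5) * step

    def lon_centers(self) -> np.ndarray:
        """Longitude (deg) of each column center."""
        step = math.degrees(self.beta)
        cols = self.pixels.shape[1]
        return self.lon_start + (np.arange(cols) + 0.5) * step


def lonlat_to_surface(phi: float, lam: float, model: SpheroidModel) -> SurfacePoint:
    """Map (longitude, latitude) in degrees to fruit-frame coordinates."""
    X, Y, Z = _lonlat_to_xyz(np.asarray(phi, float), np.asarray(lam, float), model)
    return SurfacePoint(float(X), float(Y), float(Z), float(phi), float(lam))


def _lonlat_to_xyz(phi_deg, lam_deg, model: SpheroidModel):
    phi = np.deg2rad(phi_deg)
    lam = np.deg2rad(lam_deg)
    cl = np.cos(lam)
    return model.rx * cl * np.cos(phi), model.ry * np.sin(lam), model.rz * cl * np.sin(phi)


def surface_to_view(
    point: SurfacePoint, frame: FruitFrame
) -> tuple[float, float, float, bool]:
    """Project a fruit-surface point into a view's coordinates.

    Returns ``(x, y, z, visible)`` where the view coordinates are the
    linear combination ``X*vx + Y*vy + Z*vz`` and the point is visible
    in the view exactly when ``z > 0`` (camera side of the fruit).
    """
    v = frame.matrix @ np.array([point.X, point.Y, point.Z])
    return float(v[0]), float(v[1]), float(v[2]), bool(v[2] > 0)


def view_to_lonlat(
    x: float, y: float, model: SpheroidModel, frame: FruitFrame
) -> tuple[float, float]:
    """Longitude and latitude of the visible surface point at view (x, y).

    The height ``z`` comes from the spheroid model; the fruit-frame
    coordinates are the projections of ``(x, y, z)`` onto the fruit
    axes, and the angular coordinates invert the surface
    parametrization. Longitude is returned in (-180, 180]; unwrapping
    across views is the longitude schedule's job. Points outside the
    silhouette return ``(nan, nan)``.
    """
    z = surface_height(x, y, model, frame)
    if not np.isfinite(z):
        return (math.nan, math.nan)
    XYZ = frame.matrix.T @ np.array([x, y, z], dtype=float)
    return _xyz_to_lonlat(XYZ[0], XYZ[1], XYZ[2], model)


def _xyz_to_lonlat(X, Y, Z, model: SpheroidModel):
    lam = np.degrees(np.arcsin(np.clip(Y / model.ry, -1.0, 1.0)))
    phi = np.degrees(np.arctan2(Z / model.rz, X / model.rx))
    # atan2 yields [-180, 180]; fold -180 onto +180 for the documented range
    phi = np.where(phi <= -180.0, phi + 360.0, phi) if np.ndim(phi) else (
        phi + 360.0 if phi <= -180.0 else phi
    )
    return float(phi) if np.ndim(phi) == 0 else phi, (
        float(lam) if np.ndim(lam) == 0 else lam
    )


def compute_longitude_schedule(
    views: list[ViewObservation],
    model: SpheroidModel,
    frames: list[FruitFrame],
    preroll: float = 45.0,
    postroll: float = 45.0,
) -> LongitudeSchedule:
    """Central longitude of every view, unwrapped to a monotone sequence.

    The central point of view *i* is the fruit point seen at the
    centroid (0, 0); since the fruit rotates in a known direction each
    longitude must exceed the previous one, so 360 degrees are added to
    any raw longitude (and all its successors) that fails the check.
    """
    if len(views) != len(frames):
        raise ValueError("one frame per view required")
    raw = [view_to_lonlat(0.0, 0.0, model, f)[0] for f in frames]
    L = np.array(raw, dtype=float)
    offset = 0.0
    for i in range(1, len(L)):
        L[i] += offset
        while L[i] <= L[i - 1]:
            L[i] += 360.0
            offset += 360.0
    return LongitudeSchedule(L=L, preroll=preroll, postroll=postroll)


def blend_weights(phi: float, schedule: LongitudeSchedule) -> list[tuple[int, float]]:
    """Views contributing at longitude ``phi`` and their linear weights.

    Between consecutive central longitudes the two bracketing views
    cross-fade linearly (weights sum to 1); before the first and after
    the last central longitude a single end view carries weight 1.
    """
    L = schedule.L
    if phi < schedule.lon_start - 1e-9 or phi > schedule.lon_end + 1e-9:
        raise ValueError(f"longitude {phi} outside map span")
    if phi <= L[0]:
        return [(0, 1.0)]
    if phi >= L[-1]:
        return [(len(L) - 1, 1.0)]
    i = int(np.searchsorted(L, phi, side="right") - 1)
    if phi == L[i]:
        return [(i, 1.0)]
    w_next = (phi - L[i]) / (L[i + 1] - L[i])
    return [(i, 1.0 - w_next), (i + 1, w_next)]


def angular_step(r_max: float) -> float:
    """Angular step (rad/px) for 1-pixel resolution at the equator.

    At the equator one map pixel subtends ``beta * R`` view pixels for
    a fruit of largest radius ``R``, so ``beta = 1/R`` matches the map
    resolution to the view resolution at the view center.
    """
    if r_max <= 0:
        raise ValueError("radius must be positive")
    return 1.0 / r_max


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


def map_dimensions(
    beta: float, span_deg: float, lambda_max_deg: float | None = None
) -> tuple[int, int]:
    """(rows, cols) of a map with angular step ``beta``.

    ``lambda_max_deg=None`` gives the uncropped +/-90 latitude height
    ``pi / beta``; otherwise ``2 * lambda_max / beta``. Width covers
    the longitude span. Rounding is half-away-from-zero.
    """
    cols = _round_half_away(math.radians(span_deg) / beta)
    if lambda_max_deg is None:
        rows = _round_half_away(math.pi / beta)
    else:
        rows = _round_half_away(2.0 * math.radians(lambda_max_deg) / beta)
    return rows, cols


def _view_weight_profile(i: int, phi: np.ndarray, schedule: LongitudeSchedule):
    """Weight of view i at each longitude, per the linear cross-fade."""
    L = schedule.L
    n = len(L)
    knots_x = []
    knots_w = []
    if i == 0:
        knots_x += [schedule.lon_start, L[0]]
        knots_w += [1.0, 1.0]
    else:
        knots_x += [L[i - 1], L[i]]
        knots_w += [0.0, 1.0]
    if i == n - 1:
        knots_x += [schedule.lon_end]
        knots_w += [1.0]
    else:
        knots_x += [L[i + 1]]
        knots_w += [0.0]
    return np.interp(phi, knots_x, knots_w, left=0.0, right=0.0)


def _sample_view(view: ViewObservation, x: np.ndarray, y: np.ndarray, order: int):
    """Bilinear (or nearest) sample of image and mask at view coords."""
    cx, cy = view.centroid
    rows = cy - y
    cols = cx + x
    coords = np.stack([rows, cols])
    img = view.image
    if img.ndim == 2:
        img = img[:, :, None]
    out = np.stack(
        [
            ndimage.map_coordinates(
                img[:, :, c].astype(float), coords, order=order, mode="constant", cval=0.0
            )
            for c in range(img.shape[2])
        ],
        axis=-1,
    )
    inside = ndimage.map_coordinates(
        (np.asarray(view.mask) > 0).astype(float), coords, order=order, mode="constant"
    )
    return out, inside > 0.5


def fill_map(
    views: list[ViewObservation],
    model: SpheroidModel,
    frames: list[FruitFrame],
    schedule: LongitudeSchedule,
    beta: float,
    lambda_max: float = 60.0,
    interp: str = "bilinear",
    background: tuple[int, int, int] = BACKGROUND_RGB,
) -> SurfaceMap:
    """Fuse all views into one equirectangular surface map.

    For every map pixel inside the latitude crop, the fruit-surface
    point is projected into the one or two scheduled views; invisible
    contributions (``z <= 0`` or outside the silhouette) are dropped
    and the surviving weight renormalized, so at most two views are
    ever touched per pixel. Rows beyond ``lambda_max`` and pixels no
    scheduled view can see are filled with the background gray.
    """
    if len(views) != len(frames) or len(views) != len(schedule.L):
        raise ValueError("views, frames and schedule lengths must agree")
    if interp not in ("bilinear", "nearest"):
        raise ValueError("interp must be 'bilinear' or 'nearest'")
    order = 1 if interp == "bilinear" else 0

    n_rows, n_cols = map_dimensions(beta, schedule.span, lambda_max_deg=None)
    step = math.degrees(beta)
    lat = 90.0 - (np.arange(n_rows) + 0.5) * step
    lon = schedule.lon_start + (np.arange(n_cols) + 0.5) * step
    active_rows = np.abs(lat) < lambda_max
    lat_a = lat[active_rows]

    X, Y, Z = np.broadcast_arrays(
        *_lonlat_to_xyz(lon[None, :], lat_a[:, None], model)
    )

    acc = np.zeros((lat_a.size, n_cols, 3))
    wsum = np.zeros((lat_a.size, n_cols))
    cov = np.zeros((lat_a.size, n_cols), dtype=np.uint8)

    for i, (view, frame) in enumerate(zip(views, frames)):
        w_cols = _view_weight_profile(i, lon, schedule)
        sel = np.nonzero(w_cols > 0)[0]
        if sel.size == 0:
            continue
        m = frame.matrix
        Xs, Ys, Zs = X[:, sel], Y[:, sel], Z[:, sel]
        x = m[0, 0] * Xs + m[0, 1] * Ys + m[0, 2] * Zs
        y = m[1, 0] * Xs + m[1, 1] * Ys + m[1, 2] * Zs
        z = m[2, 0] * Xs + m[2, 1] * Ys + m[2, 2] * Zs
        rgb, inside = _sample_view(view, x, y, order)
        w = np.broadcast_to(w_cols[sel], z.shape).copy()
        w[(z <= 0) | ~inside] = 0.0
        acc[:, sel, :] += w[:, :, None] * rgb
        wsum[:, sel] += w
        cov[:, sel] += (w > 0).astype(np.uint8)

    pixels = np.empty((n_rows, n_cols, 3), dtype=np.uint8)
    pixels[:] = np.asarray(background, dtype=np.uint8)
    coverage = np.zeros((n_rows, n_cols), dtype=np.uint8)
    filled = wsum > 0
    block = np.empty((lat_a.size, n_cols, 3), dtype=np.uint8)
    block[:] = np.asarray(background, dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        vals = acc / wsum[:, :, None]
    block[filled] = np.clip(np.rint(vals[filled]), 0, 255).astype(np.uint8)
    pixels[active_rows] = block
    coverage[active_rows] = cov
    unseen = int(np.sum(~filled))

    return SurfaceMap(
        pixels=pixels,
        coverage=coverage,
        beta=beta,
        lambda_max=lambda_max,
        lon_start=schedule.lon_start,
        lon_end=schedule.lon_end,
        schedule=schedule,
        unseen_pixels=unseen,
        meta={"radii": model.radii.tolist(), "geometry_class": model.geometry_class},
    )


_GAUSS2 = (0.5 - 0.5 / math.sqrt(3.0), 0.5 + 0.5 / math.sqrt(3.0))


def pixel_area(
    lam: np.ndarray | float,
    phi: np.ndarray | float,
    model: SpheroidModel,
    beta: float,
) -> np.ndarray | float:
    """Surface area (px^2) of the map patch starting at (lam, phi).

    The patch spans ``[phi, phi+beta] x [lam, lam+beta]`` (inputs in
    degrees, ``beta`` in radians). Spheres use the closed form
    ``r^2 * beta * (sin(lam+beta) - sin(lam))``; general spheroids
    integrate the parametric area element ``|d_phi r x d_lam r|`` with
    a 2-point Gauss rule per axis.
    """
    lam_r = np.deg2rad(np.asarray(lam, dtype=float))
    phi_r = np.deg2rad(np.asarray(phi, dtype=float))
    if model.geometry_class == "spherical":
        r = model.rx
        area = r * r * beta * (np.sin(lam_r + beta) - np.sin(lam_r))
        area = np.broadcast_to(area, np.broadcast(lam_r, phi_r).shape)
        return float(area) if np.ndim(area) == 0 else area.copy()
    rx, ry, rz = model.rx, model.ry, model.rz
    area = np.zeros(np.broadcast(lam_r, phi_r).shape)
    for gl in _GAUSS2:
        for gp in _GAUSS2:
            la = lam_r + gl * beta
            ph = phi_r + gp * beta
            cl, sl = np.cos(la), np.sin(la)
            cp, sp = np.cos(ph), np.sin(ph)
            # r_phi = (-rx cl sp, 0, rz cl cp); r_lam = (-rx sl cp, ry cl, -rz sl sp)
            cx = -ry * rz * cl * cl * cp
            cy = rx * rz * cl * sl * (sp * sp + cp * cp)
            cz = -rx * ry * cl * cl * sp
            area += 0.25 * np.sqrt(cx * cx + cy * cy + cz * cz) * beta * beta
    return float(area) if np.ndim(area) == 0 else area


def surface_fraction(
    surface_map: SurfaceMap,
    class_mask: np.ndarray,
    model: SpheroidModel,
    beta: float | None = None,
) -> float:
    """Area-weighted fraction of the covered surface matching a class mask.

    Each map pixel is weighted by its true surface area (latitude- and,
    for non-spherical fruit, longitude-dependent). Only pixels at least
    one view covered are counted, and when the map spans more than a
    full turn the pixels beyond the first 360 degrees are excluded so
    re-seen surface is not double counted.
    """
    if beta is None:
        beta = surface_map.beta
    if class_mask.shape != surface_map.coverage.shape:
        raise ValueError("class mask shape must match the map")
    lat = surface_map.lat_centers()
    lon = surface_map.lon_centers()
    step = math.degrees(beta)
    lam0 = lat[:, None] - step / 2.0  # patch lower edge
    phi0 = lon[None, :] - step / 2.0
    areas = pixel_area(lam0, phi0, model, beta)
    counted = surface_map.coverage > 0
    counted &= (lon < surface_map.lon_start + 360.0)[None, :]
    total = float(np.sum(areas[counted]))
    if total <= 0:
        raise ValueError("no covered surface to measure")
    return float(np.sum(areas[counted & (class_mask > 0)]) / total)
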