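"""Spheroid geometry of a fruit from its view silhouettes.

A piece of fruit is modeled as a spheroid (ellipsoid of revolution)
described by three principal radii ``rx, ry, rz`` where by construction
the distinct axis — the axis of revolution, approximately the rotation
axis of the fruit on the machine — is the fruit *y*-axis, so
``rx == rz`` always and the geometry class follows from comparing
``ry`` with the common radius:

* oblate:    ``ry < rx == rz`` (mandarins, many tomatoes)
* spherical: ``ry == rx == rz``
* prolate:   ``ry > rx == rz`` (some lemon-like shapes)

Coordinates follow the view-centric convention: *x* rightward, *y*
upward, *z* toward the camera, origin at the fruit's center of mass.
Raster row/column indices are converted at the I/O boundary
(``x = col - cx``, ``y = cy - row``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "SpheroidModel",
    "SilhouetteEllipse",
    "ViewObservation",
    "FruitFrame",
    "fit_silhouette",
    "classify_geometry",
    "select_reference_view",
    "estimate_model",
    "init_fruit_frame",
    "surface_height",
]

GEOMETRY_CLASSES = ("oblate", "spherical", "prolate")

#: minimum silhouette size for a usable fit
_MIN_FOREGROUND_PIXELS = 100


@dataclass(frozen=True)
class SpheroidModel:
    """Principal radii (pixels) and geometry class of a fruit.

    The revolution axis is the fruit *y*-axis: ``rx == rz`` within a
    small relative tolerance, and ``ry`` is the distinct radius (equal
    to the others only in the spherical case).
    """

    rx: float
    ry: float
    rz: float
    geometry_class: str

    def __post_init__(self) -> None:
        if min(self.rx, self.ry, self.rz) <= 0:
            raise ValueError("spheroid radii must be strictly positive")
        if self.geometry_class not in GEOMETRY_CLASSES:
            raise ValueError(f"unknown geometry class {self.geometry_class!r}")
        if abs(self.rx - self.rz) > 1e-6 * max(self.rx, self.rz):
            raise ValueError("revolution axis is y: rx and rz must be equal")
        if self.geometry_class == "oblate" and not self.ry < self.rx:
            raise ValueError("oblate requires ry < rx == rz")
        if self.geometry_class == "prolate" and not self.ry > self.rx:
            raise ValueError("prolate requires ry > rx == rz")

    @property
    def radii(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz], dtype=float)

    @property
    def r_max(self) -> float:
        """Largest principal radius, the *R* that sets map resolution."""
        return float(max(self.rx, self.ry, self.rz))

    def to_dict(self) -> dict:
        return {
            "rx": self.rx,
            "ry": self.ry,
            "rz": self.rz,
            "geometry_class": self.geometry_class,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SpheroidModel":
        return cls(d["rx"], d["ry"], d["rz"], d["geometry_class"])


@dataclass(frozen=True)
class SilhouetteEllipse:
    """Second-moment ellipse of a silhouette.

    ``theta_deg`` is the angle of the major axis measured
    counterclockwise from the +x axis (x right, y up), in [0, 180).
    """

    center: tuple[float, float]  # (x, y) relative to raster origin, y up is NOT applied here; see fit_silhouette
    a: float  # semi-major (px)
    b: float  # semi-minor (px)
    theta_deg: float

    def __post_init__(self) -> None:
        if not (self.a >= self.b > 0):
            raise ValueError("ellipse requires a >= b > 0")

    def axis_directions(self) -> tuple[np.ndarray, np.ndarray]:
        """Unit vectors (x, y up) of the major and minor axes."""
        t = np.deg2rad(self.theta_deg)
        major = np.array([np.cos(t), np.sin(t)])
        minor = np.array([-np.sin(t), np.cos(t)])
        return major, minor

    def semiaxis_near_vertical(self) -> tuple[float, float]:
        """Split semi-axes into (near-vertical, near-horizontal) lengths.

        Ties at exactly 45 degrees go to the major axis.
        """
        major, _minor = self.axis_directions()
        if abs(major[1]) >= abs(major[0]):
            return self.a, self.b
        return self.b, self.a


@dataclass
class ViewObservation:
    """One view of a fruit: image, mask, centroid and silhouette ellipse.

    ``centroid`` is in raster coordinates (col, row) of the foreground
    center of mass; the ellipse angle is already in the y-up convention.
    """

    image: np.ndarray | None
    mask: np.ndarray
    centroid: tuple[float, float] = field(default=(0.0, 0.0))
    ellipse: SilhouetteEllipse | None = None


@dataclass(frozen=True)
class FruitFrame:
    """Orthonormal right-handed fruit-axis triad in view coordinates."""

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if np.abs(m.T @ m - np.eye(3)).max() > 1e-9:
            raise ValueError("fruit frame must be orthonormal")
        if abs(np.linalg.det(m) - 1.0) > 1e-9:
            raise ValueError("fruit frame must be right-handed (det +1)")

    @property
    def matrix(self) -> np.ndarray:
        """3x3 matrix with the fruit axes as columns."""
        return np.column_stack([self.vx, self.vy, self.vz])

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "FruitFrame":
        m = np.asarray(m, dtype=float)
        return cls(m[:, 0].copy(), m[:, 1].copy(), m[:, 2].copy())

    @classmethod
    def identity(cls) -> "FruitFrame":
        return cls.from_matrix(np.eye(3))

    def to_list(self) -> list:
        return self.matrix.tolist()


def fit_silhouette(mask: np.ndarray) -> ViewObservation:
    """Fit centroid and second-moment ellipse to a binary silhouette.

    Parameters
    ----------
    mask
        Binary foreground raster (nonzero = fruit). Must contain a
        single connected component of at least 100 pixels.

    Returns
    -------
    ViewObservation with ``centroid`` (col, row) and ``ellipse`` set
    (image left as None). The ellipse semi-axes come from the central
    second moments of the solid silhouette (variance along a principal
    axis of a solid ellipse with semi-axis *a* is ``a**2 / 4``).
    """
    mask = np.asarray(mask) > 0
    n = int(mask.sum())
    if n < _MIN_FOREGROUND_PIXELS:
        raise ValueError(
            f"silhouette too small or empty ({n} px, need >= {_MIN_FOREGROUND_PIXELS})"
        )
    labels, n_comp = ndimage.label(mask)
    if n_comp > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_comp + 1))
        large = np.sum(sizes >= _MIN_FOREGROUND_PIXELS)
        if large > 1:
            raise ValueError(f"{large} large connected components; expected one")
        # keep the dominant component, drop speckle
        mask = labels == (int(np.argmax(sizes)) + 1)

    rows, cols = np.nonzero(mask)
    cy = rows.mean()
    cx = cols.mean()
    # y-up centered coordinates
    x = cols - cx
    y = cy - rows
    mu20 = np.mean(x * x)
    mu02 = np.mean(y * y)
    mu11 = np.mean(x * y)
    common = mu20 + mu02
    diff = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    a = 2.0 * np.sqrt((common + diff) / 2.0)
    b = 2.0 * np.sqrt(max(common - diff, 0.0) / 2.0)
    theta = 0.5 * np.degrees(np.arctan2(2 * mu11, mu20 - mu02)) % 180.0
    ellipse = SilhouetteEllipse(center=(cx, cy), a=a, b=max(b, 1e-9), theta_deg=theta)
    return ViewObservation(image=None, mask=mask, centroid=(cx, cy), ellipse=ellipse)


def _require_ellipses(views: list[ViewObservation]) -> None:
    if any(v.ellipse is None for v in views):
        raise ValueError("all views need a fitted silhouette ellipse")


def classify_geometry(views: list[ViewObservation], tol_rel: float = 0.03) -> str:
    """Classify the fruit as oblate, spherical or prolate.

    Spherical when every silhouette is circular within ``tol_rel``
    relative eccentricity. Otherwise the semi-axis aligned with the
    near-vertical rotation axis is stable across views (the orthogonal
    one oscillates with the rotation); its median is the distinct
    radius estimate, compared against the median of the oscillating
    horizontal semi-axis.
    """
    if len(views) < 3:
        raise ValueError("geometry classification needs at least 3 views")
    _require_ellipses(views)
    ecc = max((v.ellipse.a - v.ellipse.b) / v.ellipse.a for v in views)
    if ecc <= tol_rel:
        return "spherical"
    vert = np.median([v.ellipse.semiaxis_near_vertical()[0] for v in views])
    horiz = np.median([v.ellipse.semiaxis_near_vertical()[1] for v in views])
    return "oblate" if vert < horiz else "prolate"


def select_reference_view(views: list[ViewObservation], geometry_class: str) -> int:
    """Pick the view where the fruit frame is initialized.

    Spherical fruit use the first view. For non-spherical fruit the
    reference is the view where the distinct axis lies in the image
    plane: shortest silhouette minor axis for oblate fruit, longest
    major axis for prolate. Ties break to the earliest index.
    """
    if geometry_class == "spherical":
        return 0
    _require_ellipses(views)
    if geometry_class == "oblate":
        return int(np.argmin([v.ellipse.b for v in views]))
    if geometry_class == "prolate":
        return int(np.argmax([v.ellipse.a for v in views]))
    raise ValueError(f"unknown geometry class {geometry_class!r}")


def estimate_model(
    views: list[ViewObservation],
    geometry_class: str,
    reference_index: int,
) -> SpheroidModel:
    """Estimate the spheroid radii from the silhouette ellipses.

    The common radii ``rx == rz`` are the median across views of the
    semi-axis aligned with the rotation direction (near-horizontal),
    which is robust to segmentation noise; the distinct radius ``ry``
    is the near-vertical semi-axis at the reference view, where the
    distinct axis lies in the image plane and is seen at full length.
    """
    _require_ellipses(views)
    if geometry_class == "spherical":
        r = float(np.median([(v.ellipse.a + v.ellipse.b) / 2 for v in views]))
        return SpheroidModel(r, r, r, "spherical")
    common = float(np.median([v.ellipse.semiaxis_near_vertical()[1] for v in views]))
    distinct = float(views[reference_index].ellipse.semiaxis_near_vertical()[0])
    if geometry_class == "oblate" and distinct >= common:
        distinct = min(distinct, common * (1 - 1e-6))
    if geometry_class == "prolate" and distinct <= common:
        distinct = max(distinct, common * (1 + 1e-6))
    return SpheroidModel(common, distinct, common, geometry_class)


def init_fruit_frame(ref_view: ViewObservation, geometry_class: str) -> FruitFrame:
    """Initialize the fruit-axis triad at the reference view.

    ``vz = (0, 0, 1)`` toward the camera for all geometries. Spherical
    fruit take the view axes. Otherwise the fruit *y*-axis is the
    in-plane silhouette principal direction making the smaller angle
    with the image vertical (the expected rotation axis on the
    machine), signed to point upward; ``vx = vy x vz`` completes a
    right-handed triad with both vx, vy parallel to the image plane.
    """
    vz = np.array([0.0, 0.0, 1.0])
    if geometry_class == "spherical":
        return FruitFrame.identity()
    ell = ref_view.ellipse
    if ell is None:
        raise ValueError("reference view needs a fitted ellipse")
    if (ell.a - ell.b) / ell.a < 1e-6:
        warnings.warn(
            "reference silhouette is circular; falling back to a vertical fruit y-axis",
            stacklevel=2,
        )
        dir2d = np.array([0.0, 1.0])
    else:
        major, minor = ell.axis_directions()
        # smaller angle with vertical; exact 45-degree tie goes to the major axis
        dir2d = major if abs(major[1]) >= abs(minor[1]) else minor
    if dir2d[1] < 0:
        dir2d = -dir2d
    vy = np.array([dir2d[0], dir2d[1], 0.0])
    vx = np.cross(vy, vz)
    return FruitFrame(vx, vy, vz)


def surface_height(
    x: np.ndarray | float,
    y: np.ndarray | float,
    model: SpheroidModel,
    frame: FruitFrame,
) -> np.ndarray | float:
    """Height z of the visible spheroid surface above view point (x, y).

    (x, y) are view coordinates relative to the fruit centroid. The
    orthographic viewing ray ``{(x, y, t)}`` is intersected with the
    fruit-frame ellipsoid ``(X/rx)^2 + (Y/ry)^2 + (Z/rz)^2 = 1`` and
    the camera-side (largest t) root is returned. Points outside the
    silhouette yield NaN (the no-intersection signal), not an error.
    """
    m = frame.matrix
    quad = m @ np.diag(1.0 / model.radii**2) @ m.T
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    a = quad[2, 2]
    b = 2.0 * (quad[0, 2] * x + quad[1, 2] * y)
    c = quad[0, 0] * x * x + 2.0 * quad[0, 1] * x * y + quad[1, 1] * y * y - 1.0
    disc = b * b - 4.0 * a * c
    with np.errstate(invalid="ignore"):
        z = (-b + np.sqrt(disc)) / (2.0 * a)
    if np.ndim(z) == 0:
        return float(z)
    return z
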