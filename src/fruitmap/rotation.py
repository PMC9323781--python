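"""Inter-view 3D rotation estimation and chaining.

The fruit axes rotate rigidly with the fruit, so the frame at any view
follows from the frame at the reference view and the chained product
of consecutive pairwise rotations. The pairwise estimator works from
image texture alone — no encoder or conveyor information: ORB
keypoints matched between the two masked views are back-projected onto
the spheroid surface (orthographic ray-quadric intersection), and the
rotation relating the two 3D point sets is solved as an orthogonal
Procrustes problem inside a random-sample consensus loop. This needs
visible surface texture and enough overlap, i.e. inter-view rotations
of roughly 20-40 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import ORB, match_descriptors

from .geometry import FruitFrame, SpheroidModel, ViewObservation, surface_height

__all__ = [
    "RotationChain",
    "RotationEstimationError",
    "estimate_pairwise_rotation",
    "estimate_chain",
    "chain_rotations",
    "propagate_frame",
]

_ORTHO_TOL = 1e-9  # drift beyond this triggers re-orthonormalization


class RotationEstimationError(RuntimeError):
    """Raised when a pairwise rotation cannot be estimated.

    Typical causes: textureless surface (too few keypoints), too little
    overlap between the views, or not enough consensus inliers.
    """


@dataclass
class RotationChain:
    """Consecutive pairwise rotations R_i^{i+1} plus QC metadata."""

    pairwise: list  # of 3x3 ndarrays, length n_views - 1
    reference_index: int = 0
    inlier_counts: list = field(default_factory=list)
    residuals: list = field(default_factory=list)  # mean inlier residual (px)
    substituted: list = field(default_factory=list)  # pair indices interpolated

    def __post_init__(self) -> None:
        for k, R in enumerate(self.pairwise):
            R = np.asarray(R, dtype=float)
            if np.abs(R.T @ R - np.eye(3)).max() > 1e-6 or abs(np.linalg.det(R) - 1) > 1e-6:
                raise ValueError(f"pairwise[{k}] is not a rotation matrix")
            self.pairwise[k] = R
        n = self.n_views
        if not (0 <= self.reference_index < n):
            raise ValueError("reference index out of range")

    @property
    def n_views(self) -> int:
        return len(self.pairwise) + 1

    def to_dict(self) -> dict:
        return {
            "pairwise": [R.tolist() for R in self.pairwise],
            "reference_index": self.reference_index,
            "inlier_counts": self.inlier_counts,
            "residuals": self.residuals,
            "substituted": self.substituted,
        }


def _orthonormalize(R: np.ndarray) -> np.ndarray:
    """Project onto the nearest rotation (polar decomposition)."""
    u, _, vt = np.linalg.svd(R)
    out = u @ vt
    if np.linalg.det(out) < 0:
        out = u @ np.diag([1.0, 1.0, -1.0]) @ vt
    return out


def _kabsch(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Rotation R minimizing ||q - R p|| about the origin (no centering:
    both point sets are already centroid-relative)."""
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    return vt.T @ np.diag([1.0, 1.0, d]) @ u.T


def _backproject(
    keypoints_rc: np.ndarray,
    view: ViewObservation,
    model: SpheroidModel,
    frame: FruitFrame,
    min_height_frac: float = 0.12,
) -> tuple[np.ndarray, np.ndarray]:
    """Lift (row, col) keypoints to 3D view coordinates on the spheroid.

    Points whose viewing ray misses the quadric, or whose height is a
    small fraction of the fruit radius (near the silhouette, where
    height is ill-conditioned), are rejected.
    """
    cx, cy = view.centroid
    x = keypoints_rc[:, 1] - cx
    y = cy - keypoints_rc[:, 0]
    z = surface_height(x, y, model, frame)
    ok = np.isfinite(z) & (z > min_height_frac * model.r_max)
    return np.column_stack([x, y, z])[ok], ok


def estimate_pairwise_rotation(
    view_a: ViewObservation,
    view_b: ViewObservation,
    model: SpheroidModel,
    frame_a: FruitFrame,
    seed: int = 0,
    n_keypoints: int = 500,
    min_inliers: int = 6,
    n_trials: int = 300,
    inlier_tol: float | None = None,
) -> tuple[np.ndarray, dict]:
    """Estimate the 3D rotation carrying view_a surface points to view_b.

    Matched texture keypoints are back-projected with the spheroid
    model (the quadric orientation of ``frame_a`` serves both views:
    rotation happens about the fruit's near-symmetry axis, which
    leaves the view-space quadric essentially unchanged), then a
    3-point random-sample consensus over the orthogonal Procrustes
    solution rejects bad matches and the rotation is refit on inliers.

    Returns ``(R, qc)`` with ``qc = {"n_inliers", "residual"}``.
    Raises :class:`RotationEstimationError` when fewer than
    ``min_inliers`` matches survive.
    """
    if inlier_tol is None:
        inlier_tol = max(3.0, 0.03 * model.r_max)
    from scipy.ndimage import distance_transform_edt

    margin = max(4.0, 0.08 * model.r_max)  # silhouette corners are not texture
    pts = []
    descs = []
    for view in (view_a, view_b):
        if view.image is None:
            raise ValueError("views need images for rotation estimation")
        gray = rgb2gray(view.image) if view.image.ndim == 3 else view.image / 255.0
        orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
        try:
            orb.detect_and_extract(gray)
        except RuntimeError as exc:  # no keypoints at all
            raise RotationEstimationError(f"no texture keypoints: {exc}") from exc
        kp = orb.keypoints
        rows = np.clip(kp[:, 0].astype(int), 0, view.mask.shape[0] - 1)
        cols = np.clip(kp[:, 1].astype(int), 0, view.mask.shape[1] - 1)
        depth = distance_transform_edt(np.asarray(view.mask) > 0)
        interior = depth[rows, cols] > margin
        pts.append(kp[interior])
        descs.append(orb.descriptors[interior])
    if min(len(p) for p in pts) < min_inliers:
        raise RotationEstimationError("too few texture keypoints on the fruit")

    matches = match_descriptors(descs[0], descs[1], cross_check=True)
    p_a, ok_a = _backproject(pts[0][matches[:, 0]], view_a, model, frame_a)
    kp_b = pts[1][matches[:, 1]][ok_a]
    p_b, ok_b = _backproject(kp_b, view_b, model, frame_a)
    p_a = p_a[ok_b]
    n = len(p_a)
    if n < min_inliers:
        raise RotationEstimationError(f"only {n} back-projected matches")

    rng = np.random.default_rng(seed)
    best_inliers: np.ndarray | None = None
    for _ in range(n_trials):
        idx = rng.choice(n, size=3, replace=False)
        R = _kabsch(p_a[idx], p_b[idx])
        res = np.linalg.norm(p_b - p_a @ R.T, axis=1)
        inl = res < inlier_tol
        if best_inliers is None or inl.sum() > best_inliers.sum():
            best_inliers = inl
    if best_inliers is None or best_inliers.sum() < min_inliers:
        raise RotationEstimationError(
            f"consensus failed: {0 if best_inliers is None else int(best_inliers.sum())} inliers"
        )
    # refit on inliers, then once more after re-gating
    for _ in range(2):
        R = _kabsch(p_a[best_inliers], p_b[best_inliers])
        res = np.linalg.norm(p_b - p_a @ R.T, axis=1)
        best_inliers = res < inlier_tol
    if best_inliers.sum() < min_inliers:
        raise RotationEstimationError("refit lost consensus")
    R = _kabsch(p_a[best_inliers], p_b[best_inliers])
    qc = {
        "n_inliers": int(best_inliers.sum()),
        "residual": float(res[best_inliers].mean()),
    }
    return R, qc


def estimate_chain(
    views: list[ViewObservation],
    model: SpheroidModel,
    frame_ref: FruitFrame,
    reference_index: int = 0,
    seed: int = 0,
    **estimator_kwargs,
) -> RotationChain:
    """Estimate all consecutive pairwise rotations of a sequence.

    The reference frame's quadric orientation is used for every pair
    (valid because the fruit spins about its near-vertical symmetry
    axis). A failed pair is substituted by the geodesic mean of its
    neighboring pairwise rotations; if an isolated estimate is
    impossible the whole chain fails.
    """
    from scipy.spatial.transform import Rotation

    n = len(views)
    pairwise: list = [None] * (n - 1)
    inliers = [0] * (n - 1)
    residuals = [float("nan")] * (n - 1)
    failed = []
    for i in range(n - 1):
        try:
            R, qc = estimate_pairwise_rotation(
                views[i], views[i + 1], model, frame_ref, seed=seed + i, **estimator_kwargs
            )
            pairwise[i] = R
            inliers[i] = qc["n_inliers"]
            residuals[i] = qc["residual"]
        except RotationEstimationError:
            failed.append(i)
    for i in failed:
        neighbors = [
            pairwise[j] for j in (i - 1, i + 1) if 0 <= j < n - 1 and pairwise[j] is not None
        ]
        if not neighbors:
            raise RotationEstimationError(
                f"pair {i} failed and has no successful neighbor to interpolate from"
            )
        pairwise[i] = Rotation.from_matrix(np.array(neighbors)).mean().as_matrix()
    return RotationChain(
        pairwise=pairwise,
        reference_index=reference_index,
        inlier_counts=inliers,
        residuals=residuals,
        substituted=failed,
    )


def chain_rotations(chain: RotationChain, i: int, j: int) -> np.ndarray:
    """Rotation R_i^j between arbitrary views by chaining pairwise ones.

    Forward (j > i) is the ordered product of the consecutive
    matrices; backward uses their inverses (transposes). The product
    is re-projected onto the nearest rotation whenever numerical
    drift from orthogonality exceeds tolerance.
    """
    n = chain.n_views
    if not (0 <= i < n and 0 <= j < n):
        raise IndexError(f"view index out of range (n={n})")
    R = np.eye(3)
    if j > i:
        for k in range(i, j):
            R = chain.pairwise[k] @ R
    else:
        for k in range(i - 1, j - 1, -1):
            R = chain.pairwise[k].T @ R
    if np.abs(R.T @ R - np.eye(3)).max() > _ORTHO_TOL:
        R = _orthonormalize(R)
    return R


def propagate_frame(frame_ref: FruitFrame, chain: RotationChain, j: int) -> FruitFrame:
    """Fruit frame at view j from the reference frame and the chain."""
    R = chain_rotations(chain, chain.reference_index, j)
    m = R @ frame_ref.matrix
    if np.abs(m.T @ m - np.eye(3)).max() > _ORTHO_TOL:
        m = _orthonormalize(m)
    return FruitFrame.from_matrix(m)
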