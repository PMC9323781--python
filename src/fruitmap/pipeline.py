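"""End-to-end map construction and disk plumbing.

Ties the stages together: silhouette fitting -> geometry model ->
reference view and fruit frame -> pairwise rotation chain -> longitude
schedule -> map fill. Also owns the on-disk formats: views and masks
as PNG, geometry/rotation results and the map sidecar as JSON, so a
map raster stays geo-referenceable bit-exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from . import geometry as geom
from . import mapping, rotation
from .config import PipelineConfig
from .geometry import FruitFrame, SpheroidModel, ViewObservation
from .mapping import SurfaceMap
from .synthetic import GroundTruthBundle

log = logging.getLogger("fruitmap")

__all__ = [
    "PipelineResult",
    "analyze_geometry",
    "build_map",
    "load_views",
    "save_bundle",
    "write_map",
    "read_map",
    "class_mask_from_rule",
    "measure_map",
]


@dataclass
class PipelineResult:
    """A built map plus every intermediate worth auditing."""

    surface_map: SurfaceMap
    model: SpheroidModel
    geometry_class: str
    reference_index: int
    frames: list
    chain: rotation.RotationChain
    schedule: mapping.LongitudeSchedule
    qc: dict = field(default_factory=dict)


def analyze_geometry(
    views: list[ViewObservation], config: PipelineConfig
) -> tuple[SpheroidModel, int, FruitFrame]:
    """Classify geometry, pick the reference view, fit radii and frame."""
    if config.geometry_class != "auto":
        gclass = config.geometry_class
    elif len(views) >= 3:
        gclass = geom.classify_geometry(views, tol_rel=config.tol_spherical)
    else:
        warnings.warn("fewer than 3 views: assuming spherical geometry", stacklevel=2)
        gclass = "spherical"
    ref = geom.select_reference_view(views, gclass)
    model = geom.estimate_model(views, gclass, ref)
    frame_ref = geom.init_fruit_frame(views[ref], gclass)
    return model, ref, frame_ref


def build_map(
    views: list[ViewObservation],
    config: PipelineConfig | None = None,
    chain: rotation.RotationChain | None = None,
    model: SpheroidModel | None = None,
) -> PipelineResult:
    """Run the whole pipeline on silhouette-fitted views.

    A precomputed rotation chain and/or model may be supplied (e.g.
    ground truth from the synthetic renderer); anything missing is
    estimated from the images.
    """
    config = config or PipelineConfig()
    if not views:
        raise ValueError("no views")
    est_model, ref, frame_ref = analyze_geometry(views, config)
    if model is None:
        model = est_model
    if chain is None:
        chain = rotation.estimate_chain(
            views, model, frame_ref, reference_index=ref, seed=config.seed
        )
    elif chain.reference_index != ref:
        chain = rotation.RotationChain(
            pairwise=list(chain.pairwise),
            reference_index=ref,
            inlier_counts=chain.inlier_counts,
            residuals=chain.residuals,
            substituted=chain.substituted,
        )
    frames = [rotation.propagate_frame(frame_ref, chain, j) for j in range(len(views))]
    schedule = mapping.compute_longitude_schedule(
        views, model, frames, preroll=config.preroll_deg, postroll=config.postroll_deg
    )
    beta = mapping.angular_step(model.r_max)
    surface_map = mapping.fill_map(
        views, model, frames, schedule, beta,
        lambda_max=config.lambda_max_deg, interp=config.interp,
    )
    qc = {
        "inlier_counts": chain.inlier_counts,
        "residuals": chain.residuals,
        "substituted_pairs": chain.substituted,
        "unseen_pixels": surface_map.unseen_pixels,
    }
    if chain.substituted:
        log.warning("substituted %d failed pairwise rotations", len(chain.substituted))
    return PipelineResult(
        surface_map=surface_map,
        model=model,
        geometry_class=model.geometry_class,
        reference_index=ref,
        frames=frames,
        chain=chain,
        schedule=schedule,
        qc=qc,
    )


def _mask_from_image(image: np.ndarray, background_thresh: float = 40.0) -> np.ndarray:
    """Foreground = pixels brighter than the (dark) machine background."""
    lum = image.mean(axis=-1) if image.ndim == 3 else image
    return (lum > background_thresh).astype(np.uint8) * 255


def load_views(
    input_dir: str | Path,
    manifest: str | None = "manifest.json",
    background_thresh: float = 40.0,
) -> list[ViewObservation]:
    """Load an ordered view sequence from a directory.

    Views are ``view_*.png`` (or ``.tif``) sorted by filename, each
    with an optional ``mask_*`` sibling; absent masks are derived by
    thresholding against the dark background. A ``manifest.json``
    listing ``{"views": [...], "masks": [...]}`` overrides the sort.
    """
    input_dir = Path(input_dir)
    man = input_dir / manifest if manifest else None
    if man is not None and man.exists():
        listing = json.loads(man.read_text())
        view_paths = [input_dir / p for p in listing["views"]]
        mask_paths = [input_dir / p if p else None for p in listing.get("masks") or []]
        if not mask_paths:
            mask_paths = [None] * len(view_paths)
    else:
        view_paths = sorted(
            p for p in input_dir.iterdir()
            if p.name.startswith("view_") and p.suffix.lower() in (".png", ".tif", ".tiff")
        )
        mask_paths = [
            (m if (m := p.with_name(p.name.replace("view_", "mask_"))).exists() else None)
            for p in view_paths
        ]
    if not view_paths:
        raise FileNotFoundError(f"no view images found in {input_dir}")
    views = []
    for vp, mp in zip(view_paths, mask_paths):
        try:
            image = np.asarray(iio.imread(vp))
        except Exception as exc:
            raise OSError(f"unreadable view image {vp}: {exc}") from exc
        if image.ndim == 3 and image.shape[2] == 4:
            image = image[:, :, :3]
        if mp is not None:
            mask = np.asarray(iio.imread(mp))
            if mask.ndim == 3:
                mask = mask[:, :, 0]
        else:
            mask = _mask_from_image(image, background_thresh)
        obs = geom.fit_silhouette(mask)
        obs.image = image
        views.append(obs)
    return views


def save_bundle(bundle: GroundTruthBundle, out_dir: str | Path) -> Path:
    """Write a synthetic sequence as view/mask PNGs plus truth.json."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scene = bundle.scene
    for i, view in enumerate(bundle.views):
        iio.imwrite(out_dir / f"view_{i:03d}.png", view.image)
        iio.imwrite(
            out_dir / f"mask_{i:03d}.png", (np.asarray(view.mask) > 0).astype(np.uint8) * 255
        )
    iio.imwrite(out_dir / "texture.png", scene.texture)
    truth = {
        "radii": scene.model.radii.tolist(),
        "geometry_class": scene.model.geometry_class,
        "rotation_axis": scene.rotation_axis.tolist(),
        "step_angles_deg": scene.step_angles.tolist(),
        "pairwise_rotations": [R.tolist() for R in bundle.pairwise_rotations],
        "frames": [f.to_list() for f in bundle.frames],
        "spots": scene.spots,
        "seed": scene.seed,
        "noise_sigma": scene.noise_sigma,
    }
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=1))
    return out_dir


def write_map(
    surface_map: SurfaceMap, path: str | Path, write_coverage: bool = True
) -> Path:
    """Write the map PNG with its geo-reference JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, surface_map.pixels)
    sched = surface_map.schedule
    sidecar = {
        "beta": surface_map.beta,
        "lambda_max": surface_map.lambda_max,
        "lon_start": surface_map.lon_start,
        "lon_end": surface_map.lon_end,
        "L": sched.L.tolist() if sched is not None else [],
        "preroll": sched.preroll if sched is not None else 0.0,
        "postroll": sched.postroll if sched is not None else 0.0,
        **surface_map.meta,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if write_coverage:
        iio.imwrite(path.with_name(path.stem + "_coverage.png"), surface_map.coverage)
    return path


def read_map(path: str | Path) -> tuple[SurfaceMap, SpheroidModel]:
    """Load a map PNG + sidecar (+ coverage if present) back."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing map sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    pixels = np.asarray(iio.imread(path))[:, :, :3]
    cov_path = path.with_name(path.stem + "_coverage.png")
    if cov_path.exists():
        coverage = np.asarray(iio.imread(cov_path)).astype(np.uint8)
    else:
        coverage = np.ones(pixels.shape[:2], dtype=np.uint8)
    schedule = None
    if meta.get("L"):
        schedule = mapping.LongitudeSchedule(
            L=np.asarray(meta["L"]), preroll=meta["preroll"], postroll=meta["postroll"]
        )
    smap = SurfaceMap(
        pixels=pixels,
        coverage=coverage,
        beta=meta["beta"],
        lambda_max=meta["lambda_max"],
        lon_start=meta["lon_start"],
        lon_end=meta["lon_end"],
        schedule=schedule,
        meta={k: meta[k] for k in ("radii", "geometry_class") if k in meta},
    )
    rx, ry, rz = meta["radii"]
    model = SpheroidModel(rx, ry, rz, meta["geometry_class"])
    return smap, model


def class_mask_from_rule(pixels: np.ndarray, rule: str) -> np.ndarray:
    """Binary class mask from a simple color-threshold rule.

    ``green``       green channel dominates both others by a margin
    ``dark[:T]``    mean intensity below T (default 80)
    """
    rgb = pixels.astype(float)
    if rule == "green":
        return (rgb[:, :, 1] > rgb[:, :, 0] + 20) & (rgb[:, :, 1] > rgb[:, :, 2] + 20)
    if rule.startswith("dark"):
        thresh = float(rule.split(":", 1)[1]) if ":" in rule else 80.0
        return rgb.mean(axis=-1) < thresh
    raise ValueError(f"unknown mask rule {rule!r}")


def detect_spots(
    surface_map: SurfaceMap,
    rule: str = "dark",
    min_pixels: int = 4,
    dedup_tol_deg: float = 6.0,
) -> list[dict]:
    """Locate compact defect spots on a map, deduplicated modulo 360.

    Connected components of the rule's class mask (covered pixels
    only) become candidate spots; when the map spans more than a full
    turn the same surface point appears twice 360 degrees apart, so
    detections whose longitudes agree modulo 360 (and latitudes agree)
    within ``dedup_tol_deg`` are merged. Returns one
    ``{"phi", "lam", "n_pixels"}`` per unique spot, with phi folded
    into the first turn.
    """
    from scipy.ndimage import label as cc_label

    mask = class_mask_from_rule(surface_map.pixels, rule) & (surface_map.coverage > 0)
    labels, n = cc_label(mask)
    lat = surface_map.lat_centers()
    lon = surface_map.lon_centers()
    raw = []
    for k in range(1, n + 1):
        rr, cc = np.nonzero(labels == k)
        if rr.size < min_pixels:
            continue
        raw.append({"phi": float(lon[cc].mean()), "lam": float(lat[rr].mean()),
                    "n_pixels": int(rr.size)})
    unique: list[dict] = []
    for s in sorted(raw, key=lambda s: -s["n_pixels"]):
        dup = False
        for u in unique:
            dphi = abs(s["phi"] - u["phi"]) % 360.0
            dphi = min(dphi, 360.0 - dphi)
            # compare along-surface longitude distance at this latitude
            if dphi * np.cos(np.deg2rad(u["lam"])) < dedup_tol_deg and abs(
                s["lam"] - u["lam"]
            ) < dedup_tol_deg:
                dup = True
                break
        if not dup:
            unique.append(dict(s, phi=((s["phi"] - surface_map.lon_start) % 360.0)
                               + surface_map.lon_start))
    return unique


def measure_map(map_path: str | Path, rule: str) -> dict:
    """Area-weighted surface fraction of a stored map matching a rule."""
    smap, model = read_map(map_path)
    class_mask = class_mask_from_rule(smap.pixels, rule)
    frac = mapping.surface_fraction(smap, class_mask, model)
    return {
        "rule": rule,
        "fraction": frac,
        "covered_pixels": int(np.sum(smap.coverage > 0)),
        "matched_pixels": int(np.sum(class_mask & (smap.coverage > 0))),
    }
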