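"""Map-view correspondence, schedule, blending, fill and measurement."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fruitmap.config import PipelineConfig
from fruitmap.geometry import FruitFrame, SpheroidModel
from fruitmap.mapping import (
    LongitudeSchedule,
    angular_step,
    blend_weights,
    compute_longitude_schedule,
    fill_map,
    lonlat_to_surface,
    map_dimensions,
    pixel_area,
    surface_fraction,
    surface_to_view,
    view_to_lonlat,
)
from fruitmap.pipeline import build_map
from fruitmap.rotation import RotationChain
from fruitmap.synthetic import _sample_texture

SPHERE = SpheroidModel(100, 100, 100, "spherical")
OBLATE = SpheroidModel(125, 95, 125, "oblate")
PROLATE = SpheroidModel(95, 125, 95, "prolate")


class TestCorrespondence:
    def test_equator_prime_meridian(self):
        p = lonlat_to_surface(0, 0, OBLATE)
        assert (p.X, p.Y, p.Z) == pytest.approx((125, 0, 0))

    def test_ninety_longitude_points_at_camera(self):
        p = lonlat_to_surface(90, 0, OBLATE)
        assert (p.X, p.Y, p.Z) == pytest.approx((0, 0, 125), abs=1e-12)

    def test_direct_substitution(self):
        p = lonlat_to_surface(30, 45, OBLATE)
        cl = math.cos(math.radians(45))
        assert p.X == pytest.approx(125 * cl * math.cos(math.radians(30)))
        assert p.Y == pytest.approx(95 * math.sin(math.radians(45)))
        assert p.Z == pytest.approx(125 * cl * math.sin(math.radians(30)))

    def test_identity_frame_passthrough(self):
        p = lonlat_to_surface(40, 10, SPHERE)
        x, y, z, vis = surface_to_view(p, FruitFrame.identity())
        assert (x, y, z) == pytest.approx((p.X, p.Y, p.Z))
        assert vis

    def test_back_side_flagged_invisible(self):
        p = lonlat_to_surface(-90, 0, SPHERE)  # Z = -r
        *_, z, vis = surface_to_view(p, FruitFrame.identity())
        assert z < 0 and not vis

    def test_frame_rotated_about_view_y(self):
        """90 deg about the view y-axis carries the fruit x-axis onto
        the view z-axis."""
        rot = Rotation.from_euler("y", 90, degrees=True).as_matrix()
        frame = FruitFrame.from_matrix(rot)
        p = lonlat_to_surface(0, 0, SPHERE)  # (r, 0, 0) in fruit coords
        x, y, z, vis = surface_to_view(p, frame)
        assert (x, y, z) == pytest.approx((0, 0, -100), abs=1e-9)
        assert not vis

    def test_centroid_maps_to_ninety_longitude(self):
        phi, lam = view_to_lonlat(0, 0, SPHERE, FruitFrame.identity())
        assert (phi, lam) == pytest.approx((90.0, 0.0))

    def test_outside_silhouette_signals(self):
        phi, lam = view_to_lonlat(500, 0, SPHERE, FruitFrame.identity())
        assert np.isnan(phi) and np.isnan(lam)

    @pytest.mark.parametrize("model", [SPHERE, OBLATE, PROLATE])
    def test_round_trip_identity(self, model, rng):
        """lonlat -> fruit xyz -> view xy -> lonlat is the identity for
        visible points, under arbitrary frames. Visibility means the
        outward surface normal faces the camera (for tilted spheroids
        a z > 0 point can still be on the hidden far side of the ray).
        """
        for k in range(50):
            frame = FruitFrame.from_matrix(
                Rotation.random(random_state=k).as_matrix()
            )
            phi0 = rng.uniform(-179, 179)
            lam0 = rng.uniform(-80, 80)
            p = lonlat_to_surface(phi0, lam0, model)
            x, y, z, vis = surface_to_view(p, frame)
            normal = frame.matrix @ (
                np.array([p.X, p.Y, p.Z]) / np.array(
                    [model.rx, model.ry, model.rz]) ** 2
            )
            if not vis or normal[2] < 0.05 * np.linalg.norm(normal):
                continue
            phi1, lam1 = view_to_lonlat(x, y, model, frame)
            assert phi1 == pytest.approx(phi0, abs=1e-6)
            assert lam1 == pytest.approx(lam0, abs=1e-6)

    def test_matches_renderer_ground_truth(self, sphere_bundle):
        """view_to_lonlat agrees with the renderer's stored per-pixel
        angles on real rendered views."""
        model = sphere_bundle.scene.model
        for i in (0, 5):
            frame = sphere_bundle.frames[i]
            gt = sphere_bundle.lonlat_rasters[i]
            v = sphere_bundle.views[i]
            cx, cy = v.centroid
            ok = 0
            pts = [(30, -20), (0, 0), (-25, 35), (10, 40)]
            for px, py in pts:
                # snap to the raster pixel the ground truth is stored at
                r, c = int(round(cy - py)), int(round(cx + px))
                phi, lam = view_to_lonlat(c - cx, cy - r, model, frame)
                gphi, glam = gt[r, c]
                dphi = min(abs(phi - gphi), 360 - abs(phi - gphi))
                if dphi < 0.5 and abs(lam - glam) < 0.5:
                    ok += 1
            assert ok >= len(pts) - 1


class TestLongitudeSchedule:
    def test_wrap_adds_full_turn(self):
        # raw longitudes [170, -170]: the drop triggers a +360 unwrap
        frames = [
            FruitFrame.from_matrix(
                Rotation.from_euler("y", a, degrees=True).as_matrix()
            )
            for a in (80, 100)  # raw L = 90 + a, i.e. [170, -170]
        ]
        views = [None, None]
        sched = compute_longitude_schedule(views, SPHERE, frames)
        np.testing.assert_allclose(sched.L, [170, 190], atol=1e-9)

    def test_monotone_input_unchanged(self):
        frames = [
            FruitFrame.from_matrix(
                Rotation.from_euler("y", a, degrees=True).as_matrix()
            )
            for a in (0, 30, 60)
        ]
        sched = compute_longitude_schedule([None] * 3, SPHERE, frames)
        np.testing.assert_allclose(sched.L, [90, 120, 150], atol=1e-9)

    def test_thirty_degree_steps_recovered(self, sphere_bundle):
        model = sphere_bundle.scene.model
        sched = compute_longitude_schedule(
            sphere_bundle.views, model, sphere_bundle.frames
        )
        steps = np.diff(sched.L)
        np.testing.assert_allclose(steps, 30.0, atol=2.0)

    @given(st.lists(st.floats(-179.9, 180), min_size=2, max_size=16))
    def test_unwrapped_always_strictly_increasing(self, raw):
        frames = [
            FruitFrame.from_matrix(
                Rotation.from_euler("y", a - 90, degrees=True).as_matrix()
            )
            for a in raw
        ]
        sched = compute_longitude_schedule([None] * len(raw), SPHERE, frames)
        assert np.all(np.diff(sched.L) > 0)

    def test_decreasing_schedule_rejected(self):
        with pytest.raises(ValueError):
            LongitudeSchedule(L=np.array([100.0, 90.0]))


class TestBlendWeights:
    SCHED = LongitudeSchedule(L=np.array([100.0, 130.0, 175.0]))

    def test_knot_gets_full_weight(self):
        assert blend_weights(130.0, self.SCHED) == [(1, 1.0)]

    def test_midpoint_half_half(self):
        w = dict(blend_weights(115.0, self.SCHED))
        assert w == pytest.approx({0: 0.5, 1: 0.5})

    def test_linear_interpolation_values(self):
        w = dict(blend_weights(110.0, self.SCHED))
        assert w[0] == pytest.approx(2 / 3)
        assert w[1] == pytest.approx(1 / 3)

    def test_preroll_single_view(self):
        assert blend_weights(60.0, self.SCHED) == [(0, 1.0)]
        assert blend_weights(200.0, self.SCHED) == [(2, 1.0)]

    def test_outside_span_rejected(self):
        with pytest.raises(ValueError):
            blend_weights(10.0, self.SCHED)

    @given(st.floats(55.0, 220.0))
    def test_weights_sum_to_one(self, phi):
        w = blend_weights(phi, self.SCHED)
        assert len(w) <= 2
        assert sum(v for _, v in w) == pytest.approx(1.0, abs=1e-12)


class TestMapSizing:
    def test_orange_sized_fruit(self):
        beta = angular_step(125)
        assert beta == pytest.approx(0.008)
        rows, cols = map_dimensions(beta, 360.0)
        assert cols == 785
        assert rows == 393

    def test_unit_radius(self):
        assert angular_step(1) == 1.0

    def test_cropped_height(self):
        rows, _ = map_dimensions(angular_step(125), 360.0, lambda_max_deg=60)
        assert rows == round(2 * math.radians(60) * 125)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            angular_step(0)


def texture_mae(surface_map, texture, lat_limit=45.0):
    lat = surface_map.lat_centers()
    lon = surface_map.lon_centers()
    sel = np.abs(lat) < lat_limit
    P, L = np.meshgrid(lon, lat[sel])
    ref = _sample_texture(texture, P, L)
    cov = surface_map.coverage[sel] > 0
    err = np.abs(surface_map.pixels[sel].astype(float) - ref)
    return err[cov].mean()


class TestFillMap:
    def test_single_view_round_trip(self, sphere_bundle):
        """A one-view map is just that view resampled to (phi, lam)."""
        scene = sphere_bundle.scene
        view = sphere_bundle.views[0]
        frame = sphere_bundle.frames[0]
        sched = compute_longitude_schedule([view], scene.model, [frame])
        smap = fill_map(
            [view], scene.model, [frame], sched, angular_step(scene.model.r_max)
        )
        assert texture_mae(smap, scene.texture, lat_limit=30.0) < 2.0

    def test_full_turn_reconstruction(self, sphere_bundle):
        scene = sphere_bundle.scene
        sched = compute_longitude_schedule(
            sphere_bundle.views, scene.model, sphere_bundle.frames
        )
        smap = fill_map(
            sphere_bundle.views, scene.model, sphere_bundle.frames, sched,
            angular_step(scene.model.r_max),
        )
        assert texture_mae(smap, scene.texture) < 5.0
        assert smap.coverage.max() <= 2

    def test_oblate_reconstruction(self, oblate_bundle):
        scene = oblate_bundle.scene
        sched = compute_longitude_schedule(
            oblate_bundle.views, scene.model, oblate_bundle.frames
        )
        smap = fill_map(
            oblate_bundle.views, scene.model, oblate_bundle.frames, sched,
            angular_step(scene.model.r_max),
        )
        assert texture_mae(smap, scene.texture) < 5.0

    def test_blending_idempotent_for_identical_views(self, sphere_bundle):
        """Two coincident views blend to exactly the single-view map."""
        scene = sphere_bundle.scene
        view = sphere_bundle.views[0]
        frame = sphere_bundle.frames[0]
        beta = angular_step(scene.model.r_max)
        sched2 = compute_longitude_schedule(
            [view, view], scene.model, [frame, frame]
        )  # unwrap forces L2 = L1 + 360
        two = fill_map([view, view], scene.model, [frame, frame], sched2, beta)
        sched1 = LongitudeSchedule(
            L=sched2.L[:1], preroll=45.0, postroll=45.0 + 360.0
        )
        one = fill_map([view], scene.model, [frame], sched1, beta)
        # identical content, so blending must not change it (up to the
        # final integer rounding of identical float sums)
        diff = np.abs(two.pixels.astype(int) - one.pixels.astype(int))
        assert diff.max() <= 1

    def test_pole_rows_are_background(self, sphere_bundle):
        scene = sphere_bundle.scene
        view = sphere_bundle.views[0]
        frame = sphere_bundle.frames[0]
        sched = compute_longitude_schedule([view], scene.model, [frame])
        smap = fill_map(
            [view], scene.model, [frame], sched, angular_step(scene.model.r_max),
            lambda_max=60.0,
        )
        lat = smap.lat_centers()
        polar = np.abs(lat) >= 60.0
        assert np.all(smap.pixels[polar] == 128)
        assert np.all(smap.coverage[polar] == 0)


class TestPixelArea:
    def test_sphere_total_area_conserved(self):
        beta = math.radians(1.0)
        lam0 = -90 + np.arange(180)[:, None] * 1.0
        phi0 = np.arange(360)[None, :] * 1.0
        total = pixel_area(lam0, phi0, SPHERE, beta).sum()
        assert total == pytest.approx(4 * math.pi * 100**2, rel=1e-3)

    def test_latitude_weighting(self):
        beta = math.radians(0.01)
        ratio = pixel_area(60.0, 0.0, SPHERE, beta) / pixel_area(0.0, 0.0, SPHERE, beta)
        assert ratio == pytest.approx(0.5, abs=1e-3)

    def test_oblate_total_matches_quadrature_oracle(self):
        # dense midpoint quadrature of the parametric area element
        n_lam, n_phi = 2000, 400
        lam = np.deg2rad(-90 + (np.arange(n_lam) + 0.5) * 180 / n_lam)
        phi = np.deg2rad((np.arange(n_phi) + 0.5) * 360 / n_phi)
        L, P = np.meshgrid(lam, phi, indexing="ij")
        rx, ry, rz = OBLATE.rx, OBLATE.ry, OBLATE.rz
        r_phi = np.stack(
            [-rx * np.cos(L) * np.sin(P), 0 * L, rz * np.cos(L) * np.cos(P)]
        )
        r_lam = np.stack(
            [-rx * np.sin(L) * np.cos(P), ry * np.cos(L), -rz * np.sin(L) * np.sin(P)]
        )
        element = np.linalg.norm(np.cross(r_phi, r_lam, axis=0), axis=0)
        oracle = element.sum() * (np.pi / n_lam) * (2 * np.pi / n_phi)

        beta = math.radians(0.5)
        lam0 = -90 + np.arange(360)[:, None] * 0.5
        phi0 = np.arange(720)[None, :] * 0.5
        total = pixel_area(lam0, phi0, OBLATE, beta).sum()
        assert total == pytest.approx(oracle, rel=5e-3)


class TestSurfaceFraction:
    def _gt_map(self, bundle):
        scene = bundle.scene
        chain = RotationChain(pairwise=list(bundle.pairwise_rotations))
        res = build_map(bundle.views, PipelineConfig(), chain=chain,
                        model=scene.model)
        return res.surface_map, scene.model

    def test_full_mask_is_one(self, sphere_bundle):
        smap, model = self._gt_map(sphere_bundle)
        mask = np.ones(smap.shape, dtype=bool)
        assert surface_fraction(smap, mask, model) == pytest.approx(1.0)

    def test_empty_mask_is_zero(self, sphere_bundle):
        smap, model = self._gt_map(sphere_bundle)
        mask = np.zeros(smap.shape, dtype=bool)
        assert surface_fraction(smap, mask, model) == 0.0

    def test_shape_mismatch_rejected(self, sphere_bundle):
        smap, model = self._gt_map(sphere_bundle)
        with pytest.raises(ValueError):
            surface_fraction(smap, np.ones((3, 3), dtype=bool), model)
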