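"""Synthetic renderer: analytic truth, exact projection, determinism."""

import numpy as np
import pytest
from dataclasses import replace

from woundpatch import CaptureConfig, SceneSpec, circle_scene, render_scene, truth_area
from woundpatch.scene import camera_matrix, project_plane_points

BLOB = dict(
    wound_shape="blob",
    shape_params={"r0": 1.8, "amplitudes": [0.0, 0.12, 0.08], "phases": [0.0, 0.7, 2.1]},
)


class TestTruthArea:
    def test_circle_radius_2_matches_defect_model(self):
        sc = SceneSpec(wound_shape="circle", shape_params={"r": 2.0})
        assert truth_area(sc) == pytest.approx(12.566, abs=5e-3)

    def test_unit_ellipse_is_unit_circle(self):
        sc = SceneSpec(wound_shape="ellipse", shape_params={"a": 1.0, "b": 1.0})
        assert truth_area(sc) == pytest.approx(np.pi, rel=1e-12)

    def test_blob_area_matches_monte_carlo(self):
        """Shoelace area of the blob polygon vs rejection sampling."""
        sc = SceneSpec(**BLOB)
        rng = np.random.default_rng(42)
        lim = 1.8 * (1 + 0.12 + 0.08) * 1.01
        n = 10**6
        x = rng.uniform(-lim, lim, n)
        y = rng.uniform(-lim, lim, n)
        rho = np.hypot(x, y)
        phi = np.arctan2(y, x)
        r_phi = 1.8 * (1 + 0.12 * np.cos(2 * phi + 0.7) + 0.08 * np.cos(3 * phi + 2.1))
        mc_area = (rho <= r_phi).mean() * (2 * lim) ** 2
        assert truth_area(sc) == pytest.approx(mc_area, rel=2e-3)

    def test_unsupported_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            SceneSpec(wound_shape="square", shape_params={"s": 1.0})


class TestProjection:
    def test_fronto_parallel_preserves_square(self, circle_spec):
        cam = CaptureConfig(distance_cm=40, angle_deg=90)
        corners = project_plane_points(cam, circle_spec.patch_corners_cm())
        sides = np.linalg.norm(np.roll(corners, -1, axis=0) - corners, axis=1)
        assert sides.max() / sides.min() == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("d,theta", [(30, 90), (40, 60), (50, 30)])
    def test_corners_match_independent_camera_matrix(self, circle_spec, d, theta):
        """Oracle: direct 3x4 camera-matrix multiply, built from scratch."""
        cam = CaptureConfig(distance_cm=d, angle_deg=theta)
        rendered = render_scene(circle_spec, cam)
        th = np.deg2rad(theta)
        look = np.array([*cam.look_at_cm, 0.0])
        center = look + d * np.array([0.0, -np.cos(th), np.sin(th)])
        z = (look - center) / d
        x = np.array([1.0, 0.0, 0.0])
        y = np.cross(z, x)
        rot = np.vstack([x, y, z])
        k_mat = np.array(
            [
                [cam.focal_px, 0, (cam.image_width_px - 1) / 2],
                [0, cam.focal_px, (cam.image_height_px - 1) / 2],
                [0, 0, 1],
            ]
        )
        expected = []
        for cx, cy in circle_spec.patch_corners_cm():
            pc = rot @ (np.array([cx, cy, 0.0]) - center)
            expected.append(k_mat @ pc / pc[2])
        expected = np.array(expected)[:, :2]
        np.testing.assert_allclose(rendered.projected_patch_corners, expected, atol=1e-9)

    def test_theta90_no_perspective_distortion(self, circle_spec):
        cam = CaptureConfig(distance_cm=40, angle_deg=90)
        corners = project_plane_points(cam, circle_spec.patch_corners_cm())
        side = np.linalg.norm(corners[1] - corners[0])
        area = 0.5 * abs(
            np.dot(corners[:, 0], np.roll(corners[:, 1], -1))
            - np.dot(np.roll(corners[:, 0], -1), corners[:, 1])
        )
        assert side**2 / area == pytest.approx(1.0, abs=1e-6)


class TestRendering:
    def test_seeded_determinism(self, circle_spec):
        sc = replace(circle_spec, noise_sigma=0.02, seed=123)
        cam = CaptureConfig(distance_cm=40, angle_deg=60)
        a = render_scene(sc, cam)
        b = render_scene(sc, cam)
        assert np.array_equal(a.image, b.image)

    def test_different_seed_changes_noise(self, circle_spec):
        cam = CaptureConfig(distance_cm=40, angle_deg=60)
        a = render_scene(replace(circle_spec, noise_sigma=0.02, seed=1), cam)
        b = render_scene(replace(circle_spec, noise_sigma=0.02, seed=2), cam)
        assert not np.array_equal(a.image, b.image)

    def test_truth_mask_area_close_to_analytic(self, fronto_render):
        cam = fronto_render.camera
        px_per_cm = cam.focal_px / cam.distance_cm
        mask_cm2 = fronto_render.truth_mask.sum() / px_per_cm**2
        assert mask_cm2 == pytest.approx(fronto_render.truth_area_cm2, rel=5e-3)

    def test_resolution_doubling_stable_mask_area(self, circle_spec):
        cam1 = CaptureConfig(distance_cm=40, angle_deg=90)
        cam2 = replace(
            cam1,
            focal_px=cam1.focal_px * 2,
            image_width_px=cam1.image_width_px * 2,
            image_height_px=cam1.image_height_px * 2,
        )
        a1 = render_scene(circle_spec, cam1).truth_mask.sum()
        a2 = render_scene(circle_spec, cam2).truth_mask.sum() / 4.0
        assert a2 == pytest.approx(a1, rel=5e-3)

    def test_out_of_frame_patch_raises(self, circle_spec):
        sc = replace(circle_spec, patch_offset_cm=(14.0, 0.0))
        cam = CaptureConfig(distance_cm=30, angle_deg=90)
        with pytest.raises(ValueError, match="patch"):
            render_scene(sc, cam)

    def test_illumination_scales_channels(self, circle_spec):
        cam = CaptureConfig(distance_cm=40, angle_deg=90)
        base = render_scene(circle_spec, cam)
        tinted = render_scene(replace(circle_spec, illumination=(0.5, 1.0, 1.0)), cam)
        sample = base.truth_mask
        np.testing.assert_allclose(
            tinted.image[sample][:, 0], 0.5 * base.image[sample][:, 0], atol=1e-12
        )


class TestSceneValidation:
    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            circle_scene(12.57, patch_offset_cm=(2.0, 0.0))

    def test_bad_illumination_rejected(self):
        with pytest.raises(ValueError, match="illumination"):
            circle_scene(12.57, illumination=(0.0, 1.0, 1.0))

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="noise"):
            circle_scene(12.57, noise_sigma=-0.1)

    def test_bad_angle_rejected(self):
        with pytest.raises(ValueError, match="angle"):
            CaptureConfig(angle_deg=0.0)
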