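"""Patch detection and metric rectification against renderer ground truth."""

import numpy as np
import pytest
from dataclasses import replace

from woundpatch import (
    CaptureConfig,
    PatchNotDetectedError,
    PatchSpec,
    circle_scene,
    detect_patch,
    render_scene,
)
from woundpatch.measure import patch_cell_side_cm
from woundpatch.rectify import rectify
from woundpatch.scene import project_plane_points

from conftest import rectified_truth_mask


class TestDetect:
    def test_corners_match_truth_noise_free(self, fronto_render):
        det = detect_patch(fronto_render.image)
        err = np.abs(det.outer_corners - fronto_render.projected_patch_corners).max()
        assert err < 1.0
        assert det.confidence == 1.0

    def test_corners_match_truth_oblique(self, oblique_render, oblique_detection):
        err = np.abs(
            oblique_detection.outer_corners - oblique_render.projected_patch_corners
        ).max()
        assert err < 1.0

    def test_rotated_patch_arrangement_resolved(self, circle_spec):
        """Rotating the printed color arrangement 90 deg in-plane must give
        the same canonical (physical TL first) corner ordering."""
        rot_colors = np.rot90(PatchSpec().color_grid, k=1).reshape(9, 3)
        rot_spec = PatchSpec(reference_colors=rot_colors)
        sc = replace(circle_spec, patch=rot_spec)
        cam = CaptureConfig(distance_cm=30, angle_deg=90)
        rendered = render_scene(sc, cam)
        det = detect_patch(rendered.image, rot_spec)
        err = np.abs(det.outer_corners - rendered.projected_patch_corners).max()
        assert err < 1.0
        # sampled colors must match the rotated reference arrangement cell by cell
        d = np.linalg.norm(
            det.cell_mean_colors[:, None] - rot_spec.reference_colors[None], axis=-1
        )
        assert (np.argmin(d, axis=1) == np.arange(9)).all()

    def test_uniform_image_not_detected(self):
        img = np.full((200, 300, 3), 0.5)
        with pytest.raises(PatchNotDetectedError, match="not detected"):
            detect_patch(img)

    def test_detection_equivariant_under_patch_shift(self, circle_spec):
        """Shifting the patch 0.5 cm in the scene shifts detected corners by
        the projected amount, within 1 px."""
        cam = CaptureConfig(distance_cm=40, angle_deg=60)
        sc2 = replace(circle_spec, patch_offset_cm=(3.8, 0.0))
        r1 = render_scene(circle_spec, cam)
        r2 = render_scene(sc2, cam)
        d1 = detect_patch(r1.image)
        d2 = detect_patch(r2.image)
        expected_shift = r2.projected_patch_corners - r1.projected_patch_corners
        got_shift = d2.outer_corners - d1.outer_corners
        assert np.abs(got_shift - expected_shift).max() < 1.0

    def test_detection_survives_illumination_tint(self, circle_spec):
        cam = CaptureConfig(distance_cm=40, angle_deg=90)
        sc = replace(circle_spec, illumination=(0.7, 0.8, 1.2))
        rendered = render_scene(sc, cam)
        det = detect_patch(rendered.image)
        err = np.abs(det.outer_corners - rendered.projected_patch_corners).max()
        assert err < 1.0


class TestPatchSpecValidation:
    def test_too_close_colors_rejected(self):
        colors = PatchSpec().reference_colors.copy()
        colors[1] = [0.95, 0.05, 0.05]  # nearly the red of cell 0
        with pytest.raises(ValueError, match="apart"):
            PatchSpec(reference_colors=colors)


class TestRectify:
    def test_patch_becomes_canonical_square(self, fronto_rectified):
        x0, y0, x1, y1 = fronto_rectified.patch_region
        assert (x1 - x0) == pytest.approx(210.0, abs=1.0)
        assert (y1 - y0) == pytest.approx(210.0, abs=1.0)
        assert fronto_rectified.scale_cm_per_px == pytest.approx(0.01)

    def test_scale_is_reciprocal_of_target(self, fronto_render):
        det = detect_patch(fronto_render.image)
        rect = rectify(fronto_render.image, det, None, 50.0, roi_cm=(-1, -1, 3.1, 3.1))
        assert rect.scale_cm_per_px == pytest.approx(0.02)

    def test_oblique_circle_becomes_round(self, oblique_render, oblique_detection):
        """After rectification of a 60 deg capture the circular wound's
        bounding box has aspect ratio 1 within 2% (perspective removed)."""
        rect = rectify(
            oblique_render.image,
            oblique_detection,
            None,
            100.0,
            roi_cm=(-8, -8, 10.1, 10.1),
        )
        mask = rectified_truth_mask(oblique_render, rect)
        ys, xs = np.nonzero(mask)
        aspect = (xs.max() - xs.min()) / (ys.max() - ys.min())
        assert aspect == pytest.approx(1.0, abs=0.02)

    @pytest.mark.parametrize("d,theta", [(30, 90), (40, 60), (50, 30)])
    def test_scale_correctness_noise_free(self, circle_spec, d, theta):
        """Rectified truth-mask pixel area x scale^2 within 1% of the
        analytic wound area, across the capture grid."""
        cam = CaptureConfig(distance_cm=d, angle_deg=theta)
        rendered = render_scene(circle_spec, cam)
        det = detect_patch(rendered.image)
        rect = rectify(rendered.image, det, None, 100.0, roi_cm=(-8, -8, 10.1, 10.1))
        mask = rectified_truth_mask(rendered, rect)
        area = mask.sum() * rect.scale_cm_per_px**2
        assert area == pytest.approx(rendered.truth_area_cm2, rel=0.01)

    def test_cell_side_recovered(self, oblique_render, oblique_detection):
        rect = rectify(
            oblique_render.image, oblique_detection, None, 100.0, roi_cm=(-1, -1, 3.1, 3.1)
        )
        side = patch_cell_side_cm(rect)
        assert side == pytest.approx(0.7, rel=0.02)

    def test_raster_limit_enforced(self, fronto_render):
        det = detect_patch(fronto_render.image)
        with pytest.raises(ValueError, match="max_raster_px"):
            rectify(fronto_render.image, det, None, 1000.0, roi_cm=(-8, -8, 10, 10), max_raster_px=2000)

    def test_manual_corner_override_measures_same(self, fronto_render):
        """Measurement with renderer-truth corners agrees with automatic
        detection (both scales near truth)."""
        from woundpatch import measure_image

        m = measure_image(
            fronto_render.image, corners=fronto_render.projected_patch_corners, seed=1
        )
        assert m.area_cm2 == pytest.approx(12.57, rel=0.01)
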