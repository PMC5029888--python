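"""Shared fixtures: rendered scenes and measurements reused across tests.

Rendering and full-pipeline measurement are the expensive operations, so
session-scoped fixtures hold one instance of each canonical configuration.
"""

from __future__ import annotations

import numpy as np
import pytest

from woundpatch import (
    CaptureConfig,
    circle_scene,
    detect_patch,
    measure_image,
    render_scene,
)
from woundpatch.rectify import rectify

TRUTH_AREA = 12.57  # circular defect model: radius 2 cm


@pytest.fixture(scope="session")
def circle_spec():
    return circle_scene(TRUTH_AREA, noise_sigma=0.0, seed=1)


@pytest.fixture(scope="session")
def fronto_render(circle_spec):
    """Noise-free fronto-parallel capture at 30 cm."""
    return render_scene(circle_spec, CaptureConfig(distance_cm=30, angle_deg=90))


@pytest.fixture(scope="session")
def oblique_render(circle_spec):
    """Noise-free oblique capture at 40 cm / 60 degrees."""
    return render_scene(circle_spec, CaptureConfig(distance_cm=40, angle_deg=60))


@pytest.fixture(scope="session")
def fronto_measurement(fronto_render):
    return measure_image(fronto_render.image, seed=1)


@pytest.fixture(scope="session")
def oblique_detection(oblique_render):
    return detect_patch(oblique_render.image)


@pytest.fixture(scope="session")
def fronto_rectified(fronto_render):
    det = detect_patch(fronto_render.image)
    return rectify(
        fronto_render.image, det, None, 100.0, roi_cm=(-8.0, -8.0, 10.1, 10.1)
    )


def rectified_truth_mask(render, rect):
    """Ground-truth wound mask transported into a rectified frame."""
    from woundpatch.geometry import points_in_polygon
    from woundpatch.scene import project_plane_points

    boundary_cm = render.scene.wound_boundary_cm(720)
    boundary_img = project_plane_points(render.camera, boundary_cm)
    boundary_rect = rect.homography.apply(boundary_img)
    h, w = rect.image.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    return points_in_polygon(boundary_rect, xx.ravel(), yy.ravel()).reshape(h, w)


def contour_mask(contour, shape):
    from woundpatch.geometry import points_in_polygon

    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return points_in_polygon(contour, xx.ravel(), yy.ravel()).reshape(shape)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union
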