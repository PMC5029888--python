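"""Perspective rectification against the detected color patch.

Warping the image by the homography that sends the detected patch corners
to an axis-aligned square of known physical size makes the wound plane
fronto-parallel: pixel area becomes proportional to physical area with a
known cm-per-pixel scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import ProjectiveTransform, warp

from .detect import PatchDetection
from .homography import Homography, estimate_homography
from .patch import PatchSpec


@dataclass(frozen=True)
class RectifiedImage:
    """Image in the rectified (fronto-parallel, metric) frame."""

    image: np.ndarray  # (H, W, 3) float RGB
    scale_cm_per_px: float
    patch_region: tuple[float, float, float, float]  # (x0, y0, x1, y1) px
    homography: Homography  # original image pixels -> rectified pixels
    origin_cm: tuple[float, float]  # patch-plane cm coords of rectified pixel (0, 0)


def patch_plane_homography(det: PatchDetection, spec: PatchSpec) -> Homography:
    """Homography from image pixels to patch-plane cm coordinates
    (origin at the patch's physical top-left corner, x right, y down)."""
    return estimate_homography(det.outer_corners, spec.corner_positions_cm())


def rectify(
    image: np.ndarray,
    det: PatchDetection,
    spec: PatchSpec | None = None,
    target_px_per_cm: float = 100.0,
    *,
    roi_cm: tuple[float, float, float, float] | None = None,
    max_raster_px: int = 4096,
    fill: np.ndarray | None = None,
) -> RectifiedImage:
    """Warp the image so the patch becomes an axis-aligned square of side
    ``gross_side_cm * target_px_per_cm`` pixels (bilinear interpolation).

    By default the output frame covers the whole warped footprint of the
    input image; ``roi_cm = (x0, y0, x1, y1)`` — in patch-plane cm, origin
    at the patch top-left corner — restricts the output to a window, which
    is what the measurement pipeline uses (at grazing capture angles the
    full footprint can approach the plane horizon).  Raises ``ValueError``
    when the output raster would exceed ``max_raster_px`` on a side,
    advising a lower ``target_px_per_cm``.
    """
    spec = spec or PatchSpec()
    if target_px_per_cm <= 0:
        raise ValueError("target_px_per_cm must be positive")
    image = np.asarray(image, dtype=float)
    h_cm = patch_plane_homography(det, spec)

    if roi_cm is None:
        h_img, w_img = image.shape[:2]
        frame = np.array(
            [[0, 0], [w_img - 1, 0], [w_img - 1, h_img - 1], [0, h_img - 1]], float
        )
        hom = np.column_stack([frame, np.ones(4)]) @ h_cm.matrix.T
        if np.any(hom[:, 2] <= 1e-9 * np.abs(hom).max()):
            raise ValueError(
                "image frame crosses the plane horizon; rectify a region of "
                "interest instead (pass roi_cm)"
            )
        corners_cm = hom[:, :2] / hom[:, 2:3]
        x0, y0 = corners_cm.min(axis=0)
        x1, y1 = corners_cm.max(axis=0)
    else:
        x0, y0, x1, y1 = roi_cm
        if not (x1 > x0 and y1 > y0):
            raise ValueError("roi_cm must satisfy x1 > x0 and y1 > y0")

    width = int(np.ceil((x1 - x0) * target_px_per_cm)) + 1
    height = int(np.ceil((y1 - y0) * target_px_per_cm)) + 1
    if max(width, height) > max_raster_px:
        raise ValueError(
            f"rectified raster {width}x{height} exceeds max_raster_px="
            f"{max_raster_px}; lower target_px_per_cm or restrict roi_cm"
        )

    # image px -> rectified px: scale the cm map and shift the origin
    scale_mat = np.array(
        [
            [target_px_per_cm, 0.0, -x0 * target_px_per_cm],
            [0.0, target_px_per_cm, -y0 * target_px_per_cm],
            [0.0, 0.0, 1.0],
        ]
    )
    h_rect = Homography(scale_mat @ h_cm.matrix, scale_cm_per_px=1.0 / target_px_per_cm)

    tform = ProjectiveTransform(matrix=np.linalg.inv(h_rect.matrix))
    warped = warp(image, tform, output_shape=(height, width), order=1, cval=0.0)
    footprint = warp(
        np.ones(image.shape[:2]), tform, output_shape=(height, width), order=1, cval=0.0
    )
    if fill is None:
        border = np.concatenate(
            [image[0], image[-1], image[:, 0], image[:, -1]], axis=0
        )
        fill = np.median(border, axis=0)
    # any pixel whose bilinear support touches the outside is replaced, so
    # no seam artifact survives at the footprint boundary
    outside = footprint < 0.999
    warped = np.clip(warped, 0.0, 1.0)
    warped[outside] = fill

    side_px = spec.gross_side_cm * target_px_per_cm
    px0, py0 = -x0 * target_px_per_cm, -y0 * target_px_per_cm
    patch_region = (px0, py0, px0 + side_px, py0 + side_px)
    return RectifiedImage(
        image=warped,
        scale_cm_per_px=1.0 / target_px_per_cm,
        patch_region=patch_region,
        homography=h_rect,
        origin_cm=(float(x0), float(y0)),
    )
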