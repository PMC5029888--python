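"""Automatic detection of the 3x3 color patch in a photograph.

Detection is color-driven: pixels close to any of the 9 reference colors are
grouped into candidate regions, the patch is the region presenting (at
least 7 of) the 9 distinct reference colors, and its outer quadrilateral is
fitted from the region's convex hull.  The 4-fold rotation ambiguity of a
square grid is resolved by matching the observed cell-color arrangement to
the reference arrangement.  Outer corners are then refined to sub-pixel
accuracy by fitting straight lines to the patch border edges and
intersecting them — the corner accuracy directly bounds the accuracy of the
recovered cm-per-pixel scale, hence of every area measurement.

A per-channel white-patch normalization (divide by a high percentile) is
applied before color matching only, so that a global illumination tint does
not defeat the reference-color threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.morphology import disk

from .geometry import convex_hull, max_quadrilateral, order_corners_canonical
from .homography import Homography, estimate_homography
from .patch import PatchSpec


class PatchNotDetectedError(ValueError):
    """Raised when no color patch can be located in the image."""


@dataclass(frozen=True)
class PatchDetection:
    """Located patch: outer corners (TL, TR, BR, BL of the *physical* patch,
    i.e. after orientation resolution), observed per-cell mean colors in
    row-major physical order, and a detection confidence in [0, 1]."""

    outer_corners: np.ndarray  # (4, 2) pixel coords
    cell_mean_colors: np.ndarray  # (9, 3) RGB
    confidence: float

    def __post_init__(self) -> None:
        c = np.asarray(self.outer_corners, dtype=float)
        if c.shape != (4, 2):
            raise ValueError("outer_corners must be (4, 2)")
        # convexity / non-degeneracy: consecutive-edge cross products share sign
        edges = np.roll(c, -1, axis=0) - c
        cross = edges[:, 0] * np.roll(edges, -1, axis=0)[:, 1] - edges[:, 1] * np.roll(
            edges, -1, axis=0
        )[:, 0]
        if np.any(cross == 0) or not (np.all(cross > 0) or np.all(cross < 0)):
            raise ValueError("outer corners do not form a convex quadrilateral")


def _whitepatch_normalize(image: np.ndarray) -> np.ndarray:
    scale = np.maximum(np.percentile(image.reshape(-1, 3), 99.9, axis=0), 0.25)
    return np.clip(image / scale[None, None, :], 0.0, 1.0)


def _canonical_cell_units(spec: PatchSpec) -> np.ndarray:
    """Outer corners of the patch in cell units: TL (0,0) .. BL (0, rows)."""
    return np.array(
        [[0.0, 0.0], [spec.grid_cols, 0.0], [spec.grid_cols, spec.grid_rows], [0.0, spec.grid_rows]],
        dtype=float,
    )


def _bilinear_sample(image: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Sample (N, 2) (x, y) points from an RGB image, bilinear."""
    coords = np.vstack([points[:, 1], points[:, 0]])  # (row, col)
    out = np.empty((len(points), image.shape[2]))
    for ch in range(image.shape[2]):
        out[:, ch] = ndimage.map_coordinates(
            image[:, :, ch], coords, order=1, mode="nearest"
        )
    return out


def sample_cell_colors(
    image: np.ndarray, corners: np.ndarray, spec: PatchSpec, inner_fraction: float = 0.6
) -> np.ndarray:
    """Mean observed RGB of each cell, sampled over the inner
    ``inner_fraction`` of the cell to avoid edge bleed.  Row-major order
    with respect to the given corner labeling."""
    h = estimate_homography(_canonical_cell_units(spec), np.asarray(corners, float))
    half = inner_fraction / 2.0
    lin = np.linspace(-half, half, 5)
    gx, gy = np.meshgrid(lin, lin)
    offsets = np.column_stack([gx.ravel(), gy.ravel()])
    colors = np.empty((spec.grid_rows * spec.grid_cols, 3))
    for row in range(spec.grid_rows):
        for col in range(spec.grid_cols):
            centers = offsets + np.array([col + 0.5, row + 0.5])
            px = h.apply(centers)
            colors[row * spec.grid_cols + col] = _bilinear_sample(image, px).mean(axis=0)
    return colors


def _affine_fit_residual(observed: np.ndarray, reference: np.ndarray) -> float:
    """RMS residual of the best 3x4 affine map from observed to reference."""
    design = np.column_stack([observed, np.ones(len(observed))])
    sol, *_ = np.linalg.lstsq(design, reference, rcond=None)
    resid = design @ sol - reference
    return float(np.sqrt(np.mean(resid**2)))


def _corrected_colors(observed: np.ndarray, reference: np.ndarray) -> np.ndarray:
    design = np.column_stack([observed, np.ones(len(observed))])
    sol, *_ = np.linalg.lstsq(design, reference, rcond=None)
    return design @ sol


def _resolve_orientation(
    image: np.ndarray, corners: np.ndarray, spec: PatchSpec
) -> tuple[np.ndarray, np.ndarray, int]:
    """Try the 4 cyclic corner labelings; keep the one whose sampled cell
    colors best match the reference arrangement under an affine color map."""
    best = None
    for roll in range(4):
        cand = np.roll(corners, -roll, axis=0)
        obs = sample_cell_colors(image, cand, spec)
        resid = _affine_fit_residual(obs, spec.reference_colors)
        if best is None or resid < best[0]:
            best = (resid, cand, obs, roll)
    _, cand, obs, roll = best
    return cand, obs, roll


def _match_count(colors: np.ndarray, reference: np.ndarray) -> int:
    d = np.linalg.norm(colors[:, None, :] - reference[None, :, :], axis=-1)
    return int(np.sum(np.argmin(d, axis=1) == np.arange(len(colors))))


def _refine_corners(image: np.ndarray, corners: np.ndarray, passes: int = 2) -> np.ndarray:
    """Sub-pixel corner refinement.

    For each of the 4 border sides, intensity profiles are sampled
    perpendicular to the side; the edge crossing is located as the
    baseline-subtracted centroid of the color-gradient magnitude around its
    peak, a straight line is fitted through the crossings, and corners are
    re-derived as the intersections of adjacent lines.  Two passes let the
    second pass sample exactly perpendicular profiles.  The corner accuracy
    directly bounds the cm-per-pixel scale (and the homography
    extrapolation to the wound region), so this is worth sub-0.2 px care.
    Falls back to the input corners when profiles are too ambiguous.
    """
    corners = np.asarray(corners, dtype=float).copy()
    step = 0.125
    s_grid = np.arange(-3.0, 3.0 + step / 2, step)
    s_mid = s_grid[:-1] + step / 2
    search = np.abs(s_mid) <= 2.0  # true edge lies near s = 0 by construction
    for _ in range(passes):
        centroid = corners.mean(axis=0)
        lines = []
        for i in range(4):
            p0, p1 = corners[i], corners[(i + 1) % 4]
            side = p1 - p0
            normal = np.array([-side[1], side[0]])
            normal /= np.linalg.norm(normal)
            if np.dot(normal, (p0 + p1) / 2.0 - centroid) < 0:
                normal = -normal  # point outward
            pts = []
            for t in np.linspace(0.12, 0.88, 25):
                base = p0 + t * side
                prof = _bilinear_sample(image, base[None, :] + s_grid[:, None] * normal[None, :])
                grad = np.linalg.norm(np.diff(prof, axis=0), axis=1)
                j = int(np.flatnonzero(search)[np.argmax(grad[search])])
                if grad[j] < 0.025:
                    continue
                lo, hi = max(0, j - 12), j + 13
                w = np.maximum(grad[lo:hi] - np.median(grad), 0.0)
                if w.sum() <= 0:
                    continue
                s_star = float((w * s_mid[lo:hi]).sum() / w.sum())
                pts.append(base + s_star * normal)
            if len(pts) < 8:
                return corners
            pts = np.asarray(pts)
            mean = pts.mean(axis=0)
            _, _, vt = np.linalg.svd(pts - mean)
            lines.append((mean, vt[0]))
        refined = np.empty_like(corners)
        for i in range(4):
            # corner i = intersection of side (i-1) and side i
            (m1, d1), (m2, d2) = lines[(i - 1) % 4], lines[i]
            mat = np.column_stack([d1, -d2])
            if abs(np.linalg.det(mat)) < 1e-9:
                return corners
            t = np.linalg.solve(mat, m2 - m1)
            refined[i] = m1 + t[0] * d1
        if np.max(np.linalg.norm(refined - corners, axis=1)) > 6.0:
            return corners
        corners = refined
    return corners


def detect_patch(
    image: np.ndarray,
    spec: PatchSpec | None = None,
    *,
    color_threshold: float = 0.30,
    min_region_px: int = 64,
    refine: bool = True,
) -> PatchDetection:
    """Locate the color patch and return its corners, cell colors and a
    confidence score.

    Raises :class:`PatchNotDetectedError` when no region presents at least
    7 of the 9 reference colors.
    """
    spec = spec or PatchSpec()
    image = np.asarray(image, dtype=float)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    norm = _whitepatch_normalize(image).astype(np.float32)
    refs = spec.reference_colors.astype(np.float32)
    flat = norm.reshape(-1, 3)
    # squared distances via |p|^2 - 2 p.r + |r|^2, no (H, W, 9, 3) temporary
    d2 = (
        np.sum(flat**2, axis=1)[:, None]
        - 2.0 * flat @ refs.T
        + np.sum(refs**2, axis=1)[None, :]
    )
    nearest = d2.argmin(axis=1).reshape(norm.shape[:2])
    dmin = np.sqrt(np.maximum(d2.min(axis=1), 0.0)).reshape(norm.shape[:2])
    del d2, flat

    footprint = disk(3)
    for thr in (color_threshold, 0.22, 0.15):
        mask = dmin < thr
        if not mask.any():
            continue
        regions = cc_label(ndimage.binary_dilation(mask, structure=footprint), connectivity=2)
        detection = _try_regions(image, mask, nearest, regions, spec, refine)
        if detection is not None:
            return detection
    raise PatchNotDetectedError("patch not detected")


def _try_regions(image, mask, nearest, regions, spec, refine):
    h_img, w_img = mask.shape
    n_cells = spec.grid_rows * spec.grid_cols
    counts = np.bincount(regions.ravel())
    order = np.argsort(counts)[::-1]
    for lab in order:
        if lab == 0 or counts[lab] < 64:
            continue
        region = regions == lab
        rows, cols = np.nonzero(region)
        if rows.min() == 0 or cols.min() == 0 or rows.max() == h_img - 1 or cols.max() == w_img - 1:
            continue  # background / skin region touching the border
        cell_mask = mask & region
        if cell_mask.sum() < 64:
            continue
        labels_here = nearest[cell_mask]
        present = np.bincount(labels_here, minlength=n_cells)
        min_px = max(16, int(0.01 * cell_mask.sum()))
        if np.sum(present >= min_px) < 7:
            continue
        ys, xs = np.nonzero(cell_mask)
        pts = np.column_stack([xs, ys]).astype(float)
        try:
            quad = max_quadrilateral(convex_hull(pts))
        except Exception:
            continue
        corners = order_corners_canonical(quad)
        try:
            corners, observed, _ = _resolve_orientation(image, corners, spec)
            if refine:
                corners = _refine_corners(image, corners)
                observed = sample_cell_colors(image, corners, spec)
        except ValueError:
            continue
        corrected = _corrected_colors(observed, spec.reference_colors)
        if _match_count(corrected, spec.reference_colors) < 7:
            continue
        confidence = _match_count(observed, spec.reference_colors) / n_cells
        try:
            return PatchDetection(
                outer_corners=corners,
                cell_mean_colors=observed,
                confidence=confidence,
            )
        except ValueError:
            continue
    return None
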