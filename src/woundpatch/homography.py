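"""Planar homography estimation (direct linear transform).

A 3x3 projective map H relates two images of the same plane; here it sends
the detected patch quadrilateral to its canonical square, which makes pixel
area proportional to physical area after warping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class Homography:
    """3x3 planar projective map, normalized so matrix[2, 2] = 1."""

    matrix: np.ndarray
    scale_cm_per_px: float | None = None  # set when H targets a metric frame

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("homography matrix must be 3x3")
        if abs(m[2, 2]) < 1e-300:
            raise ValueError("homography cannot be normalized: H[2,2] = 0")
        m = m / m[2, 2]
        cond = np.linalg.cond(m)
        if not np.isfinite(cond):
            raise ValueError("homography matrix is singular")
        object.__setattr__(self, "matrix", m)

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (N, 2) points through H."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        hom = np.column_stack([pts, np.ones(len(pts))]) @ self.matrix.T
        return hom[:, :2] / hom[:, 2:3]

    def inverse(self) -> "Homography":
        return Homography(np.linalg.inv(self.matrix))


def _collinear_triple(points: np.ndarray, tol: float = 1e-9) -> bool:
    p = np.asarray(points, dtype=float)
    scale = max(np.ptp(p[:, 0]), np.ptp(p[:, 1]), 1.0)
    n = len(p)
    for i in range(n - 2):
        for j in range(i + 1, n - 1):
            for k in range(j + 1, n):
                cross = (p[j] - p[i])[0] * (p[k] - p[i])[1] - (p[j] - p[i])[1] * (
                    p[k] - p[i]
                )[0]
                if abs(cross) < tol * scale * scale:
                    return True
    return False


def estimate_homography(src: np.ndarray, dst: np.ndarray) -> Homography:
    """DLT estimate of H with H @ src ~ dst, from >= 4 correspondences.

    With exactly 4 points the 8x8 linear system is solved exactly; with more
    the solution is least squares.  Raises ``ValueError`` on degenerate
    configurations (any 3 collinear points among either point set, checked
    for the 4-point case).
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2 or len(src) < 4:
        raise ValueError("need matching (N>=4, 2) source and destination points")
    if len(src) == 4 and (_collinear_triple(src) or _collinear_triple(dst)):
        raise ValueError("degenerate configuration: 3 collinear points")

    n = len(src)
    a = np.zeros((2 * n, 8))
    b = np.zeros(2 * n)
    x, y = src[:, 0], src[:, 1]
    u, v = dst[:, 0], dst[:, 1]
    a[0::2, 0], a[0::2, 1], a[0::2, 2] = x, y, 1.0
    a[0::2, 6], a[0::2, 7] = -u * x, -u * y
    a[1::2, 3], a[1::2, 4], a[1::2, 5] = x, y, 1.0
    a[1::2, 6], a[1::2, 7] = -v * x, -v * y
    b[0::2], b[1::2] = u, v

    try:
        if n == 4:
            h8 = np.linalg.solve(a, b)
        else:
            h8, *_ = np.linalg.lstsq(a, b, rcond=None)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"degenerate configuration: {exc}") from exc

    h = np.append(h8, 1.0).reshape(3, 3)
    return Homography(h)
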