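"""Polygon and contour utilities shared across the pipeline.

All contours are (N, 2) float arrays of (x, y) vertex positions, implicitly
closed (vertex N connects back to vertex 0).  Pixel centers sit at integer
coordinates, origin at the top-left, x rightward, y downward.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import ConvexHull
from shapely.geometry import LinearRing, Polygon


def polygon_area(vertices: np.ndarray) -> float:
    """Unsigned area of a closed polygon via the shoelace formula.

    Orientation-independent.  Raises ``ValueError`` for self-intersecting
    polygons, where the shoelace sum is not an area.
    """
    v = np.asarray(vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs at least 3 (x, y) vertices")
    if not is_simple_polygon(v):
        raise ValueError("polygon is self-intersecting")
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def signed_area(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(0.5 * (np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def is_simple_polygon(vertices: np.ndarray) -> bool:
    """True when the closed polygon does not intersect itself."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return False
    # collapse consecutive duplicates, which shapely treats as degeneracies
    keep = np.any(np.abs(np.diff(np.vstack([v, v[:1]]), axis=0)) > 1e-12, axis=1)
    v = v[keep] if keep.any() else v
    if len(v) < 3:
        return False
    try:
        return bool(LinearRing(v).is_simple)
    except Exception:
        return False


def repair_polygon(vertices: np.ndarray) -> np.ndarray:
    """Return the exterior of the largest valid piece of a (possibly
    self-touching) polygon.  Used as a last-resort cleanup for contours."""
    poly = Polygon(np.asarray(vertices, dtype=float)).buffer(0)
    if poly.is_empty:
        raise ValueError("polygon degenerated to empty set")
    if poly.geom_type == "MultiPolygon":
        poly = max(poly.geoms, key=lambda g: g.area)
    xy = np.asarray(poly.exterior.coords)[:-1]
    return xy


def resample_closed(vertices: np.ndarray, spacing: float, min_vertices: int = 8) -> np.ndarray:
    """Resample a closed polyline to (approximately) uniform arc-length spacing."""
    v = np.asarray(vertices, dtype=float)
    closed = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    perim = float(seg.sum())
    if perim <= 0:
        raise ValueError("zero-perimeter contour")
    n = max(min_vertices, int(round(perim / spacing)))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, perim, n, endpoint=False)
    x = np.interp(t, s, closed[:, 0])
    y = np.interp(t, s, closed[:, 1])
    return np.column_stack([x, y])


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull vertices of a point set, in counter-clockwise order."""
    pts = np.asarray(points, dtype=float)
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def dilate_about_centroid(vertices: np.ndarray, offset: float) -> np.ndarray:
    """Push every vertex radially outward from the centroid by ``offset``."""
    v = np.asarray(vertices, dtype=float)
    c = v.mean(axis=0)
    d = v - c
    norms = np.linalg.norm(d, axis=1)
    norms = np.where(norms < 1e-12, 1.0, norms)
    return v + d / norms[:, None] * offset


def max_quadrilateral(hull_vertices: np.ndarray) -> np.ndarray:
    """The 4 hull vertices enclosing the maximum-area quadrilateral.

    Brute force over hull-vertex 4-tuples; hulls here have only tens of
    vertices, so this is cheap and has no failure modes.
    """
    h = np.asarray(hull_vertices, dtype=float)
    m = len(h)
    if m < 4:
        raise ValueError("hull has fewer than 4 vertices")
    if m > 48:  # thin the hull to keep the O(m^4) scan trivial
        idx = np.linspace(0, m - 1, 48).astype(int)
        h, m = h[np.unique(idx)], len(np.unique(idx))
    best, best_area = None, -1.0
    # indices kept in hull order so the quad is convex by construction
    for i in range(m - 3):
        for j in range(i + 1, m - 2):
            for k in range(j + 1, m - 1):
                for l in range(k + 1, m):
                    quad = h[[i, j, k, l]]
                    a = abs(signed_area(quad))
                    if a > best_area:
                        best_area, best = a, quad
    return best


def caliper_extents(vertices: np.ndarray) -> tuple[float, float]:
    """Length L and width W of the clinical ruler measurement, as the sides
    (longer first) of the minimum-area bounding rectangle.

    Rotating-calipers search over hull-edge orientations.  This caliper
    convention reproduces the classical properties of the L x W estimate:
    exact for axis-aligned rectangles, double the area of any right
    triangle, and 4/pi (~1.27x) the area of a circle.
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        raise ValueError("need at least 3 vertices")
    try:
        h = convex_hull(v) if len(v) > 3 else v
    except Exception as exc:
        raise ValueError(f"degenerate contour: {exc}") from exc
    edges = np.roll(h, -1, axis=0) - h
    lengths = np.linalg.norm(edges, axis=1)
    good = lengths > 1e-12
    if not good.any():
        raise ValueError("degenerate contour: zero extent")
    dirs = edges[good] / lengths[good, None]
    normals = np.column_stack([-dirs[:, 1], dirs[:, 0]])
    e1 = np.ptp(h @ dirs.T, axis=0)
    e2 = np.ptp(h @ normals.T, axis=0)
    if (e1 <= 0).all() or (e2 <= 0).all():
        raise ValueError("degenerate contour: zero width")
    areas = e1 * e2
    k = int(np.argmin(areas))
    if e1[k] <= 0 or e2[k] <= 0:
        raise ValueError("degenerate contour: zero width")
    return float(max(e1[k], e2[k])), float(min(e1[k], e2[k]))


def order_corners_canonical(corners: np.ndarray) -> np.ndarray:
    """Order 4 quadrilateral corners as TL, TR, BR, BL in image coordinates.

    "Top-left" is chosen as the corner with the smallest x + y; the rest
    follow clockwise in image coordinates (y down).
    """
    c = np.asarray(corners, dtype=float)
    centroid = c.mean(axis=0)
    ang = np.arctan2(c[:, 1] - centroid[1], c[:, 0] - centroid[0])
    order = np.argsort(ang)  # CCW in math coords == CW on screen with y down
    c = c[order]
    start = int(np.argmin(c.sum(axis=1)))
    return np.roll(c, -start, axis=0)


def points_in_polygon(polygon: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized point-in-polygon test."""
    import shapely

    poly = Polygon(np.asarray(polygon, dtype=float))
    return shapely.contains_xy(poly, np.asarray(x, float), np.asarray(y, float))
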