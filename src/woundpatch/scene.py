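"""Synthetic photograph renderer with analytic ground truth.

Emulates the validation setup for the color-patch measurement method: a
planar scene (z = 0, units of cm) holding a wound of known area and the 3x3
color patch, photographed by an ideal pinhole camera placed at distance *d*
from a look-at point on the plane, with its optical axis meeting the plane
at elevation angle *theta* (theta = 90 deg is fronto-parallel capture).

Ground truth is analytic: the wound area comes from the shape parameters,
never from pixel counting, and the projected patch corners come from the
exact camera matrix.  Every downstream stage of the pipeline can therefore
be validated without any real photograph.

Rendering is done by inverse mapping (back-projecting each pixel to the
plane) with supersampling, followed by per-channel illumination gains and
i.i.d. Gaussian pixel noise, clamped to [0, 1].  Identical (scene, camera,
seed) triples give bit-identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .geometry import signed_area
from .patch import PatchSpec

_SUPPORTED_SHAPES = ("circle", "ellipse", "blob")

#: Default scene palette.  Skin is a light Caucasian-ish tone, the wound a
#: granulation-tissue red; both are far (>0.3 in RGB) from every default
#: patch reference color so color-based patch detection is well posed.
DEFAULT_SKIN_COLOR = (0.87, 0.68, 0.55)
DEFAULT_WOUND_COLOR = (0.45, 0.18, 0.16)


@dataclass(frozen=True)
class SceneSpec:
    """A planar wound + patch scene with analytic ground truth.

    wound_shape: "circle" (params: r), "ellipse" (params: a, b) or "blob"
    (params: r0, amplitudes, phases — a star-shaped radius function
    r(phi) = r0 * (1 + sum_k a_k cos(k phi + phi_k))).  All lengths in cm.
    """

    wound_shape: str = "circle"
    shape_params: dict = field(default_factory=lambda: {"r": 2.0})
    wound_center_cm: tuple[float, float] = (0.0, 0.0)
    patch_offset_cm: tuple[float, float] = (3.3, 0.0)
    patch: PatchSpec = field(default_factory=PatchSpec)
    wound_color: tuple[float, float, float] = DEFAULT_WOUND_COLOR
    skin_color: tuple[float, float, float] = DEFAULT_SKIN_COLOR
    illumination: tuple[float, float, float] = (1.0, 1.0, 1.0)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wound_shape not in _SUPPORTED_SHAPES:
            raise ValueError(f"unsupported wound shape: {self.wound_shape!r}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if any(g <= 0 for g in self.illumination):
            raise ValueError("illumination gains must be positive")
        if self.wound_area_cm2 <= 0:
            raise ValueError("wound area must be positive")
        if self._wound_patch_overlap():
            raise ValueError("wound and patch footprints overlap")

    @property
    def wound_area_cm2(self) -> float:
        return truth_area(self)

    def wound_boundary_cm(self, n: int = 512) -> np.ndarray:
        """Closed polygon approximating the wound boundary, in scene cm."""
        phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
        cx, cy = self.wound_center_cm
        if self.wound_shape == "circle":
            r = self.shape_params["r"]
            x, y = r * np.cos(phi), r * np.sin(phi)
        elif self.wound_shape == "ellipse":
            a, b = self.shape_params["a"], self.shape_params["b"]
            x, y = a * np.cos(phi), b * np.sin(phi)
        else:
            r = _blob_radius(phi, self.shape_params)
            x, y = r * np.cos(phi), r * np.sin(phi)
        return np.column_stack([x + cx, y + cy])

    def patch_corners_cm(self) -> np.ndarray:
        """Outer patch corners TL, TR, BR, BL in scene cm.

        Scene axes: x rightward, y upward as seen in a fronto-parallel
        capture (the camera projects scene +y to image up), so the physical
        top-left corner of the patch sits at (ox - half, oy + half)."""
        half = self.patch.gross_side_cm / 2.0
        ox, oy = self.patch_offset_cm
        return np.array(
            [
                [ox - half, oy + half],
                [ox + half, oy + half],
                [ox + half, oy - half],
                [ox - half, oy - half],
            ]
        )

    def _wound_patch_overlap(self) -> bool:
        from shapely.geometry import Polygon

        wound = Polygon(self.wound_boundary_cm(256))
        patch = Polygon(self.patch_corners_cm())
        return wound.intersects(patch)


@dataclass(frozen=True)
class CaptureConfig:
    """Ideal pinhole camera at distance d (cm) and elevation angle theta
    (degrees between the optical axis and the scene plane; 90 = perpendicular)."""

    distance_cm: float = 40.0
    angle_deg: float = 90.0
    focal_px: float = 1600.0
    image_width_px: int = 800
    image_height_px: int = 600
    look_at_cm: tuple[float, float] = (1.2, 0.0)
    supersample: int = 2

    def __post_init__(self) -> None:
        if self.distance_cm <= 0:
            raise ValueError("distance_cm must be positive")
        if not (0 < self.angle_deg <= 90):
            raise ValueError("angle_deg must lie in (0, 90]")
        if self.focal_px <= 0 or self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("focal length and image size must be positive")


@dataclass(frozen=True)
class RenderedScene:
    """A rendered photograph plus its ground truth."""

    image: np.ndarray  # (H, W, 3) float in [0, 1]
    truth_mask: np.ndarray  # (H, W) bool, wound pixels
    truth_area_cm2: float
    projected_patch_corners: np.ndarray  # (4, 2) pixel coords, TL TR BR BL
    scene: SceneSpec
    camera: CaptureConfig


def truth_area(scene: SceneSpec) -> float:
    """Analytic wound area in cm^2.

    circle: pi r^2; ellipse: pi a b; blob: shoelace area of a 4096-vertex
    polygon sampled from the radius function.
    """
    p = scene.shape_params
    if scene.wound_shape == "circle":
        return float(np.pi * p["r"] ** 2)
    if scene.wound_shape == "ellipse":
        return float(np.pi * p["a"] * p["b"])
    if scene.wound_shape == "blob":
        phi = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        r = _blob_radius(phi, p)
        if np.any(r <= 0):
            raise ValueError("blob radius function must stay positive")
        poly = np.column_stack([r * np.cos(phi), r * np.sin(phi)])
        return float(abs(signed_area(poly)))
    raise ValueError(f"unsupported wound shape: {scene.wound_shape!r}")


def _blob_radius(phi: np.ndarray, params: dict) -> np.ndarray:
    r0 = params["r0"]
    amps = np.asarray(params.get("amplitudes", ()), dtype=float)
    phases = np.asarray(params.get("phases", np.zeros_like(amps)), dtype=float)
    r = np.full_like(np.asarray(phi, float), 1.0)
    for k, (a, ph) in enumerate(zip(amps, phases), start=1):
        r = r + a * np.cos(k * phi + ph)
    return r0 * r


def camera_matrix(cam: CaptureConfig) -> np.ndarray:
    """3x4 pinhole projection matrix P = K R [I | -C] for the scene frame.

    Scene frame: x, y in the plane (cm), z out of the plane toward the
    camera.  The camera sits at look_at + d * (0, -cos(theta), sin(theta)),
    its optical axis through the look-at point; its x axis is the scene x
    axis, so the elevation tilt forshortens the scene y direction only.
    """
    th = np.deg2rad(cam.angle_deg)
    lx, ly = cam.look_at_cm
    look = np.array([lx, ly, 0.0])
    center = look + cam.distance_cm * np.array([0.0, -np.cos(th), np.sin(th)])
    z_cam = (look - center) / cam.distance_cm  # forward
    x_cam = np.array([1.0, 0.0, 0.0])
    y_cam = np.cross(z_cam, x_cam)  # image-down
    rot = np.vstack([x_cam, y_cam, z_cam])
    intr = np.array(
        [
            [cam.focal_px, 0.0, (cam.image_width_px - 1) / 2.0],
            [0.0, cam.focal_px, (cam.image_height_px - 1) / 2.0],
            [0.0, 0.0, 1.0],
        ]
    )
    ext = np.hstack([rot, -rot @ center[:, None]])
    return intr @ ext


def plane_to_image_homography(cam: CaptureConfig) -> np.ndarray:
    """3x3 homography mapping plane points (x_cm, y_cm, 1) to pixel coords."""
    p_mat = camera_matrix(cam)
    h = p_mat[:, [0, 1, 3]]
    return h / h[2, 2]


def project_plane_points(cam: CaptureConfig, points_cm: np.ndarray) -> np.ndarray:
    """Project (N, 2) plane points in cm to (N, 2) pixel coordinates."""
    h = plane_to_image_homography(cam)
    pts = np.asarray(points_cm, dtype=float)
    hom = np.column_stack([pts, np.ones(len(pts))]) @ h.T
    return hom[:, :2] / hom[:, 2:3]


def _scene_colors(scene: SceneSpec, x_cm: np.ndarray, y_cm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ideal (noise-free, unit-gain) scene color and wound indicator at
    plane positions, vectorized."""
    colors = np.empty(x_cm.shape + (3,), dtype=float)
    colors[:] = np.asarray(scene.skin_color)

    cx, cy = scene.wound_center_cm
    dx, dy = x_cm - cx, y_cm - cy
    p = scene.shape_params
    if scene.wound_shape == "circle":
        wound = dx * dx + dy * dy <= p["r"] ** 2
    elif scene.wound_shape == "ellipse":
        wound = (dx / p["a"]) ** 2 + (dy / p["b"]) ** 2 <= 1.0
    else:  # star-shaped blob: inside iff rho <= r(phi)
        rho = np.hypot(dx, dy)
        phi = np.arctan2(dy, dx)
        wound = rho <= _blob_radius(phi, p)
    colors[wound] = np.asarray(scene.wound_color)

    # patch cells overwrite whatever is beneath (they never overlap the wound)
    # row 0 is the top row as seen in the image, i.e. at the largest scene y
    half = scene.patch.gross_side_cm / 2.0
    ox, oy = scene.patch_offset_cm
    u = (x_cm - (ox - half)) / scene.patch.cell_side_cm
    v = ((oy + half) - y_cm) / scene.patch.cell_side_cm
    on_patch = (u >= 0) & (u < scene.patch.grid_cols) & (v >= 0) & (v < scene.patch.grid_rows)
    if on_patch.any():
        col = np.clip(u[on_patch].astype(int), 0, scene.patch.grid_cols - 1)
        row = np.clip(v[on_patch].astype(int), 0, scene.patch.grid_rows - 1)
        colors[on_patch] = scene.patch.color_grid[row, col]
        wound = wound & ~on_patch
    return colors, wound


def render_scene(scene: SceneSpec, cam: CaptureConfig) -> RenderedScene:
    """Render a photograph of the scene and return it with ground truth.

    Raises ``ValueError`` naming the offending element if the wound or the
    patch projects (partially) outside the frame.
    """
    corners_px = project_plane_points(cam, scene.patch_corners_cm())
    _check_in_frame(corners_px, cam, "color patch")
    wound_px = project_plane_points(cam, scene.wound_boundary_cm(256))
    _check_in_frame(wound_px, cam, "wound")

    ss = max(1, int(cam.supersample))
    width, height = cam.image_width_px, cam.image_height_px
    # supersampled pixel-center grid: subpixel centers of an ss x ss split
    sub = (np.arange(ss) + 0.5) / ss - 0.5
    xs = (np.arange(width)[:, None] + sub[None, :]).ravel()
    ys = (np.arange(height)[:, None] + sub[None, :]).ravel()
    xx, yy = np.meshgrid(xs, ys)

    h_inv = np.linalg.inv(plane_to_image_homography(cam))
    denom = h_inv[2, 0] * xx + h_inv[2, 1] * yy + h_inv[2, 2]
    x_cm = (h_inv[0, 0] * xx + h_inv[0, 1] * yy + h_inv[0, 2]) / denom
    y_cm = (h_inv[1, 0] * xx + h_inv[1, 1] * yy + h_inv[1, 2]) / denom

    colors, wound = _scene_colors(scene, x_cm, y_cm)
    # box-filter the supersampled rasters down to the native grid
    colors = colors.reshape(height, ss, width, ss, 3).mean(axis=(1, 3))
    wound_frac = wound.reshape(height, ss, width, ss).mean(axis=(1, 3))
    truth_mask = wound_frac >= 0.5

    colors = colors * np.asarray(scene.illumination)[None, None, :]
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        colors = colors + rng.normal(0.0, scene.noise_sigma, colors.shape)
    image = np.clip(colors, 0.0, 1.0)

    return RenderedScene(
        image=image,
        truth_mask=truth_mask,
        truth_area_cm2=truth_area(scene),
        projected_patch_corners=corners_px,
        scene=scene,
        camera=cam,
    )


def _check_in_frame(points_px: np.ndarray, cam: CaptureConfig, name: str) -> None:
    x, y = points_px[:, 0], points_px[:, 1]
    if (
        x.min() < 0
        or y.min() < 0
        or x.max() > cam.image_width_px - 1
        or y.max() > cam.image_height_px - 1
    ):
        raise ValueError(
            f"{name} projects outside the image frame "
            f"(x in [{x.min():.1f}, {x.max():.1f}], y in [{y.min():.1f}, {y.max():.1f}])"
        )


def circle_scene(area_cm2: float = np.pi * 4.0, **kwargs) -> SceneSpec:
    """Convenience: the circular defect model of the validation study
    (default area pi * 2^2 = 12.566 cm^2, i.e. radius 2 cm)."""
    r = float(np.sqrt(area_cm2 / np.pi))
    return SceneSpec(wound_shape="circle", shape_params={"r": r}, **kwargs)


def scene_with_seed(scene: SceneSpec, seed: int) -> SceneSpec:
    return replace(scene, seed=int(seed))
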