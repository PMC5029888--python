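"""Device / lighting color normalization against the patch references.

The observed mean colors of the 9 patch cells and their known reference
values determine a per-channel affine map (3x3 gain block + offset, 12
parameters) by least squares.  Applying it to the whole image removes the
global device/illuminant cast, so that segmentation sees comparable colors
regardless of camera or lighting.  Colors are handled in the image's native
sRGB encoding throughout (no linearization).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .patch import PatchSpec
from .rectify import RectifiedImage


@dataclass(frozen=True)
class ColorCorrection:
    """Affine color map: out = gain @ rgb + offset, per pixel."""

    gain: np.ndarray  # (3, 3)
    offset: np.ndarray  # (3,)
    fit_residual_rms: float

    def __post_init__(self) -> None:
        g = np.asarray(self.gain, dtype=float)
        o = np.asarray(self.offset, dtype=float)
        if g.shape != (3, 3) or o.shape != (3,):
            raise ValueError("gain must be (3, 3) and offset (3,)")
        if abs(np.linalg.det(g)) < 1e-12:
            raise ValueError("gain block is singular")
        object.__setattr__(self, "gain", g)
        object.__setattr__(self, "offset", o)

    @property
    def matrix(self) -> np.ndarray:
        """The 3x4 affine matrix [gain | offset]."""
        return np.hstack([self.gain, self.offset[:, None]])

    @classmethod
    def identity(cls) -> "ColorCorrection":
        return cls(gain=np.eye(3), offset=np.zeros(3), fit_residual_rms=0.0)


def fit_color_correction(
    observed: np.ndarray,
    reference: np.ndarray,
    *,
    exclude_clipped: bool = False,
) -> ColorCorrection:
    """Least-squares affine fit mapping observed patch colors to references.

    Needs >= 4 color pairs whose observed colors span 3 dimensions.  With
    ``exclude_clipped`` pairs whose observed color has a channel at the
    sensor ceiling (> 0.99) are dropped when enough pairs remain, since
    clipping breaks the affine model.
    Raises ``ValueError`` on rank-deficient observations (e.g. all gray).
    """
    observed = np.asarray(observed, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if observed.shape != reference.shape or observed.ndim != 2 or observed.shape[1] != 3:
        raise ValueError("observed and reference must both be (N, 3)")
    if len(observed) < 4:
        raise ValueError("need at least 4 color pairs")
    if exclude_clipped:
        # a channel at the ceiling may be legitimate (a saturated reference)
        # or sensor-clipped; drop a ceiling cell only when it also misfits
        # an initial all-pairs fit, and only while the fit stays well posed
        design = np.column_stack([observed, np.ones(len(observed))])
        if np.linalg.matrix_rank(design, tol=1e-8) >= 4:
            sol0, *_ = np.linalg.lstsq(design, reference, rcond=None)
            resid0 = np.linalg.norm(design @ sol0 - reference, axis=1)
            suspect = (np.max(observed, axis=1) >= 0.995) & (resid0 > 0.01)
            keep = ~suspect
            design_kept = np.column_stack([observed[keep], np.ones(int(keep.sum()))])
            if keep.sum() >= 5 and np.linalg.matrix_rank(design_kept, tol=1e-8) >= 4:
                observed, reference = observed[keep], reference[keep]

    design = np.column_stack([observed, np.ones(len(observed))])
    if np.linalg.matrix_rank(design, tol=1e-8) < 4:
        raise ValueError("degenerate color set: observed colors do not span 3D")
    sol, *_ = np.linalg.lstsq(design, reference, rcond=None)  # (4, 3)
    resid = design @ sol - reference
    rms = float(np.sqrt(np.mean(resid**2)))
    return ColorCorrection(gain=sol[:3].T, offset=sol[3], fit_residual_rms=rms)


def apply_correction(image: np.ndarray, corr: ColorCorrection) -> np.ndarray:
    """Per-pixel affine color transform, clamped to [0, 1]."""
    image = np.asarray(image, dtype=float)
    out = image @ corr.gain.T + corr.offset[None, None, :]
    return np.clip(out, 0.0, 1.0)


def rectified_cell_colors(rect: RectifiedImage, spec: PatchSpec | None = None) -> np.ndarray:
    """Mean color of each patch cell sampled over the inner 60% of the cell
    in the rectified frame (axis-aligned, so sampling is a plain crop)."""
    spec = spec or PatchSpec()
    x0, y0, x1, y1 = rect.patch_region
    cell_px = (x1 - x0) / spec.grid_cols
    inner = 0.6
    colors = np.empty((spec.grid_rows * spec.grid_cols, 3))
    for row in range(spec.grid_rows):
        for col in range(spec.grid_cols):
            cx = x0 + (col + 0.5) * cell_px
            cy = y0 + (row + 0.5) * cell_px
            half = inner * cell_px / 2.0
            sl = rect.image[
                int(round(cy - half)) : int(round(cy + half)) + 1,
                int(round(cx - half)) : int(round(cx + half)) + 1,
            ]
            colors[row * spec.grid_cols + col] = sl.reshape(-1, 3).mean(axis=0)
    return colors


def normalize_rectified(
    rect: RectifiedImage, spec: PatchSpec | None = None
) -> tuple[RectifiedImage, ColorCorrection]:
    """Fit the correction on the rectified patch cells and apply it."""
    from dataclasses import replace

    spec = spec or PatchSpec()
    observed = rectified_cell_colors(rect, spec)
    corr = fit_color_correction(observed, spec.reference_colors, exclude_clipped=True)
    corrected = apply_correction(rect.image, corr)
    return replace(rect, image=corrected), corr
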