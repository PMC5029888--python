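"""The fiducial color patch: physical geometry and reference colors.

The patch is a printed 3x3 grid of known colors placed in the wound plane.
Each cell is 0.7 cm x 0.7 cm, so the gross patch is 2.1 cm x 2.1 cm.  Its
known physical size anchors the cm-per-pixel scale after rectification, and
its known colors anchor the device/lighting color correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default reference colors, row-major (row 0 = physical top row).
#: Chosen maximally separated in sRGB and arranged asymmetrically so that the
#: 4-fold rotation ambiguity of a square grid is resolvable from colors alone.
DEFAULT_PATCH_COLORS = np.array(
    [
        [1.0, 0.0, 0.0],  # red
        [0.0, 1.0, 0.0],  # green
        [0.0, 0.0, 1.0],  # blue
        [0.0, 1.0, 1.0],  # cyan
        [1.0, 0.0, 1.0],  # magenta
        [1.0, 1.0, 0.0],  # yellow
        [0.0, 0.0, 0.0],  # black
        [1.0, 1.0, 1.0],  # white
        [0.5, 0.5, 0.5],  # mid-gray
    ]
)


@dataclass(frozen=True)
class PatchSpec:
    """Physical geometry and the 9 reference colors of the 3x3 color patch."""

    cell_side_cm: float = 0.7
    grid_rows: int = 3
    grid_cols: int = 3
    reference_colors: np.ndarray = field(
        default_factory=lambda: DEFAULT_PATCH_COLORS.copy()
    )

    def __post_init__(self) -> None:
        colors = np.asarray(self.reference_colors, dtype=float)
        if colors.shape != (self.grid_rows * self.grid_cols, 3):
            raise ValueError(
                f"need {self.grid_rows * self.grid_cols} RGB reference colors"
            )
        if colors.min() < 0 or colors.max() > 1:
            raise ValueError("reference colors must lie in [0, 1]")
        d = np.linalg.norm(colors[:, None] - colors[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < 0.2:
            raise ValueError("reference colors must be pairwise >= 0.2 apart")
        if self.cell_side_cm <= 0:
            raise ValueError("cell_side_cm must be positive")
        if self._is_rotation_symmetric(colors):
            raise ValueError(
                "reference color arrangement is rotation-symmetric: "
                "patch orientation would be ambiguous"
            )
        object.__setattr__(self, "reference_colors", colors)

    def _is_rotation_symmetric(self, colors: np.ndarray) -> bool:
        grid = colors.reshape(self.grid_rows, self.grid_cols, 3)
        for k in (1, 2, 3):
            if np.allclose(np.rot90(grid, k), grid):
                return True
        return False

    @property
    def gross_side_cm(self) -> float:
        return self.grid_rows * self.cell_side_cm

    @property
    def color_grid(self) -> np.ndarray:
        """Reference colors as a (rows, cols, 3) grid."""
        return self.reference_colors.reshape(self.grid_rows, self.grid_cols, 3)

    def corner_positions_cm(self) -> np.ndarray:
        """Outer corners TL, TR, BR, BL in patch-local cm coordinates
        (origin at the top-left corner, x rightward, y downward)."""
        s = self.gross_side_cm
        return np.array([[0.0, 0.0], [s, 0.0], [s, s], [0.0, s]])

    def cell_center_cm(self, row: int, col: int) -> np.ndarray:
        c = self.cell_side_cm
        return np.array([(col + 0.5) * c, (row + 0.5) * c])


def patch_spec_from_hex(hex_colors: list[str], cell_side_cm: float = 0.7) -> PatchSpec:
    """Build a PatchSpec from 9 hex color strings like ``#ff0000``."""
    colors = []
    for h in hex_colors:
        h = h.lstrip("#")
        if len(h) != 6:
            raise ValueError(f"bad hex color: {h!r}")
        colors.append([int(h[i : i + 2], 16) / 255.0 for i in (0, 2, 4)])
    return PatchSpec(cell_side_cm=cell_side_cm, reference_colors=np.array(colors))
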