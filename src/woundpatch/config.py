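"""Run configuration: defaults, YAML round-tripping, strict key checking."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from .patch import DEFAULT_PATCH_COLORS, PatchSpec, patch_spec_from_hex
from .segmentation import GVFParams, SnakeParams


def _hex(rgb) -> str:
    return "#" + "".join(f"{int(round(c * 255)):02x}" for c in rgb)


DEFAULTS: dict = {
    "patch.colors": [_hex(c) for c in DEFAULT_PATCH_COLORS],
    "patch.cell_cm": 0.7,
    "rectify.px_per_cm": 100.0,
    "rectify.margin_cm": 8.0,
    "rectify.max_raster_px": 4096,
    "detect.color_threshold": 0.30,
    "normalize.enabled": True,
    "snake.alpha": 0.2,
    "snake.beta": 0.2,
    "snake.gamma": 1.0,
    "snake.kappa": 0.5,
    "snake.max_iter": 500,
    "snake.tol_px": 0.01,
    "snake.spacing_px": 2.0,
    "gvf.mu": 0.2,
    "gvf.dt": 1.0,
    "gvf.tol": 1.0e-4,
    "kmeans.k": 2,
    "segment.edge_sigma": 1.0,
    "longitudinal.half_mode": "interp",
    "seed": 0,
    "log_level": "info",
}


class RunConfig:
    """Flat dotted-key configuration with strict unknown-key rejection.

    Files are YAML, either nested sections or flat dotted keys; both load
    to the same flat mapping and save losslessly.
    """

    def __init__(self, overrides: dict | None = None):
        self.values = dict(DEFAULTS)
        if overrides:
            self.update(overrides)

    def update(self, overrides: dict) -> None:
        flat = _flatten(overrides)
        unknown = set(flat) - set(DEFAULTS)
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        self.values.update(flat)

    def __getitem__(self, key: str):
        return self.values[key]

    def __eq__(self, other) -> bool:
        return isinstance(other, RunConfig) and self.values == other.values

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.values, fh, sort_keys=True)

    # ----- typed views -------------------------------------------------

    def patch_spec(self) -> PatchSpec:
        return patch_spec_from_hex(self["patch.colors"], self["patch.cell_cm"])

    def snake_params(self) -> SnakeParams:
        return SnakeParams(
            alpha=self["snake.alpha"],
            beta=self["snake.beta"],
            gamma=self["snake.gamma"],
            kappa=self["snake.kappa"],
            max_iter=self["snake.max_iter"],
            tol_px=self["snake.tol_px"],
            spacing_px=self["snake.spacing_px"],
        )

    def gvf_params(self) -> GVFParams:
        return GVFParams(mu=self["gvf.mu"], dt=self["gvf.dt"], tol=self["gvf.tol"])

    def measure_kwargs(self) -> dict:
        return dict(
            px_per_cm=self["rectify.px_per_cm"],
            margin_cm=self["rectify.margin_cm"],
            max_raster_px=self["rectify.max_raster_px"],
            snake_params=self.snake_params(),
            gvf_params=self.gvf_params(),
            normalize=self["normalize.enabled"],
        )

    def digest(self) -> str:
        import hashlib
        import json

        blob = json.dumps(self.values, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _flatten(data: dict, prefix: str = "") -> dict:
    flat: dict = {}
    for key, value in data.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            flat.update(_flatten(value, f"{full}."))
        else:
            if isinstance(value, np.generic):
                value = value.item()
            flat[full] = value
    return flat
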