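"""Image and report I/O."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageOps


def read_image(path: str | Path) -> np.ndarray:
    """Decode PNG/JPEG/TIFF to a float RGB raster in [0, 1].

    EXIF orientation is honored; grayscale is promoted to RGB; 16-bit
    inputs are scaled by 1/65535.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    try:
        with Image.open(path) as img:
            img = ImageOps.exif_transpose(img)
            arr = np.asarray(img)
    except Exception as exc:
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:  # drop alpha
        arr = arr[..., :3]
    return np.clip(arr, 0.0, 1.0)


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a float [0, 1] RGB (or bool mask) raster as 8-bit PNG."""
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = arr.astype(float)
    arr = (np.clip(arr, 0, 1) * 255).round().astype(np.uint8)
    Image.fromarray(arr).save(path)


def _round_floats(obj, ndigits: int = 4):
    if isinstance(obj, (float, np.floating)):
        value = float(obj)
        return None if np.isnan(value) else round(value, ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def measurement_report(measurement, seed: int | None = None) -> dict:
    """JSON-ready report for one measurement (floats at 4 decimals,
    deterministic field order)."""
    rep = {
        "area_cm2": measurement.area_cm2,
        "lw_area_cm2": measurement.lw_area_cm2,
        "scale_cm_per_px": measurement.scale_cm_per_px,
        "homography": measurement.homography,
        "patch_corners": measurement.detection.outer_corners,
        "detection_confidence": measurement.detection.confidence,
        "color_residual": measurement.color_residual_rms,
        "color_matrix": measurement.color_matrix,
        "stages": measurement.stage_report,
        "seed": seed,
        "metadata": measurement.metadata,
    }
    return _round_floats(rep)


def write_report(obj, path: str | Path, fmt: str = "json") -> None:
    """Write a measurement/summary report as JSON or CSV."""
    path = Path(path)
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(_round_floats(obj), fh, indent=2)
            fh.write("\n")
    elif fmt == "csv":
        if not isinstance(obj, pd.DataFrame):
            obj = pd.DataFrame(obj)
        obj.round(4).to_csv(path, index=False)
    else:
        raise ValueError(f"unsupported report format: {fmt}")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a longitudinal manifest CSV.

    Columns: patient_id, site_class, day, then either area_cm2
    (precomputed) or image_path (areas to be measured).
    """
    df = pd.read_csv(path)
    required = {"patient_id", "site_class", "day"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "area_cm2" not in df.columns and "image_path" not in df.columns:
        raise ValueError("manifest needs an 'area_cm2' or 'image_path' column")
    return df
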