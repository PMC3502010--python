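"""Image and table IO, configuration, and provenance helpers.

Readers return real-valued arrays regardless of the on-disk integer
format; quantization happens only on write.  Supported formats: 8/16-bit
grayscale PNG and TIFF, single-slice DICOM (pixel data, rescale slope /
intercept and PixelSpacing only), CSV for contours and feature tables,
YAML/JSON for configuration.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ParameterError
from .morphometry import FEATURE_NAMES

__all__ = [
    "GrayImage",
    "read_image",
    "write_image",
    "write_mask",
    "read_contour_csv",
    "write_contour_csv",
    "write_features_csv",
    "load_config",
    "save_json",
    "config_hash",
]


@dataclass
class GrayImage:
    """A 2-D intensity grid plus optional physical pixel spacing (mm)."""

    pixels: np.ndarray
    spacing: float = 1.0


def _to_gray(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        warnings.warn("RGB input converted to luminance", stacklevel=3)
        arr = arr[..., :3] @ np.array([0.2125, 0.7154, 0.0721])
    if arr.ndim != 2:
        raise DataError("expected a single 2-D image")
    return np.asarray(arr, dtype=float)


def read_image(path: str | Path) -> GrayImage:
    """Read a grayscale PNG/TIFF/DICOM image as floats.

    DICOM rescale slope/intercept are applied and PixelSpacing (row
    spacing) is reported when present; multi-frame DICOM is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise ParameterError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        import pydicom

        ds = pydicom.dcmread(path)
        if int(getattr(ds, "NumberOfFrames", 1)) > 1:
            raise DataError("multi-frame DICOM is not supported")
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        arr = arr * slope + intercept
        spacing = 1.0
        if getattr(ds, "PixelSpacing", None) is not None:
            spacing = float(ds.PixelSpacing[0])
        return GrayImage(_to_gray(arr), spacing)
    if suffix in (".png", ".tif", ".tiff"):
        return GrayImage(_to_gray(iio.imread(path)))
    raise ParameterError(f"unsupported image format: {suffix}")


def write_image(path: str | Path, pixels: np.ndarray,
                dtype: str = "uint16") -> None:
    """Quantize to 8/16-bit and write PNG or TIFF.

    Values are rounded and clipped to the dtype range; callers holding
    data outside that range should rescale first.
    """
    path = Path(path)
    if dtype not in ("uint8", "uint16"):
        raise ParameterError("dtype must be 'uint8' or 'uint16'")
    info = np.iinfo(dtype)
    data = np.clip(np.round(np.asarray(pixels, dtype=float)),
                   info.min, info.max).astype(dtype)
    iio.imwrite(path, data)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a binary mask as an 8-bit PNG (0 / 255)."""
    write_image(path, np.asarray(mask, dtype=bool) * 255, dtype="uint8")


def read_contour_csv(path: str | Path) -> np.ndarray:
    """Read a contour as an (N, 2) array from a CSV with x,y columns."""
    df = pd.read_csv(path)
    if not {"x", "y"} <= set(df.columns):
        raise DataError("contour CSV must have 'x' and 'y' columns")
    return df[["x", "y"]].to_numpy(dtype=float)


def write_contour_csv(path: str | Path, contour: np.ndarray) -> None:
    pd.DataFrame(np.asarray(contour, dtype=float),
                 columns=["x", "y"]).to_csv(path, index=False)


def write_features_csv(path: str | Path,
                       rows: list[dict[str, float]],
                       node_ids: list | None = None) -> None:
    """Write feature rows using the canonical 19-column contract."""
    df = pd.DataFrame(rows)[list(FEATURE_NAMES)]
    df.insert(0, "node_id", node_ids if node_ids is not None
              else list(range(len(df))))
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    cfg = (json.loads(text) if path.suffix.lower() == ".json"
           else yaml.safe_load(text))
    if not isinstance(cfg, dict):
        raise DataError("configuration must be a mapping")
    return cfg


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration for provenance stamping."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def save_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
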