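"""File formats: PNG images, 16-bit depth maps, CSV manifests, YAML configs.

Depth maps are written as 16-bit PNG with a declared millimetres-per-
unit scale (default 0.01 mm/unit, i.e. 0–655 mm range at 0.01 mm
resolution); the scale travels in the manifest / sidecar, never implied.
Background (no-geometry) pixels are stored as 0 and restored as invalid.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .depth import DepthMap

__all__ = [
    "DEFAULT_DEPTH_SCALE_MM",
    "write_rgb",
    "write_mask",
    "write_depth_png",
    "read_depth_png",
    "write_sample",
    "write_manifest",
    "read_manifest",
    "load_config",
    "dump_config",
]

DEFAULT_DEPTH_SCALE_MM = 0.01  # mm per 16-bit unit


def write_rgb(path: str | Path, rgb: np.ndarray) -> None:
    iio.imwrite(Path(path), np.asarray(rgb, dtype=np.uint8))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    iio.imwrite(Path(path), (np.asarray(mask, bool) * np.uint8(255)))


def read_mask(path: str | Path) -> np.ndarray:
    return np.asarray(iio.imread(Path(path))) > 127


def write_depth_png(
    path: str | Path, depth: DepthMap, scale_mm_per_unit: float = DEFAULT_DEPTH_SCALE_MM
) -> None:
    """Quantise a depth map to 16-bit PNG; invalid pixels become 0."""
    units = np.zeros(depth.shape, dtype=np.uint16)
    vals = np.round(depth.values_mm / scale_mm_per_unit)
    vals = np.clip(vals, 1, 65535)  # 0 is reserved for background
    units[depth.valid] = vals[depth.valid].astype(np.uint16)
    iio.imwrite(Path(path), units)


def read_depth_png(
    path: str | Path, scale_mm_per_unit: float = DEFAULT_DEPTH_SCALE_MM
) -> DepthMap:
    units = np.asarray(iio.imread(Path(path)))
    valid = units > 0
    return DepthMap(units.astype(float) * scale_mm_per_unit, valid)


def write_sample(sample, directory: str | Path, stem: str, scale_mm_per_unit: float = DEFAULT_DEPTH_SCALE_MM) -> dict:
    """Write one scene sample (RGB + depth + mask) and return its file row."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "rgb": directory / f"{stem}_rgb.png",
        "depth": directory / f"{stem}_depth.png",
        "mask": directory / f"{stem}_mask.png",
    }
    write_rgb(paths["rgb"], sample.rgb)
    write_depth_png(paths["depth"], sample.depth_gt, scale_mm_per_unit)
    write_mask(paths["mask"], sample.polyp_mask)
    return {k: str(v) for k, v in paths.items()} | {"depth_scale_mm": scale_mm_per_unit}


def write_manifest(path: str | Path, manifest: pd.DataFrame) -> None:
    manifest.to_csv(Path(path), index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


CONFIG_SCHEMA_VERSION = 1


def dump_config(config_dict: dict, path: str | Path) -> None:
    doc = {"schema_version": CONFIG_SCHEMA_VERSION, **config_dict}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path: str | Path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    version = doc.pop("schema_version", CONFIG_SCHEMA_VERSION)
    if version != CONFIG_SCHEMA_VERSION:
        raise ValueError(f"unsupported config schema version {version}")
    return doc
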