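"""Reading and writing of images, masks, point sets and configs.

Images are TIFF / OME-TIFF stacks (z-plane major). Voxel spacing is read
from OME-XML metadata (``PhysicalSizeZ/Y/X``, assumed µm) when present
and can always be overridden; masks are 8-bit single-channel TIFFs with
0 = false, 255 = true; point sets are CSV files with the header
``z_um,y_um,x_um[,label]``.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import BinaryMask, PointSet, VolumetricImage, VoxelGrid

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_points",
    "write_points",
    "load_config",
    "dump_config",
]


def _ome_spacing(tif: "tifffile.TiffFile") -> Optional[tuple[float, float, float]]:
    xml = tif.ome_metadata
    if not xml:
        return None
    out = {}
    for ax in ("Z", "Y", "X"):
        m = re.search(rf'PhysicalSize{ax}="([0-9.eE+-]+)"', xml)
        if not m:
            return None
        out[ax] = float(m.group(1))
    return (out["Z"], out["Y"], out["X"])


def read_image(
    path: str | Path,
    spacing: Optional[tuple[float, float, float]] = None,
    channel_label: str = "",
) -> VolumetricImage:
    """Load a 3D TIFF/OME-TIFF stack as a :class:`VolumetricImage`.

    ``spacing`` (dz, dy, dx in µm) overrides any file metadata; without
    either, an error is raised.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        if spacing is None:
            spacing = _ome_spacing(tif)
    if spacing is None:
        raise ValueError(
            f"{path}: no voxel spacing in metadata; pass spacing=(dz, dy, dx) in µm"
        )
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a single-channel 3D stack, got shape {arr.shape}")
    grid = VoxelGrid(arr.shape, spacing)
    return VolumetricImage(grid, np.asarray(arr, dtype=float), channel_label or path.stem)


def write_image(path: str | Path, image: VolumetricImage) -> None:
    """Write a stack as OME-TIFF with voxel spacing metadata (µm)."""
    dz, dy, dx = image.grid.spacing
    tifffile.imwrite(
        str(path),
        np.asarray(image.values, dtype=np.float32),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
        },
    )


def read_mask(
    path: str | Path,
    spacing: Optional[tuple[float, float, float]] = None,
    role: str = "domain",
) -> BinaryMask:
    """Load an 8-bit TIFF mask (0 = background, anything else = foreground)."""
    img = read_image(path, spacing=spacing)
    return BinaryMask(img.grid, img.values > 0, role=role)


def write_mask(path: str | Path, mask: BinaryMask) -> None:
    dz, dy, dx = mask.grid.spacing
    tifffile.imwrite(
        str(path),
        (mask.values.astype(np.uint8) * 255),
        ome=True,
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeY": dy,
            "PhysicalSizeX": dx,
        },
    )


def read_points(path: str | Path) -> PointSet:
    """Read a point set CSV with columns ``z_um,y_um,x_um[,label]``."""
    path = Path(path)
    df = pd.read_csv(path)
    required = ["z_um", "y_um", "x_um"]
    if list(df.columns[:3]) != required:
        raise ValueError(
            f"{path}: expected header starting with {','.join(required)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    coords = df[required].to_numpy(dtype=float)
    bad = ~np.all(np.isfinite(coords), axis=1)
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ValueError(f"{path}: malformed coordinate at line {line}")
    labels = df["label"].to_numpy() if "label" in df.columns else None
    return PointSet(coords, labels=labels)


def write_points(path: str | Path, points: PointSet) -> None:
    data = {
        "z_um": np.round(points.coords[:, 0], 6),
        "y_um": np.round(points.coords[:, 1], 6),
        "x_um": np.round(points.coords[:, 2], 6),
    }
    if points.labels is not None:
        data["label"] = points.labels
    pd.DataFrame(data).to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def dump_config(path: str | Path, config: dict) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(config, indent=2, default=str))
    else:
        path.write_text(yaml.safe_dump(config, sort_keys=False))
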