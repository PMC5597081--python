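"""Reading and writing of field images and tidy tables.

Fields travel as OME-TIFF with named channels (DNA/CX43/ITGA3/EEA1/LAMP1/
GFP); ground truth and quantification outputs are plain CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .image2d import ImageSet

CHANNEL_ORDER = ["DNA", "CX43", "ITGA3", "EEA1", "LAMP1", "GFP"]


def write_imageset(path: str | Path, imageset: ImageSet) -> None:
    """Write a multi-channel field as OME-TIFF with channel names."""
    path = Path(path)
    names = [c for c in CHANNEL_ORDER if c in imageset.channels]
    names += [c for c in imageset.channels if c not in names]
    stack = np.stack([imageset.channels[c] for c in names]).astype(np.float32)
    tifffile.imwrite(
        path,
        stack,
        ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": names},
            "PhysicalSizeX": imageset.pixel_size_um,
            "PhysicalSizeY": imageset.pixel_size_um,
        },
    )
    sidecar = {
        "channels": names,
        "pixel_size_um": imageset.pixel_size_um,
        "well_id": imageset.well_id,
        "site_id": imageset.site_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_imageset(path: str | Path) -> ImageSet:
    """Read a field written by :func:`write_imageset`."""
    path = Path(path)
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None]
    sidecar_path = path.with_suffix(".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        names = meta["channels"]
        pixel_size = float(meta.get("pixel_size_um", 1.0))
        well_id = meta.get("well_id", "well")
        site_id = meta.get("site_id", "site")
    else:
        names = CHANNEL_ORDER[: stack.shape[0]]
        pixel_size, well_id, site_id = 1.0, path.stem, path.stem
    channels = {name: stack[i].astype(float) for i, name in enumerate(names)}
    return ImageSet(
        channels=channels,
        pixel_size_um=pixel_size,
        well_id=well_id,
        site_id=site_id,
    )


def write_zstack(path: str | Path, volume: np.ndarray) -> None:
    tifffile.imwrite(Path(path), np.asarray(volume, dtype=np.float32))


def read_zstack(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


def read_rois(path: str | Path) -> list[np.ndarray]:
    """Read ROI polygons from CSV with columns roi_id, row, col."""
    df = pd.read_csv(path)
    return [
        grp[["row", "col"]].to_numpy(dtype=float)
        for _, grp in df.groupby("roi_id", sort=True)
    ]
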