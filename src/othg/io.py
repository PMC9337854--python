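"""TIFF stack I/O, power-log CSV, mosaic assembly and run manifests.

Stacks are multi-page TIFFs written with ImageJ-style metadata so that
voxel sizes (and the frame interval of 4D hyperstacks) survive a
round trip.  Axis order is normalised to (t,)z,y,x on read.  A stack
without physical pixel-size metadata and without an explicit override is
an error — never a silent 1 µm assumption.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .core import ImageVolume

__all__ = [
    "read_stack",
    "write_stack",
    "read_power_log",
    "TileLayout",
    "assemble_mosaic",
    "write_manifest",
]


def write_stack(path, volume: ImageVolume) -> None:
    """Write an ImageVolume as an ImageJ-compatible (hyper)stack TIFF."""
    data = volume.data
    if data.dtype == np.float64:
        data = data.astype(np.float32)
    axes = "TZYX" if volume.is_timelapse else "ZYX"
    vz, vy, vx = volume.voxel_size
    metadata = {"axes": axes, "spacing": vz, "unit": "um"}
    if volume.frame_interval is not None:
        metadata["finterval"] = volume.frame_interval * 60.0  # seconds
    tifffile.imwrite(path, data, imagej=True,
                     resolution=(1.0 / vx, 1.0 / vy), metadata=metadata)


def read_stack(path, voxel_size: Optional[Tuple[float, float, float]] = None,
               frame_interval: Optional[float] = None) -> ImageVolume:
    """Read a multi-page TIFF into an ImageVolume with axes (t,)z,y,x.

    Voxel sizes come from the file's metadata; an explicit ``voxel_size``
    override wins.  Missing metadata without an override raises.
    """
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta = tf.imagej_metadata or {}
        page = tf.pages[0]
        res = {}
        for tagname in ("XResolution", "YResolution"):
            tag = page.tags.get(tagname)
            if tag is not None:
                num, den = tag.value
                if num:
                    res[tagname] = den / num

    # normalise axes: accept YX, ZYX, TZYX, CZYX-free layouts
    if axes.endswith("YX"):
        lead = axes[:-2]
        if lead in ("", "Z", "TZ", "QZ", "IZ", "ZT"):
            pass
        elif lead in ("T", "I", "Q", "S"):
            axes = "Z" + axes[-2:]  # treat a bare page axis as z
        else:
            raise ValueError(f"unsupported TIFF axis order {axes!r} in {path}")
    else:
        raise ValueError(f"unsupported TIFF axis order {axes!r} in {path}")
    if data.ndim == 2:
        data = data[None]

    if voxel_size is not None:
        vs = tuple(float(v) for v in voxel_size)
    else:
        spacing = meta.get("spacing")
        vy = res.get("YResolution")
        vx = res.get("XResolution")
        if spacing is None or vy is None or vx is None:
            raise ValueError(
                f"{path}: no voxel-size metadata found and no override given; "
                "pass voxel_size=(z, y, x) in µm explicitly")
        vs = (float(spacing), float(vy), float(vx))

    fi = frame_interval
    if fi is None and meta.get("finterval"):
        fi = float(meta["finterval"]) / 60.0
    if data.ndim == 3:
        fi = None
    return ImageVolume(data, vs, frame_interval=fi)


def read_power_log(path) -> pd.DataFrame:
    """Read a per-depth excitation power log CSV (columns z_um, power_mW)."""
    df = pd.read_csv(path)
    missing = {"z_um", "power_mW"} - set(df.columns)
    if missing:
        raise ValueError(f"power log {path} lacks columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# mosaic assembly

@dataclass
class TileLayout:
    """Tiles of a serial multi-site acquisition with their stage offsets.

    Each tile is an ``(ImageVolume, (y_um, x_um))`` pair; stage coordinates
    are physical µm with y down / x right, matching image axes.
    """

    tiles: List[Tuple[ImageVolume, Tuple[float, float]]]
    overlap_policy: str = "average"  # or "max", "first"

    def __post_init__(self) -> None:
        if self.overlap_policy not in ("average", "max", "first"):
            raise ValueError(f"unknown overlap policy {self.overlap_policy!r}")
        offsets = [tuple(off) for _, off in self.tiles]
        if len(set(offsets)) != len(offsets):
            raise ValueError("tile stage offsets must be unique")


def assemble_mosaic(layout: TileLayout) -> ImageVolume:
    """Place tiles at nearest-voxel stage offsets and blend overlaps.

    All tiles must share z extent and voxel size; the output bounding box
    is the union of the placed tiles.
    """
    if not layout.tiles:
        raise ValueError("no tiles to assemble")
    first_vol = layout.tiles[0][0]
    vs = first_vol.voxel_size
    nz = first_vol.data.shape[0]
    for vol, _ in layout.tiles:
        if vol.is_timelapse:
            raise ValueError("mosaic assembly expects 3D tiles")
        if vol.voxel_size != vs:
            raise ValueError("tiles must share voxel size")
        if vol.data.shape[0] != nz:
            raise ValueError(
                f"tile z extent {vol.data.shape[0]} != {nz}: all tiles must "
                "share z extent")

    placements = []
    for vol, (oy, ox) in layout.tiles:
        iy = int(round(oy / vs[1]))
        ix = int(round(ox / vs[2]))
        placements.append((vol, iy, ix))
    y0 = min(iy for _, iy, _ in placements)
    x0 = min(ix for _, _, ix in placements)
    y1 = max(iy + v.data.shape[1] for v, iy, _ in placements)
    x1 = max(ix + v.data.shape[2] for v, _, ix in placements)

    out = np.zeros((nz, y1 - y0, x1 - x0), dtype=np.float64)
    if layout.overlap_policy == "average":
        counts = np.zeros_like(out)
    filled = np.zeros(out.shape, dtype=bool)
    for vol, iy, ix in placements:
        sl = (slice(None), slice(iy - y0, iy - y0 + vol.data.shape[1]),
              slice(ix - x0, ix - x0 + vol.data.shape[2]))
        if layout.overlap_policy == "average":
            out[sl] += vol.data
            counts[sl] += 1
        elif layout.overlap_policy == "max":
            out[sl] = np.maximum(out[sl], vol.data)
        else:  # first
            region = out[sl]
            fresh = ~filled[sl]
            region[fresh] = np.asarray(vol.data, dtype=np.float64)[fresh]
            out[sl] = region
        filled[sl] = True
    if layout.overlap_policy == "average":
        out = np.divide(out, counts, out=out, where=counts > 0)
    return ImageVolume(out.astype(first_vol.data.dtype, copy=False), vs)


# ---------------------------------------------------------------------------
# manifests

def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: Optional[int] = None,
                   inputs: Sequence[Union[str, Path]] = ()) -> dict:
    """Write a JSON run manifest: config, seed, versions and input hashes."""
    import othg

    manifest = {
        "config": config,
        "seed": seed,
        "versions": {
            "othg": othg.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "tifffile": tifffile.__version__,
        },
        "inputs": {str(p): _sha256(p) for p in inputs},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
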