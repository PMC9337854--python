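"""Shared data containers for image volumes and label volumes.

All geometry in this package is expressed in micrometres.  Voxel indices
are 0-based and a physical coordinate refers to the *centre* of a voxel,
so ``position_um = index * voxel_size``.  3D arrays are ordered (z, y, x)
and 4D time-lapse arrays (t, z, y, x); z = 0 is the first acquired slice
(the sample surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np

__all__ = ["ImageVolume", "LabelVolume", "um_to_index", "index_to_um"]


def _check_voxel_size(voxel_size: Sequence[float]) -> Tuple[float, float, float]:
    vs = tuple(float(v) for v in voxel_size)
    if len(vs) != 3:
        raise ValueError("voxel_size must be (z, y, x) in micrometres")
    if any(v <= 0 for v in vs):
        raise ValueError(f"voxel sizes must be positive, got {vs}")
    return vs


@dataclass
class ImageVolume:
    """Intensity volume with physical voxel sizes.

    Parameters
    ----------
    data:
        3D ``(z, y, x)`` or 4D ``(t, z, y, x)`` intensity array.
    voxel_size:
        ``(z, y, x)`` voxel edge lengths in micrometres.
    frame_interval:
        Time between volumetric frames in minutes (4D data only).
    channel:
        Optional channel label (e.g. ``"THG"``, ``"GFP"``, ``"7AAD"``).
    """

    data: np.ndarray
    voxel_size: Tuple[float, float, float]
    frame_interval: Optional[float] = None
    channel: Optional[str] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(f"data must be 3D or 4D, got ndim={self.data.ndim}")
        self.voxel_size = _check_voxel_size(self.voxel_size)
        if self.is_timelapse:
            if self.frame_interval is not None and self.frame_interval <= 0:
                raise ValueError("frame_interval must be positive")
        elif self.frame_interval is not None:
            raise ValueError("frame_interval only applies to 4D time-lapse data")

    @property
    def is_timelapse(self) -> bool:
        return self.data.ndim == 4

    @property
    def n_frames(self) -> int:
        return self.data.shape[0] if self.is_timelapse else 1

    @property
    def spatial_shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape[-3:])

    def depths_um(self) -> np.ndarray:
        """Physical depth of each z slice (z = 0 at the first slice)."""
        nz = self.spatial_shape[0]
        return np.arange(nz, dtype=float) * self.voxel_size[0]

    def frame(self, t: int) -> "ImageVolume":
        """Extract one 3D frame from a 4D time-lapse."""
        if not self.is_timelapse:
            raise ValueError("frame() requires 4D time-lapse data")
        return ImageVolume(self.data[t], self.voxel_size, channel=self.channel)

    def with_data(self, data: np.ndarray) -> "ImageVolume":
        out = replace(self, data=np.asarray(data))
        return out


@dataclass
class LabelVolume:
    """Integer-labelled 3D segmentation sharing geometry with an ImageVolume.

    Label 0 is background; positive labels identify regions (e.g. individual
    ventricular-zone shells).
    """

    labels: np.ndarray
    voxel_size: Tuple[float, float, float]
    provenance: str = "semi_automatic"  # or "manual_import"

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D (z, y, x) array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.voxel_size = _check_voxel_size(self.voxel_size)
        if self.provenance not in ("manual_import", "semi_automatic"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return int(self.label_ids.size)

    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.voxel_size))


def um_to_index(position_um: np.ndarray, voxel_size: Sequence[float]) -> np.ndarray:
    """Convert physical (z, y, x) µm coordinates to nearest voxel indices."""
    pos = np.asarray(position_um, dtype=float)
    vs = np.asarray(voxel_size, dtype=float)
    return np.rint(pos / vs).astype(int)


def index_to_um(index: np.ndarray, voxel_size: Sequence[float]) -> np.ndarray:
    """Convert voxel indices to physical (z, y, x) µm coordinates (voxel centres)."""
    return np.asarray(index, dtype=float) * np.asarray(voxel_size, dtype=float)
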