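"""Two-channel colocalization: voxelwise mask overlap and per-cell overlap.

Overlap is Manders-style count overlap on thresholded masks (percentage of
above-threshold voxels of one channel that are also above threshold in the
other), not intensity correlation.  Per-cell overlap asks whether each
detected cell carries signal in a second channel within a radius of its
centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .core import ImageVolume, um_to_index

__all__ = ["ColocResult", "CellOverlap", "voxel_overlap", "cell_overlap"]


@dataclass
class ColocResult:
    overlap_a_in_b: float      # %, NaN when |A| = 0
    overlap_b_in_a: float      # %, NaN when |B| = 0
    threshold_a: float
    threshold_b: float
    n_voxels_a: int
    n_voxels_b: int
    n_voxels_joint: int
    thresh_method: str = "otsu"


@dataclass
class CellOverlap:
    n_cells_a: int
    n_cells_a_with_b: int
    fraction: float
    radius: float              # µm

    @classmethod
    def from_counts(cls, n_with: int, n_total: int, radius: float = math.nan
                    ) -> "CellOverlap":
        """Build directly from tabulated counts (e.g. published cell tallies)."""
        if n_total <= 0:
            raise ValueError("need at least one cell")
        if n_with > n_total:
            raise ValueError("overlap count cannot exceed total count")
        return cls(n_cells_a=int(n_total), n_cells_a_with_b=int(n_with),
                   fraction=n_with / n_total, radius=radius)

    @property
    def percentage(self) -> float:
        return 100.0 * self.fraction


def _threshold(data: np.ndarray, method: str, value: Optional[float],
               percentile: float) -> float:
    if method == "fixed":
        if value is None:
            raise ValueError("fixed thresholding requires a threshold value")
        return float(value)
    if method == "otsu":
        return float(threshold_otsu(data))
    if method == "percentile":
        return float(np.percentile(data, percentile))
    raise ValueError(f"unknown threshold method {method!r}")


def voxel_overlap(
    chan_a: ImageVolume,
    chan_b: ImageVolume,
    thresh_method: str = "otsu",
    threshold_a: Optional[float] = None,
    threshold_b: Optional[float] = None,
    percentile: float = 99.0,
) -> ColocResult:
    """Percentage overlap of the thresholded masks of two channels.

    ``overlap_a_in_b = 100 * |A and B| / |A|`` and symmetrically for B.
    An empty mask makes the corresponding percentage undefined (NaN).
    """
    if chan_a.data.shape != chan_b.data.shape:
        raise ValueError("channels must share shape")
    if chan_a.voxel_size != chan_b.voxel_size:
        raise ValueError("channels must share voxel size")
    ta = _threshold(chan_a.data, thresh_method, threshold_a, percentile)
    tb = _threshold(chan_b.data, thresh_method, threshold_b, percentile)
    mask_a = chan_a.data > ta
    mask_b = chan_b.data > tb
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    nj = int((mask_a & mask_b).sum())
    return ColocResult(
        overlap_a_in_b=100.0 * nj / na if na else math.nan,
        overlap_b_in_a=100.0 * nj / nb if nb else math.nan,
        threshold_a=ta, threshold_b=tb,
        n_voxels_a=na, n_voxels_b=nb, n_voxels_joint=nj,
        thresh_method=thresh_method)


def cell_overlap(
    cells_a: pd.DataFrame,
    chan_b: ImageVolume,
    radius_um: float = 5.0,
    b_threshold: Optional[float] = None,
) -> CellOverlap:
    """Fraction of channel-A cells with channel-B signal near their centroid.

    A cell "has" B signal when the mean B intensity within ``radius_um`` of
    its centroid exceeds ``b_threshold`` (Otsu of channel B when omitted).
    ``cells_a`` needs columns ``z_um, y_um, x_um``.
    """
    if len(cells_a) == 0:
        raise ValueError("no cells given")
    vs = np.asarray(chan_b.voxel_size, dtype=float)
    if np.any(radius_um < vs):
        raise ValueError("radius must be at least one voxel in every axis")
    if b_threshold is None:
        b_threshold = float(threshold_otsu(chan_b.data))

    data = chan_b.data
    shape = np.asarray(data.shape)
    half = np.ceil(radius_um / vs).astype(int)
    offs = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    dist2 = sum((o * v) ** 2 for o, v in zip(offs, vs))
    ball = dist2 <= radius_um ** 2

    n_with = 0
    for row in cells_a.itertuples(index=False):
        center = np.array([row.z_um, row.y_um, row.x_um])
        idx = um_to_index(center, vs)
        lo = idx - half
        hi = idx + half + 1
        clo = np.maximum(lo, 0)
        chi = np.minimum(hi, shape)
        if np.any(clo >= chi):
            continue
        win = data[tuple(slice(a, b) for a, b in zip(clo, chi))]
        bwin = ball[tuple(slice(a - l, a - l + (b - a))
                          for a, b, l in zip(clo, chi, lo))]
        vals = win[bwin]
        if vals.size and float(vals.mean()) > b_threshold:
            n_with += 1
    return CellOverlap(n_cells_a=len(cells_a), n_cells_a_with_b=n_with,
                       fraction=n_with / len(cells_a), radius=radius_um)
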