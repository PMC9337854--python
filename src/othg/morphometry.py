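"""3D morphometry of ventricular-zone regions.

Volume is voxel count x voxel volume; surface area is measured on a
triangulated isosurface of the binary region (anisotropy-aware marching
cubes at level 0.5), which tracks curved surfaces far better than
voxel-face counting.  Thickness is the volume-to-area ratio V/A.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure as skmeasure
from skimage.filters import gaussian, threshold_multiotsu

from .core import ImageVolume, LabelVolume

__all__ = [
    "RegionMetrics",
    "OrganoidMorphometry",
    "segment_vz",
    "import_manual_masks",
    "measure_region",
    "measure_organoid",
]

log = logging.getLogger(__name__)

#: default minimum region volume retained by segment_vz (µm³), ~13 µm cube
DEFAULT_MIN_VOLUME_UM3 = 1e4


@dataclass
class RegionMetrics:
    label: int
    volume: float          # µm³
    surface_area: float    # µm²
    thickness: float       # µm, V/A
    centroid: Tuple[float, float, float]  # (z, y, x) µm
    clipped: bool = False  # region touches the volume boundary


@dataclass
class OrganoidMorphometry:
    total_vz_volume: float     # µm³
    total_vz_area: float       # µm²
    mean_thickness: float      # µm, mean of per-region V/A
    pooled_thickness: float    # µm, total V / total A (reported alternative)
    n_ventricles: int
    regions: List[RegionMetrics]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": r.label, "volume_um3": r.volume,
                 "surface_area_um2": r.surface_area, "thickness_um": r.thickness,
                 "centroid_z_um": r.centroid[0], "centroid_y_um": r.centroid[1],
                 "centroid_x_um": r.centroid[2], "clipped": r.clipped}
                for r in self.regions]
        return pd.DataFrame(rows)


def segment_vz(
    volume: ImageVolume,
    smoothing_sigma_um: float = 4.0,
    min_volume_um3: float = DEFAULT_MIN_VOLUME_UM3,
    closing_radius_um: float = 4.0,
) -> LabelVolume:
    """Segment the low-signal ventricular-zone band in a 3D stack.

    Pipeline: Gaussian smoothing -> three-class Otsu threshold selecting the
    intermediate-intensity band (cavity/exterior below, bright plate above)
    -> 3D morphological closing -> connected components -> minimum-size
    filter.  Deterministic for fixed parameters.
    """
    if volume.is_timelapse:
        raise ValueError("segment_vz expects a single-channel 3D volume")
    data = np.asarray(volume.data, dtype=float)
    vs = np.asarray(volume.voxel_size)

    sigma_vox = smoothing_sigma_um / vs
    smooth = gaussian(data, sigma=sigma_vox, preserve_range=True)

    if np.ptp(smooth) == 0:
        warnings.warn("blank volume: no VZ regions found")
        return LabelVolume(np.zeros(data.shape, dtype=np.int32), volume.voxel_size)

    try:
        t_low, t_high = threshold_multiotsu(smooth, classes=3)
    except ValueError:  # fewer than 3 grey levels
        warnings.warn("volume has too few intensity levels; no VZ regions found")
        return LabelVolume(np.zeros(data.shape, dtype=np.int32), volume.voxel_size)
    band = (smooth > t_low) & (smooth <= t_high)

    radius_vox = np.maximum(np.rint(closing_radius_um / vs).astype(int), 0)
    if radius_vox.max() > 0:
        struct = _anisotropic_ball(radius_vox)
        band = ndi.binary_closing(band, structure=struct)

    # the VZ band surrounds *cavities*; discard band components touching the
    # border-connected exterior (the organoid's outer rim falls in the same
    # intensity class but wraps the outside, not a cavity)
    band &= ~_touching_exterior(band, smooth <= t_low)

    labels, n = ndi.label(band)
    voxvol = float(np.prod(vs))
    if n:
        counts = np.bincount(labels.ravel())
        too_small = np.flatnonzero(counts * voxvol < min_volume_um3)
        kill = np.isin(labels, too_small[too_small > 0])
        labels[kill] = 0
        labels, n = ndi.label(labels > 0)
    if n == 0:
        warnings.warn("no VZ region survived size filtering")
    log.info("segment_vz: %d regions retained (min volume %.3g µm³)", n, min_volume_um3)
    return LabelVolume(labels.astype(np.int32), volume.voxel_size)


def _touching_exterior(band: np.ndarray, low: np.ndarray) -> np.ndarray:
    """Mask of band components adjacent to the border-connected low region."""
    low_labels, _ = ndi.label(low)
    border_ids = set()
    for face in (low_labels[0], low_labels[-1], low_labels[:, 0],
                 low_labels[:, -1], low_labels[:, :, 0], low_labels[:, :, -1]):
        border_ids |= set(np.unique(face))
    border_ids.discard(0)
    if not border_ids:
        return np.zeros_like(band)
    exterior = np.isin(low_labels, list(border_ids))
    near_ext = ndi.binary_dilation(exterior)
    band_labels, _ = ndi.label(band)
    bad = np.unique(band_labels[near_ext & band])
    bad = bad[bad > 0]
    return np.isin(band_labels, bad)


def _anisotropic_ball(radius_vox: np.ndarray) -> np.ndarray:
    rz, ry, rx = (int(max(r, 0)) for r in radius_vox)
    zz, yy, xx = np.ogrid[-rz:rz + 1, -ry:ry + 1, -rx:rx + 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = ((zz / max(rz, 1)) ** 2 + (yy / max(ry, 1)) ** 2 + (xx / max(rx, 1)) ** 2)
    return d <= 1.0


def import_manual_masks(masks: np.ndarray, voxel_size) -> LabelVolume:
    """Import externally drawn per-slice masks, relabelled by 3D connectivity."""
    arr = np.asarray(masks)
    labels, _ = ndi.label(arr > 0)
    return LabelVolume(labels.astype(np.int32), voxel_size, provenance="manual_import")


def measure_region(labels: LabelVolume, label: int) -> RegionMetrics:
    """Volume, triangulated surface area, V/A thickness and centroid of one region."""
    mask = labels.labels == label
    n_vox = int(mask.sum())
    if n_vox == 0:
        raise ValueError(f"label {label} not present")

    vs = labels.voxel_size
    volume = n_vox * labels.voxel_volume_um3()

    clipped = _touches_boundary(mask)
    area = _isosurface_area(mask, vs)

    centroid_vox = np.array(ndi.center_of_mass(mask))
    centroid = tuple(float(c) for c in centroid_vox * np.asarray(vs))

    metrics = RegionMetrics(label=int(label), volume=float(volume),
                            surface_area=area, thickness=float(volume / area),
                            centroid=centroid, clipped=clipped)
    if clipped:
        log.info("region %d touches the volume boundary; metrics flagged clipped", label)
    return metrics


#: pre-mesh smoothing in voxels; 0.9 cancels the stair-step area bias of
#: marching cubes on binary data (~+8% on spheres) to well under 2%
_MESH_SIGMA_VOX = 0.9


def _isosurface_area(mask: np.ndarray, voxel_size) -> float:
    """Area of the 0.5-level triangulated isosurface of a binary region.

    The mask is padded (so clipped regions still yield a closed surface)
    and lightly smoothed before meshing; if smoothing erases a very thin
    region the raw binary surface is used instead.
    """
    padded = np.pad(mask.astype(np.float32), 4)
    smooth = ndi.gaussian_filter(padded, _MESH_SIGMA_VOX)
    if smooth.max() <= 0.5:  # region thinner than the smoothing kernel
        smooth = padded
    verts, faces, _, _ = skmeasure.marching_cubes(smooth, level=0.5,
                                                  spacing=voxel_size)
    return float(skmeasure.mesh_surface_area(verts, faces))


def _touches_boundary(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any()
                or mask[:, 0].any() or mask[:, -1].any()
                or mask[:, :, 0].any() or mask[:, :, -1].any())


def measure_organoid(labels: LabelVolume) -> OrganoidMorphometry:
    """Aggregate per-region metrics into per-organoid totals.

    ``mean_thickness`` is the mean of per-region V/A ratios; the pooled
    total-V / total-A alternative is reported alongside.
    """
    ids = labels.label_ids
    regions = [measure_region(labels, int(i)) for i in ids]
    if not regions:
        return OrganoidMorphometry(0.0, 0.0, 0.0, 0.0, 0, [])
    tot_v = sum(r.volume for r in regions)
    tot_a = sum(r.surface_area for r in regions)
    mean_t = float(np.mean([r.thickness for r in regions]))
    return OrganoidMorphometry(total_vz_volume=tot_v, total_vz_area=tot_a,
                               mean_thickness=mean_t,
                               pooled_thickness=tot_v / tot_a,
                               n_ventricles=len(regions), regions=regions)
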