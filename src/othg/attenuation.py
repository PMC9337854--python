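"""Depth-resolved signal profiles and extinction-length estimation.

The detected n-photon signal at depth z follows
``S(z) ~ P(z)^n * exp(-n * z / l)`` where ``P`` is the surface power,
``n`` the photon order (3 for THG) and ``l`` the effective extinction
length.  ``fit_extinction`` performs ordinary least squares of
``ln(S / P^n)`` against z and inverts the slope as ``l = -n / slope``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ImageVolume, LabelVolume
from .stats import GroupSummary, TestResult, summarize, t_test_from_summary

__all__ = [
    "DepthProfile",
    "ExtinctionFit",
    "extract_depth_profile",
    "fit_extinction",
    "compare_extinction",
]

log = logging.getLogger(__name__)

SUMMARY_METHODS = ("mean_top_fraction", "mean", "median")


@dataclass
class DepthProfile:
    """Per-slice signal summary with the delivered surface power.

    Invariants: ``z`` strictly increasing, ``power > 0``, ``signal >= 0``
    slices that contributed fewer voxels than the configured minimum are
    excluded and counted in ``n_slices_excluded``.
    """

    z: np.ndarray            # µm per retained slice
    signal: np.ndarray       # summary intensity per slice
    power: np.ndarray        # surface power per slice, mW
    n_pixels_used: np.ndarray
    summary_method: str = "mean_top_fraction"
    n_slices_excluded: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        self.n_pixels_used = np.asarray(self.n_pixels_used, dtype=int)
        if not (self.z.shape == self.signal.shape == self.power.shape):
            raise ValueError("z, signal and power must have equal length")
        if self.z.size > 1 and not np.all(np.diff(self.z) > 0):
            raise ValueError("z must be strictly increasing")
        if np.any(self.power <= 0):
            raise ValueError("powers must be positive")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"z_um": self.z, "signal": self.signal,
                             "power_mW": self.power,
                             "n_pixels_used": self.n_pixels_used})


@dataclass
class ExtinctionFit:
    """Result of the semi-log extinction fit."""

    slope: float                 # 1/µm
    intercept: float
    extinction_length: float     # µm; +inf sentinel when non-physical
    r_squared: float
    z_range_used: Tuple[float, float]
    n_slices_used: int
    photon_order: int = 3
    non_physical: bool = False
    summary_method: Optional[str] = None

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["z_range_used"] = list(self.z_range_used)
        return d


def _interp_power(z: np.ndarray, power_log: pd.DataFrame) -> np.ndarray:
    """Linear interpolation of logged surface power; error outside the log range."""
    if not {"z_um", "power_mW"}.issubset(power_log.columns):
        raise ValueError("power log must have columns z_um, power_mW")
    tab = power_log.sort_values("z_um")
    zl = tab["z_um"].to_numpy(dtype=float)
    pl = tab["power_mW"].to_numpy(dtype=float)
    if np.any(pl <= 0):
        raise ValueError("logged powers must be positive")
    if z.min() < zl.min() - 1e-9 or z.max() > zl.max() + 1e-9:
        raise ValueError(
            f"stack depth range [{z.min():.1f}, {z.max():.1f}] µm extends outside "
            f"the power log range [{zl.min():.1f}, {zl.max():.1f}] µm; "
            "interpolation is only valid inside the logged range")
    return np.interp(z, zl, pl)


def _summarize_slice(values: np.ndarray, method: str, top_fraction: float) -> float:
    if method == "mean":
        return float(values.mean())
    if method == "median":
        return float(np.median(values))
    if method == "mean_top_fraction":
        k = max(1, int(math.ceil(top_fraction * values.size)))
        if k >= values.size:
            return float(values.mean())
        part = np.partition(values, values.size - k)[-k:]
        return float(part.mean())
    raise ValueError(f"unknown summary method {method!r}; choose from {SUMMARY_METHODS}")


def extract_depth_profile(
    volume: ImageVolume,
    power_log: pd.DataFrame,
    summary: str = "mean_top_fraction",
    top_fraction: float = 0.01,
    mask: Optional[LabelVolume] = None,
    min_voxels_per_slice: int = 1,
    background: float = 0.0,
) -> DepthProfile:
    """Summarise signal per z slice and attach interpolated surface power.

    With ``mask`` given only in-mask (label > 0) voxels contribute.  Slices
    with fewer than ``min_voxels_per_slice`` contributing voxels, or whose
    summary is <= 0 after background subtraction, are dropped (dropping is
    counted, never clamped).
    """
    if volume.is_timelapse:
        raise ValueError("extract_depth_profile expects a single 3D stack")
    data = volume.data
    if mask is not None:
        if mask.labels.shape != data.shape:
            raise ValueError("mask shape does not match volume shape")
        mask_arr = mask.labels > 0
    else:
        mask_arr = None

    depths = volume.depths_um()
    power = _interp_power(depths, power_log)

    zs: List[float] = []
    sig: List[float] = []
    pw: List[float] = []
    npx: List[int] = []
    excluded = 0
    for iz in range(data.shape[0]):
        sl = data[iz]
        if mask_arr is not None:
            vals = sl[mask_arr[iz]]
        else:
            vals = sl.ravel()
        if vals.size < min_voxels_per_slice or vals.size == 0:
            excluded += 1
            warnings.warn(f"slice {iz}: {vals.size} contributing voxels, excluded")
            continue
        s = _summarize_slice(np.asarray(vals, dtype=float), summary, top_fraction) - background
        if s <= 0:
            excluded += 1
            continue
        zs.append(depths[iz])
        sig.append(s)
        pw.append(power[iz])
        npx.append(vals.size)

    log.info("depth profile: %d slices retained, %d excluded", len(zs), excluded)
    return DepthProfile(np.array(zs), np.array(sig), np.array(pw), np.array(npx),
                        summary_method=summary, n_slices_excluded=excluded)


def fit_extinction(
    profile: DepthProfile,
    photon_order: int = 3,
    z_window: Optional[Tuple[float, float]] = None,
) -> ExtinctionFit:
    """OLS fit of ln(S / P^n) against depth; extinction length = -n / slope.

    A non-negative slope is flagged ``non_physical`` with the extinction
    length reported as ``+inf``.
    """
    z = profile.z
    s = profile.signal
    p = profile.power
    keep = s > 0
    if z_window is not None:
        z0, z1 = z_window
        keep &= (z >= z0) & (z <= z1)
    z, s, p = z[keep], s[keep], p[keep]
    if s.size == 0:
        raise ValueError("no positive signal")
    if s.size < 3:
        raise ValueError(f"need at least 3 usable slices, have {s.size}")

    y = np.log(s / p ** photon_order)
    slope, intercept = np.polyfit(z, y, 1)
    yhat = slope * z + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)

    if slope < 0:
        ell = -photon_order / slope
        non_physical = False
    else:
        ell = math.inf
        non_physical = True
    return ExtinctionFit(slope=float(slope), intercept=float(intercept),
                         extinction_length=float(ell), r_squared=r2,
                         z_range_used=(float(z.min()), float(z.max())),
                         n_slices_used=int(s.size), photon_order=photon_order,
                         non_physical=non_physical,
                         summary_method=profile.summary_method)


def compare_extinction(
    groups: Dict[str, Sequence[ExtinctionFit]],
    method: str = "pooled",
) -> Tuple[Dict[str, GroupSummary], Optional[TestResult]]:
    """Per-group mean ± SEM of extinction lengths plus a two-sample t-test.

    Requires >= 2 fits per group.  The t-test is computed for exactly two
    groups; with more, only summaries are returned.
    """
    summaries: Dict[str, GroupSummary] = {}
    for name, fits in groups.items():
        values = [f.extinction_length for f in fits]
        if len(values) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 fits (no dispersion)")
        if any(not math.isfinite(v) for v in values):
            raise ValueError(f"group {name!r} contains non-physical (infinite) fits")
        summaries[name] = summarize(values, name)

    test = None
    if len(summaries) == 2:
        a, b = summaries.values()
        test = t_test_from_summary(a, b, method=method)
    return summaries, test
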