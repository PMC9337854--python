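"""Soma detection, track linking and migration metrics.

Detection is multiscale Laplacian-of-Gaussian blob finding with 3D
non-maximum suppression and intensity-weighted sub-voxel refinement,
anisotropy-corrected (sigmas specified in µm).  Linking solves a globally
optimal one-to-one assignment per frame pair (Hungarian algorithm on
squared displacement, gated at ``max_step``), with optional single-frame
gap closing.  All geometry is in µm.

Metric conventions: ``straightness = displacement / path_length``;
``mean_speed = path_length / duration`` (track-speed convention, not
net-displacement speed); instantaneous speed is assigned to the step's
ending timepoint.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

from .core import ImageVolume
from .stats import GroupSummary, TestResult, summarize, t_test_from_summary

__all__ = [
    "Track",
    "TrackMetrics",
    "detect_spots",
    "link_tracks",
    "compute_metrics",
    "metrics_table",
    "tracks_from_table",
    "summarize_groups",
]

log = logging.getLogger(__name__)

DEFAULT_MIN_TRACK_FRAMES = 4  # short fragments inflate straightness


@dataclass
class Track:
    """One cell trajectory: ordered (t, z, y, x) points plus any closed gaps."""

    track_id: int
    t_min: np.ndarray       # minutes, strictly increasing
    points_um: np.ndarray   # (n, 3) µm
    gaps: List[int] = field(default_factory=list)  # skipped frame indices

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.points_um = np.asarray(self.points_um, dtype=float)
        if len(self.t_min) != len(self.points_um):
            raise ValueError("t and points must have equal length")
        if len(self.t_min) < 2:
            raise ValueError("a track needs at least 2 points")
        if not np.all(np.diff(self.t_min) > 0):
            raise ValueError("track timepoints must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_min)


@dataclass
class TrackMetrics:
    track_id: int
    displacement: float          # µm, straight-line start -> end
    path_length: float           # µm
    duration: float              # hours
    mean_speed: float            # µm/hr, path_length / duration
    straightness: float          # displacement / path_length; NaN if stationary
    instantaneous_speed: np.ndarray  # µm/hr per step (assigned to step end)


# ---------------------------------------------------------------------------
# detection

def detect_spots(
    volume: ImageVolume,
    sigma_range_um: Tuple[float, float] = (2.0, 5.0),
    threshold_rel: float = 0.2,
    n_scales: int = 3,
) -> pd.DataFrame:
    """Detect bright somata in a 3D stack or 4D time-lapse.

    Scale-normalised LoG responses are maximised over ``n_scales`` sigmas
    spanning ``sigma_range_um``; local maxima above ``threshold_rel`` times
    the global response maximum are kept (so doubling the intensity leaves
    detections unchanged) and refined to sub-voxel centroids.

    Returns a table with columns
    ``frame, t_min, z_um, y_um, x_um, intensity, spot_id``.
    """
    frames = volume.data[None] if not volume.is_timelapse else volume.data
    dt = volume.frame_interval or 0.0
    vs = np.asarray(volume.voxel_size, dtype=float)
    sigmas_um = np.linspace(sigma_range_um[0], sigma_range_um[1], n_scales)

    rows = []
    spot_id = 0
    for f, frame in enumerate(frames):
        frame = np.asarray(frame, dtype=np.float32)
        if frame.max() <= 0:
            continue
        best = None
        for s_um in sigmas_um:
            sig_vox = s_um / vs
            resp = -(s_um ** 2) * ndi.gaussian_laplace(frame, sigma=sig_vox)
            best = resp if best is None else np.maximum(best, resp)
        if best.max() <= 0:
            continue
        thr = threshold_rel * best.max()
        # non-maximum suppression over roughly one soma radius
        size = np.maximum((sigmas_um[0] / vs).astype(int) * 2 + 1, 3)
        local_max = (best == ndi.maximum_filter(best, size=size)) & (best > thr)
        for idx in np.argwhere(local_max):
            center = _refine_centroid(frame, idx, vs, sigmas_um[0])
            pos = center * vs
            rows.append((f, f * dt, pos[0], pos[1], pos[2],
                         float(frame[tuple(idx)]), spot_id))
            spot_id += 1
    return pd.DataFrame(rows, columns=["frame", "t_min", "z_um", "y_um",
                                       "x_um", "intensity", "spot_id"])


def _refine_centroid(frame: np.ndarray, idx: np.ndarray, vs: np.ndarray,
                     sigma_um: float) -> np.ndarray:
    """Background-subtracted intensity-weighted centroid in a local window."""
    half = np.maximum(np.ceil(1.5 * sigma_um / vs).astype(int), 1)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, frame.shape)
    win = np.asarray(frame[tuple(slice(a, b) for a, b in zip(lo, hi))], dtype=float)
    # squared weights suppress the pull of background gradients on the centroid
    w = (win - win.min()) ** 2
    tot = w.sum()
    if tot == 0:
        return idx.astype(float)
    grids = np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij")
    return np.array([float((g * w).sum() / tot) for g in grids])


# ---------------------------------------------------------------------------
# linking

def link_tracks(
    spots: pd.DataFrame,
    max_step_um: float = 20.0,
    max_gap_frames: int = 0,
    min_track_frames: int = DEFAULT_MIN_TRACK_FRAMES,
) -> List[Track]:
    """Link per-frame spots into tracks.

    Frame pairs are linked by a globally optimal one-to-one assignment
    minimising summed squared displacement, with candidate pairs gated at
    ``max_step_um``.  With ``max_gap_frames >= 1``, track ends are joined
    to later track starts across skipped frames (gap recorded on the
    track).  Tracks spanning fewer than ``min_track_frames`` frames are
    discarded, with the count reported in the log.
    """
    if spots.empty:
        return []
    cols = ["z_um", "y_um", "x_um"]
    frames = sorted(spots["frame"].unique())
    by_frame = {f: spots[spots["frame"] == f].reset_index(drop=True) for f in frames}

    # active chains: list of dicts with frames, times, points, gaps
    chains: List[dict] = []
    open_by_tail: Dict[int, List[int]] = {}  # frame -> chain indices ending there

    def new_chain(f, row):
        chains.append({"frames": [f], "t": [row["t_min"]],
                       "pts": [np.array([row[c] for c in cols])], "gaps": []})
        open_by_tail.setdefault(f, []).append(len(chains) - 1)

    for row in by_frame[frames[0]].itertuples(index=False):
        new_chain(frames[0], row._asdict())

    n_ambiguous = 0
    for f in frames[1:]:
        cur = by_frame[f]
        # chains whose tail is within the allowed (gap-inclusive) frame span;
        # empty frames count as gaps, so gate on true frame numbers
        cand_chains: List[int] = []
        for src in range(f - 1 - max_gap_frames, f):
            cand_chains += [ci for ci in open_by_tail.get(src, [])
                            if chains[ci]["frames"][-1] == src]
        assigned_rows = set()
        if cand_chains and len(cur):
            tails = np.array([chains[ci]["pts"][-1] for ci in cand_chains])
            pts = cur[cols].to_numpy()
            d = np.linalg.norm(tails[:, None, :] - pts[None, :, :], axis=2)
            gap_span = np.array([f - chains[ci]["frames"][-1] for ci in cand_chains])
            gate = max_step_um * gap_span[:, None]
            big = 1e12
            cost = np.where(d <= gate, d ** 2, big)
            ri, cj = linear_sum_assignment(cost)
            for i, j in zip(ri, cj):
                if cost[i, j] >= big:
                    continue
                ci = cand_chains[i]
                row = cur.iloc[j]
                skipped = list(range(chains[ci]["frames"][-1] + 1, f))
                chains[ci]["gaps"] += skipped
                chains[ci]["frames"].append(f)
                chains[ci]["t"].append(row["t_min"])
                chains[ci]["pts"].append(row[cols].to_numpy(dtype=float))
                open_by_tail.setdefault(f, []).append(ci)
                assigned_rows.add(j)
            # crude ambiguity measure: competing candidates inside the gate
            n_ambiguous += int(np.sum((d <= gate).sum(axis=0) > 1))
        for j in range(len(cur)):
            if j not in assigned_rows:
                new_chain(f, cur.iloc[j].to_dict())

    tracks: List[Track] = []
    n_discarded = 0
    tid = 0
    for ch in chains:
        span = ch["frames"][-1] - ch["frames"][0] + 1
        if len(ch["frames"]) < 2 or span < min_track_frames:
            n_discarded += 1
            continue
        tracks.append(Track(track_id=tid, t_min=np.array(ch["t"]),
                            points_um=np.array(ch["pts"]), gaps=ch["gaps"]))
        tid += 1
    log.info("link_tracks: %d tracks, %d fragments discarded (<%d frames), "
             "%d ambiguous candidate links", len(tracks), n_discarded,
             min_track_frames, n_ambiguous)
    return tracks


# ---------------------------------------------------------------------------
# metrics

def compute_metrics(track: Track) -> TrackMetrics:
    """Displacement, path length, duration, speeds and straightness of a track.

    A stationary track (zero path length) has undefined straightness,
    reported as NaN — never 0 or 1.
    """
    pts = track.points_um
    steps = np.diff(pts, axis=0)
    step_len = np.linalg.norm(steps, axis=1)
    dt_hr = np.diff(track.t_min) / 60.0
    path = float(step_len.sum())
    disp = float(np.linalg.norm(pts[-1] - pts[0]))
    duration = float((track.t_min[-1] - track.t_min[0]) / 60.0)
    straight = disp / path if path > 0 else math.nan
    return TrackMetrics(track_id=track.track_id, displacement=disp,
                        path_length=path, duration=duration,
                        mean_speed=path / duration,
                        straightness=straight,
                        instantaneous_speed=step_len / dt_hr)


def metrics_table(tracks: Sequence[Track]) -> pd.DataFrame:
    rows = []
    for tr in tracks:
        m = compute_metrics(tr)
        rows.append({"track_id": m.track_id, "displacement_um": m.displacement,
                     "path_length_um": m.path_length, "duration_hr": m.duration,
                     "mean_speed_um_hr": m.mean_speed,
                     "straightness": m.straightness})
    return pd.DataFrame(rows)


def tracks_from_table(table: pd.DataFrame) -> List[Track]:
    """Build Track objects from a long-format table (track_id, t_min, z/y/x_um)."""
    out = []
    for tid, grp in table.groupby("track_id"):
        grp = grp.sort_values("t_min")
        if len(grp) < 2:
            continue
        out.append(Track(track_id=int(tid), t_min=grp["t_min"].to_numpy(),
                         points_um=grp[["z_um", "y_um", "x_um"]].to_numpy()))
    return out


def summarize_groups(
    metrics: Dict[str, Sequence[TrackMetrics]],
    which: Sequence[str] = ("displacement", "mean_speed", "straightness"),
    method: str = "pooled",
) -> Tuple[Dict[str, Dict[str, GroupSummary]], Dict[str, TestResult]]:
    """Per-group mean/SEM/90% CI per metric, plus two-sample t-tests.

    Returns ``(summaries[metric][group], tests[metric])``; tests are only
    produced when exactly two groups are given.  NaN metric values
    (undefined straightness) are excluded per metric.
    """
    summaries: Dict[str, Dict[str, GroupSummary]] = {}
    tests: Dict[str, TestResult] = {}
    for metric in which:
        per_group: Dict[str, GroupSummary] = {}
        for gname, ms in metrics.items():
            vals = [getattr(m, metric) for m in ms]
            vals = [v for v in vals if not math.isnan(v)]
            if len(vals) < 2:
                raise ValueError(f"group {gname!r} has <2 tracks for {metric}")
            per_group[gname] = summarize(vals, f"{gname}:{metric}")
        summaries[metric] = per_group
        if len(per_group) == 2:
            a, b = per_group.values()
            tests[metric] = t_test_from_summary(a, b, method=method)
    return summaries, tests
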