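"""Synthetic organoid phantoms with known ground truth.

Generates 3D stacks that mimic the structure the analysis modules assume:
a bright cortical-plate (CP) ball containing dark ventricle cavities, each
wrapped in a dimmer ventricular-zone (VZ) shell, with bright somata
scattered through the CP.  Depth attenuation follows the n-photon
convention ``scale(z) = (P(z)/P(0))^n * exp(-n z / l)`` and noise is
Poisson shot noise followed by additive Gaussian read noise.

Cell motion is a persistent random walk: each step direction is drawn
from a von Mises-Fisher distribution concentrated (kappa) around the
previous direction, optionally blended with an outward radial unit vector
(radial_bias in [0, 1]); step lengths are ``max(0, N(speed*dt, sd*dt))``.
Ground truth (labels, tracks, attenuation length) is returned alongside
every rendered volume.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import ImageVolume, LabelVolume

__all__ = [
    "PhantomSpec",
    "OpticsSpec",
    "MotionSpec",
    "generate_phantom",
    "apply_attenuation",
    "add_noise",
    "generate_timelapse",
    "simulate_tracks",
    "calibrate_straightness",
    "kappa_for_straightness",
]


# ---------------------------------------------------------------------------
# specs

@dataclass
class PhantomSpec:
    """Geometry and contrast of a static organoid phantom."""

    organoid_radius: float = 120.0            # µm
    n_ventricles: int = 1
    ventricle_radius_range: Tuple[float, float] = (30.0, 40.0)  # µm
    vz_shell_thickness: float = 20.0          # µm
    cp_soma_density: float = 2e4              # somata per mm³
    soma_radius: float = 5.0                  # µm
    vz_intensity: float = 0.3
    cp_intensity: float = 1.0
    soma_intensity: float = 4.0
    cavity_intensity: float = 0.05
    voxel_size: Tuple[float, float, float] = (2.0, 2.0, 2.0)
    margin: float = 6.0                       # empty border around the organoid, µm

    def __post_init__(self) -> None:
        if self.n_ventricles < 0:
            raise ValueError("n_ventricles must be >= 0")
        r_lo, r_hi = self.ventricle_radius_range
        if not (0 < r_lo <= r_hi):
            raise ValueError("ventricle_radius_range must be positive and ordered")
        if r_hi + self.vz_shell_thickness >= self.organoid_radius:
            raise ValueError(
                "ventricle radius + VZ shell thickness must fit inside the organoid")
        for name in ("vz_intensity", "cp_intensity", "soma_intensity",
                     "cavity_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def to_yaml(self, path) -> None:
        _dump_yaml(self, path)

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        return _load_yaml(cls, path)


@dataclass
class OpticsSpec:
    """Depth attenuation and noise of the simulated acquisition."""

    extinction_length: float = math.inf       # µm; inf = no attenuation
    surface_power_by_depth: Optional[pd.DataFrame] = None  # columns z_um, power_mW
    photon_order: int = 3
    shot_noise_scale: float = 0.0             # expected photons per signal unit; 0 = off
    read_noise_sd: float = 0.0                # additive Gaussian, signal units

    def __post_init__(self) -> None:
        if self.extinction_length <= 0:
            raise ValueError("extinction_length must be positive")
        if self.photon_order < 1:
            raise ValueError("photon_order must be >= 1")
        if self.surface_power_by_depth is not None:
            p = self.surface_power_by_depth
            if not {"z_um", "power_mW"}.issubset(p.columns):
                raise ValueError("power table needs columns z_um, power_mW")
            if (p["power_mW"] <= 0).any():
                raise ValueError("powers must be positive")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if self.surface_power_by_depth is not None:
            d["surface_power_by_depth"] = self.surface_power_by_depth.to_dict("list")
        d["extinction_length"] = (None if math.isinf(self.extinction_length)
                                  else self.extinction_length)
        with open(path, "w") as fh:
            yaml.safe_dump({type(self).__name__: d}, fh)

    @classmethod
    def from_yaml(cls, path) -> "OpticsSpec":
        with open(path) as fh:
            d = yaml.safe_load(fh)[cls.__name__]
        if d.get("surface_power_by_depth") is not None:
            d["surface_power_by_depth"] = pd.DataFrame(d["surface_power_by_depth"])
        if d.get("extinction_length") is None:
            d["extinction_length"] = math.inf
        return cls(**d)


@dataclass
class MotionSpec:
    """Persistent-random-walk parameters for migrating cells."""

    n_cells: int = 20
    frame_interval: float = 20.0              # minutes
    n_frames: int = 16
    mean_speed: float = 23.0                  # µm/hr
    speed_sd: float = 0.0                     # µm/hr
    turning_concentration: float = math.inf   # kappa >= 0; inf = no turning
    radial_bias: float = 0.0                  # in [0, 1]

    def __post_init__(self) -> None:
        if self.mean_speed < 0 or self.speed_sd < 0:
            raise ValueError("speeds must be non-negative")
        if self.turning_concentration < 0:
            raise ValueError("turning_concentration (kappa) must be >= 0")
        if not 0 <= self.radial_bias <= 1:
            raise ValueError("radial_bias must lie in [0, 1]")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.n_frames < 2:
            raise ValueError("need at least 2 frames")

    @property
    def dt_hr(self) -> float:
        return self.frame_interval / 60.0

    def to_yaml(self, path) -> None:
        _dump_yaml(self, path)

    @classmethod
    def from_yaml(cls, path) -> "MotionSpec":
        return _load_yaml(cls, path)


def _dump_yaml(spec, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({type(spec).__name__: _jsonable(asdict(spec))}, fh)


def _jsonable(d):
    out = {}
    for k, v in d.items():
        if isinstance(v, tuple):
            v = list(v)
        if isinstance(v, float) and math.isinf(v):
            v = None
        out[k] = v
    return out


def _load_yaml(cls, path):
    with open(path) as fh:
        d = yaml.safe_load(fh)[cls.__name__]
    for k, v in list(d.items()):
        if v is None:
            d[k] = math.inf
        elif isinstance(v, list):
            d[k] = tuple(v)
    return cls(**d)


# ---------------------------------------------------------------------------
# static phantom

def _ventricle_layout(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Deterministic ventricle centres (µm, relative to organoid centre) and radii.

    Geometry is intentionally non-random so that two seeds share identical
    ground-truth labels; only soma placement and noise are randomised.
    """
    n = spec.n_ventricles
    if n == 0:
        return np.zeros((0, 3)), np.zeros(0)
    r_lo, r_hi = spec.ventricle_radius_range
    radii = np.linspace(r_lo, r_hi, n)
    if n == 1:
        return np.zeros((1, 3)), radii

    # Fibonacci-sphere directions at a fixed fraction of the organoid radius
    k = np.arange(n)
    phi = math.pi * (3.0 - math.sqrt(5.0)) * k
    cosl = 1 - 2 * (k + 0.5) / n
    sinl = np.sqrt(1 - cosl ** 2)
    dirs = np.stack([cosl, sinl * np.cos(phi), sinl * np.sin(phi)], axis=1)
    dist = 0.55 * spec.organoid_radius
    centers = dirs * dist

    outer = radii + spec.vz_shell_thickness
    if np.any(dist + outer >= spec.organoid_radius):
        raise ValueError("ventricles do not fit inside the organoid; reduce "
                         "radii, shell thickness or n_ventricles")
    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centers[i] - centers[j]) <= outer[i] + outer[j]:
                raise ValueError(
                    f"ventricle shells {i} and {j} overlap; the requested "
                    "geometry cannot fit inside the organoid")
    return centers, radii


def generate_phantom(spec: PhantomSpec, seed: int = 0) -> Tuple[ImageVolume, LabelVolume]:
    """Render a noiseless organoid phantom and its ground-truth VZ labels.

    Contrast ordering: cavity < VZ < CP, with bright somata in the CP.
    Each VZ shell voxel carries its ventricle's (1-based) label.  Identical
    seeds give identical output; ventricle geometry is deterministic.
    """
    rng = np.random.default_rng(seed)
    vs = np.asarray(spec.voxel_size, dtype=float)
    extent = 2.0 * (spec.organoid_radius + spec.margin)
    shape = tuple(int(math.ceil(extent / v)) for v in vs)
    center = (np.asarray(shape) - 1) / 2.0 * vs  # µm

    coords = [np.arange(s) * v - c for s, v, c in zip(shape, vs, center)]
    zz = coords[0][:, None, None]
    yy = coords[1][None, :, None]
    xx = coords[2][None, None, :]
    d2_org = zz ** 2 + yy ** 2 + xx ** 2

    data = np.zeros(shape, dtype=np.float32)
    inside = d2_org <= spec.organoid_radius ** 2
    data[inside] = spec.cp_intensity

    labels = np.zeros(shape, dtype=np.int32)
    centers, radii = _ventricle_layout(spec)
    for i, (c, r) in enumerate(zip(centers, radii), start=1):
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        shell = (d2 <= (r + spec.vz_shell_thickness) ** 2) & (d2 > r ** 2)
        cavity = d2 <= r ** 2
        data[shell] = spec.vz_intensity
        data[cavity] = spec.cavity_intensity
        labels[shell] = i

    # somata: homogeneous Poisson process over the CP compartment
    cp_mask = inside & (labels == 0)
    for i, (c, r) in enumerate(zip(centers, radii), start=1):
        d2 = (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2
        cp_mask &= d2 > (r + spec.vz_shell_thickness) ** 2
    cp_volume_mm3 = cp_mask.sum() * float(np.prod(vs)) * 1e-9
    n_somata = rng.poisson(spec.cp_soma_density * cp_volume_mm3)
    placed = 0
    while placed < n_somata:
        p = rng.uniform(-spec.organoid_radius, spec.organoid_radius, size=3)
        idx = np.rint((p + center) / vs).astype(int)
        if np.all(idx >= 0) and np.all(idx < np.asarray(shape)) and cp_mask[tuple(idx)]:
            _render_blob(data, p + center, spec.soma_radius / 2.0,
                         spec.soma_intensity, vs)
            placed += 1

    vol = ImageVolume(data, tuple(vs), channel="THG")
    lab = LabelVolume(labels, tuple(vs))
    return vol, lab


def _render_blob(data: np.ndarray, center_um: np.ndarray, sigma_um: float,
                 peak: float, voxel_size: np.ndarray) -> None:
    """Paint a Gaussian blob (max-composited) into ``data`` in place."""
    vs = np.asarray(voxel_size, dtype=float)
    c_vox = np.asarray(center_um) / vs
    half = np.ceil(3.0 * sigma_um / vs).astype(int)
    lo = np.maximum(np.floor(c_vox).astype(int) - half, 0)
    hi = np.minimum(np.floor(c_vox).astype(int) + half + 1, data.shape)
    if np.any(lo >= hi):
        return
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    grids = np.meshgrid(*[(np.arange(a, b) * v - cu)
                          for a, b, v, cu in zip(lo, hi, vs, center_um)],
                        indexing="ij")
    d2 = sum(g ** 2 for g in grids)
    blob = peak * np.exp(-0.5 * d2 / sigma_um ** 2)
    np.maximum(data[sl], blob, out=data[sl])


# ---------------------------------------------------------------------------
# optics

def _depth_scale(depths: np.ndarray, optics: OpticsSpec) -> np.ndarray:
    """Per-slice multiplicative attenuation factor (P(z)/P(0))^n * exp(-n z / l)."""
    n = optics.photon_order
    if optics.surface_power_by_depth is not None:
        from .attenuation import _interp_power
        power = _interp_power(depths, optics.surface_power_by_depth)
        p0 = _interp_power(np.array([0.0]), optics.surface_power_by_depth)[0]
        pratio = (power / p0) ** n
    else:
        pratio = np.ones_like(depths)
    if math.isinf(optics.extinction_length):
        decay = np.ones_like(depths)
    else:
        decay = np.exp(-n * depths / optics.extinction_length)
    return pratio * decay


def apply_attenuation(volume: ImageVolume, optics: OpticsSpec) -> ImageVolume:
    """Scale each slice by the depth-dependent n-photon attenuation factor.

    Noiseless and invertible given the optics.  With an unlogged depth in
    the power table's range an error is raised rather than extrapolating.
    """
    scale = _depth_scale(volume.depths_um(), optics)
    if volume.is_timelapse:
        data = volume.data * scale[None, :, None, None]
    else:
        data = volume.data * scale[:, None, None]
    return volume.with_data(data.astype(np.float32))


def add_noise(volume: ImageVolume, optics: OpticsSpec, seed: int = 0) -> ImageVolume:
    """Poisson shot noise on expected photon counts, then Gaussian read noise.

    ``shot_noise_scale`` converts signal units to expected photons; either
    noise source is skipped when its parameter is zero.  Output is clipped
    at zero (detected intensities are non-negative).
    """
    rng = np.random.default_rng(seed)
    data = np.asarray(volume.data, dtype=np.float64)
    if optics.shot_noise_scale > 0:
        data = rng.poisson(np.clip(data, 0, None) * optics.shot_noise_scale)
        data = data / optics.shot_noise_scale
    if optics.read_noise_sd > 0:
        data = data + rng.normal(0.0, optics.read_noise_sd, size=data.shape)
    return volume.with_data(np.clip(data, 0, None).astype(np.float32))


# ---------------------------------------------------------------------------
# motion

def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def _sample_vmf(mu: np.ndarray, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw a unit vector from a 3D von Mises-Fisher distribution around mu."""
    if kappa == 0:
        return _unit(rng.normal(size=3))
    if kappa > 1e8 or math.isinf(kappa):
        return mu
    # Ulrich/Wood simulation, closed form for S^2
    u = rng.uniform()
    w = 1.0 + math.log(u + (1.0 - u) * math.exp(-2.0 * kappa)) / kappa
    w = min(1.0, max(-1.0, w))
    # orthonormal basis perpendicular to mu
    a = np.array([1.0, 0.0, 0.0]) if abs(mu[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = _unit(np.cross(mu, a))
    e2 = np.cross(mu, e1)
    phi = rng.uniform(0.0, 2.0 * math.pi)
    s = math.sqrt(max(0.0, 1.0 - w * w))
    return w * mu + s * (math.cos(phi) * e1 + math.sin(phi) * e2)


def simulate_tracks(
    motion: MotionSpec,
    seed: int = 0,
    starts: Optional[np.ndarray] = None,
    center: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Simulate persistent-random-walk trajectories.

    Returns positions of shape ``(n_cells, n_frames, 3)`` in µm (z, y, x).
    ``center`` is the origin of the outward radial bias; when omitted,
    radial bias (if any) points away from the coordinate origin.  Initial
    directions are radial when a centre is known, otherwise uniform.
    """
    rng = np.random.default_rng(seed)
    n, m = motion.n_cells, motion.n_frames
    if starts is None:
        starts = np.zeros((n, 3))
    starts = np.asarray(starts, dtype=float)
    if center is None:
        center = np.zeros(3)
    center = np.asarray(center, dtype=float)

    dt = motion.dt_hr
    kappa = motion.turning_concentration
    b = motion.radial_bias
    pos = np.empty((n, m, 3))
    for i in range(n):
        p = starts[i].copy()
        radial = _unit(p - center)
        if np.linalg.norm(radial) == 0:
            radial = _unit(rng.normal(size=3))
        d = radial if (b > 0 or math.isinf(kappa)) else _unit(rng.normal(size=3))
        pos[i, 0] = p
        for k in range(1, m):
            d = _sample_vmf(d, kappa, rng)
            if b > 0:
                radial = _unit(p - center)
                d = _unit((1.0 - b) * d + b * radial)
            step = motion.mean_speed * dt
            if motion.speed_sd > 0:
                step = max(0.0, rng.normal(step, motion.speed_sd * dt))
            p = p + step * d
            pos[i, k] = p
    return pos


def _track_table(positions: np.ndarray, motion: MotionSpec,
                 last_frame: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Assemble the ground-truth track table from simulated positions."""
    n, m, _ = positions.shape
    if last_frame is None:
        last_frame = np.full(n, m - 1)
    rows = []
    for i in range(n):
        trunc = last_frame[i] < m - 1
        for k in range(int(last_frame[i]) + 1):
            rows.append((i, k, k * motion.frame_interval,
                         positions[i, k, 0], positions[i, k, 1],
                         positions[i, k, 2], trunc))
    return pd.DataFrame(rows, columns=["track_id", "frame", "t_min",
                                       "z_um", "y_um", "x_um", "truncated"])


def generate_timelapse(
    spec: PhantomSpec,
    motion: MotionSpec,
    optics: OpticsSpec,
    seed: int = 0,
) -> Tuple[ImageVolume, pd.DataFrame]:
    """Render a 4D movie of migrating somata plus the exact ground-truth tracks.

    Cells are seeded inside VZ shells (cycling over ventricles) and migrate
    per the persistent-random-walk model, with the radial bias pointing away
    from the parent ventricle's centre.  A cell that leaves the rendered
    volume has its track truncated at the last in-bounds frame and flagged
    ``truncated`` — never silently dropped.  The movie passes through the
    attenuation and noise models in ``optics``.
    """
    rng = np.random.default_rng(seed)
    base_vol, labels = generate_phantom(spec, seed=seed)
    vs = np.asarray(spec.voxel_size, dtype=float)
    shape = base_vol.data.shape
    vol_center = (np.asarray(shape) - 1) / 2.0 * vs

    centers, radii = _ventricle_layout(spec)
    if len(centers) == 0:
        raise ValueError("generate_timelapse needs at least one ventricle "
                         "to seed cells in a VZ shell")
    centers_abs = centers + vol_center

    starts = np.empty((motion.n_cells, 3))
    parent = np.empty(motion.n_cells, dtype=int)
    for i in range(motion.n_cells):
        j = i % len(centers)
        parent[i] = j
        r = radii[j]
        # uniform in the spherical VZ shell annulus
        while True:
            u = rng.uniform(-1, 1, size=3)
            nrm = np.linalg.norm(u)
            if 0 < nrm <= 1:
                rad = (r ** 3 + rng.uniform() *
                       ((r + spec.vz_shell_thickness) ** 3 - r ** 3)) ** (1 / 3)
                starts[i] = centers_abs[j] + u / nrm * rad
                break

    # per-cell simulation with per-cell radial centre
    positions = np.empty((motion.n_cells, motion.n_frames, 3))
    for i in range(motion.n_cells):
        one = MotionSpec(**{**asdict(motion), "n_cells": 1})
        positions[i] = simulate_tracks(one, seed=int(rng.integers(2 ** 31)),
                                       starts=starts[i][None],
                                       center=centers_abs[parent[i]])[0]

    upper = (np.asarray(shape) - 1) * vs
    in_bounds = np.all((positions >= 0) & (positions <= upper), axis=2)
    last_frame = np.empty(motion.n_cells, dtype=int)
    for i in range(motion.n_cells):
        bad = np.flatnonzero(~in_bounds[i])
        last_frame[i] = (bad[0] - 1) if bad.size else motion.n_frames - 1
    n_trunc = int(np.sum(last_frame < motion.n_frames - 1))
    if n_trunc:
        warnings.warn(f"{n_trunc} track(s) left the volume and were truncated")

    frames = np.empty((motion.n_frames, *shape), dtype=np.float32)
    for k in range(motion.n_frames):
        frame = base_vol.data.copy()
        for i in range(motion.n_cells):
            if k <= last_frame[i]:
                _render_blob(frame, positions[i, k], spec.soma_radius / 2.0,
                             spec.soma_intensity, vs)
        frames[k] = frame

    movie = ImageVolume(frames, tuple(vs), frame_interval=motion.frame_interval,
                        channel="THG")
    movie = apply_attenuation(movie, optics)
    if optics.shot_noise_scale > 0 or optics.read_noise_sd > 0:
        movie = add_noise(movie, optics, seed=int(rng.integers(2 ** 31)))

    tracks = _track_table(positions, motion, last_frame)
    return movie, tracks


# ---------------------------------------------------------------------------
# straightness calibration

def calibrate_straightness(
    motion: MotionSpec,
    kappa_grid: Sequence[float],
    n_tracks: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Map turning concentration kappa to expected track straightness.

    Pure simulation (no rendering): for each kappa the motion spec is
    simulated for ``n_tracks`` walks and the mean straightness — computed
    by the tracking module's metric code on the ground-truth points — is
    tabulated.  Reproducible under ``seed``.
    """
    from .tracking import Track, compute_metrics

    if n_tracks < 100:
        warnings.warn(f"n_tracks={n_tracks} < 100: calibration will be unstable")
    rows = []
    for j, kappa in enumerate(kappa_grid):
        m = MotionSpec(**{**asdict(motion),
                          "n_cells": n_tracks,
                          "turning_concentration": float(kappa)})
        # start off-centre so a radial bias (if any) is well defined
        starts = np.tile(np.array([0.0, 0.0, 50.0]), (n_tracks, 1))
        pos = simulate_tracks(m, seed=seed + 7919 * j, starts=starts,
                              center=np.zeros(3))
        vals = []
        for i in range(n_tracks):
            t = np.arange(m.n_frames) * m.frame_interval
            track = Track(track_id=i, t_min=t, points_um=pos[i])
            met = compute_metrics(track)
            if not math.isnan(met.straightness):
                vals.append(met.straightness)
        rows.append((float(kappa), float(np.mean(vals)), len(vals)))
    return pd.DataFrame(rows, columns=["kappa", "straightness", "n_tracks"])


def kappa_for_straightness(
    target: float,
    motion: MotionSpec,
    kappa_grid: Optional[Sequence[float]] = None,
    n_tracks: int = 500,
    seed: int = 0,
) -> float:
    """Invert the calibration table to find kappa matching a target straightness."""
    if kappa_grid is None:
        kappa_grid = [0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 64.0, 128.0]

    def _invert(grid, n, sd):
        table = calibrate_straightness(motion, grid, n_tracks=n, seed=sd)
        s = table["straightness"].to_numpy()
        k = table["kappa"].to_numpy()
        order = np.argsort(s)
        return float(np.interp(target, s[order], k[order]))

    # coarse pass, then a dense local grid to kill interpolation bias
    k0 = _invert(kappa_grid, n_tracks, seed)
    local = np.linspace(max(0.0, 0.6 * k0), 1.5 * k0 + 1e-6, 7)
    return _invert(local, 2 * n_tracks, seed + 1)
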