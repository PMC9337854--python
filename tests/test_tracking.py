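import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from pytest import approx
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from othg.core import ImageVolume
from othg.stats import GroupSummary
from othg.synthetic import MotionSpec, OpticsSpec, PhantomSpec, generate_timelapse
from othg.tracking import (Track, compute_metrics, detect_spots, link_tracks,
                           metrics_table, summarize_groups, tracks_from_table)


def make_track(points, dt_min=20.0):
    pts = np.asarray(points, dtype=float)
    return Track(track_id=0, t_min=np.arange(len(pts)) * dt_min, points_um=pts)


class TestComputeMetrics:
    def test_straight_track(self):
        pts = [(0, 0, 8 * i) for i in range(11)]
        m = compute_metrics(make_track(pts))
        assert m.displacement == approx(80.0)
        assert m.path_length == approx(80.0)
        assert m.straightness == approx(1.0)
        assert m.mean_speed == approx(24.0)
        assert np.allclose(m.instantaneous_speed, 24.0)

    def test_3_4_5_hand_computed(self):
        pts = [(0, 0, 0), (0, 3, 4), (5, 3, 4)]
        m = compute_metrics(make_track(pts))
        assert m.path_length == approx(10.0)
        assert m.displacement == approx(math.sqrt(50))
        assert m.straightness == approx(math.sqrt(50) / 10)
        assert m.duration == approx(2 / 3)
        assert m.mean_speed == approx(15.0)
        assert m.instantaneous_speed == approx([15.0, 15.0])

    def test_closed_loop_zero_straightness(self):
        pts = [(0, 0, 0), (0, 0, 5), (0, 5, 5), (0, 5, 0), (0, 0, 0)]
        m = compute_metrics(make_track(pts))
        assert m.displacement == 0
        assert m.straightness == 0

    def test_stationary_track_nan_straightness(self):
        m = compute_metrics(make_track([(1, 1, 1), (1, 1, 1), (1, 1, 1)]))
        assert math.isnan(m.straightness)
        assert m.path_length == 0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_motion_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(-50, 50, (8, 3))
        rot = Rotation.random(random_state=seed).as_matrix()
        shift = rng.uniform(-100, 100, 3)
        m0 = compute_metrics(make_track(pts))
        m1 = compute_metrics(make_track(pts @ rot.T + shift))
        assert m1.displacement == approx(m0.displacement, rel=1e-9)
        assert m1.path_length == approx(m0.path_length, rel=1e-9)
        assert m1.straightness == approx(m0.straightness, rel=1e-9)

    def test_subsampling_never_increases_path(self):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(0, 3, (21, 3)), axis=0)  # odd: ends retained
        full = compute_metrics(make_track(pts))
        sub = compute_metrics(Track(0, np.arange(11) * 40.0, pts[::2]))
        assert sub.path_length <= full.path_length + 1e-9
        assert sub.displacement == approx(full.displacement)

    def test_subsampled_straight_track_unchanged(self):
        pts = np.array([(0, 0, 4 * i) for i in range(13)], dtype=float)
        full = compute_metrics(make_track(pts))
        sub = compute_metrics(Track(0, np.arange(7) * 40.0, pts[::2]))
        assert sub.displacement == approx(full.displacement)
        assert sub.straightness == approx(full.straightness)

    def test_displacement_le_path_invariant(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            pts = rng.uniform(0, 100, (6, 3))
            m = compute_metrics(make_track(pts))
            assert m.displacement <= m.path_length + 1e-9

    def test_too_short_track_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            make_track([(0, 0, 0)])


class TestDetectSpots:
    def test_blank_volume_empty_table(self):
        vol = ImageVolume(np.zeros((8, 16, 16), np.float32), (2, 2, 2))
        spots = detect_spots(vol)
        assert spots.empty

    def test_isolated_somata_recovered(self):
        from othg.synthetic import _render_blob
        rng = np.random.default_rng(0)
        vs = np.array([2.0, 2.0, 2.0])
        data = np.full((40, 60, 60), 0.1, np.float32)
        # ≥8 µm apart by grid placement
        centers = []
        for iz in range(2):
            for iy in range(3):
                for ix in range(3):
                    c = (np.array([12 + iz * 25, 15 + iy * 35, 15 + ix * 35])
                         + rng.uniform(-3, 3, 3))
                    centers.append(c)
                    _render_blob(data, c, 2.5, 4.0, vs)
        centers = np.array(centers)
        vol = ImageVolume(data, tuple(vs))
        spots = detect_spots(vol, sigma_range_um=(2.0, 4.0), threshold_rel=0.3)
        det = spots[["z_um", "y_um", "x_um"]].to_numpy()
        d, _ = cKDTree(det).query(centers)
        assert (d < 2.0).sum() >= len(centers) - 1
        assert np.sqrt((d[d < 2.0] ** 2).mean()) < 2.0  # < 1 voxel RMS

    def test_intensity_scaling_invariance(self):
        from othg.synthetic import _render_blob
        data = np.full((20, 30, 30), 0.1, np.float32)
        for c in ([10, 8, 8], [10, 20, 20]):
            _render_blob(data, np.array(c, float) * 2.0, 2.5, 4.0,
                         np.array([2.0, 2.0, 2.0]))
        v1 = ImageVolume(data, (2, 2, 2))
        v2 = ImageVolume(data * 2.0, (2, 2, 2))
        s1 = detect_spots(v1, (2.0, 4.0), 0.3)
        s2 = detect_spots(v2, (2.0, 4.0), 0.3)
        assert len(s1) == len(s2)
        assert np.allclose(s1[["z_um", "y_um", "x_um"]], s2[["z_um", "y_um", "x_um"]])

    def test_phantom_detection_rate(self, single_ventricle_spec):
        motion = MotionSpec(n_cells=20, n_frames=2, mean_speed=20.0,
                            turning_concentration=8.0)
        optics = OpticsSpec(shot_noise_scale=200.0, read_noise_sd=0.02)
        spec = PhantomSpec(**{**single_ventricle_spec.__dict__,
                              "cp_soma_density": 0.0, "cp_intensity": 0.2,
                              "vz_intensity": 0.1, "cavity_intensity": 0.02})
        movie, gt = generate_timelapse(spec, motion, optics, seed=9)
        spots = detect_spots(movie, (2.0, 4.0), 0.3)
        g0 = gt[gt.frame == 0][["z_um", "y_um", "x_um"]].to_numpy()
        s0 = spots[spots.frame == 0][["z_um", "y_um", "x_um"]].to_numpy()
        d, _ = cKDTree(s0).query(g0)
        assert (d < 2.0).sum() >= 19
        assert np.sqrt((d[d < 2.0] ** 2).mean()) < 2.0


class TestLinkTracks:
    @staticmethod
    def spots_from_positions(per_frame, dt=20.0):
        rows = []
        sid = 0
        for f, pts in enumerate(per_frame):
            for p in pts:
                rows.append({"frame": f, "t_min": f * dt, "z_um": p[0],
                             "y_um": p[1], "x_um": p[2], "intensity": 1.0,
                             "spot_id": sid})
                sid += 1
        return pd.DataFrame(rows)

    def test_two_parallel_cells(self):
        frames = [[(0, 0, 5 * f), (0, 200, 5 * f)] for f in range(6)]
        spots = self.spots_from_positions(frames)
        tracks = link_tracks(spots, max_step_um=20)
        assert len(tracks) == 2
        for tr in tracks:
            assert compute_metrics(tr).straightness == approx(1.0)

    def test_gap_closing_contract(self):
        frames = [[(0, 0, 0)], [], [(0, 0, 6)], [(0, 0, 9)], [(0, 0, 12)]]
        spots = self.spots_from_positions(frames)
        no_gap = link_tracks(spots, max_step_um=10, max_gap_frames=0,
                             min_track_frames=2)
        with_gap = link_tracks(spots, max_step_um=10, max_gap_frames=1,
                               min_track_frames=2)
        assert len(with_gap) == 1
        assert with_gap[0].gaps == [1]
        # without gap closing the isolated first spot cannot form a track
        assert len(no_gap) == 1
        assert len(no_gap[0]) == 3

    def test_min_track_frames_filter(self):
        frames = [[(0, 0, 0)], [(0, 0, 5)]]
        spots = self.spots_from_positions(frames)
        assert link_tracks(spots, max_step_um=10, min_track_frames=4) == []
        assert len(link_tracks(spots, max_step_um=10, min_track_frames=2)) == 1

    def test_empty_input(self):
        assert link_tracks(pd.DataFrame()) == []

    def test_ground_truth_link_accuracy(self, single_ventricle_spec):
        spec = PhantomSpec(**{**single_ventricle_spec.__dict__,
                              "cp_soma_density": 0.0, "cp_intensity": 0.2,
                              "vz_intensity": 0.1, "cavity_intensity": 0.02})
        motion = MotionSpec(n_cells=25, n_frames=8, mean_speed=23.0, speed_sd=2.0,
                            turning_concentration=10.0)
        optics = OpticsSpec(shot_noise_scale=200.0, read_noise_sd=0.02)
        movie, gt = generate_timelapse(spec, motion, optics, seed=21)
        spots = detect_spots(movie, (2.0, 4.0), 0.3)
        tracks = link_tracks(spots, max_step_um=14, min_track_frames=4)
        # map detections to ground-truth identities
        ident = {}
        for f in sorted(gt.frame.unique()):
            g = gt[gt.frame == f]
            tree = cKDTree(g[["z_um", "y_um", "x_um"]].to_numpy())
            sub = spots[spots.frame == f]
            d, i = tree.query(sub[["z_um", "y_um", "x_um"]].to_numpy())
            for (sid, dd, ii) in zip(sub.spot_id, d, i):
                ident[(f, round(float(sub[sub.spot_id == sid].z_um.iloc[0]), 6))] = (
                    g.track_id.iloc[ii] if dd < 3 else -1)
        good = total = 0
        for tr in tracks:
            fr = np.rint(tr.t_min / 20.0).astype(int)
            ids = [ident.get((f, round(p[0], 6)), -2)
                   for f, p in zip(fr, tr.points_um)]
            for a, b in zip(ids, ids[1:]):
                total += 1
                good += (a == b and a >= 0)
        assert total > 0
        assert good / total >= 0.95


class TestSummarizeGroups:
    def _metrics(self, speeds, straightness=0.9):
        out = []
        for i, s in enumerate(speeds):
            out.append(type("M", (), {"track_id": i, "displacement": s,
                                      "mean_speed": s,
                                      "straightness": straightness})())
        return out

    def test_identical_groups_p_one(self):
        g = self._metrics([20, 21, 22, 23])
        summaries, tests = summarize_groups(
            {"a": g, "b": g}, which=("mean_speed",))
        assert tests["mean_speed"].p == approx(1.0)

    def test_paper_scale_speed_difference(self):
        rng = np.random.default_rng(0)
        wt = self._metrics(rng.normal(23.4, 3.0, 208))
        mt = self._metrics(rng.normal(13.3, 1.5, 217))
        summaries, tests = summarize_groups({"wt": wt, "mt": mt},
                                            which=("mean_speed",))
        assert tests["mean_speed"].p < 1e-4
        assert summaries["mean_speed"]["wt"].mean == approx(23.4, abs=1.0)

    def test_nan_straightness_excluded(self):
        g = self._metrics([20, 21, 22], straightness=float("nan"))
        with pytest.raises(ValueError, match="<2 tracks"):
            summarize_groups({"a": g, "b": g}, which=("straightness",))

    def test_metrics_table_columns(self):
        tr = make_track([(0, 0, 0), (0, 0, 5), (0, 0, 10)])
        df = metrics_table([tr])
        assert {"mean_speed_um_hr", "straightness",
                "displacement_um"} <= set(df.columns)
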