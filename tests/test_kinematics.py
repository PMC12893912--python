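"""Body-frame kinematics, joint angles, loop areas and non-reciprocity."""

import math

import numpy as np
import pytest

from mesoswim import (
    PoseTrack,
    antenna_length,
    body_frame,
    free_swimming_speed,
    joint_angles,
    loop_area,
    make_pose_track,
    nonreciprocity,
    predicted_speed,
    sector_area,
)
from mesoswim.calibration import InvalidInputError
from mesoswim.kinematics import BODY_PARTS, analyze_track


def simple_track(n=8, tether_mode="head", body_frame_flag=True):
    """Static straight-armed track: antennae perpendicular to the body."""
    coords = {
        "head": np.zeros((n, 2)),
        "tail": np.tile([0.0, -1000e-6], (n, 1)),
    }
    for side, sgn in (("left", -1.0), ("right", 1.0)):
        coords[f"shoulder_{side}"] = np.tile([sgn * 80e-6, -150e-6], (n, 1))
        coords[f"elbow_{side}"] = np.tile([sgn * 380e-6, -150e-6], (n, 1))
        coords[f"tip_{side}"] = np.tile([sgn * 580e-6, -150e-6], (n, 1))
    return PoseTrack(sample_rate=100.0, coords=coords, confidence={},
                     tether_mode=tether_mode, body_frame=body_frame_flag)


def rigid_motion(track, angle, shift):
    c, s = math.cos(angle), math.sin(angle)
    R = np.array([[c, -s], [s, c]])
    coords = {p: xy @ R.T + np.asarray(shift) for p, xy in track.coords.items()}
    return PoseTrack(sample_rate=track.sample_rate, coords=coords,
                     confidence={}, tether_mode=track.tether_mode,
                     body_frame=False)


def rasterized_area(poly, n_grid=400):
    """Independent loop-area oracle: count grid points with winding != 0."""
    poly = np.asarray(poly)
    lo = poly.min(axis=0)
    hi = poly.max(axis=0)
    pad = 0.05 * (hi - lo).max() + 1e-12
    lo, hi = lo - pad, hi + pad
    xs = np.linspace(lo[0], hi[0], n_grid)
    ys = np.linspace(lo[1], hi[1], n_grid)
    X, Y = np.meshgrid(xs, ys)
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    closed = np.vstack([poly, poly[:1]])
    winding = np.zeros(len(pts))
    for a, b in zip(closed[:-1], closed[1:]):
        va = a - pts
        vb = b - pts
        cross = va[:, 0] * vb[:, 1] - va[:, 1] * vb[:, 0]
        dot = va[:, 0] * vb[:, 0] + va[:, 1] * vb[:, 1]
        winding += np.arctan2(cross, dot)
    inside = np.abs(winding) > math.pi  # |winding| ~ 2*pi*k for enclosed pts
    cell = (xs[1] - xs[0]) * (ys[1] - ys[0])
    return inside.sum() * cell


class TestBodyFrame:
    def test_already_aligned_is_identity(self):
        track = simple_track(body_frame_flag=False)
        out = body_frame(track)
        for p in BODY_PARTS:
            assert out.coords[p] == pytest.approx(track.coords[p], abs=1e-18)

    def test_rigid_motion_invariance(self):
        track = simple_track(body_frame_flag=False)
        moved = rigid_motion(track, math.pi / 2, [3e-3, -2e-3])
        out0 = body_frame(track)
        out1 = body_frame(moved)
        for p in BODY_PARTS:
            assert out1.coords[p] == pytest.approx(out0.coords[p], abs=1e-15)

    def test_per_frame_random_motion_leaves_angles_unchanged(self):
        track, _ = make_pose_track(1.0, 0.2, n_cycles=3, seed=11)
        rng = np.random.default_rng(11)
        coords = {p: np.empty_like(xy) for p, xy in track.coords.items()}
        n = track.n_frames
        angles = rng.uniform(0, 2 * math.pi, n)
        shifts = rng.uniform(-1e-3, 1e-3, (n, 2))
        for i in range(n):
            c, s = math.cos(angles[i]), math.sin(angles[i])
            R = np.array([[c, -s], [s, c]])
            for p in BODY_PARTS:
                coords[p][i] = R @ track.coords[p][i] + shifts[i]
        jittered = PoseTrack(sample_rate=track.sample_rate, coords=coords,
                             confidence={}, tether_mode="head")
        a0 = joint_angles(body_frame(track))
        a1 = joint_angles(body_frame(jittered))
        for side in ("left", "right"):
            assert a1.theta_a[side] == pytest.approx(a0.theta_a[side],
                                                     abs=1e-6)
            assert a1.theta_e[side] == pytest.approx(a0.theta_e[side],
                                                     abs=1e-6)

    def test_tail_catch_anchors_tail(self):
        track = simple_track(tether_mode="tail", body_frame_flag=False)
        out = body_frame(track)
        assert out.coords["tail"] == pytest.approx(0.0, abs=1e-18)


class TestJointAngles:
    def test_straight_antenna_gives_180_elbow(self):
        angles = joint_angles(simple_track())
        for side in ("left", "right"):
            assert angles.theta_e[side] == pytest.approx(180.0, abs=1e-9)

    def test_perpendicular_segments_give_90_elbow(self):
        track = simple_track()
        coords = dict(track.coords)
        coords["tip_right"] = np.tile([380e-6, -350e-6], (track.n_frames, 1))
        track2 = PoseTrack(sample_rate=100.0, coords=coords, confidence={},
                           body_frame=True)
        angles = joint_angles(track2)
        assert angles.theta_e["right"] == pytest.approx(90.0, abs=1e-9)

    def test_perpendicular_antenna_gives_90_armpit(self):
        angles = joint_angles(simple_track())
        for side in ("left", "right"):
            assert angles.theta_a[side] == pytest.approx(90.0, abs=1e-9)


class TestAntennaLength:
    def test_rigid_two_segment_antenna(self):
        track = simple_track()
        l_a, sd = antenna_length(track)
        assert l_a == pytest.approx(500e-6, rel=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-15)

    def test_flexing_preserves_length(self):
        # generator track flexes both joints but keeps segment lengths fixed
        track, truth = make_pose_track(1.0, 0.2, n_cycles=3, seed=1)
        l_a, sd = antenna_length(body_frame(track))
        assert l_a == pytest.approx(truth["l_a"], rel=1e-9)
        assert sd < 1e-9 * l_a


class TestLoopArea:
    def test_polygonal_circle(self):
        th = np.linspace(0, 2 * np.pi, 65)[:-1]
        area, degen = loop_area(np.stack([np.cos(th), np.sin(th)], axis=1))
        assert not degen
        assert area == pytest.approx(3.1364, abs=2e-3)
        th = np.linspace(0, 2 * np.pi, 1001)[:-1]
        area, _ = loop_area(np.stack([np.cos(th), np.sin(th)], axis=1))
        assert area == pytest.approx(math.pi, rel=1e-4)

    def test_lemniscate_counts_both_lobes(self):
        # r^2 = cos(2 th), a = 1: enclosed area 1.0 (0.5 per lobe)
        th = np.linspace(-np.pi / 4, np.pi / 4, 2000)
        r = np.sqrt(np.cos(2 * th))
        right = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
        left = -right
        loop = np.vstack([right, left])
        area, degen = loop_area(loop)
        assert not degen
        assert area == pytest.approx(1.0, rel=2e-3)

    def test_retraced_path_has_zero_area(self):
        th = np.linspace(0, np.pi, 100)
        arc = np.stack([np.cos(th), 0.3 * np.sin(th)], axis=1)
        path = np.vstack([arc, arc[::-1][1:]])
        area, _ = loop_area(path)
        assert area == pytest.approx(0.0, abs=1e-12)

    def test_collinear_points_flagged_degenerate(self):
        pts = np.stack([np.linspace(0, 1, 30), np.linspace(0, 2, 30)], axis=1)
        area, degen = loop_area(pts)
        assert area == 0.0 and degen

    def test_agrees_with_rasterization_oracle(self):
        # random smooth closed curves, both simple and figure-eight
        rng = np.random.default_rng(42)
        th = np.linspace(0, 2 * np.pi, 600, endpoint=False)
        for trial in range(20):
            r = 1.0 + 0.3 * rng.normal() * np.cos(th + rng.uniform(0, 6)) \
                + 0.2 * rng.normal() * np.cos(2 * th + rng.uniform(0, 6))
            if trial % 2:
                # pinched curve producing a self-intersecting figure-eight
                x = np.cos(th)
                y = 0.6 * np.sin(2 * th) + 0.05 * rng.normal() * np.sin(th)
                poly = np.stack([x, y], axis=1)
            else:
                poly = np.stack([r * np.cos(th), r * np.sin(th)], axis=1)
            area, _ = loop_area(poly)
            oracle = rasterized_area(poly)
            assert area == pytest.approx(oracle, rel=0.01)


class TestSectorArea:
    def test_full_disc(self):
        assert sector_area(1.0, 360.0) == pytest.approx(math.pi, rel=1e-12)

    def test_hand_computed_quarter(self):
        # l_a = 1 mm, 90 degrees -> 0.7854 mm^2
        assert sector_area(1e-3, 90.0) == pytest.approx(0.7854e-6, rel=1e-3)

    def test_quadratic_scaling(self):
        assert sector_area(2.0, 45.0) == pytest.approx(
            4 * sector_area(1.0, 45.0), rel=1e-12)

    def test_out_of_range_angle_rejected(self):
        with pytest.raises(InvalidInputError):
            sector_area(1.0, 0.0)
        with pytest.raises(InvalidInputError):
            sector_area(1.0, 400.0)


class TestNonreciprocity:
    def test_reciprocal_stroke_has_zero_chi(self):
        track, _ = make_pose_track(1.0, 0.0, n_cycles=5, seed=0)
        result = nonreciprocity(body_frame(track))
        assert result["chi"] == pytest.approx(0.0, abs=1e-6)

    def test_scale_invariance(self):
        track, _ = make_pose_track(1.0, 0.2, n_cycles=5, seed=0)
        bf = body_frame(track)
        chi0 = nonreciprocity(bf)["chi"]
        scaled = PoseTrack(
            sample_rate=bf.sample_rate,
            coords={p: 2.0 * xy for p, xy in bf.coords.items()},
            confidence={}, tether_mode="head", body_frame=True)
        assert nonreciprocity(scaled)["chi"] == pytest.approx(chi0, rel=1e-9)

    def test_commanded_chi_recovered(self):
        track, _ = make_pose_track(1.0, 0.20, n_cycles=30, seed=5)
        result = nonreciprocity(body_frame(track))
        assert result["chi"] == pytest.approx(0.20, abs=0.01)

    def test_mirror_symmetric_sides_agree(self):
        track, _ = make_pose_track(1.0, 0.2, n_cycles=4, seed=0)
        bf = body_frame(track)
        from mesoswim.kinematics import segment_stroke_cycles

        angles = joint_angles(bf)
        cycles = segment_stroke_cycles(angles)
        a, b = cycles[0], cycles[1]
        areas = {}
        for side in ("left", "right"):
            areas[side], _ = loop_area(bf.coords[f"tip_{side}"][a:b])
        assert areas["left"] == pytest.approx(areas["right"], rel=1e-9)

    def test_chi_calibration_sweep(self):
        for target in (0.05, 0.1, 0.2, 0.3):
            track, _ = make_pose_track(1.0, target, n_cycles=6, seed=3)
            chi = nonreciprocity(body_frame(track))["chi"]
            assert chi == pytest.approx(target, rel=0.05)


class TestFreeSwimmingSpeed:
    def test_stationary_track_has_zero_speed(self):
        track, _ = make_pose_track(1.0, 0.2, n_cycles=5, seed=0)
        free = PoseTrack(sample_rate=track.sample_rate, coords=track.coords,
                         confidence={}, tether_mode="free")
        U, _ = free_swimming_speed(free)
        assert U == pytest.approx(0.0, abs=1e-9)

    def test_uniform_drift_recovered(self):
        track, _ = make_pose_track(1.0, 0.2, n_cycles=8, seed=0)
        t = track.times
        drift = np.stack([3e-3 * t, -4e-3 * t], axis=1)  # 5 mm/s
        coords = {p: xy + drift for p, xy in track.coords.items()}
        free = PoseTrack(sample_rate=track.sample_rate, coords=coords,
                         confidence={}, tether_mode="free")
        U, _ = free_swimming_speed(free)
        assert U == pytest.approx(5e-3, rel=0.01)

    def test_tethered_track_rejected(self):
        track, _ = make_pose_track(1.0, 0.2, n_cycles=5, seed=0)
        with pytest.raises(InvalidInputError):
            free_swimming_speed(track)

    def test_predicted_speed_hand_value(self):
        assert predicted_speed(0.25, 8.0, 1e-3) == pytest.approx(4e-3)
        assert predicted_speed(0.0, 8.0, 1e-3) == 0.0
        assert predicted_speed(0.25, 8.0, 2e-3) == pytest.approx(8e-3)

    def test_generator_free_mode_matches_prediction(self):
        track, truth = make_pose_track(1.0, 0.25, f=8.0, n_cycles=8,
                                       tether_mode="free", seed=2)
        U, _ = free_swimming_speed(track)
        assert U == pytest.approx(2 * 0.25 * 8.0 * 1e-3, rel=0.02)


class TestAnalyzeTrack:
    def test_full_summary_consistency(self):
        track, truth = make_pose_track(0.8, 0.15, n_cycles=10,
                                       noise_sd=1e-6, seed=9)
        s = analyze_track(track)
        assert s.chi == pytest.approx(0.15, rel=0.1)
        assert s.f == pytest.approx(truth["f"], rel=0.02)
        assert s.l_a == pytest.approx(truth["l_a"], rel=0.02)
        assert s.chi == pytest.approx(s.A_sb / s.A_sector, rel=0.05)

    def test_low_confidence_keypoints_interpolated(self):
        track, _ = make_pose_track(1.0, 0.2, n_cycles=5, seed=4)
        conf = {p: np.ones(track.n_frames) for p in BODY_PARTS}
        coords = {p: xy.copy() for p, xy in track.coords.items()}
        # corrupt a few frames and mark them unreliable
        coords["tip_left"][50:53] = 1.0
        conf["tip_left"][50:53] = 0.1
        corrupted = PoseTrack(sample_rate=track.sample_rate, coords=coords,
                              confidence=conf, tether_mode="head")
        s_clean = analyze_track(track)
        s_corr = analyze_track(corrupted)
        assert s_corr.chi == pytest.approx(s_clean.chi, rel=0.05)
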