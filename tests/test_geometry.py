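"""Trajectory geometry: axes, tilt angles, tip distances, summaries, and the
XYZ interchange round trip."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cnetvna import synthdata
from cnetvna.geometry import (
    TrajectoryFrameSet,
    analyze_trajectory,
    duplex_axis,
    expected_duplex_length,
    read_trajectory,
    summarize_geometry,
    tilt_angle,
    tip_surface_distance,
    tube_axis,
)


def cylinder_lattice(radius=0.38, length=10.0, dz=0.1, nphi=36):
    z = np.arange(-length / 2, length / 2 + dz, dz)
    phi = 2 * math.pi * np.arange(nphi) / nphi
    zz, pp = np.meshgrid(z, phi, indexing="ij")
    return np.column_stack(
        [radius * np.cos(pp.ravel()), radius * np.sin(pp.ravel()), zz.ravel()]
    )


class TestTubeAxis:
    def test_ideal_cylinder_along_z(self):
        coords = cylinder_lattice()
        axis = tube_axis(coords, np.ones(len(coords), bool))
        assert np.allclose(np.abs(axis), [0, 0, 1], atol=1e-6)

    def test_equivariance_under_rotation(self):
        coords = cylinder_lattice()
        R = Rotation.from_euler("xyz", [20, 35, 50], degrees=True).as_matrix()
        axis = tube_axis(coords @ R.T, np.ones(len(coords), bool))
        target = R @ np.array([0, 0, 1.0])
        assert min(np.linalg.norm(axis - target), np.linalg.norm(axis + target)) < 1e-6

    def test_atom_order_invariance(self, rng):
        coords = cylinder_lattice()
        perm = rng.permutation(len(coords))
        a = tube_axis(coords, np.ones(len(coords), bool))
        b = tube_axis(coords[perm], np.ones(len(coords), bool))
        assert np.allclose(a, b, atol=1e-9)

    def test_anchor_side_fixes_sign(self):
        coords = cylinder_lattice()
        axis = tube_axis(coords, np.ones(len(coords), bool),
                         anchor_centroid=np.array([0.38, 0, -3.0]))
        assert axis[2] > 0  # anchor projects negative

    def test_degenerate_cloud_rejected(self, rng):
        sphere = rng.normal(0, 1.0, (200, 3))
        # perfectly isotropic synthetic cloud: shrink anisotropy to zero
        sphere = sphere / np.linalg.norm(sphere, axis=1, keepdims=True)
        with pytest.raises(ValueError, match="degenerate|unique"):
            # exactly equal eigenvalues via symmetrized copies
            pts = np.vstack([np.eye(3), -np.eye(3)]) * 2.0
            pts = np.vstack([pts] * 4)
            tube_axis(pts, np.ones(len(pts), bool))


class TestDuplexAxis:
    def make_rod(self, direction, n_bp=12, jitter=0.0, rng=None):
        direction = np.asarray(direction, float)
        direction = direction / np.linalg.norm(direction)
        pts = np.outer(np.arange(n_bp) * 0.34, direction)
        if jitter and rng is not None:
            pts = pts + rng.normal(0, jitter, pts.shape)
        return pts

    def test_rod_along_x(self):
        rod = self.make_rod([1, 0, 0])
        axis = duplex_axis(rod, np.ones(len(rod), bool), np.arange(len(rod)))
        assert np.allclose(axis, [1, 0, 0], atol=1e-9)

    def test_jittered_rod_within_two_degrees(self, rng):
        rod = self.make_rod([0, 1, 1], jitter=0.05, rng=rng)
        axis = duplex_axis(rod, np.ones(len(rod), bool), np.arange(len(rod)))
        target = np.array([0, 1, 1]) / math.sqrt(2)
        angle = math.degrees(math.acos(np.clip(abs(np.dot(axis, target)), -1, 1)))
        assert angle < 2.0

    def test_reversing_bp_order_flips_sign(self):
        rod = self.make_rod([1, 0, 0])
        bp = np.arange(len(rod))
        a = duplex_axis(rod, np.ones(len(rod), bool), bp)
        b = duplex_axis(rod, np.ones(len(rod), bool), bp[::-1])
        assert np.allclose(a, -b, atol=1e-9)

    def test_single_centroid_rejected(self):
        rod = self.make_rod([1, 0, 0], n_bp=4)
        with pytest.raises(ValueError, match="base-pair"):
            duplex_axis(rod, np.ones(4, bool), np.zeros(4, dtype=int))


class TestTiltAngle:
    @pytest.mark.parametrize("v,expected", [
        ((0, 0, 1), 0.0),
        ((1, 0, 0), 90.0),
        ((0, 0, -1), 180.0),
    ])
    def test_reference_directions(self, v, expected):
        assert tilt_angle(np.array([0, 0, 1.0]), np.array(v, dtype=float)) == (
            pytest.approx(expected, abs=1e-9)
        )

    def test_constructed_thirty_degree_tilt(self):
        v = np.array([math.sin(math.radians(30)), 0, math.cos(math.radians(30))])
        assert tilt_angle(np.array([0, 0, 1.0]), v) == pytest.approx(30.0, abs=1e-6)

    def test_rejects_non_unit_vectors(self):
        with pytest.raises(ValueError, match="unit"):
            tilt_angle(np.array([0, 0, 2.0]), np.array([0, 0, 1.0]))


class TestTipDistance:
    def test_tip_above_cylinder(self):
        sw = cylinder_lattice()
        h = 4.08
        frame = np.vstack([sw, [[0.38 + h, 0.0, 0.0]]])
        tip = np.zeros(len(frame), bool)
        tip[-1] = True
        swm = ~tip
        d = tip_surface_distance(frame, tip, swm)
        assert d == pytest.approx(h, abs=0.1)  # within one lattice spacing

    def test_coincident_tip_gives_zero(self):
        sw = cylinder_lattice()
        frame = np.vstack([sw, sw[:1]])
        tip = np.zeros(len(frame), bool)
        tip[-1] = True
        assert tip_surface_distance(frame, tip, ~tip) == 0.0

    def test_isometry_invariance(self):
        sw = cylinder_lattice()
        frame = np.vstack([sw, [[0.38 + 2.0, 0.0, 0.5]]])
        tip = np.zeros(len(frame), bool)
        tip[-1] = True
        d0 = tip_surface_distance(frame, tip, ~tip)
        R = Rotation.from_euler("zyx", [12, 77, -31], degrees=True).as_matrix()
        moved = frame @ R.T + np.array([5.0, -3.0, 2.0])
        assert tip_surface_distance(moved, tip, ~tip) == pytest.approx(d0, abs=1e-9)


class TestExpectedLength:
    @pytest.mark.parametrize("n_bp,expected", [(12, 4.08), (1, 0.34), (24, 8.16)])
    def test_values(self, n_bp, expected):
        assert expected_duplex_length(n_bp) == pytest.approx(expected, abs=1e-12)

    def test_rejects_zero_bp(self):
        with pytest.raises(ValueError):
            expected_duplex_length(0)


class TestSummaries:
    def test_constant_series_has_undefined_correlation(self):
        s = summarize_geometry(np.full(20, 90.0), np.full(20, 4.0))
        assert s["angle_deg"]["mean"] == s["angle_deg"]["median"] == 90.0
        assert s["tilt_distance_correlation"] is None

    def test_tilt_lowers_tip_negative_correlation(self):
        traj = synthdata.simulate_trajectory(
            12, 200, tilt_distribution=(90.0, 15.0), seed=2
        )
        geo = analyze_trajectory(traj)
        assert geo.summary["tilt_distance_correlation"] < 0

    def test_frame_permutation_invariance(self, rng):
        angles = rng.uniform(60, 120, 50)
        dists = rng.uniform(2, 5, 50)
        s1 = summarize_geometry(angles, dists)
        perm = rng.permutation(50)
        s2 = summarize_geometry(angles[perm], dists[perm])
        for key in ("angle_deg", "tip_distance_nm"):
            for stat, val in s1[key].items():
                assert s2[key][stat] == pytest.approx(val, rel=1e-12)
        assert s2["tilt_distance_correlation"] == pytest.approx(
            s1["tilt_distance_correlation"], rel=1e-9
        )


class TestTrajectoryIO:
    def test_round_trip_preserves_coordinates(self, tilted_trajectory, tmp_path):
        xyz, grp = tmp_path / "t.xyz", tmp_path / "g.csv"
        tilted_trajectory.write(xyz, grp)
        fs = read_trajectory(xyz, grp)
        assert fs.n_frames == tilted_trajectory.frames.__len__()
        for a, b in zip(fs.frames, tilted_trajectory.frames):
            assert np.abs(a - b).max() < 1e-6

    def test_missing_tip_flag_rejected(self, tilted_trajectory, tmp_path):
        xyz, grp = tmp_path / "t.xyz", tmp_path / "g.csv"
        traj = tilted_trajectory
        from cnetvna import io as cio

        cio.write_xyz(traj.frames, traj.labels, xyz)
        cio.write_group_map(traj.groups, traj.bp_index,
                            np.zeros_like(traj.is_tip), grp)
        with pytest.raises(ValueError, match="tip"):
            read_trajectory(xyz, grp)

    def test_single_frame_file(self, tmp_path):
        traj = synthdata.simulate_trajectory(12, 1, seed=0)
        xyz, grp = tmp_path / "t.xyz", tmp_path / "g.csv"
        traj.write(xyz, grp)
        assert read_trajectory(xyz, grp).n_frames == 1

    def test_frame_atom_count_mismatch_names_frame(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("2\nc\nA 0 0 0\nB 1 1 1\n1\nc\nA 0 0 0\n")
        from cnetvna.io import read_xyz

        with pytest.raises(ValueError, match="frame 1"):
            read_xyz(p)


class TestEndToEndGeometry:
    @pytest.mark.parametrize("theta", [60.0, 90.0, 120.0])
    def test_prescribed_tilt_recovered(self, theta):
        traj = synthdata.simulate_trajectory(
            12, 5, tilt_distribution=(theta, 0.0), seed=1
        )
        geo = analyze_trajectory(traj)
        assert np.allclose(geo.angle_deg, theta, atol=1.0)
        expected = 12 * 0.34 * math.sin(math.radians(theta))
        assert np.allclose(geo.tip_distance_nm, expected, rtol=0.02)

    def test_rigid_body_invariance(self, tilted_trajectory):
        base = analyze_trajectory(tilted_trajectory)
        R = Rotation.from_euler("xyz", [33, -21, 75], degrees=True).as_matrix()
        shift = np.array([1.0, -2.0, 3.0])
        fs = TrajectoryFrameSet.from_synthetic(tilted_trajectory)
        moved = TrajectoryFrameSet(
            frames=[f @ R.T + shift for f in fs.frames],
            groups=fs.groups, bp_index=fs.bp_index, is_tip=fs.is_tip,
        )
        geo = analyze_trajectory(moved)
        assert np.abs(geo.angle_deg - base.angle_deg).max() < 1e-6
        assert np.abs(geo.tip_distance_nm - base.tip_distance_nm).max() < 1e-6
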