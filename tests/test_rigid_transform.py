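"""Rigid-transform machinery: matrices, point maps, volume resampling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import rotodose as rd
from rotodose.grids import VolumeGrid
from rotodose.rigid_transform import euler_angles, rotation_matrix

angles = st.floats(min_value=-179.0, max_value=179.0, allow_nan=False)


def brute_force_rotation(pitch, roll, yaw):
    """Independent elementary-matrix product (column-vector convention)."""
    p, r, y = np.deg2rad([pitch, roll, yaw])
    rx = np.array([[1, 0, 0], [0, np.cos(p), -np.sin(p)], [0, np.sin(p), np.cos(p)]])
    ry = np.array([[np.cos(r), 0, np.sin(r)], [0, 1, 0], [-np.sin(r), 0, np.cos(r)]])
    rz = np.array([[np.cos(y), -np.sin(y), 0], [np.sin(y), np.cos(y), 0], [0, 0, 1]])
    return rx @ ry @ rz


class TestRotationMatrix:
    def test_zero_angles_is_identity(self):
        assert np.allclose(rotation_matrix(0, 0, 0), np.eye(3), atol=1e-15)

    def test_three_half_turns_cancel(self):
        # each 180 deg elementary rotation is a diagonal sign matrix; the
        # ordered product of the three is the identity
        assert np.allclose(rotation_matrix(180, 180, 180), np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("pry", [(1, 3, 5), (7, 7, 7), (-7, 2, 0), (30, -45, 120)])
    def test_matches_brute_force_product(self, pry):
        assert np.allclose(rotation_matrix(*pry), brute_force_rotation(*pry), atol=1e-12)

    @settings(max_examples=200, derandomize=True)
    @given(pitch=angles, roll=angles, yaw=angles)
    def test_orthonormal_unit_determinant(self, pitch, roll, yaw):
        m = rotation_matrix(pitch, roll, yaw)
        assert np.allclose(m.T @ m, np.eye(3), atol=1e-10)
        assert np.isclose(np.linalg.det(m), 1.0, atol=1e-10)

    def test_many_random_triples_stay_orthonormal(self):
        rng = np.random.default_rng(0)
        for pry in rng.uniform(-180, 180, size=(1000, 3)):
            m = rotation_matrix(*pry)
            assert np.allclose(m.T @ m, np.eye(3), atol=1e-10)
            assert np.isclose(np.linalg.det(m), 1.0, atol=1e-10)

    def test_non_finite_angle_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rotation_matrix(np.nan, 0, 0)
        with pytest.raises(ValueError, match="180"):
            rotation_matrix(200, 0, 0)

    def test_row_and_column_vector_readings_agree(self):
        # the row-vector reading p' = p [R] with [R] the transpose of the
        # composed column matrix gives the same points
        rng = np.random.default_rng(3)
        m = rotation_matrix(4.0, -2.5, 6.0)
        pts = rng.normal(scale=40.0, size=(20, 3))
        assert np.allclose(pts @ m.T, (m @ pts.T).T, atol=1e-12)

    @settings(max_examples=100, derandomize=True)
    @given(pitch=st.floats(-60, 60), roll=st.floats(-60, 60), yaw=st.floats(-60, 60))
    def test_euler_angle_round_trip(self, pitch, roll, yaw):
        rec = euler_angles(rotation_matrix(pitch, roll, yaw))
        assert np.allclose(rec, (pitch, roll, yaw), atol=1e-9)

    def test_euler_angles_match_scipy_convention(self):
        from scipy.spatial.transform import Rotation

        m = rotation_matrix(5.0, -12.0, 25.0)
        assert np.allclose(euler_angles(m),
                           Rotation.from_matrix(m).as_euler("XYZ", degrees=True),
                           atol=1e-9)


class TestApplyToPoints:
    def test_isocenter_is_fixed_point_of_rotation(self):
        iso = np.array([10.0, 20.0, 30.0])
        t = rd.RigidTransform.from_angles(7, -5, 3, translation=(1, 1, 1), isocenter=iso)
        assert np.allclose(t.apply(iso), iso + 1.0, atol=1e-12)

    def test_chord_displacement_two_degrees_at_three_cm(self):
        # a 2 deg single-axis rotation displaces a point 30 mm off-axis by
        # 2 * 30 * sin(1 deg) = 1.047 mm
        iso = np.zeros(3)
        t = rd.RigidTransform.from_angles(0, 0, 2, isocenter=iso)
        p = np.array([30.0, 0.0, 0.0])
        displacement = np.linalg.norm(t.apply(p) - p)
        assert np.isclose(displacement, 2 * 30 * np.sin(np.deg2rad(1.0)), atol=1e-12)
        assert np.isclose(displacement, 1.047, atol=5e-4)

    def test_offset_lengths_preserved(self):
        rng = np.random.default_rng(7)
        iso = np.array([5.0, -3.0, 8.0])
        t = rd.RigidTransform.from_angles(7, 7, 7, translation=(1, 1, 1), isocenter=iso)
        pts = iso + rng.normal(scale=30, size=(50, 3))
        before = np.linalg.norm(pts - iso, axis=1)
        after = np.linalg.norm(t.apply(pts) - (iso + t.translation), axis=1)
        assert np.allclose(before, after, atol=1e-9)

    def test_inverse_round_trip(self):
        rng = np.random.default_rng(11)
        t = rd.RigidTransform.from_angles(3, -5, 7, translation=(1, -2, 0.5),
                                          isocenter=(4, 5, 6))
        pts = rng.normal(scale=50, size=(40, 3))
        assert np.allclose(t.inverse().apply(t.apply(pts)), pts, atol=1e-9)

    def test_matches_brute_force_matrix_arithmetic(self):
        rng = np.random.default_rng(13)
        iso = np.array([1.0, 2.0, 3.0])
        tr = np.array([0.5, -0.5, 1.0])
        t = rd.RigidTransform.from_angles(2, 4, -6, translation=tr, isocenter=iso)
        pts = rng.normal(scale=60, size=(100, 3))
        m = brute_force_rotation(2, 4, -6)
        expected = (m @ (pts - iso).T).T + iso + tr
        assert np.allclose(t.apply(pts), expected, atol=1e-9)

    def test_compose_is_sequential_application(self):
        iso = np.array([1.0, 1.0, 1.0])
        t1 = rd.RigidTransform.from_angles(3, 0, 0, translation=(1, 0, 0), isocenter=iso)
        t2 = rd.RigidTransform.from_angles(0, 5, 0, translation=(0, 1, 0), isocenter=iso)
        pts = np.array([[10.0, -20.0, 5.0], [0.0, 0.0, 0.0]])
        assert np.allclose(t2.compose(t1).apply(pts), t2.apply(t1.apply(pts)), atol=1e-12)

    def test_serialization_round_trip(self, tmp_path):
        t = rd.RigidTransform.from_angles(1, 3, 5, translation=(1, 1, 1),
                                          isocenter=(2, 3, 4))
        path = tmp_path / "t.json"
        t.save(path)
        t2 = rd.RigidTransform.load(path)
        assert np.allclose(t2.rotation, t.rotation, atol=1e-12)
        assert np.allclose(t2.translation, t.translation)
        assert np.allclose(t2.isocenter, t.isocenter)


def smooth_test_volume(n=48, spacing=2.0):
    ax = np.arange(n) * spacing
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij", sparse=True)
    values = (500 * np.sin(x / 23.0) * np.cos(y / 31.0) * np.sin(z / 17.0 + 0.5)
              + 200 * np.cos(x / 41.0))
    return VolumeGrid(values, np.full(3, spacing), np.zeros(3))


class TestResampleVolume:
    def test_identity_nearest_bit_identical(self):
        v = smooth_test_volume(24)
        t = rd.RigidTransform.identity(isocenter=v.physical_center)
        out = rd.resample_volume(v, t, interpolation="nearest")
        assert np.array_equal(out.values, v.values)

    def test_identity_trilinear_exact(self):
        v = smooth_test_volume(24)
        t = rd.RigidTransform.identity(isocenter=v.physical_center)
        out = rd.resample_volume(v, t, interpolation="trilinear")
        assert np.max(np.abs(out.values - v.values)) < 1e-9

    def test_round_trip_interior_error_small(self):
        v = smooth_test_volume(48)
        t = rd.RigidTransform.from_angles(7, 7, 7, translation=(1, 1, 1),
                                          isocenter=v.physical_center)
        back = rd.resample_volume(rd.resample_volume(v, t), t.inverse())
        interior = (slice(10, -10),) * 3
        mae = np.mean(np.abs(back.values[interior] - v.values[interior]))
        # trilinear interpolation tolerance for a smooth field
        assert mae < 0.01 * np.ptp(v.values)

    def test_marker_centroid_moves_as_point_transform_predicts(self):
        n, spacing = 48, 2.0
        v = VolumeGrid(np.zeros((n, n, n)), np.full(3, spacing), np.zeros(3))
        marker = np.array([40.0, 50.0, 62.0])
        ax = [np.arange(n) * spacing for _ in range(3)]
        x, y, z = np.meshgrid(*ax, indexing="ij", sparse=True)
        v.values += np.exp(-((x - marker[0]) ** 2 + (y - marker[1]) ** 2
                             + (z - marker[2]) ** 2) / (2 * 4.0 ** 2))
        t = rd.RigidTransform.from_angles(7, 7, 7, translation=(1, 1, 1),
                                          isocenter=v.physical_center)
        moved = rd.resample_volume(v, t)
        centroid_idx = np.array(ndimage.center_of_mass(moved.values))
        centroid = v.origin + centroid_idx * v.spacing
        assert np.linalg.norm(centroid - t.apply(marker)) < spacing

    def test_degenerate_spacing_rejected(self):
        with pytest.raises(ValueError, match="spacing"):
            VolumeGrid(np.zeros((4, 4, 4)), (1.0, 0.0, 1.0), np.zeros(3))

    def test_unknown_interpolation_rejected(self):
        v = smooth_test_volume(8)
        t = rd.RigidTransform.identity(v.physical_center)
        with pytest.raises(ValueError, match="interpolation"):
            rd.resample_volume(v, t, interpolation="cubic")


class TestTransformStructure:
    def test_identity_preserves_volume_exactly(self, fast_phantom):
        _, structures, isocenter = fast_phantom
        t = rd.RigidTransform.identity(isocenter)
        ctv = structures["CTV"]
        assert np.isclose(rd.transform_structure(ctv, t).volume_cm3,
                          ctv.volume_cm3, rtol=1e-12)

    def test_rigid_motion_preserves_analytic_ellipsoid_volume(self):
        s = rd.make_structure("ellipse", 150.0, seed=4, spacing=(2, 2, 2),
                              grid_shape=(96, 96, 96), ratios=(1.4, 1.0, 1.0 / 1.4))
        iso = s.centroid()
        t = rd.RigidTransform.from_angles(7, 7, 7, translation=(1, 1, 1), isocenter=iso)
        moved = rd.transform_structure(s, t)
        assert abs(moved.volume_cm3 - s.volume_cm3) / s.volume_cm3 < 0.005
        # both match the requested analytic volume at the generator tolerance
        assert abs(moved.volume_cm3 - 150.0) / 150.0 < 0.025

    def test_volume_preservation_tiers_across_study_transforms(self, fast_phantom):
        _, structures, isocenter = fast_phantom
        worst = {}
        for ang in (1, -1, 7, -7):
            t = rd.RigidTransform.from_angles(ang, ang, ang, (1, 1, 1), isocenter)
            for s in structures:
                moved = rd.transform_structure(s, t)
                pct = 100 * abs(moved.volume_cm3 - s.volume_cm3) / s.volume_cm3
                worst[s.name] = max(worst.get(s.name, 0.0), pct)
        for s in structures:
            vol = s.volume_cm3
            tier = 0.5 if vol >= 90 else (2.0 if vol > 1 else 5.0)
            assert worst[s.name] <= tier, (s.name, vol, worst[s.name])

    def test_clipping_warns(self):
        occ = np.zeros((20, 20, 20), dtype=np.float32)
        occ[1:5, 8:12, 8:12] = 1.0
        s = rd.Structure("edge", "OAR", "sphere", occ, np.full(3, 2.0), np.zeros(3))
        t = rd.RigidTransform.from_angles(0, 0, 0, translation=(-10, 0, 0),
                                          isocenter=(20, 20, 20))
        with pytest.warns(UserWarning, match="clipping"):
            rd.transform_structure(s, t)
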