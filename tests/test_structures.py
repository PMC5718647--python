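"""Structure algebra: volumes, margins, trimming, validation tables."""

import numpy as np
import pytest

import rotodose as rd
from rotodose.structures import (StructureSet, expand_margin, reports_to_frame,
                                 trim_overlap, volume, volume_difference_table)


def box_structure(occ, spacing=(1.0, 1.0, 2.0), name="s", role="OAR"):
    return rd.Structure(name=name, role=role, shape_class="sphere",
                        occupancy=np.asarray(occ, dtype=float),
                        spacing=np.asarray(spacing, dtype=float), origin=np.zeros(3))


class TestVolume:
    def test_single_voxel_volume(self):
        occ = np.zeros((3, 3, 3))
        occ[1, 1, 1] = 1.0
        assert np.isclose(volume(box_structure(occ)), 0.002)  # 1x1x2 mm = 0.002 cm^3

    def test_fractional_occupancy_weighted(self):
        occ = np.zeros((3, 3, 3))
        occ[0, 0, 0] = 0.25
        occ[1, 1, 1] = 0.75
        assert np.isclose(volume(box_structure(occ)), 0.002)

    def test_analytic_sphere_volume(self):
        # 100 cm^3 sphere: radius (3V/4pi)^(1/3) = 28.8 mm
        s = rd.make_structure("sphere", 100.0, seed=7, spacing=(1.0, 1.0, 2.0),
                              grid_shape=(96, 96, 48))
        assert abs(s.volume_cm3 - 100.0) / 100.0 < 0.005
        # radius check along the lateral axis through the center
        c_idx = np.round((s.centroid() - s.origin) / s.spacing).astype(int)
        row = s.occupancy[:, c_idx[1], c_idx[2]]
        crossing = np.where(row >= 0.5)[0]
        radius = (crossing[-1] - c_idx[0]) * s.spacing[0]
        assert abs(radius - 28.8) <= s.spacing[0]

    def test_empty_structure_warns_zero(self):
        with pytest.warns(UserWarning, match="empty"):
            assert volume(box_structure(np.zeros((3, 3, 3)))) == 0.0


class TestExpandMargin:
    def test_zero_margin_is_identity(self):
        s = rd.make_structure("sphere", 33.5, seed=2, spacing=(2, 2, 2),
                              grid_shape=(64, 64, 64))
        out = expand_margin(s, 0.0)
        assert abs(out.volume_cm3 - s.volume_cm3) / s.volume_cm3 < 0.001

    def test_sphere_margin_volume_ratio(self):
        # r=20 mm sphere (33.51 cm^3) + 3 mm -> volume ratio (23/20)^3 = 1.521
        target = 4.0 / 3.0 * np.pi * 20.0 ** 3 / 1000.0
        s = rd.make_structure("sphere", target, seed=2, spacing=(1.0, 1.0, 2.0),
                              grid_shape=(128, 128, 64))
        out = expand_margin(s, 3.0)
        ratio = out.volume_cm3 / s.volume_cm3
        assert abs(ratio - 1.521) / 1.521 < 0.02

    def test_expansion_is_superset_and_monotone(self):
        s = rd.make_structure("irregular", 40.0, seed=5, spacing=(2, 2, 2),
                              grid_shape=(64, 64, 64))
        m2 = expand_margin(s, 2.0)
        m4 = expand_margin(s, 4.0)
        assert np.all(m2.occupancy >= s.occupancy - 1e-6)
        assert np.all(m4.occupancy >= m2.occupancy - 1e-6)

    def test_expansion_beyond_grid_rejected(self):
        s = rd.make_structure("sphere", 30.0, seed=1, spacing=(2, 2, 2),
                              grid_shape=(22, 22, 22))
        with pytest.raises(ValueError, match="boundary"):
            expand_margin(s, 8.0)

    def test_negative_margin_rejected(self):
        s = rd.make_structure("sphere", 10.0, seed=1, spacing=(2, 2, 2),
                              grid_shape=(32, 32, 32))
        with pytest.raises(ValueError):
            expand_margin(s, -1.0)


class TestTrimOverlap:
    def test_disjoint_inputs_unchanged(self):
        ptv = np.zeros((10, 10, 10))
        ptv[2:5, 2:5, 2:5] = 1.0
        oar = np.zeros((10, 10, 10))
        oar[7:9, 7:9, 7:9] = 1.0
        out = trim_overlap(box_structure(ptv, name="PTV", role="PTV"),
                           [box_structure(oar, name="oar")])
        assert np.array_equal(out.occupancy, ptv)

    def test_constructed_fractional_overlap_subtracted_exactly(self):
        spacing = (1.0, 1.0, 2.0)  # voxel 0.002 cm^3
        ptv = np.zeros((20, 20, 20))
        ptv[2:12, 2:12, 2:12] = 1.0
        oar = np.zeros((20, 20, 20))
        # engineered overlap: 617 voxels at occupancy 1.0 -> 1.234 cm^3
        flat = oar[2:12, 2:12, 2:12].reshape(-1)
        flat[:617] = 1.0
        oar[2:12, 2:12, 2:12] = flat.reshape(10, 10, 10)
        p = box_structure(ptv, spacing, name="PTV", role="PTV")
        out = trim_overlap(p, [box_structure(oar, spacing, name="oar")])
        assert abs(out.volume_cm3 - (p.volume_cm3 - 1.234)) < 1e-6

    def test_no_residual_fractional_overlap(self):
        rng = np.random.default_rng(0)
        ptv = rng.uniform(0, 1, (12, 12, 12))
        oar = rng.uniform(0, 1, (12, 12, 12))
        out = trim_overlap(box_structure(ptv, name="PTV", role="PTV"),
                           [box_structure(oar, name="oar")])
        assert np.all(out.occupancy + oar <= 1.0 + 1e-6)
        assert np.all(out.occupancy <= ptv + 1e-6)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        ptv = box_structure(rng.uniform(0, 1, (8, 8, 8)), name="PTV", role="PTV")
        oars = [box_structure(rng.uniform(0, 1, (8, 8, 8)), name="oar")]
        once = trim_overlap(ptv, oars)
        twice = trim_overlap(once, oars)
        assert np.allclose(once.occupancy, twice.occupancy, atol=1e-7)


class TestVolumeDifferenceTable:
    def test_identity_comparison_all_zero(self, fast_phantom):
        _, structures, _ = fast_phantom
        rows = volume_difference_table(structures, structures)
        assert len(rows) == len(structures)
        assert all(r.absolute_difference_cm3 == 0 for r in rows)
        assert all(r.percent_difference == 0 for r in rows)

    def test_row_matches_independent_voxel_recount(self, fast_phantom):
        _, structures, isocenter = fast_phantom
        t = rd.RigidTransform.from_angles(5, 5, 5, (1, 1, 1), isocenter)
        moved = StructureSet([rd.transform_structure(s, t) for s in structures])
        rows = volume_difference_table(structures, moved)
        row = next(r for r in rows if r.name == "brain_stem")
        # independent recount: direct voxel summation, no library volume call
        vox = float(np.prod(structures["brain_stem"].spacing)) / 1000.0
        v0 = float(structures["brain_stem"].occupancy.astype(np.float64).sum()) * vox
        v1 = float(moved["brain_stem"].occupancy.astype(np.float64).sum()) * vox
        assert np.isclose(row.absolute_difference_cm3, abs(v1 - v0), atol=1e-9)
        assert np.isclose(row.percent_difference, 100 * abs(v1 - v0) / v0, atol=1e-9)

    def test_name_mismatch_rejected(self, fast_phantom):
        _, structures, _ = fast_phantom
        other = StructureSet([structures["CTV"].copy()])
        with pytest.raises(ValueError, match="differ"):
            volume_difference_table(structures, other)

    def test_frame_columns(self, fast_phantom):
        _, structures, _ = fast_phantom
        frame = reports_to_frame(volume_difference_table(structures, structures))
        assert list(frame.columns) == ["name", "original_cm3", "transformed_cm3",
                                       "absolute_difference_cm3", "percent_difference"]


class TestStructureSetIO:
    def test_manifest_round_trip(self, tmp_path, fast_phantom):
        _, structures, isocenter = fast_phantom
        sub = StructureSet([structures["CTV"], structures["cochlea"]])
        manifest = sub.save(tmp_path, isocenter=isocenter)
        loaded = StructureSet.load(manifest)
        assert loaded.names == sub.names
        for name in sub.names:
            assert np.allclose(loaded[name].occupancy, sub[name].occupancy, atol=1e-6)
            assert loaded[name].role == sub[name].role
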