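"""Architecture outcome measures: volume, bone length, pennation, PCSA."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import muscledti as m
from muscledti.architecture import _mode


def toy_roi(shape=(5, 5, 5), voxel=(1.0, 1.0, 1.0), endpoints=None):
    return m.MuscleROI(mask=np.ones(shape, dtype=bool), voxel_size=voxel,
                       affine=np.diag(list(voxel) + [1.0]),
                       bone_endpoints=endpoints)


class TestVolumeAndBone:
    def test_volume_is_count_times_voxel_volume(self):
        roi = toy_roi(shape=(10, 10, 1), voxel=(1.25, 1.25, 6.5))
        assert m.muscle_volume(roi) == pytest.approx(100 * 10.15625)

    def test_unit_voxel(self):
        roi = toy_roi(shape=(1, 1, 1))
        assert m.muscle_volume(roi) == pytest.approx(1.0)

    @pytest.mark.parametrize("p, q, expected", [
        ((0, 0, 0), (0, 0, 250.0), 250.0),
        ((3.0, 4.0, 0), (0, 0, 0), 5.0),
    ])
    def test_bone_length(self, p, q, expected):
        roi = toy_roi(endpoints=np.array([p, q], dtype=float))
        assert m.bone_length(roi) == pytest.approx(expected)

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=6,
                    max_size=6))
    def test_bone_length_matches_norm(self, coords):
        p = np.array(coords[:3])
        q = np.array(coords[3:])
        if np.allclose(p, q):
            return
        roi = toy_roi(endpoints=np.array([p, q]))
        assert m.bone_length(roi) == pytest.approx(
            float(np.sqrt(((p - q) ** 2).sum())), rel=1e-12)

    def test_coincident_endpoints_rejected(self):
        with pytest.raises(ValueError):
            toy_roi(endpoints=np.array([[1.0, 2, 3], [1.0, 2, 3]]))


class TestPennation:
    @pytest.fixture()
    def labelled_roi(self):
        # flat aponeurosis on top of a 9x9x9 cube
        shape = (9, 9, 9)
        mask = np.ones(shape, dtype=bool)
        roi = m.MuscleROI(mask=mask, voxel_size=(1.0, 1.0, 1.0),
                          affine=np.eye(4))
        apo = np.zeros(shape, dtype=bool)
        apo[:, :, -1] = True
        roi.aponeurosis_voxels = apo
        return roi

    def fascicle_at(self, angle_deg, length=8.0):
        th = math.radians(angle_deg)
        p0 = np.array([1.0, 4.0, 8.0])
        u = np.array([math.cos(th), 0.0, -math.sin(th)])
        pts = p0 + np.linspace(0, length, 9)[:, None] * u
        return m.Fascicle(points=pts, seed_voxel=(0, 0, 0), valid=True)

    @pytest.mark.parametrize("angle", [0.0, 15.0, 30.0, 90.0])
    def test_chord_angle_against_flat_plane(self, labelled_roi, angle):
        f = self.fascicle_at(angle)
        assert m.pennation_angle(f, labelled_roi) == pytest.approx(angle,
                                                                   abs=1e-6)

    def test_tangent_variant_agrees_on_straight_fascicle(self, labelled_roi):
        f = self.fascicle_at(20.0)
        chord = m.pennation_angle(f, labelled_roi, method="chord")
        tang = m.pennation_angle(f, labelled_roi, method="tangent")
        assert chord == pytest.approx(tang, abs=1e-9)

    def test_missing_labels_raise(self):
        roi = toy_roi()
        f = self.fascicle_at(10.0)
        with pytest.raises(ValueError, match="aponeurosis"):
            m.pennation_angle(f, roi)

    def test_phantom_recovery(self, raw_tracts15, phantom15):
        _, _, roi, truth = phantom15
        valid = m.filter_tracts(raw_tracts15, roi,
                                m.FilterConstraints(endpoint_pair=True))
        angles = [m.pennation_angle(f, roi) for f in valid.valid_fascicles]
        assert np.mean(angles) == pytest.approx(truth["pennation_deg"], abs=2.0)


class TestSummary:
    @pytest.mark.parametrize("vol, pen, length, expected", [
        (1000.0, 0.0, 10.0, 100.0),
        (1000.0, 60.0, 10.0, 50.0),
    ])
    def test_pcsa_formula(self, vol, pen, length, expected):
        assert vol * math.cos(math.radians(pen)) / length == pytest.approx(
            expected)

    def test_summary_on_phantom(self, raw_tracts15, phantom15):
        _, _, roi, truth = phantom15
        valid = m.filter_tracts(raw_tracts15, roi,
                                m.FilterConstraints(endpoint_pair=True))
        s = m.architecture_summary(valid, roi)
        # identity: stored PCSA re-derivable from the stored mu fields
        assert s.pcsa_mm2 == pytest.approx(
            s.muscle_volume_mm3 * math.cos(math.radians(s.mean_pennation_deg))
            / s.mean_length_mm, abs=1e-9)
        assert s.pcsa_mm2 == pytest.approx(truth["pcsa_mm2"], rel=0.10)
        assert s.normalized_length == pytest.approx(
            s.mean_length_mm / truth["bone_length_mm"], rel=1e-12)
        assert s.fascicle_count == len(valid.valid_fascicles)
        assert s.count_per_mm3 == pytest.approx(
            s.fascicle_count / s.muscle_volume_mm3)

    def test_normalized_length_halves_with_doubled_bone(self, raw_tracts15,
                                                        phantom15):
        spec, _, roi, _ = phantom15
        valid = m.filter_tracts(raw_tracts15, roi,
                                m.FilterConstraints(endpoint_pair=True))
        s1 = m.architecture_summary(valid, roi)
        roi2 = m.MuscleROI(
            mask=roi.mask, voxel_size=roi.voxel_size, affine=roi.affine,
            aponeurosis_voxels=roi.aponeurosis_voxels,
            deep_voxels=roi.deep_voxels,
            lateral_edge_voxels=roi.lateral_edge_voxels,
            bone_endpoints=np.array([[0.0, -15.0, 0.0], [500.0, -15.0, 0.0]]))
        s2 = m.architecture_summary(valid, roi2)
        assert s2.normalized_length == pytest.approx(s1.normalized_length / 2,
                                                     rel=1e-9)

    def test_median_and_mode_variants(self, raw_tracts15, phantom15):
        _, _, roi, truth = phantom15
        valid = m.filter_tracts(raw_tracts15, roi,
                                m.FilterConstraints(endpoint_pair=True))
        for stat in ("median", "mode"):
            s = m.architecture_summary(valid, roi, mu_statistic=stat)
            assert s.mean_length_mm == pytest.approx(
                truth["fascicle_length_mm"], rel=0.05)

    def test_zero_valid_fascicles_yields_nan_summary(self, phantom15):
        _, _, roi, _ = phantom15
        empty = m.FascicleSet(fascicles=[], muscle_name=roi.muscle_name,
                              params=m.TrackingParams())
        s = m.architecture_summary(empty, roi)
        assert s.fascicle_count == 0
        assert math.isnan(s.pcsa_mm2) and math.isnan(s.mean_length_mm)

    def test_mode_of_constant_sample(self):
        assert _mode(np.full(50, 3.7)) == pytest.approx(3.7)


class TestAggregate:
    def test_equal_volumes(self):
        out = m.aggregate_muscles([{"x": 10.0}, {"x": 20.0}], [5.0, 5.0])
        assert out["x"] == pytest.approx(15.0)

    def test_weighted(self):
        out = m.aggregate_muscles([{"x": 10.0}, {"x": 20.0}], [3.0, 1.0])
        assert out["x"] == pytest.approx(12.5)

    def test_single_muscle_identity(self):
        out = m.aggregate_muscles([{"x": 7.0, "name": "FCR"}], [4.0])
        assert out == {"x": 7.0}

    @given(st.lists(st.tuples(st.floats(0.1, 100), st.floats(0.1, 1e4)),
                    min_size=2, max_size=4))
    def test_matches_independent_weighted_mean(self, pairs):
        vals = [p[0] for p in pairs]
        vols = [p[1] for p in pairs]
        out = m.aggregate_muscles([{"x": v} for v in vals], vols)
        expected = sum(v * w for v, w in pairs) / sum(vols)
        assert out["x"] == pytest.approx(expected, rel=1e-9)

    def test_zero_total_volume_rejected(self):
        with pytest.raises(ValueError):
            m.aggregate_muscles([{"x": 1.0}], [0.0])
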