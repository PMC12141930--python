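"""Streamline propagation, termination rules and anatomical filtering."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import muscledti as m
from muscledti.tracking import _Grid, sample_orientation


def make_two_zone_field(angle_deg: float):
    """Uniform-fiber slab whose principal direction rotates by
    ``angle_deg`` (about y) halfway along x; isotropic voxels."""
    shape = (40, 9, 9)
    mask = np.zeros(shape, dtype=bool)
    mask[2:-2, 2:-2, 2:-2] = True
    affine = np.eye(4)
    evecs = np.zeros(shape + (3, 3))
    th = math.radians(angle_deg)
    R1 = np.eye(3)
    R2 = np.array([[math.cos(th), 0, -math.sin(th)], [0, 1, 0],
                   [math.sin(th), 0, math.cos(th)]])
    evecs[: shape[0] // 2] = R1
    evecs[shape[0] // 2:] = R2
    evals = np.broadcast_to(np.array([2.1e-3, 1.6e-3, 1.6e-3]),
                            shape + (3,)).copy()
    field = m.TensorField(
        tensor=np.zeros(shape + (3, 3)), eigenvalues=evals,
        eigenvectors=evecs, s0=np.ones(shape),
        fit_ok=np.ones(shape, dtype=bool), affine=affine,
        voxel_size=(1.0, 1.0, 1.0))
    roi = m.MuscleROI(mask=mask, voxel_size=(1.0, 1.0, 1.0), affine=affine)
    return field, roi


class TestOrientation:
    def test_deterministic_mode_returns_v1(self):
        evecs = np.eye(3)
        d = sample_orientation(evecs, math.inf)
        assert np.allclose(d, [1.0, 0.0, 0.0])

    def test_sign_coherence_with_previous_direction(self):
        evecs = np.eye(3)
        d = sample_orientation(evecs, math.inf, prev_dir=np.array([-1.0, 0, 0]))
        assert np.allclose(d, [-1.0, 0.0, 0.0])

    def test_angular_spread_shrinks_with_kappa(self):
        evecs = np.eye(3)
        mu = evecs[:, 0]
        prev_dev = None
        for kappa in (5.0, 50.0, 500.0):
            rng = np.random.default_rng(12)
            devs = []
            for _ in range(2000):
                d = sample_orientation(evecs, kappa, rng, prev_dir=mu)
                devs.append(math.degrees(math.acos(min(1.0, abs(float(d @ mu))))))
            mean_dev = float(np.mean(devs))
            if prev_dev is not None:
                assert mean_dev < prev_dev
            prev_dev = mean_dev

    def test_probabilistic_mode_requires_rng(self):
        with pytest.raises(ValueError):
            sample_orientation(np.eye(3), 10.0)


class TestPropagate:
    def test_slab_transit_length(self):
        # fibers along z, slab 40 mm thick: track length = 40 +- one step
        spec = m.PhantomSpec(pennation_true=0.0,
                             muscle_extent=(40.0, 20.0, 13.0),
                             voxel_size=(1.0, 1.0, 1.0))
        tfield, roi, truth = m.make_phantom(spec)
        params = m.TrackingParams()
        center = np.array([20.0, 10.0, 6.5])
        f = m.propagate(center, tfield, roi, params)
        assert abs(f.length_mm - 40.0) <= params.step_mm

    def test_turning_angle_terminates_at_interface(self):
        # fiber axes are sign-symmetric, so an orientation change of 60
        # degrees is the effective turn; a 45-degree cap terminates at the
        # interface while a 90-degree cap lets the track bend through
        field, roi = make_two_zone_field(60.0)
        tight = m.TrackingParams(step_mm=0.5, max_turn_deg=45.0)
        f = m.propagate(np.array([10.0, 4.0, 4.0]), field, roi, tight)
        assert f.points[:, 0].max() < 20.2
        loose = m.TrackingParams(step_mm=0.5, max_turn_deg=90.0)
        f2 = m.propagate(np.array([10.0, 4.0, 4.0]), field, roi, loose)
        assert f2.points[:, 0].max() > 20.2

    def test_step_length_conserved(self, raw_tracts15):
        params = raw_tracts15.params
        for f in list(raw_tracts15)[::50]:
            seg = np.linalg.norm(np.diff(f.points, axis=0), axis=1)
            if len(seg) > 2:
                # all but the two (possibly clipped) terminal segments
                assert np.allclose(seg[1:-1], params.step_mm, atol=1e-6)
                assert np.all(seg <= params.step_mm + 1e-6)

    def test_fa_floor_never_terminates(self, fitted15):
        fit, roi, _ = fitted15
        # fa_min = 0 cannot terminate (FA >= 0 everywhere)
        p0 = m.TrackingParams(fa_min=0.0)
        p1 = m.TrackingParams(fa_min=0.99)
        seed = roi.voxel_centers_world()[roi.mask.sum() // 2]
        long = m.propagate(seed, fit, roi, p0)
        short = m.propagate(seed, fit, roi, p1)
        assert long.length_mm > 0
        assert short.points.shape[0] == 1  # FA below threshold at the seed

    def test_seed_outside_mask_rejected(self, fitted15):
        fit, roi, _ = fitted15
        with pytest.raises(ValueError, match="outside"):
            m.propagate(np.array([-50.0, -50.0, -50.0]), fit, roi,
                        m.TrackingParams())


class TestTrackMuscle:
    def test_one_tract_per_seed(self, raw_tracts15, phantom15):
        _, _, roi, _ = phantom15
        assert len(raw_tracts15) == int(roi.mask.sum())
        assert all(f.valid is None for f in raw_tracts15)

    def test_multiplicity(self, fitted15):
        fit, roi, _ = fitted15
        params = m.TrackingParams(kappa=50.0, n_samples_per_seed=3, seed=7,
                                  max_steps=20)
        fs = m.track_muscle(fit, roi, params)
        assert len(fs) == 3 * int(roi.mask.sum())

    def test_reproducibility_bit_identical(self, fitted15):
        fit, roi, _ = fitted15
        params = m.TrackingParams(kappa=100.0, seed=21, max_steps=40)
        a = m.track_muscle(fit, roi, params)
        b = m.track_muscle(fit, roi, params)
        assert len(a) == len(b)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.points, fb.points)


class TestFilter:
    def test_boundary_contact_mandatory(self, fitted15, phantom15):
        _, _, roi, _ = phantom15
        fit, _, _ = fitted15
        # a short interior stub never reaches the boundary
        center = roi.voxel_centers_world()[roi.mask.sum() // 2]
        stub = m.Fascicle(points=np.array([center, center + [0.3, 0, 0]]),
                          seed_voxel=(0, 0, 0))
        fs = m.FascicleSet(fascicles=[stub], muscle_name="x",
                           params=m.TrackingParams())
        out = m.filter_tracts(fs, roi, m.FilterConstraints())
        # in a thin slab every point is near the boundary shell, so build a
        # fat isotropic ROI for a genuine interior test
        big = np.zeros((21, 21, 21), dtype=bool)
        big[2:-2, 2:-2, 2:-2] = True
        roi_big = m.MuscleROI(mask=big, voxel_size=(1.0, 1.0, 1.0),
                              affine=np.eye(4))
        stub2 = m.Fascicle(points=np.array([[10.0, 10, 10], [10.3, 10, 10]]),
                           seed_voxel=(0, 0, 0))
        out2 = m.filter_tracts(
            m.FascicleSet(fascicles=[stub2], muscle_name="x",
                          params=m.TrackingParams()),
            roi_big, m.FilterConstraints())
        assert out2.fascicles[0].valid is False
        assert out2.fascicles[0].reject_reason == "no_boundary_contact"

    def test_all_transits_pass_boundary_only(self, raw_tracts15, phantom15):
        _, _, roi, _ = phantom15
        out = m.filter_tracts(raw_tracts15, roi, m.FilterConstraints())
        assert len(out.valid_fascicles) == len(raw_tracts15)

    def test_length_bounds_match_brute_force(self, raw_tracts15, phantom15):
        _, _, roi, _ = phantom15
        lengths = raw_tracts15.lengths()
        rng = np.random.default_rng(17)
        for _ in range(10):
            lo = float(rng.uniform(0, lengths.max()))
            hi = float(lo + rng.uniform(0, lengths.max()))
            out = m.filter_tracts(raw_tracts15, roi,
                                  m.FilterConstraints(min_len_mm=lo,
                                                      max_len_mm=hi))
            expected = int(np.sum((lengths >= lo) & (lengths <= hi)))
            assert len(out.valid_fascicles) == expected

    @given(st.floats(min_value=0.0, max_value=80.0),
           st.floats(min_value=0.0, max_value=40.0))
    def test_valid_count_monotone_in_min_length(self, lo, delta):
        lengths = self._cached_lengths()
        n_lo = int(np.sum(lengths >= lo))
        n_hi = int(np.sum(lengths >= lo + delta))
        assert n_hi <= n_lo

    def _cached_lengths(self):
        if not hasattr(TestFilter, "_lengths"):
            spec = m.PhantomSpec()
            tfield, roi, _ = m.make_phantom(spec)
            raw = m.track_muscle(tfield, roi, m.TrackingParams())
            TestFilter._lengths = raw.lengths()
            TestFilter._roi = roi
            TestFilter._raw = raw
        return TestFilter._lengths

    def test_monotonicity_through_filter_path(self):
        lengths = self._cached_lengths()
        roi, raw = TestFilter._roi, TestFilter._raw
        prev = len(raw) + 1
        for lo in (0.0, 10.0, 30.0, 50.0, 70.0):
            n = len(m.filter_tracts(
                raw, roi, m.FilterConstraints(min_len_mm=lo)).valid_fascicles)
            assert n <= prev
            prev = n

    def test_endpoint_pair_requires_labels(self, raw_tracts15):
        bare = m.MuscleROI(mask=TestFilter._roi.mask
                           if hasattr(TestFilter, "_roi") else
                           m.make_phantom(m.PhantomSpec())[1].mask,
                           voxel_size=(1.25, 1.25, 6.5), affine=np.eye(4))
        with pytest.raises(ValueError, match="labels"):
            m.filter_tracts(raw_tracts15, bare,
                            m.FilterConstraints(endpoint_pair=True))

    def test_endpoint_pair_keeps_full_transits_only(self, raw_tracts15,
                                                    phantom15):
        _, _, roi, truth = phantom15
        out = m.filter_tracts(raw_tracts15, roi,
                              m.FilterConstraints(endpoint_pair=True))
        valid = out.valid_fascicles
        assert 0 < len(valid) < len(raw_tracts15)
        lengths = np.array([f.length_mm for f in valid])
        assert np.allclose(lengths, truth["fascicle_length_mm"], atol=1.0)
        reasons = {f.reject_reason for f in out.fascicles if not f.valid}
        assert reasons == {"endpoint_pair"}
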