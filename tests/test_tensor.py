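"""Tensor estimation and diffusivity scalars."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

import muscledti as m
from muscledti.gradients import TWELVE_DIRECTIONS


def random_spd_tensors(n, rng, scale=1e-3):
    """Random symmetric positive-definite tensors at muscle-like magnitude."""
    A = rng.normal(size=(n, 3, 3))
    D = np.einsum("nij,nkj->nik", A, A)
    # normalise trace to ~3*scale with some spread
    tr = np.trace(D, axis1=1, axis2=2)
    return D * (scale * rng.uniform(1.5, 4.5, n) / tr)[:, None, None]


def signal_from_tensor(D, scheme, s0=1000.0):
    quad = np.einsum("kq,qr,kr->k", scheme.bvecs, D, scheme.bvecs)
    return s0 * np.exp(-scheme.bvals * quad)


def fit_single_tensor(sig, scheme):
    """WLLS fit of one voxel via the package path."""
    dwi = m.DWIVolume(signal=sig.reshape(1, 1, 1, -1), scheme=scheme,
                      voxel_size=(1.0, 1.0, 1.0), affine=np.eye(4))
    field = m.fit_tensor(dwi, np.ones((1, 1, 1), dtype=bool))
    return field.tensor[0, 0, 0], field

def nls_oracle(sig, scheme, x0=None):
    """Independent nonlinear least-squares fit in the signal domain."""
    A = scheme.design_matrix()

    def model(p):
        return np.exp(A @ p)

    if x0 is None:
        x0 = np.linalg.lstsq(A, np.log(sig), rcond=None)[0]
    res = least_squares(lambda p: model(p) - sig, x0, method="lm",
                        xtol=1e-15, ftol=1e-15, gtol=1e-15)
    p = res.x
    D = np.array([[p[1], p[4], p[5]],
                  [p[4], p[2], p[6]],
                  [p[5], p[6], p[3]]])
    return D


class TestFit:
    def test_noiseless_recovery_exact(self, fitted15, phantom15):
        _, tfield_true, roi, _ = phantom15
        fit, _, _ = fitted15
        sel = roi.mask
        rel = np.abs(fit.tensor[sel] - tfield_true.tensor[sel]).max() \
            / np.abs(tfield_true.tensor[sel]).max()
        assert rel < 1e-8
        assert fit.fit_ok[sel].all()

    def test_isotropic_fit_has_zero_fa(self):
        scheme = m.default_scheme()
        D = 1.7e-3 * np.eye(3)
        sig = signal_from_tensor(D, scheme)
        _, field = fit_single_tensor(sig, scheme)
        fa = m.diffusivity_metrics(field.eigenvalues[0, 0, 0]).fa
        assert fa == pytest.approx(0.0, abs=1e-10)

    def test_wlls_matches_nls_oracle(self):
        # brute-force NLS is an independent estimator of the same model
        scheme = m.default_scheme()
        rng = np.random.default_rng(42)
        tensors = random_spd_tensors(25, rng)
        for D in tensors:
            sig = signal_from_tensor(D, scheme)
            D_wlls, _ = fit_single_tensor(sig, scheme)
            D_nls = nls_oracle(sig, scheme)
            rel = np.abs(D_wlls - D_nls).max() / np.abs(D).max()
            assert rel < 1e-6

    def test_rotational_invariance(self):
        # rotating gradients and tensor together leaves the scalars unchanged
        scheme = m.default_scheme()
        rng = np.random.default_rng(3)
        D = random_spd_tensors(1, rng)[0]
        R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
        scheme_rot = m.GradientScheme(bvals=scheme.bvals,
                                      bvecs=scheme.bvecs @ R.T,
                                      n_averages=scheme.n_averages)
        sig = signal_from_tensor(D, scheme)
        sig_rot = signal_from_tensor(R @ D @ R.T, scheme_rot)
        _, f1 = fit_single_tensor(sig, scheme)
        _, f2 = fit_single_tensor(sig_rot, scheme_rot)
        m1 = m.diffusivity_metrics(f1.eigenvalues[0, 0, 0])
        m2 = m.diffusivity_metrics(f2.eigenvalues[0, 0, 0])
        for k in ("fa", "md", "ad", "rd"):
            assert getattr(m1, k) == pytest.approx(getattr(m2, k), abs=1e-8)

    def test_nonpositive_signal_flagged_not_raised(self):
        scheme = m.default_scheme()
        sig = np.zeros((2, 1, 1, scheme.n_volumes))
        sig[0, 0, 0] = signal_from_tensor(1.7e-3 * np.eye(3), scheme)
        dwi = m.DWIVolume(signal=sig, scheme=scheme, voxel_size=(1, 1, 1),
                          affine=np.eye(4))
        field = m.fit_tensor(dwi, np.ones((2, 1, 1), dtype=bool))
        assert field.fit_ok[0, 0, 0]
        assert not field.fit_ok[1, 0, 0]

    def test_minimum_volume_count(self):
        # 7 volumes (6 directions + 1 b=0) is the fit's minimum and works;
        # schemes with fewer directions are rejected at construction
        scheme = m.GradientScheme(
            bvals=np.array([0.0] + [400.0] * 6),
            bvecs=np.vstack([np.zeros(3), TWELVE_DIRECTIONS[:6]]))
        D = random_spd_tensors(1, np.random.default_rng(0))[0]
        sig = signal_from_tensor(D, scheme)
        D_fit, _ = fit_single_tensor(sig, scheme)
        assert np.abs(D_fit - D).max() / np.abs(D).max() < 1e-8


class TestScalars:
    @pytest.mark.parametrize("ev, expected", [
        ((1.7e-3,) * 3, dict(fa=0.0, md=1.7e-3, ad=1.7e-3, rd=1.7e-3)),
        ((1.7e-3, 0.0, 0.0), dict(fa=1.0, md=1.7e-3 / 3, ad=1.7e-3, rd=0.0)),
        ((2.1e-3, 1.6e-3, 1.6e-3),
         dict(fa=0.16197, md=1.76667e-3, ad=2.1e-3, rd=1.6e-3)),
    ])
    def test_closed_forms(self, ev, expected):
        got = m.diffusivity_metrics(np.array(ev))
        for k, v in expected.items():
            assert getattr(got, k) == pytest.approx(v, rel=1e-4)

    def test_zero_tensor_fa_defined_as_zero(self):
        got = m.diffusivity_metrics(np.zeros(3))
        assert got.fa == 0.0 and got.md == 0.0

    @given(st.lists(st.floats(min_value=-1e-3, max_value=5e-3), min_size=3,
                    max_size=3))
    def test_identities_on_arbitrary_triples(self, ev):
        ev = np.sort(np.asarray(ev))[::-1]
        got = m.diffusivity_metrics(ev)
        assert 0.0 <= got.fa <= 1.0
        assert got.md == pytest.approx((got.ad + 2 * got.rd) / 3, abs=1e-12)
        assert got.ad >= got.rd

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_fa_scale_invariant(self, c):
        ev = np.array([2.1e-3, 1.6e-3, 1.1e-3])
        assert m.diffusivity_metrics(ev).fa == pytest.approx(
            m.diffusivity_metrics(c * ev).fa, rel=1e-9)


class TestWholeVolume:
    def test_uniform_field_mean_equals_voxel(self, fitted15, phantom15):
        _, _, roi, _ = phantom15
        fit, _, _ = fitted15
        wv = m.whole_volume_metrics(fit, roi)
        vox = m.diffusivity_metrics(fit.eigenvalues[roi.mask][0])
        for k in ("fa", "md", "ad", "rd"):
            assert getattr(wv, k) == pytest.approx(getattr(vox, k), rel=1e-9)

    def test_mean_of_mixed_fas(self):
        # construct a field with half FA=a, half FA=b by hand
        shape = (2, 1, 1)
        evals = np.zeros(shape + (3,))
        evals[0, 0, 0] = [2.0e-3, 2.0e-3, 2.0e-3]     # FA 0
        evals[1, 0, 0] = [2.0e-3, 0.0, 0.0]           # FA 1
        field = m.TensorField(
            tensor=np.zeros(shape + (3, 3)), eigenvalues=evals,
            eigenvectors=np.broadcast_to(np.eye(3), shape + (3, 3)).copy(),
            s0=np.ones(shape), fit_ok=np.ones(shape, dtype=bool),
            affine=np.eye(4), voxel_size=(1, 1, 1))
        roi = m.MuscleROI(mask=np.ones(shape, dtype=bool),
                          voxel_size=(1, 1, 1), affine=np.eye(4))
        assert m.whole_volume_metrics(field, roi).fa == pytest.approx(0.5)

    def test_md_identity_survives_averaging(self, fitted15, phantom15):
        _, _, roi, _ = phantom15
        fit, _, _ = fitted15
        wv = m.whole_volume_metrics(fit, roi)
        assert wv.md == pytest.approx((wv.ad + 2 * wv.rd) / 3, abs=1e-12)

    def test_noisy_phantom_md_close_to_truth(self):
        spec = m.PhantomSpec(snr=30.0, seed=9)
        tfield, roi, _ = m.make_phantom(spec)
        dwi = m.simulate_dwi(tfield, roi, m.default_scheme(), snr=30.0, seed=9)
        fit = m.fit_tensor(dwi, roi.mask)
        wv = m.whole_volume_metrics(fit, roi)
        md_true = np.mean(spec.eigenvalues_true)
        assert abs(wv.md - md_true) / md_true < 0.03

    def test_empty_usable_mask_raises(self, fitted15):
        fit, roi, _ = fitted15
        empty = m.MuscleROI(mask=np.ones(roi.mask.shape, dtype=bool),
                            voxel_size=roi.voxel_size, affine=roi.affine)
        fit_bad = m.TensorField(
            tensor=fit.tensor, eigenvalues=fit.eigenvalues,
            eigenvectors=fit.eigenvectors, s0=fit.s0,
            fit_ok=np.zeros(fit.shape, dtype=bool),
            affine=fit.affine, voxel_size=fit.voxel_size)
        with pytest.raises(ValueError):
            m.whole_volume_metrics(fit_bad, empty)
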