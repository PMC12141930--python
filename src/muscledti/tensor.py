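"""Per-voxel diffusion tensor estimation and diffusivity scalars.

The estimator is a two-pass weighted linear least squares (WLLS) on the
log signal: an ordinary least-squares pass initialises the tensor, then
one reweighting pass with weights equal to the squared predicted signal
corrects the log-transform noise heteroscedasticity.  This is the
standard deterministic DTI estimator; with noiseless data it inverts the
mono-exponential model exactly.

Scalars follow the usual eigenvalue formulas: MD = mean(lambda),
AD = lambda1, RD = (lambda2 + lambda3)/2, and
FA = sqrt(3/2) * ||lambda - MD|| / ||lambda||.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:
    from .phantom import DWIVolume
    from .roi import MuscleROI


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensor with sorted eigensystem.

    ``eigenvalues[..., i]`` are sorted descending (lambda1 >= lambda2 >=
    lambda3); ``eigenvectors[..., :, i]`` is the unit eigenvector paired
    with ``eigenvalues[..., i]``.  ``spd`` marks voxels whose fitted
    tensor was positive definite before clamping; ``fit_ok`` marks voxels
    where the fit was attempted and produced finite numbers.
    """

    tensor: np.ndarray         # (X, Y, Z, 3, 3), mm2/s
    eigenvalues: np.ndarray    # (X, Y, Z, 3)
    eigenvectors: np.ndarray   # (X, Y, Z, 3, 3), columns are eigenvectors
    s0: np.ndarray             # (X, Y, Z)
    fit_ok: np.ndarray         # (X, Y, Z) bool
    affine: np.ndarray
    voxel_size: tuple
    spd: np.ndarray | None = None

    def __post_init__(self):
        if self.spd is None:
            self.spd = self.eigenvalues[..., 2] > 0
        self._fa_map = None

    @property
    def shape(self):
        return self.s0.shape

    @property
    def fa_map(self) -> np.ndarray:
        """Cached per-voxel FA (zero where fit_ok is False)."""
        if self._fa_map is None:
            fa = diffusivity_metrics(self.eigenvalues).fa
            fa = np.where(self.fit_ok, fa, 0.0)
            self._fa_map = fa
        return self._fa_map

    def principal_direction(self, ijk) -> np.ndarray:
        return self.eigenvectors[tuple(ijk)][:, 0]


@dataclass
class DiffusivityMetrics:
    """FA (unitless) and MD/AD/RD (mm2/s); scalar or voxel-wise arrays."""

    fa: np.ndarray | float
    md: np.ndarray | float
    ad: np.ndarray | float
    rd: np.ndarray | float

    def as_dict(self) -> dict:
        return {k: (float(v) if np.ndim(v) == 0 else v)
                for k, v in (("fa", self.fa), ("md", self.md),
                             ("ad", self.ad), ("rd", self.rd))}


def diffusivity_metrics(eigenvalues: np.ndarray) -> DiffusivityMetrics:
    """Diffusivity scalars from (possibly batched) sorted eigenvalue triples.

    Negative eigenvalues (non-positive-definite fits) are clamped to zero
    before evaluation; the all-zero triple yields FA = 0 by convention.
    """
    ev = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    if ev.shape[-1] != 3:
        raise ValueError("eigenvalues must have trailing dimension 3")
    md = ev.mean(axis=-1)
    ad = ev[..., 0]
    rd = 0.5 * (ev[..., 1] + ev[..., 2])
    norm = np.sqrt((ev ** 2).sum(axis=-1))
    dev = np.sqrt(((ev - md[..., None]) ** 2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * np.where(norm > 0, dev / np.where(norm > 0, norm, 1.0), 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    if np.ndim(eigenvalues) == 1:
        return DiffusivityMetrics(float(fa), float(md), float(ad), float(rd))
    return DiffusivityMetrics(fa, md, ad, rd)


def _solve_wls(A: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Batched weighted LS: solve (A' W A) beta = A' W y per row of y.

    A is (K, 7), y and w are (n, K); returns (n, 7).
    """
    AtWA = np.einsum("nk,ki,kj->nij", w, A, A)
    AtWy = np.einsum("nk,ki->ni", w * y, A)
    return np.linalg.solve(AtWA, AtWy[..., None])[..., 0]


def fit_tensor(dwi: "DWIVolume", mask: np.ndarray) -> TensorField:
    """Fit the diffusion tensor in every masked voxel.

    Voxels containing non-positive signal in any volume are flagged
    ``fit_ok = False`` and skipped rather than raising.  Requires at
    least 7 volumes (>= 6 unique directions plus b = 0, enforced by the
    gradient scheme).
    """
    scheme = dwi.scheme
    if scheme.n_volumes < 7:
        raise ValueError(
            f"need >= 7 volumes to fit a tensor, got {scheme.n_volumes}"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.signal.shape[:3]:
        raise ValueError("mask grid does not match DWI grid")

    A = scheme.design_matrix()
    shape = dwi.signal.shape[:3]
    sig = dwi.signal[mask]                      # (n, K)
    usable = np.all(sig > 0, axis=1) & np.all(np.isfinite(sig), axis=1)

    beta = np.zeros((sig.shape[0], 7))
    if usable.any():
        y = np.log(sig[usable])
        # pass 1: OLS on log signal
        b0, *_ = np.linalg.lstsq(A, y.T, rcond=None)
        b0 = b0.T
        # pass 2: reweight with squared predicted signal
        w = np.exp(2.0 * (b0 @ A.T))
        b1 = _solve_wls(A, y, w)
        good = np.all(np.isfinite(b1), axis=1)
        b1[~good] = b0[~good]
        beta[usable] = b1
        usable_idx = np.flatnonzero(usable)
        usable[usable_idx] &= np.all(np.isfinite(beta[usable_idx]), axis=1)

    # assemble symmetric tensors
    n = sig.shape[0]
    D = np.zeros((n, 3, 3))
    D[:, 0, 0] = beta[:, 1]
    D[:, 1, 1] = beta[:, 2]
    D[:, 2, 2] = beta[:, 3]
    D[:, 0, 1] = D[:, 1, 0] = beta[:, 4]
    D[:, 0, 2] = D[:, 2, 0] = beta[:, 5]
    D[:, 1, 2] = D[:, 2, 1] = beta[:, 6]

    evals, evecs = np.linalg.eigh(D)            # ascending
    evals = evals[:, ::-1]
    evecs = evecs[:, :, ::-1]

    field_tensor = np.zeros(shape + (3, 3))
    field_evals = np.zeros(shape + (3,))
    field_evecs = np.zeros(shape + (3, 3))
    field_evecs[..., 0, 0] = field_evecs[..., 1, 1] = field_evecs[..., 2, 2] = 1.0
    field_s0 = np.zeros(shape)
    fit_ok = np.zeros(shape, dtype=bool)

    field_tensor[mask] = D
    field_evals[mask] = evals
    field_evecs[mask] = evecs
    field_s0[mask] = np.exp(beta[:, 0])
    fit_ok[mask] = usable

    return TensorField(
        tensor=field_tensor,
        eigenvalues=field_evals,
        eigenvectors=field_evecs,
        s0=field_s0,
        fit_ok=fit_ok,
        affine=dwi.affine,
        voxel_size=dwi.voxel_size,
        spd=fit_ok & (field_evals[..., 2] > 0),
    )


def whole_volume_metrics(tfield: TensorField, roi: "MuscleROI") -> DiffusivityMetrics:
    """Unweighted mean of each per-voxel scalar over successfully fitted
    muscle voxels (no further volume normalisation)."""
    if roi.mask.shape != tfield.shape:
        raise ValueError("ROI grid does not match tensor field grid")
    sel = roi.mask & tfield.fit_ok
    if not sel.any():
        raise ValueError("no successfully fitted voxels inside the ROI")
    per_voxel = diffusivity_metrics(tfield.eigenvalues[sel])
    return DiffusivityMetrics(
        fa=float(np.mean(per_voxel.fa)),
        md=float(np.mean(per_voxel.md)),
        ad=float(np.mean(per_voxel.ad)),
        rd=float(np.mean(per_voxel.rd)),
    )
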