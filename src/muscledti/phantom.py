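"""Unipennate muscle phantoms with closed-form architecture, and Rician
DWI simulation from them.

The phantom is a rectangular muscle slab.  World axes: x runs along the
muscle line of action, y across it, z through the muscle depth.  The
aponeurosis is the top face of the slab (largest z), the deep surface
the bottom face.  Fibers are straight lines in the x-z plane at the
pennation angle theta to the aponeurosis plane, so the fiber unit vector
is (cos theta, 0, sin theta) and a fiber spanning the full depth T has
length T / sin(theta); at theta = 0 fibers run the slab's x extent.

These closed forms give every downstream stage an analytic acceptance
surface: muscle volume, mean fascicle length, pennation angle, and PCSA
are all known exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .gradients import GradientScheme
from .roi import MuscleROI
from .tensor import TensorField

#: literature-typical skeletal-muscle tensor eigenvalues, mm2/s
DEFAULT_EIGENVALUES = (2.1e-3, 1.6e-3, 1.6e-3)

#: background (non-muscle) voxels carry an isotropic signal at this
#: fraction of the muscle S0, so that boundary termination is exercised
#: by signal and not only by the mask
BACKGROUND_S0_FRACTION = 0.1

_PAD = 2  # background voxels padded around the slab on every axis


@dataclass
class PhantomSpec:
    """Geometry, microstructure and acquisition noise of a slab phantom.

    ``muscle_extent`` is the (x, y, z) slab size in mm; ``thickness_true``
    is the deep-surface-to-aponeurosis distance (<= extent z).
    ``snr`` is S0 over the Rician channel noise sigma; ``math.inf``
    means noiseless.
    """

    muscle_extent: tuple = (60.0, 20.0, 13.0)
    pennation_true: float = 15.0            # degrees
    thickness_true: float = 13.0            # mm
    eigenvalues_true: tuple = DEFAULT_EIGENVALUES
    s0: float = 1000.0
    voxel_size: tuple = (1.25, 1.25, 6.5)
    bone_endpoints: tuple = ((0.0, -15.0, 0.0), (250.0, -15.0, 0.0))
    snr: float = math.inf
    seed: int = 0
    muscle_name: str = "phantom"

    def __post_init__(self):
        ev = tuple(float(v) for v in self.eigenvalues_true)
        if not (ev[0] >= ev[1] >= ev[2] > 0):
            raise ValueError("eigenvalues must be sorted descending and positive")
        self.eigenvalues_true = ev
        if not (0.0 <= self.pennation_true < 90.0):
            raise ValueError("pennation must lie in [0, 90) degrees")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(e <= 0 for e in self.muscle_extent):
            raise ValueError("muscle extent must be positive")
        if self.thickness_true <= 0 or self.thickness_true > self.muscle_extent[2]:
            raise ValueError("thickness must be positive and <= depth extent")
        if self.s0 <= 0:
            raise ValueError("s0 must be positive")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    # -- closed-form architecture ------------------------------------------
    @property
    def fiber_direction(self) -> np.ndarray:
        th = math.radians(self.pennation_true)
        return np.array([math.cos(th), 0.0, math.sin(th)])

    @property
    def fascicle_length_true(self) -> float:
        if self.pennation_true == 0.0:
            return float(self.muscle_extent[0])
        return self.thickness_true / math.sin(math.radians(self.pennation_true))

    @property
    def volume_true(self) -> float:
        ex = self.muscle_extent
        return float(ex[0] * ex[1] * self.thickness_true)

    @property
    def pcsa_true(self) -> float:
        th = math.radians(self.pennation_true)
        return self.volume_true * math.cos(th) / self.fascicle_length_true

    def validate_geometry(self):
        diag = math.sqrt(sum(e * e for e in self.muscle_extent))
        if self.fascicle_length_true > diag + 1e-9:
            raise ValueError(
                f"fascicle length {self.fascicle_length_true:.1f} mm exceeds "
                f"slab diagonal {diag:.1f} mm; no fiber fits the slab"
            )


def _slab_grid(spec: PhantomSpec):
    """Voxel grid with the slab at world [0, extent) and _PAD background
    voxels around it.  Returns (shape, affine, mask)."""
    vx = np.asarray(spec.voxel_size, dtype=float)
    extent = np.array([spec.muscle_extent[0], spec.muscle_extent[1],
                       spec.thickness_true])
    n_in = np.ceil(extent / vx - 1e-9).astype(int)
    shape = tuple(n_in + 2 * _PAD)
    affine = np.eye(4)
    affine[:3, :3] = np.diag(vx)
    affine[:3, 3] = (0.5 - _PAD) * vx
    ijk = np.indices(shape).reshape(3, -1).T
    centers = ijk * vx + affine[:3, 3]
    inside = np.all((centers >= 0) & (centers < extent - 1e-12), axis=1)
    mask = inside.reshape(shape)
    return shape, affine, mask


def make_phantom(spec: PhantomSpec):
    """Build the ground-truth tensor field, ROI and architecture record.

    Returns ``(field, roi, truth)`` where ``truth`` is a plain dict of the
    closed-form architecture values.
    """
    spec.validate_geometry()
    shape, affine, mask = _slab_grid(spec)

    # eigenbasis: v1 = fiber direction, v2 across the slab, v3 = v1 x v2
    v1 = spec.fiber_direction
    v2 = np.array([0.0, 1.0, 0.0])
    v3 = np.cross(v1, v2)
    R = np.column_stack([v1, v2, v3])
    lam = np.asarray(spec.eigenvalues_true)
    D_muscle = R @ np.diag(lam) @ R.T
    d_bg = float(lam.mean())

    tensor = np.empty(shape + (3, 3))
    tensor[...] = d_bg * np.eye(3)
    tensor[mask] = D_muscle
    evals = np.empty(shape + (3,))
    evals[...] = d_bg
    evals[mask] = lam
    evecs = np.empty(shape + (3, 3))
    evecs[...] = np.eye(3)
    evecs[mask] = R
    s0 = np.full(shape, spec.s0 * BACKGROUND_S0_FRACTION)
    s0[mask] = spec.s0

    tfield = TensorField(
        tensor=tensor, eigenvalues=evals, eigenvectors=evecs, s0=s0,
        fit_ok=np.ones(shape, dtype=bool), affine=affine,
        voxel_size=tuple(spec.voxel_size),
    )

    # label the boundary shell: aponeurosis = top-z face, deep = bottom-z
    roi = MuscleROI(mask=mask, voxel_size=tuple(spec.voxel_size),
                    affine=affine, muscle_name=spec.muscle_name,
                    bone_endpoints=np.asarray(spec.bone_endpoints))
    k = np.arange(shape[2])[None, None, :]
    top_face = np.zeros(shape, dtype=bool)
    bot_face = np.zeros(shape, dtype=bool)
    kmax = np.where(mask.any(axis=2), shape[2] - 1 - mask[:, :, ::-1].argmax(axis=2), -1)
    kmin = np.where(mask.any(axis=2), mask.argmax(axis=2), shape[2])
    top_face = mask & (k == kmax[..., None])
    bot_face = mask & (k == kmin[..., None])
    roi.aponeurosis_voxels = top_face
    roi.deep_voxels = bot_face
    roi.lateral_edge_voxels = roi.boundary_voxels & ~top_face & ~bot_face

    truth = {
        "pennation_deg": spec.pennation_true,
        "thickness_mm": spec.thickness_true,
        "fascicle_length_mm": spec.fascicle_length_true,
        "muscle_volume_mm3": spec.volume_true,
        "pcsa_mm2": spec.pcsa_true,
        "bone_length_mm": float(np.linalg.norm(
            np.asarray(spec.bone_endpoints[1]) - np.asarray(spec.bone_endpoints[0]))),
        "eigenvalues_mm2_per_s": list(spec.eigenvalues_true),
        "fiber_direction": v1.tolist(),
        "s0": spec.s0,
        "snr": None if math.isinf(spec.snr) else spec.snr,
    }
    return tfield, roi, truth


@dataclass
class DWIVolume:
    """4-D diffusion-weighted signal with its gradient scheme and geometry."""

    signal: np.ndarray          # (X, Y, Z, N)
    scheme: GradientScheme
    voxel_size: tuple
    affine: np.ndarray

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4-D")
        if self.signal.shape[3] != self.scheme.n_volumes:
            raise ValueError(
                f"signal has {self.signal.shape[3]} volumes but scheme has "
                f"{self.scheme.n_volumes}"
            )
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")


def simulate_dwi(tfield: TensorField, roi: MuscleROI, scheme: GradientScheme,
                 snr: float = math.inf, seed: int = 0) -> DWIVolume:
    """Simulate magnitude DWI from a tensor field.

    Per volume k the noiseless signal is S_k = S0 exp(-b_k g_k' D g_k).
    At finite ``snr`` each of the scheme's ``n_averages`` repeats (b > 0
    volumes only; b = 0 volumes are single acquisitions) receives Rician
    noise with channel sigma = S0_muscle / snr, and the noisy magnitudes
    are averaged, mirroring scanner magnitude averaging.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    if roi.mask.shape != tfield.shape:
        raise ValueError("ROI grid does not match tensor field grid")

    b, g = scheme.bvals, scheme.bvecs
    quad = np.einsum("kq,xyzqr,kr->xyzk", g, tfield.tensor, g)
    mean_signal = tfield.s0[..., None] * np.exp(-b * quad)

    if math.isinf(snr):
        signal = mean_signal
    else:
        rng = np.random.default_rng(seed)
        sigma = float(tfield.s0.max()) / snr
        signal = np.empty_like(mean_signal)
        for k in range(scheme.n_volumes):
            n_avg = scheme.n_averages if b[k] > 0 else 1
            s = mean_signal[..., k]
            acc = np.zeros_like(s)
            for _ in range(n_avg):
                re = s + rng.normal(0.0, sigma, s.shape)
                im = rng.normal(0.0, sigma, s.shape)
                acc += np.hypot(re, im)
            signal[..., k] = acc / n_avg

    return DWIVolume(signal=signal, scheme=scheme,
                     voxel_size=tfield.voxel_size, affine=tfield.affine)
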