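"""Diffusion gradient schemes.

The default scheme mirrors a standard skeletal-muscle DTI protocol:
10 b = 0 volumes plus 12 unique directions at b = 400 s/mm2, each
direction acquired with 3 averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 12 unit vectors obtained by minimising the antipodally-symmetric
# electrostatic energy sum(1/|gi-gj|^2 + 1/|gi+gj|^2) on the sphere
# (L-BFGS from a golden-spiral start, signs folded to the upper
# hemisphere).  Minimum inter-direction angle 38.9 degrees; the
# [1, b gg^T] tensor design matrix together with the b=0 rows has
# condition number ~2.5e2.
TWELVE_DIRECTIONS = np.array(
    [
        [0.9846954350, 0.1240278539, 0.1224417890],
        [-0.7145254318, -0.6253655936, 0.3136419640],
        [0.1470425843, 0.9691232990, 0.1979356203],
        [0.5802602760, -0.7942514163, 0.1801740821],
        [-0.8758005662, 0.3665606773, 0.3140169393],
        [0.6315169377, 0.5760347787, 0.5190089510],
        [-0.0632910866, -0.8708653568, 0.4874297577],
        [-0.3473308465, 0.7040272599, 0.6194407965],
        [0.7020787220, -0.2454184236, 0.6684723371],
        [-0.5926821353, -0.0764216775, 0.8018027274],
        [0.1372140689, 0.3109444284, 0.9404710850],
        [0.0455045128, -0.3802164975, 0.9237774377],
    ]
)


@dataclass
class GradientScheme:
    """Diffusion sensitisation table.

    Parameters
    ----------
    bvals : (N,) array
        b-value per volume, s/mm2.
    bvecs : (N, 3) array
        Unit gradient direction per volume; the zero vector for b = 0.
    n_averages : int
        Number of noisy magnitude acquisitions averaged per b > 0 volume.
        b = 0 volumes are acquired once each.
    """

    bvals: np.ndarray
    bvecs: np.ndarray
    n_averages: int = 1

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvals.ndim != 1 or self.bvecs.shape != (self.bvals.size, 3):
            raise ValueError(
                f"bvals ({self.bvals.shape}) and bvecs ({self.bvecs.shape}) "
                "must have matching lengths"
            )
        if self.n_averages < 1:
            raise ValueError("n_averages must be >= 1")
        if not np.any(self.bvals == 0):
            raise ValueError("scheme needs at least one b = 0 volume")
        norms = np.linalg.norm(self.bvecs, axis=1)
        nonzero = self.bvals > 0
        if np.any(nonzero & (norms < 1e-12)):
            raise ValueError("zero gradient vector paired with b > 0")
        bad = nonzero & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            raise ValueError("b > 0 gradient vectors must be unit-norm")
        if self.n_unique_directions < 6:
            raise ValueError(
                "scheme needs >= 6 unique non-collinear nonzero directions"
            )

    @property
    def n_volumes(self) -> int:
        return self.bvals.size

    @property
    def n_unique_directions(self) -> int:
        """Count of antipodally-distinct b > 0 directions."""
        dirs = self.bvecs[self.bvals > 0]
        unique: list[np.ndarray] = []
        for d in dirs:
            if all(abs(float(d @ u)) < 1.0 - 1e-9 for u in unique):
                unique.append(d)
        return len(unique)

    def design_matrix(self) -> np.ndarray:
        """(N, 7) matrix A with log S = A @ [ln S0, Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]."""
        b, g = self.bvals, self.bvecs
        return np.column_stack(
            [
                np.ones_like(b),
                -b * g[:, 0] ** 2,
                -b * g[:, 1] ** 2,
                -b * g[:, 2] ** 2,
                -2 * b * g[:, 0] * g[:, 1],
                -2 * b * g[:, 0] * g[:, 2],
                -2 * b * g[:, 1] * g[:, 2],
            ]
        )


def default_scheme(b_nonzero: float = 400.0, n_b0: int = 10,
                   n_averages: int = 3) -> GradientScheme:
    """The package's reference acquisition: ``n_b0`` b = 0 volumes followed
    by the 12 optimised directions at ``b_nonzero`` s/mm2."""
    bvals = np.concatenate([np.zeros(n_b0), np.full(12, b_nonzero)])
    bvecs = np.vstack([np.zeros((n_b0, 3)), TWELVE_DIRECTIONS])
    return GradientScheme(bvals=bvals, bvecs=bvecs, n_averages=n_averages)
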