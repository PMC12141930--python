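"""Muscle regions of interest.

A :class:`MuscleROI` bundles the binary muscle mask with the labelled
sub-regions the architecture stage needs: the boundary shell, the
aponeurosis face (the tendinous sheet pennate fibers insert on), the
deep face opposite it, and the remaining lateral edge, plus the paired
bone's endpoints for length normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _neighbors_outside(mask: np.ndarray) -> np.ndarray:
    """Boolean array: mask voxels with at least one 6-connected
    background (or out-of-grid) neighbor."""
    padded = np.pad(mask, 1, constant_values=False)
    core = padded[1:-1, 1:-1, 1:-1]
    out = np.zeros_like(mask, dtype=bool)
    for axis in range(3):
        for shift in (-1, 1):
            out |= core & ~np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    return out & mask


@dataclass
class MuscleROI:
    """Voxel-grid muscle region with labelled surfaces.

    ``boundary_voxels``, ``aponeurosis_voxels``, ``deep_voxels`` and
    ``lateral_edge_voxels`` are boolean arrays on the same grid as
    ``mask``; aponeurosis/deep/lateral partition the boundary shell.
    ``affine`` maps voxel indices (voxel centers at integer indices) to
    world mm coordinates, RAS convention.
    """

    mask: np.ndarray
    voxel_size: tuple
    affine: np.ndarray
    muscle_name: str = "muscle"
    boundary_voxels: np.ndarray | None = None
    aponeurosis_voxels: np.ndarray | None = None
    deep_voxels: np.ndarray | None = None
    lateral_edge_voxels: np.ndarray | None = None
    bone_endpoints: np.ndarray | None = None  # (2, 3) world mm

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if not self.mask.any():
            raise ValueError("muscle mask is empty")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if self.boundary_voxels is None:
            self.boundary_voxels = _neighbors_outside(self.mask)
        if self.bone_endpoints is not None:
            self.bone_endpoints = np.asarray(self.bone_endpoints, dtype=float)
            if self.bone_endpoints.shape != (2, 3):
                raise ValueError("bone_endpoints must be two 3-vectors")
            if np.allclose(self.bone_endpoints[0], self.bone_endpoints[1]):
                raise ValueError("bone endpoints coincide")
        for name in ("aponeurosis_voxels", "deep_voxels", "lateral_edge_voxels"):
            lab = getattr(self, name)
            if lab is not None:
                lab = np.asarray(lab, dtype=bool)
                setattr(self, name, lab)
                if np.any(lab & ~(self.mask | self.boundary_voxels)):
                    raise ValueError(f"{name} extends outside mask/boundary")

    # -- coordinate helpers -------------------------------------------------
    def voxel_centers_world(self, which: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers where ``which`` (default mask)
        is True, as an (n, 3) array."""
        sel = self.mask if which is None else which
        ijk = np.argwhere(sel)
        return self.voxel_to_world(ijk)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates (centers at integers)."""
        inv = np.linalg.inv(self.affine)
        xyz = np.atleast_2d(xyz)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def contains_point(self, xyz: np.ndarray) -> bool:
        """Half-open voxel ownership: a world point belongs to the voxel
        whose center is nearest with ties going to the higher index."""
        vc = self.world_to_voxel(np.asarray(xyz, dtype=float))[0]
        idx = np.floor(vc + 0.5).astype(int)
        if np.any(idx < 0) or np.any(idx >= np.array(self.mask.shape)):
            return False
        return bool(self.mask[tuple(idx)])
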