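"""Standard-format readers and writers.

DWI volumes and maps are NIfTI-1 (RAS affine); gradient tables are
FSL-dialect bval/bvec text (whitespace rows, bvec as 3 rows x N columns,
with transposed N x 3 files auto-detected); tractograms are written both
as TrackVis .trk (world-mm points) and as a plain TSV; tabular results
are TSV; configuration, manifests and metric summaries are JSON.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .gradients import GradientScheme
from .phantom import DWIVolume
from .roi import MuscleROI
from .tracking import Fascicle, FascicleSet, TrackingParams

# label values in the ROI label volume
LABEL_MUSCLE, LABEL_APONEUROSIS, LABEL_DEEP, LABEL_LATERAL = 1, 2, 3, 4


# ---------------------------------------------------------------------------
# NIfTI

def write_nifti(path, data: np.ndarray, affine: np.ndarray, dtype=None):
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    img = nib.Nifti1Image(arr, np.asarray(affine, dtype=float))
    nib.save(img, str(path))


def read_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj), img.affine


def _voxel_size_from_affine(affine: np.ndarray) -> tuple:
    return tuple(float(v) for v in np.linalg.norm(affine[:3, :3], axis=0))


# ---------------------------------------------------------------------------
# FSL bval / bvec

def write_bval_bvec(scheme: GradientScheme, bval_path, bvec_path):
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{v:g}" for v in scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in scheme.bvecs.T:            # 3 rows x N columns
            fh.write(" ".join(f"{v:.10f}" for v in row) + "\n")


def read_bval_bvec(bval_path, bvec_path, n_averages: int = 1) -> GradientScheme:
    bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    mat = np.loadtxt(bvec_path, ndmin=2)
    if mat.shape[0] == 3:
        bvecs = mat.T                          # FSL dialect: 3 rows x N
    elif mat.shape[1] == 3:
        bvecs = mat                            # transposed dialect
    else:
        raise ValueError(f"bvec file has shape {mat.shape}; expected 3xN or Nx3")
    if bvecs.shape[0] != bvals.size:
        raise ValueError(
            f"bval count {bvals.size} does not match bvec count {bvecs.shape[0]}"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    nonzero = bvals > 0
    if np.any(nonzero & (norms < 1e-12)):
        raise ValueError("zero gradient vector paired with b > 0 is inconsistent")
    off = nonzero & (np.abs(norms - 1.0) > 1e-3)
    if np.any(off):
        warnings.warn(f"renormalising {int(off.sum())} non-unit gradient vectors")
    bvecs = bvecs.copy()
    bvecs[nonzero] /= norms[nonzero, None]
    return GradientScheme(bvals=bvals, bvecs=bvecs, n_averages=n_averages)


def write_dwi(dwi: DWIVolume, nii_path, bval_path, bvec_path):
    write_nifti(nii_path, dwi.signal, dwi.affine)
    write_bval_bvec(dwi.scheme, bval_path, bvec_path)


def read_dwi(nii_path, bval_path, bvec_path, n_averages: int = 1) -> DWIVolume:
    signal, affine = read_nifti(nii_path)
    if signal.ndim != 4:
        raise ValueError("DWI NIfTI must be 4-D")
    scheme = read_bval_bvec(bval_path, bvec_path, n_averages=n_averages)
    if signal.shape[3] != scheme.n_volumes:
        raise ValueError(
            f"DWI has {signal.shape[3]} volumes but gradient table has "
            f"{scheme.n_volumes}"
        )
    return DWIVolume(signal=np.asarray(signal, dtype=float), scheme=scheme,
                     voxel_size=_voxel_size_from_affine(affine), affine=affine)


# ---------------------------------------------------------------------------
# ROI masks

def write_roi(roi: MuscleROI, mask_path, labels_path):
    """Mask as uint8 NIfTI plus a label volume (1 muscle, 2 aponeurosis,
    3 deep surface, 4 lateral edge)."""
    write_nifti(mask_path, roi.mask.astype(np.uint8), roi.affine)
    labels = roi.mask.astype(np.uint8) * LABEL_MUSCLE
    for lab, val in ((roi.aponeurosis_voxels, LABEL_APONEUROSIS),
                     (roi.deep_voxels, LABEL_DEEP),
                     (roi.lateral_edge_voxels, LABEL_LATERAL)):
        if lab is not None:
            labels[lab] = val
    write_nifti(labels_path, labels, roi.affine)


def read_roi(mask_path, labels_path, muscle_name: str = "muscle",
             bone_endpoints=None) -> MuscleROI:
    mask, affine = read_nifti(mask_path)
    labels, _ = read_nifti(labels_path)
    mask = mask.astype(bool)
    return MuscleROI(
        mask=mask, voxel_size=_voxel_size_from_affine(affine), affine=affine,
        muscle_name=muscle_name,
        aponeurosis_voxels=labels == LABEL_APONEUROSIS,
        deep_voxels=labels == LABEL_DEEP,
        lateral_edge_voxels=labels == LABEL_LATERAL,
        bone_endpoints=bone_endpoints,
    )


# ---------------------------------------------------------------------------
# tractograms

def write_trk(fset: FascicleSet, path, reference_shape, affine):
    """TrackVis .trk with world-mm streamlines."""
    affine = np.asarray(affine, dtype=float)
    header = {
        nib.streamlines.trk.Field.VOXEL_SIZES:
            tuple(np.linalg.norm(affine[:3, :3], axis=0)),
        nib.streamlines.trk.Field.DIMENSIONS: tuple(reference_shape[:3]),
        nib.streamlines.trk.Field.VOXEL_TO_RASMM: affine,
    }
    tractogram = nib.streamlines.Tractogram(
        [f.points.astype(np.float32) for f in fset],
        affine_to_rasmm=np.eye(4),
    )
    nib.streamlines.save(nib.streamlines.TrkFile(tractogram, header=header),
                         str(path))


def read_trk(path) -> list:
    trk = nib.streamlines.load(str(path))
    return [np.asarray(s) for s in trk.tractogram.streamlines]


def write_tracts_tsv(fset: FascicleSet, path):
    rows = []
    for tid, f in enumerate(fset):
        valid = "" if f.valid is None else str(bool(f.valid))
        for pidx, p in enumerate(f.points):
            rows.append((tid, pidx, p[0], p[1], p[2], valid, f.reject_reason))
    df = pd.DataFrame(rows, columns=["tract_id", "point_index", "x", "y", "z",
                                     "valid", "reject_reason"])
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tracts_tsv(path, params: TrackingParams | None = None,
                    muscle_name: str = "muscle") -> FascicleSet:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     dtype={"valid": str, "reject_reason": str},
                     float_precision="round_trip")
    fascicles = []
    for tid, g in df.groupby("tract_id", sort=True):
        g = g.sort_values("point_index")
        valid_str = g["valid"].iloc[0]
        valid = None if valid_str == "" else valid_str == "True"
        fascicles.append(Fascicle(
            points=g[["x", "y", "z"]].to_numpy(dtype=float),
            seed_voxel=(-1, -1, -1), valid=valid,
            reject_reason=g["reject_reason"].iloc[0],
        ))
    return FascicleSet(fascicles=fascicles, muscle_name=muscle_name,
                       params=params or TrackingParams())


# ---------------------------------------------------------------------------
# tables and JSON

def write_tsv(df: pd.DataFrame, path):
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


def write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
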