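"""Fascicle architecture outcome measures.

From the valid fascicles and the ROI geometry this module derives the
outcome measures of the structural analysis: muscle volume, bone length,
fascicle length (raw and normalised to bone length), pennation angle,
fascicle count (raw and per-mm3), and the physiological cross-sectional
area

    PCSA = volume * cos(mu_pennation) / mu_fascicle_length,

where mu is the summary statistic over valid fascicles (arithmetic mean
by default; median and mode are available as robustness variants).

Pennation is measured between the fascicle end-to-end chord and the
local aponeurosis tangent plane near the fascicle's aponeurosis-side
endpoint; the chord is robust to step-level jitter.  A per-step variant
(mean segment tangent) is exposed for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .roi import MuscleROI
from .tracking import Fascicle, FascicleSet

#: radius (mm) of the neighbourhood used for the local aponeurosis
#: plane fit
APONEUROSIS_NEIGHBORHOOD_MM = 10.0


def muscle_volume(roi: MuscleROI) -> float:
    """Mask voxel count times voxel volume, mm3."""
    if not roi.mask.any():
        raise ValueError("muscle mask is empty")
    return float(roi.mask.sum()) * float(np.prod(roi.voxel_size))


def bone_length(roi: MuscleROI) -> float:
    """Euclidean distance between the paired bone's endpoints, mm."""
    if roi.bone_endpoints is None:
        raise ValueError("ROI carries no bone endpoints")
    p, q = roi.bone_endpoints
    if np.allclose(p, q):
        raise ValueError("bone endpoints coincide")
    return float(np.linalg.norm(q - p))


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the principal plane through a point cloud."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[-1]


def _fascicle_direction(fascicle: Fascicle, method: str) -> np.ndarray:
    if method == "chord":
        d = fascicle.chord
    elif method == "tangent":
        seg = np.diff(fascicle.points, axis=0)
        seg /= np.linalg.norm(seg, axis=1, keepdims=True)
        # align each segment with the chord before averaging (sign coherence)
        chord = fascicle.chord
        seg *= np.sign(seg @ chord)[:, None]
        d = seg.mean(axis=0)
    else:
        raise ValueError(f"unknown pennation method {method!r}")
    n = np.linalg.norm(d)
    if n == 0:
        raise ValueError("degenerate fascicle with zero extent")
    return d / n


def pennation_angle(fascicle: Fascicle, roi: MuscleROI,
                    method: str = "chord",
                    neighborhood_mm: float = APONEUROSIS_NEIGHBORHOOD_MM) -> float:
    """Angle (degrees, in [0, 90]) between the fascicle and the local
    aponeurosis tangent plane.

    The plane is fit (principal plane of the labelled voxel centers)
    within ``neighborhood_mm`` of the fascicle endpoint nearest the
    aponeurosis; if fewer than 3 labelled voxels fall inside, the
    nearest 3 are used instead.
    """
    if roi.aponeurosis_voxels is None or not roi.aponeurosis_voxels.any():
        raise ValueError("ROI carries no aponeurosis labels")
    apo = roi.voxel_centers_world(roi.aponeurosis_voxels)
    tree = cKDTree(apo)
    ends = fascicle.endpoints
    d_end, _ = tree.query(ends)
    anchor = ends[int(np.argmin(d_end))]
    idx = tree.query_ball_point(anchor, neighborhood_mm)
    if len(idx) < 3:
        _, idx = tree.query(anchor, k=min(3, len(apo)))
        idx = np.atleast_1d(idx)
    local = apo[np.asarray(idx, dtype=int)]
    if len(local) < 3:
        raise ValueError("too few aponeurosis voxels for a plane fit")
    normal = _plane_normal(local)
    u = _fascicle_direction(fascicle, method)
    s = min(1.0, abs(float(u @ normal)))
    return math.degrees(math.asin(s))


def _mode(values: np.ndarray) -> float:
    """Histogram mode for continuous data (Freedman-Diaconis bins,
    center of the fullest bin)."""
    values = np.asarray(values, dtype=float)
    if values.size == 1:
        return float(values[0])
    span = float(values.max() - values.min())
    q75, q25 = np.percentile(values, [75, 25])
    iqr = q75 - q25
    if iqr <= 0 or span < 1e-9 * max(1.0, abs(float(values.max()))):
        return float(np.median(values))
    width = 2 * iqr / values.size ** (1 / 3)
    nbins = min(1000, max(1, int(np.ceil(span / width))))
    counts, edges = np.histogram(values, bins=nbins)
    k = int(np.argmax(counts))
    return float(0.5 * (edges[k] + edges[k + 1]))


_STATS = {"mean": np.mean, "median": np.median, "mode": _mode}


@dataclass
class ArchitectureSummary:
    """Architecture outcomes for one muscle.

    ``fascicle_lengths_mm`` and ``pennation_angles_deg`` keep the full
    per-fascicle distributions so that PCSA can be re-derived with any
    summary statistic.  With zero valid fascicles the distribution-based
    metrics are NaN.
    """

    muscle_name: str
    muscle_volume_mm3: float
    bone_length_mm: float | None
    fascicle_count: int
    count_per_mm3: float
    mean_length_mm: float
    normalized_length: float | None
    mean_pennation_deg: float
    pcsa_mm2: float
    mu_statistic: str
    fascicle_lengths_mm: np.ndarray
    pennation_angles_deg: np.ndarray

    def as_dict(self) -> dict:
        return {
            "muscle_name": self.muscle_name,
            "muscle_volume_mm3": self.muscle_volume_mm3,
            "bone_length_mm": self.bone_length_mm,
            "fascicle_count": self.fascicle_count,
            "count_per_mm3": self.count_per_mm3,
            "mean_length_mm": self.mean_length_mm,
            "normalized_length": self.normalized_length,
            "mean_pennation_deg": self.mean_pennation_deg,
            "pcsa_mm2": self.pcsa_mm2,
            "mu_statistic": self.mu_statistic,
        }


def architecture_summary(valid: FascicleSet, roi: MuscleROI,
                         mu_statistic: str = "mean",
                         pennation_method: str = "chord") -> ArchitectureSummary:
    """Summarise a filtered fascicle set into the outcome measures.

    ``mu_statistic`` selects the summary used for both fascicle length
    and pennation in the PCSA formula ("mean", "median" or "mode").
    """
    if mu_statistic not in _STATS:
        raise ValueError(f"mu_statistic must be one of {sorted(_STATS)}")
    stat = _STATS[mu_statistic]
    vol = muscle_volume(roi)
    blen = bone_length(roi) if roi.bone_endpoints is not None else None

    fascicles = valid.valid_fascicles
    n = len(fascicles)
    if n == 0:
        nan = float("nan")
        return ArchitectureSummary(
            muscle_name=roi.muscle_name, muscle_volume_mm3=vol,
            bone_length_mm=blen, fascicle_count=0, count_per_mm3=0.0,
            mean_length_mm=nan, normalized_length=None if blen is None else nan,
            mean_pennation_deg=nan, pcsa_mm2=nan, mu_statistic=mu_statistic,
            fascicle_lengths_mm=np.array([]), pennation_angles_deg=np.array([]),
        )

    lengths = np.array([f.length_mm for f in fascicles])
    angles = np.array([
        pennation_angle(f, roi, method=pennation_method) for f in fascicles
    ])
    mu_len = float(stat(lengths))
    mu_pen = float(stat(angles))
    pcsa = vol * math.cos(math.radians(mu_pen)) / mu_len
    return ArchitectureSummary(
        muscle_name=roi.muscle_name, muscle_volume_mm3=vol,
        bone_length_mm=blen, fascicle_count=n, count_per_mm3=n / vol,
        mean_length_mm=mu_len,
        normalized_length=None if blen is None else mu_len / blen,
        mean_pennation_deg=mu_pen, pcsa_mm2=pcsa, mu_statistic=mu_statistic,
        fascicle_lengths_mm=lengths, pennation_angles_deg=angles,
    )


def aggregate_muscles(records: list, volumes: list) -> dict:
    """Volume-weighted average of per-muscle outcome records.

    ``records`` are dicts (or objects with ``as_dict``) sharing numeric
    outcome fields; ``volumes`` are the muscle volumes (mm3) used as
    weights.  Non-numeric fields are dropped; a single-muscle input is
    returned unchanged (minus non-numeric fields).
    """
    if len(records) == 0:
        raise ValueError("no records to aggregate")
    if len(records) != len(volumes):
        raise ValueError("records and volumes differ in length")
    dicts = [r.as_dict() if hasattr(r, "as_dict") else dict(r) for r in records]
    w = np.asarray(volumes, dtype=float)
    if w.sum() <= 0:
        raise ValueError("total volume is zero")
    keys = [k for k in dicts[0]
            if all(isinstance(d.get(k), (int, float)) and d.get(k) is not None
                   and not isinstance(d.get(k), bool) for d in dicts)]
    out = {}
    for k in keys:
        vals = np.array([float(d[k]) for d in dicts])
        out[k] = float((vals * w).sum() / w.sum())
    return out
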