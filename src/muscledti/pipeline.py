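"""End-to-end pipeline runner.

Stage order mirrors the acquisition-to-statistics flow: simulate the
phantom DWI, fit tensors, track, filter, summarise architecture,
simulate the bilateral cohort, and run the interlimb statistics.  Every
stage reads its inputs from files written by the previous stage (so the
standard-format round trips are exercised on every run), and the run
manifest records the config hash, per-stage seeds and a sha256 checksum
for every output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io
from .architecture import architecture_summary, bone_length
from .config import PipelineConfig, derive_stage_seed
from .phantom import make_phantom, simulate_dwi
from .gradients import default_scheme
from .stats import (demographics, fit_interlimb_lme, integrated_model,
                    pd_correlations, pd_table)
from .cohort import simulate_cohort
from .tensor import diffusivity_metrics, fit_tensor, whole_volume_metrics
from .tracking import filter_tracts, track_muscle

STAGES = ("simulate_phantom", "fit_tensor", "track", "architecture",
          "simulate_cohort", "stats")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    stage_seeds: dict
    outputs: dict = field(default_factory=dict)   # path -> sha256
    stage_outputs: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def record(self, stage: str, out_dir: Path, paths):
        self.stage_outputs.setdefault(stage, [])
        for p in paths:
            p = Path(p)
            digest = hashlib.sha256(p.read_bytes()).hexdigest()
            rel = str(p.relative_to(out_dir))
            self.outputs[rel] = digest
            self.stage_outputs[stage].append(rel)
        self.timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


class StageError(RuntimeError):
    """Failure inside one pipeline stage, named."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute the full pipeline into ``out_dir`` and return the manifest.

    Deterministic for a fixed ``config.seed``: per-stage seeds are
    derived from it, and rerunning with the same config produces
    byte-identical outputs.  A stage failure aborts with the stage name;
    outputs of completed stages are left intact.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seeds = {s: derive_stage_seed(config.seed, s) for s in STAGES}
    manifest = RunManifest(config_hash=config.config_hash(),
                           version=__version__, stage_seeds=seeds)
    (out_dir / "config.json").write_text(config.to_json() + "\n")
    manifest.record("config", out_dir, [out_dir / "config.json"])

    paths = {
        "dwi": out_dir / "dwi.nii.gz",
        "bval": out_dir / "dwi.bval",
        "bvec": out_dir / "dwi.bvec",
        "mask": out_dir / "muscle_mask.nii.gz",
        "labels": out_dir / "roi_labels.nii.gz",
        "truth": out_dir / "ground_truth.json",
        "metrics": out_dir / "diffusivity_metrics.json",
        "raw_trk": out_dir / "tracts_raw.trk",
        "raw_tsv": out_dir / "tracts_raw.tsv",
        "valid_trk": out_dir / "fascicles_valid.trk",
        "valid_tsv": out_dir / "fascicles_valid.tsv",
        "arch": out_dir / "architecture.json",
        "cohort": out_dir / "cohort.tsv",
        "pd": out_dir / "percent_deficits.tsv",
        "stats": out_dir / "stats.json",
    }

    # stage 1: phantom + DWI simulation -------------------------------------
    stage = "simulate_phantom"
    try:
        spec = dataclasses.replace(config.phantom, seed=seeds[stage])
        tfield_true, roi, truth = make_phantom(spec)
        scheme = default_scheme(config.b_value, config.n_b0, config.n_averages)
        dwi = simulate_dwi(tfield_true, roi, scheme, snr=spec.snr,
                           seed=seeds[stage])
        io.write_dwi(dwi, paths["dwi"], paths["bval"], paths["bvec"])
        io.write_roi(roi, paths["mask"], paths["labels"])
        io.write_json(truth, paths["truth"])
        manifest.record(stage, out_dir, [paths[k] for k in
                                         ("dwi", "bval", "bvec", "mask",
                                          "labels", "truth")])
    except Exception as err:
        raise StageError(stage, err) from err

    # stage 2: tensor fit ----------------------------------------------------
    stage = "fit_tensor"
    try:
        dwi = io.read_dwi(paths["dwi"], paths["bval"], paths["bvec"],
                          n_averages=config.n_averages)
        roi = io.read_roi(paths["mask"], paths["labels"],
                          muscle_name=config.phantom.muscle_name,
                          bone_endpoints=np.asarray(config.phantom.bone_endpoints))
        tfield = fit_tensor(dwi, np.ones(roi.mask.shape, dtype=bool))
        wv = whole_volume_metrics(tfield, roi)
        scalars = diffusivity_metrics(tfield.eigenvalues)
        maps = []
        for name in ("fa", "md", "ad", "rd"):
            p = out_dir / f"{name}.nii.gz"
            io.write_nifti(p, getattr(scalars, name), roi.affine)
            maps.append(p)
        io.write_json({roi.muscle_name: wv.as_dict(),
                       "n_fit_failed": int((~tfield.fit_ok).sum())},
                      paths["metrics"])
        manifest.record(stage, out_dir, maps + [paths["metrics"]])
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, err) from err

    # stage 3: tractography --------------------------------------------------
    stage = "track"
    try:
        params = dataclasses.replace(config.tracking, seed=seeds[stage])
        raw = track_muscle(tfield, roi, params)
        io.write_trk(raw, paths["raw_trk"], roi.mask.shape, roi.affine)
        io.write_tracts_tsv(raw, paths["raw_tsv"])
        manifest.record(stage, out_dir, [paths["raw_trk"], paths["raw_tsv"]])
    except Exception as err:
        raise StageError(stage, err) from err

    # stage 4: filtering + architecture ---------------------------------------
    stage = "architecture"
    try:
        raw = io.read_tracts_tsv(paths["raw_tsv"], params=params,
                                 muscle_name=roi.muscle_name)
        valid = filter_tracts(raw, roi, config.filters)
        io.write_trk(valid, paths["valid_trk"], roi.mask.shape, roi.affine)
        io.write_tracts_tsv(valid, paths["valid_tsv"])
        summary = architecture_summary(valid, roi,
                                       mu_statistic=config.stats.mu_statistic)
        io.write_json({"summary": summary.as_dict(),
                       "n_raw": len(raw), "n_valid": summary.fascicle_count},
                      paths["arch"])
        manifest.record(stage, out_dir, [paths["valid_trk"], paths["valid_tsv"],
                                         paths["arch"]])
    except Exception as err:
        raise StageError(stage, err) from err

    # stage 5: cohort simulation ----------------------------------------------
    stage = "simulate_cohort"
    try:
        cspec = dataclasses.replace(config.cohort, seed=seeds[stage])
        cohort = simulate_cohort(cspec)
        io.write_tsv(cohort, paths["cohort"])
        manifest.record(stage, out_dir, [paths["cohort"]])
    except Exception as err:
        raise StageError(stage, err) from err

    # stage 6: interlimb statistics --------------------------------------------
    stage = "stats"
    try:
        cohort = io.read_tsv(paths["cohort"])
        pdt = pd_table(cohort)
        io.write_tsv(pdt, paths["pd"])
        results = {"demographics": demographics(cohort)}
        lme = {}
        for outcome in sorted(cohort["outcome"].unique()):
            res = fit_interlimb_lme(
                cohort, outcome,
                include_participant=config.stats.include_participant_intercept)
            lme[outcome] = _lme_to_dict(res)
        results["interlimb_lme"] = lme
        results["pd_correlations"] = {
            k: {"r": v[0], "p": v[1]}
            for k, v in pd_correlations(pdt).items()
        }
        results["integrated_model"] = _lme_to_dict(integrated_model(pdt))
        io.write_json(results, paths["stats"])
        manifest.record(stage, out_dir, [paths["pd"], paths["stats"]])
    except Exception as err:
        raise StageError(stage, err) from err

    io.write_json(manifest.to_dict(), out_dir / "manifest.json")
    return manifest


def _lme_to_dict(res) -> dict:
    return {
        "fixed_effects": {
            name: {"estimate": fe.estimate, "se": fe.se, "p": fe.pvalue,
                   "ci": [fe.ci_low, fe.ci_high]}
            for name, fe in res.fixed_effects.items()
        },
        "random_effect_variances": res.random_effect_variances,
        "r_squared": res.r_squared,
        "n_obs": res.n_obs,
        "converged": res.converged,
        "flags": res.flags,
    }
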