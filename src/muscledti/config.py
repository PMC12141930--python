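"""Pipeline configuration.

A :class:`PipelineConfig` serialises to/from one JSON document.  Unknown
keys are rejected so that typos in config files fail loudly.  The single
global seed deterministically derives per-stage seeds (a hash of the
stage name mixed with the global seed) so stages can be rerun in
isolation and still reproduce a full run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

from .cohort import CohortSpec, OutcomeSpec, default_outcomes
from .phantom import PhantomSpec
from .tracking import FilterConstraints, TrackingParams


def derive_stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{stage}:{global_seed}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


def _from_dict(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys at {path}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class StatsOptions:
    """Switches for the statistics stage."""

    include_participant_intercept: bool = True
    mu_statistic: str = "mean"          # summary used for PCSA mu fields


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    filters: FilterConstraints = field(default_factory=lambda: FilterConstraints(
        endpoint_pair=True))
    cohort: CohortSpec = field(default_factory=CohortSpec)
    stats: StatsOptions = field(default_factory=StatsOptions)
    n_b0: int = 10
    n_averages: int = 3
    b_value: float = 400.0
    seed: int = 0

    # -- (de)serialisation --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        ph = d["phantom"]
        for key in ("muscle_extent", "eigenvalues_true", "voxel_size"):
            ph[key] = list(ph[key])
        ph["bone_endpoints"] = [list(map(float, p))
                                for p in self.phantom.bone_endpoints]
        for sub in (ph, d["tracking"]):
            for k, v in sub.items():
                if isinstance(v, float) and math.isinf(v):
                    sub[k] = "inf"
        d["cohort"]["outcomes"] = {
            name: dataclasses.asdict(spec)
            for name, spec in self.cohort.outcomes.items()
        }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        out = {}
        if "phantom" in data:
            ph = dict(data.pop("phantom"))
            if ph.get("snr") == "inf":
                ph["snr"] = math.inf
            for key in ("muscle_extent", "eigenvalues_true", "voxel_size"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            if "bone_endpoints" in ph:
                ph["bone_endpoints"] = tuple(tuple(p) for p in ph["bone_endpoints"])
            out["phantom"] = _from_dict(PhantomSpec, ph, "phantom")
        if "tracking" in data:
            tr = dict(data.pop("tracking"))
            if tr.get("kappa") == "inf":
                tr["kappa"] = math.inf
            out["tracking"] = _from_dict(TrackingParams, tr, "tracking")
        if "filters" in data:
            out["filters"] = _from_dict(FilterConstraints, dict(data.pop("filters")),
                                        "filters")
        if "cohort" in data:
            co = dict(data.pop("cohort"))
            if "outcomes" in co:
                co["outcomes"] = {
                    name: _from_dict(OutcomeSpec, dict(spec), f"cohort.outcomes.{name}")
                    for name, spec in co["outcomes"].items()
                }
            out["cohort"] = _from_dict(CohortSpec, co, "cohort")
        if "stats" in data:
            out["stats"] = _from_dict(StatsOptions, dict(data.pop("stats")), "stats")
        out.update(data)
        return cls(**out)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(json.loads(text))

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()
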