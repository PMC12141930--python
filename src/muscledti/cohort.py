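"""Bilateral cohort simulator.

Emulates a two-group study: participants with hemiparetic cerebral
palsy (HCP) compared across their nonparetic (reference) and paretic
(other) arms, and typically developing (TD) controls compared across
dominant (reference) and nondominant (other) arms.  Each MR-derived
outcome gets a participant-level baseline on the reference arm; the
other arm is the baseline scaled by one minus a per-participant
fractional deficit drawn from the group's deficit distribution
(truncated below 1 so the other arm stays positive).  The grip-strength
percent deficit is generated as a linear function of the muscle-volume
and mean-diffusivity percent deficits plus residual noise, so the
integrated deficit model has known ground-truth coefficients.

Default effect sizes are the cohort conditions the statistics stage is
validated against: a 27% / 4.5% (HCP / TD) interlimb volume deficit, a
9.3% HCP diffusivity deficit, and grip-deficit weights 1.27 (volume)
and 0.843 (MD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class OutcomeSpec:
    """Generator parameters for one MR-derived outcome."""

    baseline_mean: float
    baseline_cv: float
    deficit_mean_hcp: float    # fractional (0.27 = 27%)
    deficit_mean_td: float
    deficit_sd: float

    def __post_init__(self):
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be positive")
        if self.baseline_cv < 0 or self.deficit_sd < 0:
            raise ValueError("baseline_cv and deficit_sd must be >= 0")


def default_outcomes() -> dict:
    """The study conditions: forearm-flexor volume (mm3), whole-volume
    MD (mm2/s), and their group deficit distributions."""
    return {
        "muscle_volume": OutcomeSpec(
            baseline_mean=30000.0, baseline_cv=0.25,
            deficit_mean_hcp=0.27, deficit_mean_td=0.045, deficit_sd=0.10),
        "md": OutcomeSpec(
            baseline_mean=1.767e-3, baseline_cv=0.05,
            deficit_mean_hcp=0.093, deficit_mean_td=0.0, deficit_sd=0.05),
    }


@dataclass
class CohortSpec:
    """Cohort composition and effect structure.

    ``beta_volume`` and ``beta_md`` are the grip-deficit regression
    weights (percent grip deficit per percent predictor deficit);
    ``residual_sd`` is the grip-deficit noise in percentage points,
    sized so the two predictors jointly explain roughly 60% of the
    grip-deficit variance at these effect sizes.
    """

    n_hcp: int = 14
    n_td: int = 16
    outcomes: dict = field(default_factory=default_outcomes)
    beta_volume: float = 1.27
    beta_md: float = 0.843
    grip_baseline_mean: float = 250.0     # N
    grip_baseline_cv: float = 0.30
    residual_sd: float = 17.5             # percentage points
    seed: int = 0

    def __post_init__(self):
        if self.n_hcp < 2 or self.n_td < 2:
            raise ValueError("each group needs at least 2 participants")
        if self.residual_sd < 0 or self.grip_baseline_cv < 0:
            raise ValueError("spreads must be >= 0")


def _truncated_deficit(rng, mean, sd, size):
    """Normal(mean, sd) truncated below 1 (resampled), so the scaled arm
    value stays positive."""
    if sd == 0:
        if mean >= 1:
            raise ValueError("degenerate deficit >= 1")
        return np.full(size, mean)
    d = rng.normal(mean, sd, size)
    while np.any(d >= 1):
        redo = d >= 1
        d[redo] = rng.normal(mean, sd, redo.sum())
    return d


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a long-format cohort table.

    One row per participant x arm x outcome with columns
    ``participant_id, group, arm, age_years, sex, outcome, value``;
    ``arm`` is "reference" (nonparetic/dominant) or "other"
    (paretic/nondominant).  Bit-reproducible for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_hcp + spec.n_td
    groups = np.array(["HCP"] * spec.n_hcp + ["TD"] * spec.n_td)
    ages = rng.uniform(6.0, 40.0, n)
    sexes = np.where(rng.random(n) < 0.6, "F", "M")  # cohort is ~60% female
    pids = np.array([f"P{i + 1:03d}" for i in range(n)])

    pd_pct = {}   # per-outcome percent deficits, for the grip model
    rows = []
    for name, out in spec.outcomes.items():
        base = rng.normal(out.baseline_mean, out.baseline_cv * out.baseline_mean, n)
        base = np.abs(base)  # baselines are positive quantities
        dmean = np.where(groups == "HCP", out.deficit_mean_hcp, out.deficit_mean_td)
        deficit = np.empty(n)
        for g, m in (("HCP", out.deficit_mean_hcp), ("TD", out.deficit_mean_td)):
            sel = groups == g
            deficit[sel] = _truncated_deficit(rng, m, out.deficit_sd, sel.sum())
        other = base * (1.0 - deficit)
        pd_pct[name] = deficit * 100.0
        for i in range(n):
            rows.append((pids[i], groups[i], "reference", ages[i], sexes[i],
                         name, base[i]))
            rows.append((pids[i], groups[i], "other", ages[i], sexes[i],
                         name, other[i]))

    # grip strength: percent deficit is linear in the volume and MD deficits
    grip_base = np.abs(rng.normal(
        spec.grip_baseline_mean, spec.grip_baseline_cv * spec.grip_baseline_mean, n))
    noise = rng.normal(0.0, spec.residual_sd, n) if spec.residual_sd > 0 else np.zeros(n)
    grip_pd = (spec.beta_volume * pd_pct.get("muscle_volume", np.zeros(n))
               + spec.beta_md * pd_pct.get("md", np.zeros(n)) + noise)
    grip_pd = np.minimum(grip_pd, 99.9)  # keep the weaker arm positive
    grip_other = grip_base * (1.0 - grip_pd / 100.0)
    for i in range(n):
        rows.append((pids[i], groups[i], "reference", ages[i], sexes[i],
                     "grip_strength", grip_base[i]))
        rows.append((pids[i], groups[i], "other", ages[i], sexes[i],
                     "grip_strength", grip_other[i]))

    return pd.DataFrame(
        rows, columns=["participant_id", "group", "arm", "age_years", "sex",
                       "outcome", "value"])


# ---------------------------------------------------------------------------
# printed reference demographics (used by the worked example): per-participant
# group, age as a "Y y M m" string, and sex.

REFERENCE_DEMOGRAPHICS = [
    ("HCP", "10 y 2 m", "F"), ("HCP", "11 y 6 m", "M"), ("HCP", "13 y 7 m", "F"),
    ("HCP", "24 y 10 m", "M"), ("HCP", "16 y 9 m", "M"), ("HCP", "20 y 1 m", "F"),
    ("HCP", "10 y 9 m", "M"), ("HCP", "8 y 1 m", "F"), ("HCP", "12 y 9 m", "F"),
    ("HCP", "13 y 1 m", "M"), ("HCP", "39 y 2 m", "M"), ("HCP", "18 y 3 m", "F"),
    ("HCP", "24 y 6 m", "F"), ("HCP", "39 y 8 m", "M"),
    ("TD", "31 y 1 m", "F"), ("TD", "10 y 3 m", "F"), ("TD", "20 y 7 m", "M"),
    ("TD", "6 y 6 m", "F"), ("TD", "11 y 8 m", "M"), ("TD", "24 y 3 m", "F"),
    ("TD", "10 y 3 m", "F"), ("TD", "12 y 2 m", "M"), ("TD", "11 y 1 m", "F"),
    ("TD", "28 y 2 m", "F"), ("TD", "31 y 2 m", "M"), ("TD", "21 y 9 m", "M"),
    ("TD", "15 y 5 m", "F"), ("TD", "20 y 2 m", "F"), ("TD", "12 y 5 m", "F"),
    ("TD", "9 y 4 m", "F"),
]


def reference_demographics() -> pd.DataFrame:
    """The printed study demographics as a DataFrame with columns
    ``group, age, sex`` (age as a "Y y M m" string)."""
    return pd.DataFrame(REFERENCE_DEMOGRAPHICS, columns=["group", "age", "sex"])
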