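"""Interlimb deficit statistics.

The statistical stage mirrors a paired bilateral study design:

* per-participant percent deficits,
  PD = (reference - other) / reference * 100, positive when the
  paretic/nondominant arm is smaller;
* a linear mixed-effects (LME) model per outcome,
  value ~ group * arm, with random intercepts for age bin and sex
  (and, by default, participant, since arms are paired within
  participants);
* Pearson correlations between the grip-strength percent deficit and
  each structural percent deficit, pooling both groups;
* an integrated LME model,
  PD_grip ~ PD_volume + PD_MD, with the same random-effect structure;
* cohort demographics (group age mean +- sd, sex counts, Welch t-test
  for age, chi-squared test for sex).

Model fitting is delegated to statsmodels MixedLM (REML).  p-values and
confidence intervals for fixed effects use a t reference with
n_obs - rank(X) degrees of freedom, a small-sample improvement over the
Wald normal.  The reported r-squared is the marginal (fixed-effects)
variance fraction.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

ALPHA = 0.05


# ---------------------------------------------------------------------------
# percent deficits

def percent_deficit(reference_value, other_value):
    """(reference - other) / reference * 100; positive when the other
    (paretic/nondominant) arm is smaller.  Scale-invariant."""
    ref = np.asarray(reference_value, dtype=float)
    oth = np.asarray(other_value, dtype=float)
    if np.any(ref == 0):
        raise ValueError("reference value is zero; percent deficit undefined")
    out = (ref - oth) / ref * 100.0
    return float(out) if out.ndim == 0 else out


def pd_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-participant percent deficits, wide format.

    Input is the long cohort table (participant_id, group, arm, age_years,
    sex, outcome, value); output has one row per participant with a
    ``pd_<outcome>`` column per outcome.
    """
    wide = cohort.pivot_table(index=["participant_id", "group", "outcome"],
                              columns="arm", values="value", aggfunc="first")
    if not {"reference", "other"} <= set(wide.columns):
        raise ValueError("cohort table must contain both arms per outcome")
    if wide[["reference", "other"]].isna().any().any():
        raise ValueError("each participant needs exactly two arms per outcome")
    pdv = percent_deficit(wide["reference"].to_numpy(), wide["other"].to_numpy())
    tidy = wide.reset_index()[["participant_id", "group", "outcome"]]
    tidy["pd_percent"] = pdv
    out = tidy.pivot(index=["participant_id", "group"], columns="outcome",
                     values="pd_percent")
    out.columns = [f"pd_{c}" for c in out.columns]
    out = out.reset_index()
    meta = cohort[["participant_id", "age_years", "sex"]].drop_duplicates(
        "participant_id")
    return out.merge(meta, on="participant_id")


# ---------------------------------------------------------------------------
# mixed-effects machinery

@dataclass
class FixedEffect:
    estimate: float
    se: float
    pvalue: float
    ci_low: float
    ci_high: float


@dataclass
class LMEResult:
    """Fixed effects (with t-based p-values and 95% CIs), random-effect
    variances, marginal r-squared, sample size and convergence flag."""

    fixed_effects: dict
    random_effect_variances: dict
    r_squared: float
    n_obs: int
    converged: bool
    flags: list = field(default_factory=list)

    def effect(self, name: str) -> FixedEffect:
        return self.fixed_effects[name]


def _age_bins(age_years: pd.Series) -> pd.Series:
    # integer age-year bins as the random-effect grouping for age
    return age_years.astype(float).astype(int)


def _marginal_r2(fitted_fixed: np.ndarray, vcomp: np.ndarray,
                 scale: float) -> float:
    """Nakagawa-style marginal r2: fixed-effect variance over total."""
    var_f = float(np.var(fitted_fixed))
    total = var_f + float(np.sum(vcomp)) + float(scale)
    return var_f / total if total > 0 else float("nan")


def _fit_vc_lme(df: pd.DataFrame, formula: str, vc: dict,
                contrasts: dict | None = None) -> LMEResult:
    """Fit an LME with crossed variance components via MixedLM.

    ``vc`` maps component names to patsy one-hot formulas; ``contrasts``
    maps extra effect names to contrast vectors over the fixed effects.
    Falls back to OLS (zero random-effect variances, flagged) when the
    mixed fit is degenerate, which keeps the zero-noise limit exact.
    """
    flags = []
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(formula, df, groups=np.ones(len(df)),
                                vc_formula=vc, re_formula="0")
            res = model.fit(reml=True, method="lbfgs")
        fe = res.fe_params
        cov = np.asarray(res.cov_params())[: len(fe), : len(fe)]
        vcomp = dict(zip(model.exog_vc.names, np.asarray(res.vcomp, dtype=float)))
        scale = float(res.scale)
        fitted_fixed = np.asarray(model.exog) @ np.asarray(fe)
        converged = bool(getattr(res, "converged", True))
        if not np.all(np.isfinite(np.diag(cov))) or np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError("degenerate fixed-effect covariance")
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        # degenerate data (e.g. zero residual variance): ordinary LS limit
        ols = smf.ols(formula, df).fit()
        fe = ols.params
        cov = np.asarray(ols.cov_params())
        vcomp = {name: 0.0 for name in vc}
        scale = float(ols.scale)
        fitted_fixed = np.asarray(ols.fittedvalues)
        flags.append("fallback_ols")
        converged = False

    k = len(fe)
    dof = max(len(df) - k, 1)
    tcrit = sps.t.ppf(1 - ALPHA / 2, dof)
    effects = {}
    for i, name in enumerate(fe.index):
        est = float(fe.iloc[i])
        se = float(np.sqrt(max(cov[i, i], 0.0)))
        tval = est / se if se > 0 else np.inf * np.sign(est or 1)
        p = float(2 * sps.t.sf(abs(tval), dof)) if se > 0 else 0.0
        effects[name] = FixedEffect(est, se, p, est - tcrit * se, est + tcrit * se)
    for name, terms in (contrasts or {}).items():
        L = np.zeros(k)
        for term, coef in terms.items():
            if term not in fe.index:
                raise ValueError(f"contrast term {term!r} not among fixed effects "
                                 f"{list(fe.index)}")
            L[list(fe.index).index(term)] = coef
        est = float(L @ np.asarray(fe))
        se = float(np.sqrt(max(L @ cov @ L, 0.0)))
        tval = est / se if se > 0 else np.inf * np.sign(est or 1)
        p = float(2 * sps.t.sf(abs(tval), dof)) if se > 0 else 0.0
        effects[name] = FixedEffect(est, se, p, est - tcrit * se, est + tcrit * se)

    near_zero = [n for n, v in vcomp.items() if v < 1e-12]
    if near_zero and "fallback_ols" not in flags:
        flags.append("singular_random_effects:" + ",".join(sorted(near_zero)))

    return LMEResult(
        fixed_effects=effects, random_effect_variances=vcomp,
        r_squared=_marginal_r2(fitted_fixed, np.asarray(list(vcomp.values())), scale),
        n_obs=len(df), converged=converged, flags=flags,
    )


def fit_interlimb_lme(cohort: pd.DataFrame, outcome: str,
                      include_participant: bool = True) -> LMEResult:
    """Interlimb LME for one outcome: value ~ group * arm with random
    intercepts for age bin and sex.

    ``include_participant`` (default) adds a per-participant random
    intercept for the paired design; switching it off reproduces the
    literal age-and-sex-only specification.  The result carries the
    per-group interlimb contrasts as ``arm_contrast_HCP`` and
    ``arm_contrast_TD`` (other minus reference arm).
    """
    df = cohort[cohort["outcome"] == outcome].copy()
    if df.empty:
        raise ValueError(f"no rows for outcome {outcome!r}")
    counts = df.groupby("participant_id")["arm"].nunique()
    if not (counts == 2).all():
        raise ValueError("each participant needs both arms for the outcome")
    df["arm"] = pd.Categorical(df["arm"], categories=["reference", "other"])
    df["group"] = pd.Categorical(df["group"], categories=["HCP", "TD"])
    df["age_bin"] = _age_bins(df["age_years"])
    vc = {"age": "0 + C(age_bin)", "sex": "0 + C(sex)"}
    if include_participant:
        vc["participant"] = "0 + C(participant_id)"
    arm = "arm[T.other]"
    inter = "group[T.TD]:arm[T.other]"
    contrasts = {
        "arm_contrast_HCP": {arm: 1.0},
        "arm_contrast_TD": {arm: 1.0, inter: 1.0},
    }
    return _fit_vc_lme(df, "value ~ group * arm", vc, contrasts)


def pd_correlations(pdt: pd.DataFrame, target: str = "grip_strength") -> dict:
    """Pearson r (and two-sided p) between the target percent deficit and
    every other outcome's percent deficit, pooling both groups.

    Outcomes with zero variance yield NaN-marked results.
    """
    tcol = f"pd_{target}"
    if tcol not in pdt.columns:
        raise ValueError(f"pd table has no column {tcol!r}")
    out = {}
    y = pdt[tcol].to_numpy(dtype=float)
    for col in pdt.columns:
        if not col.startswith("pd_") or col == tcol:
            continue
        x = pdt[col].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        name = col[3:]
        if ok.sum() < 3:
            raise ValueError(f"fewer than 3 paired observations for {name}")
        if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            out[name] = (float("nan"), float("nan"))
            continue
        r, p = sps.pearsonr(x[ok], y[ok])
        out[name] = (float(r), float(p))
    return out


def integrated_model(pdt: pd.DataFrame,
                     predictors: tuple = ("muscle_volume", "md"),
                     target: str = "grip_strength") -> LMEResult:
    """Integrated grip-deficit model: PD_grip ~ PD_volume + PD_MD with
    age-bin and sex random intercepts.

    Near-collinear predictors (|r| > 0.999) are flagged, not rejected.
    """
    cols = [f"pd_{p}" for p in predictors] + [f"pd_{target}"]
    missing = [c for c in cols if c not in pdt.columns]
    if missing:
        raise ValueError(f"pd table lacks columns {missing}")
    df = pdt.dropna(subset=cols).copy()
    df["age_bin"] = _age_bins(df["age_years"])
    formula = f"pd_{target} ~ " + " + ".join(f"pd_{p}" for p in predictors)
    vc = {"age": "0 + C(age_bin)", "sex": "0 + C(sex)"}
    res = _fit_vc_lme(df, formula, vc)
    if len(predictors) == 2:
        x1 = df[f"pd_{predictors[0]}"]
        x2 = df[f"pd_{predictors[1]}"]
        if x1.std() > 0 and x2.std() > 0 and abs(x1.corr(x2)) > 0.999:
            res.flags.append("collinear_predictors")
    return res


# ---------------------------------------------------------------------------
# demographics

_AGE_RE = re.compile(r"^\s*(\d+)\s*y(?:\s*(\d+)\s*m)?\s*$")


def parse_age(age) -> float:
    """Fractional years from a "Y y M m" string (months / 12), or a
    pass-through for numeric ages."""
    if isinstance(age, (int, float, np.floating)):
        return float(age)
    m = _AGE_RE.match(str(age))
    if not m:
        raise ValueError(f"unparseable age string {age!r}")
    years = int(m.group(1))
    months = int(m.group(2) or 0)
    return years + months / 12.0


def demographics(table: pd.DataFrame) -> dict:
    """Group demographic summary with between-group tests.

    ``table`` needs one row per participant with columns ``group``,
    ``age`` (numeric or "Y y M m" string) and ``sex``; a long cohort
    table (with ``age_years``) is accepted and deduplicated.  Returns
    per-group n, mean +- sd age, sex counts, the Welch t-test p-value
    for age and the chi-squared p-value for sex.
    """
    df = table.copy()
    if "age" not in df.columns and "age_years" in df.columns:
        df = df.drop_duplicates("participant_id")
        df = df.rename(columns={"age_years": "age"})
    for col in ("group", "age", "sex"):
        if col not in df.columns:
            raise ValueError(f"demographics table lacks column {col!r}")
    ages = []
    for i, a in enumerate(df["age"]):
        try:
            ages.append(parse_age(a))
        except ValueError as err:
            raise ValueError(f"row {i}: {err}") from None
    df = df.assign(age_years=ages)

    out = {"groups": {}}
    for g, sub in df.groupby("group"):
        out["groups"][g] = {
            "n": int(len(sub)),
            "age_mean": float(sub["age_years"].mean()),
            "age_sd": float(sub["age_years"].std(ddof=1)),
            "sex_counts": sub["sex"].value_counts().to_dict(),
        }
    gnames = sorted(df["group"].unique())
    if len(gnames) == 2:
        a = df.loc[df["group"] == gnames[0], "age_years"]
        b = df.loc[df["group"] == gnames[1], "age_years"]
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
            out["age_ttest_p"] = 1.0
        else:
            out["age_ttest_p"] = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
        ctab = pd.crosstab(df["group"], df["sex"])
        if ctab.shape[1] > 1:
            out["sex_chi2_p"] = float(sps.chi2_contingency(ctab).pvalue)
        else:
            out["sex_chi2_p"] = 1.0
    return out
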