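"""Linear models of logit WMH load on concurrent or past blood pressure.

Three adjustment tiers mirror the published analysis: unadjusted (each
exposure alone), age- and sex-adjusted, and fully adjusted (SBP and DBP
jointly, plus age, sex, arterial stiffness index, smoking, diabetes, BP
source, assessment centre, and — for past-BP models — the time between
visits).  Effects are reported either as standardized coefficients (outcome
and continuous predictors z-scored; binary indicators left on their natural
scale, so their coefficients are in outcome-SD units per level) or per mmHg,
convertible to multiplicative WMH-load ratios per 10 mmHg SBP / 5 mmHg DBP
via ``effect_ratio_per_unit`` (logit ≈ log for small loads, so exp(beta·unit)
is a load ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import ingest

#: continuous model variables (z-scored when standardized=True)
CONTINUOUS = ("sbp", "dbp", "age", "asi", "time_diff")

FULL_ADJUSTMENT = ("age", "sex", "asi", "smoking", "diabetes", "bp_source", "centre")

RATIO_UNITS = {"sbp": 10.0, "dbp": 5.0}


@dataclass
class ModelSpec:
    """Declarative description of one association model."""
    outcome: str = "wmh_logit"
    exposures: tuple = ("sbp", "dbp")
    adjustment: str = "full"          # unadjusted | age_sex | full
    timing: str = "concurrent"        # concurrent (follow-up BP) | past (baseline BP)
    standardized: bool = True

    def __post_init__(self):
        if self.adjustment not in ("unadjusted", "age_sex", "full"):
            raise ValueError(f"unknown adjustment {self.adjustment!r}")
        if self.timing not in ("concurrent", "past"):
            raise ValueError(f"unknown timing {self.timing!r}")


@dataclass
class EffectEstimate:
    term: str
    beta: float
    ci_low: float
    ci_high: float
    scale: str
    n: int
    stratum: str = ""

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise ValueError(f"CI does not bracket the point estimate for {self.term}")


# role -> analysis-table column, by timing
def _column(role: str, timing: str) -> str:
    visit = "followup" if timing == "concurrent" else "baseline"
    mapping = {
        "sbp": f"sbp_{visit}", "dbp": f"dbp_{visit}",
        "age": f"age_{visit}", "asi": f"asi_{visit}",
        "bp_source": f"bp_source_{visit}",
        "sex": "sex", "smoking": "smoking", "diabetes": "diabetes",
        "centre": "centre", "time_diff": "time_diff",
    }
    return mapping[role]


def standardize(table: pd.DataFrame, variables) -> pd.DataFrame:
    """Return a copy with each listed column z-scored on this sample.

    The mean and SD (ddof=1) are computed on the rows of ``table`` itself, so
    standardization always reflects the fitted sample.  A zero-variance
    column is an error (its standardized values would be undefined).
    """
    out = table.copy()
    for v in variables:
        x = out[v].to_numpy(dtype=float)
        sd = np.nanstd(x, ddof=1)
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"cannot standardize zero-variance variable {v!r}")
        out[v] = (x - np.nanmean(x)) / sd
    return out


def _reference_level(series: pd.Series) -> str:
    """Most frequent level, ties broken alphabetically for determinism."""
    counts = series.value_counts()
    top = counts[counts == counts.max()].index
    return sorted(top)[0]


def _build_design(table: pd.DataFrame, spec: ModelSpec, roles,
                  interaction: str | None = None):
    """Assemble (y, X, n) for the given roles, complete-case, encoded.

    ``roles`` are model roles ('sbp', 'age', 'smoking', ...); categorical
    roles expand to indicator columns against the most frequent reference
    level (smoking against 'never').  With ``interaction='sbp'`` (or 'dbp')
    an exposure × female product term is appended.
    """
    cols = {r: _column(r, spec.timing) for r in roles}
    df = table[[spec.outcome, *dict.fromkeys(cols.values())]].dropna()
    n = len(df)
    if n == 0:
        raise ValueError("no complete-case rows for this model")

    work = pd.DataFrame(index=df.index)
    work[spec.outcome] = df[spec.outcome].astype(float)
    for role in roles:
        col = cols[role]
        if role in CONTINUOUS:
            work[role] = df[col].astype(float)
        elif role == "sex":
            work["female_sex"] = (df[col] == "female").astype(float)
        elif role == "diabetes":
            work["diabetes"] = df[col].astype(float)
        elif role == "smoking":
            work["smoking_ex"] = (df[col] == "ex").astype(float)
            work["smoking_active"] = (df[col] == "active").astype(float)
        elif role in ("bp_source", "centre"):
            ref = _reference_level(df[col])
            for lvl in sorted(df[col].unique()):
                if lvl != ref:
                    work[f"{role}[{lvl}]"] = (df[col] == lvl).astype(float)
        else:  # pragma: no cover
            raise ValueError(f"unknown model role {role!r}")

    if spec.standardized:
        to_std = [spec.outcome] + [r for r in roles if r in CONTINUOUS]
        work = standardize(work, to_std)

    if interaction is not None:
        if "female_sex" not in work or work["female_sex"].nunique() < 2:
            raise ValueError("interaction test requires both sexes in the sample")
        work[f"{interaction}_x_female"] = work[interaction] * work["female_sex"]

    y = work[spec.outcome]
    X = sm.add_constant(work.drop(columns=[spec.outcome]), has_constant="add")
    Xa = X.to_numpy()
    if np.linalg.matrix_rank(Xa) < X.shape[1]:
        rdiag = np.abs(np.diag(np.linalg.qr(Xa)[1]))
        bad = [c for c, d in zip(X.columns, rdiag) if d < 1e-8 * rdiag.max()]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    if n <= X.shape[1]:
        raise ValueError(f"n = {n} rows is not larger than the {X.shape[1]} model columns")
    return y, X, n


def _estimates_from_fit(res, X, n, spec: ModelSpec, terms=None, stratum="") -> list[EffectEstimate]:
    ci = res.conf_int(alpha=0.05)
    out = []
    for term in X.columns:
        if term == "const":
            continue
        if terms is not None and term not in terms:
            continue
        scale = ("standardized" if spec.standardized
                 else ("per_mmHg" if term in ("sbp", "dbp") else "per_unit"))
        out.append(EffectEstimate(term=term, beta=float(res.params[term]),
                                  ci_low=float(ci.loc[term, 0]),
                                  ci_high=float(ci.loc[term, 1]),
                                  scale=scale, n=n, stratum=stratum))
    return out


def _roles_for(spec: ModelSpec, exposure_group=None, drop=()):
    if spec.adjustment == "full":
        roles = list(spec.exposures)
        for r in FULL_ADJUSTMENT:
            if r not in roles:
                roles.append(r)
        if spec.timing == "past":
            roles.append("time_diff")
    elif spec.adjustment == "age_sex":
        roles = list(exposure_group) + ["age", "sex"]
    else:
        roles = list(exposure_group)
    return [r for r in dict.fromkeys(roles) if r not in drop]


def fit_linear_model(table: pd.DataFrame, spec: ModelSpec, *, drop_roles=(),
                     stratum="") -> list[EffectEstimate]:
    """OLS estimates with normal-theory (t) 95% confidence intervals.

    ``full`` adjustment fits one joint model and reports every term;
    ``unadjusted`` and ``age_sex`` fit each exposure in its own (minimally
    adjusted) model, as in the published effect tables.  Complete-case on the
    model's variables; ``n`` is the number of rows actually used.
    """
    if spec.adjustment == "full":
        roles = _roles_for(spec, drop=drop_roles)
        y, X, n = _build_design(table, spec, roles)
        res = sm.OLS(y, X).fit()
        return _estimates_from_fit(res, X, n, spec, stratum=stratum)
    out = []
    for exposure in spec.exposures:
        roles = _roles_for(spec, exposure_group=[exposure], drop=drop_roles)
        if not roles:
            continue
        y, X, n = _build_design(table, spec, roles)
        res = sm.OLS(y, X).fit()
        wanted = {"smoking": ("smoking_ex", "smoking_active"),
                  "sex": ("female_sex",)}.get(exposure, (exposure,))
        out.extend(_estimates_from_fit(res, X, n, spec, terms=wanted, stratum=stratum))
    return out


def effect_ratio_per_unit(beta_per_mmHg: float, which: str,
                          ci: tuple[float, float] | None = None,
                          n: int = 0) -> EffectEstimate:
    """Multiplicative WMH-load ratio per 10 mmHg SBP or 5 mmHg DBP.

    ``beta_per_mmHg`` must come from the unstandardized logit-scale model;
    the ratio is exp(beta × unit) and CI endpoints transform the same way.
    """
    if which not in RATIO_UNITS:
        raise ValueError("which must be 'sbp' or 'dbp'")
    if not np.isfinite(beta_per_mmHg):
        raise ValueError("beta must be finite")
    unit = RATIO_UNITS[which]
    lo, hi = (ci if ci is not None else (beta_per_mmHg, beta_per_mmHg))
    return EffectEstimate(
        term=which, beta=math.exp(beta_per_mmHg * unit),
        ci_low=math.exp(lo * unit), ci_high=math.exp(hi * unit),
        scale=f"ratio_per_{int(unit)}mmHg_{which}", n=n)


#: minimum complete-case rows beyond the column count before a stratum is fit
MIN_STRATUM_MARGIN = 10


def fit_stratified(table: pd.DataFrame, spec: ModelSpec, strata_def: str,
                   ) -> tuple[dict[str, list[EffectEstimate]], list[str]]:
    """Independent fits per stratum; the stratifying variable leaves the
    adjustment set (age for age-group strata, sex for sex strata, time_diff
    for the follow-up-duration median split).

    Returns ``(estimates_by_stratum, skipped)`` where ``skipped`` lists
    strata too small to fit.
    """
    if strata_def == "age_group":
        scheme = "followup" if spec.timing == "concurrent" else "baseline"
        key = table[f"age_group_{scheme}"]
        drop = ("age",)
        order = list(ingest.AGE_LABELS[scheme])
    elif strata_def == "sex":
        key = table["sex"]
        drop = ("sex",)
        order = ["female", "male"]
    elif strata_def == "duration":
        med = float(np.nanmedian(table["time_diff"].to_numpy(dtype=float)))
        key = np.where(table["time_diff"] <= med, "short_followup", "long_followup")
        key = pd.Series(key, index=table.index)
        drop = ("time_diff",)
        order = ["short_followup", "long_followup"]
    else:
        raise ValueError(f"unknown strata_def {strata_def!r}")

    results: dict[str, list[EffectEstimate]] = {}
    skipped: list[str] = []
    for label in order:
        sub = table[key == label]
        try:
            results[label] = fit_linear_model(sub, spec, drop_roles=drop, stratum=label)
        except ValueError:
            skipped.append(label)
    return results, skipped


def interaction_test(table: pd.DataFrame, spec: ModelSpec, exposure: str = "sbp",
                     by: str = "sex") -> EffectEstimate:
    """Coefficient of the exposure × female term in the fully adjusted model."""
    if by != "sex":
        raise ValueError("only sex interactions are supported")
    full = replace(spec, adjustment="full")
    roles = _roles_for(full)
    y, X, n = _build_design(table, full, roles, interaction=exposure)
    res = sm.OLS(y, X).fit()
    term = f"{exposure}_x_female"
    ci = res.conf_int(alpha=0.05)
    return EffectEstimate(term=term, beta=float(res.params[term]),
                          ci_low=float(ci.loc[term, 0]), ci_high=float(ci.loc[term, 1]),
                          scale="standardized" if spec.standardized else "per_mmHg",
                          n=n)


def estimates_to_frame(estimates, **extra) -> pd.DataFrame:
    rows = [{"term": e.term, "beta": e.beta, "ci_low": e.ci_low,
             "ci_high": e.ci_high, "scale": e.scale, "stratum": e.stratum,
             "n": e.n, **extra} for e in estimates]
    return pd.DataFrame(rows)
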