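"""WMH by hypertension category and antihypertensive treatment.

Participants are classified into four severity categories by the *worse* of
their SBP and DBP bands — the categories are phrased as an "or" rule, so a
normotensive SBP with a hypertensive DBP still counts as hypertensive:

=================  =======================  ==========================
category           untreated reading        treated reading
=================  =======================  ==========================
low_range_nt       SBP <120 and DBP <70     very well-controlled HT
high_range_nt      SBP 120–130 or DBP 70–80 well-controlled HT
pre_ht             SBP 130–140 or DBP 80–90 controlled HT
ht                 SBP ≥140 or DBP ≥90      uncontrolled HT
=================  =======================  ==========================

crossed with the medication flag.  Each category is contrasted against
unmedicated low-range-normotensive participants in a multivariable linear
model of logit WMH load adjusted for decade of age, sex, arterial stiffness,
smoking, diabetes, assessment centre and (for baseline BP) the inter-visit
interval; per-category medians/quantiles are also emitted as plotting data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import ingest
from .models import EffectEstimate, _reference_level

SEVERITY_LABELS = ("low_range_nt", "high_range_nt", "pre_ht", "ht")
REFERENCE_CATEGORY = "low_range_nt/unmedicated"


@dataclass(frozen=True)
class TreatmentCategory:
    severity: str
    medicated: bool

    @property
    def label(self) -> str:
        return f"{self.severity}/{'medicated' if self.medicated else 'unmedicated'}"


def assign_treatment_category(sbp: float, dbp: float, medicated: bool) -> TreatmentCategory:
    """Severity = max of the SBP-band and DBP-band severities, × medication."""
    sev = int(np.maximum(_severity(sbp, "sbp"), _severity(dbp, "dbp")))
    return TreatmentCategory(SEVERITY_LABELS[sev], bool(medicated))


def _severity(value, which: str):
    edges = ingest.SBP_BAND_EDGES if which == "sbp" else ingest.DBP_BAND_EDGES
    v = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError(f"invalid {which} value")
    return np.digitize(v, edges, right=False)


def categorize(analysis: pd.DataFrame, timing: str = "past") -> pd.Series:
    """Vectorized category labels using the visit matching ``timing``.

    ``past`` categorizes on baseline BP and baseline medication (the
    treatment-at-baseline stratification); ``concurrent`` on follow-up.
    """
    visit = "baseline" if timing == "past" else "followup"
    sev = np.maximum(_severity(analysis[f"sbp_{visit}"].to_numpy(dtype=float), "sbp"),
                     _severity(analysis[f"dbp_{visit}"].to_numpy(dtype=float), "dbp"))
    med = analysis[f"antihypertensive_{visit}"].to_numpy(dtype=bool)
    labels = np.array([f"{SEVERITY_LABELS[s]}/{'medicated' if m else 'unmedicated'}"
                       for s, m in zip(sev, med)], dtype=object)
    return pd.Series(labels, index=analysis.index, name="treatment_category")


def category_medians(analysis: pd.DataFrame, timing: str = "past") -> pd.DataFrame:
    """Per (age group × category) quantiles of logit WMH load (plotting data)."""
    visit = "baseline" if timing == "past" else "followup"
    sub = analysis if timing == "concurrent" else analysis[analysis["is_longitudinal"]]
    sub = sub.dropna(subset=[f"sbp_{visit}", f"dbp_{visit}", "wmh_logit"])
    df = pd.DataFrame({
        "age_group": sub[f"age_group_{visit}"].to_numpy(),
        "category": categorize(sub, timing).to_numpy(),
        "wmh_logit": sub["wmh_logit"].to_numpy(dtype=float),
    })
    qs = {"q05": 0.05, "q25": 0.25, "median": 0.5, "q75": 0.75, "q95": 0.95}
    rows = []
    for (ag, cat), grp in df.groupby(["age_group", "category"], sort=True):
        rec = {"age_group": ag, "category": cat, "n": len(grp)}
        rec.update({k: float(grp["wmh_logit"].quantile(q)) for k, q in qs.items()})
        rows.append(rec)
    return pd.DataFrame(rows)


def compare_to_reference(analysis: pd.DataFrame, timing: str = "past",
                         ) -> tuple[list[EffectEstimate], pd.DataFrame]:
    """Contrast every category against unmedicated low-range normotensives.

    Returns the model contrasts (one per non-reference category, pooled over
    age with decade-of-age as a numeric covariate) and the per-age-group
    category medians, which are computed before — and are invariant to — the
    model adjustment.
    """
    if timing not in ("past", "concurrent"):
        raise ValueError("timing must be 'past' or 'concurrent'")
    visit = "baseline" if timing == "past" else "followup"
    sub = analysis if timing == "concurrent" else analysis[analysis["is_longitudinal"]]
    needed = [f"sbp_{visit}", f"dbp_{visit}", f"age_{visit}", f"asi_{visit}",
              "sex", "smoking", "diabetes", "centre", "wmh_logit"]
    if timing == "past":
        needed.append("time_diff")
    sub = sub.dropna(subset=needed)
    cats = categorize(sub, timing)
    if (cats == REFERENCE_CATEGORY).sum() == 0:
        raise ValueError("reference category (unmedicated low-range normotensive) is empty")

    X = pd.DataFrame(index=sub.index)
    present = [c for c in sorted(cats.unique()) if c != REFERENCE_CATEGORY]
    for c in present:
        X[f"cat[{c}]"] = (cats == c).astype(float)
    X["decade_of_age"] = np.floor(sub[f"age_{visit}"].to_numpy(dtype=float) / 10.0)
    X["female_sex"] = (sub["sex"] == "female").astype(float)
    X["asi"] = sub[f"asi_{visit}"].to_numpy(dtype=float)
    X["smoking_ex"] = (sub["smoking"] == "ex").astype(float)
    X["smoking_active"] = (sub["smoking"] == "active").astype(float)
    X["diabetes"] = sub["diabetes"].astype(float)
    ref_centre = _reference_level(sub["centre"])
    for lvl in sorted(sub["centre"].unique()):
        if lvl != ref_centre:
            X[f"centre[{lvl}]"] = (sub["centre"] == lvl).astype(float)
    if timing == "past":
        X["time_diff"] = sub["time_diff"].to_numpy(dtype=float)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design in treatment-category model")
    res = sm.OLS(sub["wmh_logit"].astype(float), X).fit()
    ci = res.conf_int(alpha=0.05)
    estimates = [
        EffectEstimate(term=c, beta=float(res.params[f"cat[{c}]"]),
                       ci_low=float(ci.loc[f"cat[{c}]", 0]),
                       ci_high=float(ci.loc[f"cat[{c}]", 1]),
                       scale="logit_wmh_difference", n=len(sub))
        for c in present
    ]
    return estimates, category_medians(analysis, timing)
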