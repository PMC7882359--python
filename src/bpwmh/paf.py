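"""Population attributable fraction of severe (top-decile) WMH load.

The case definition is a WMH load above the sample's 90th percentile; the
exposure is elevated BP dichotomized at the guideline-adjacent thresholds
(SBP > 120 mmHg, DBP > 70 mmHg — strict inequalities).  The adjusted PAF is
computed by logistic g-computation (model-based standardization): fit a
logistic model of the case flag on the exposure indicator plus covariates,
then contrast the mean predicted risk as observed with the mean predicted
risk after setting everyone to unexposed:

    PAF = (p_obs − p_cf) / p_obs .

With an empty adjustment set the logistic model is saturated in the exposure
and this reduces exactly to Levin's classical formula
pe·(RR−1) / (1 + pe·(RR−1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .models import FULL_ADJUSTMENT, ModelSpec, _build_design, _column

#: strict exposure thresholds, mmHg
EXPOSURE_THRESHOLDS = {"sbp": 120.0, "dbp": 70.0}


@dataclass
class PAFEstimate:
    exposure: str            # e.g. "sbp>120"
    timing: str              # concurrent | past
    adjustment: str          # none | full
    paf: float
    n_cases: int
    n: int
    prevalence_exposed: float


def top_decile_indicator(loads) -> np.ndarray:
    """Flag loads strictly above the sample 90th percentile.

    The percentile uses linear interpolation of order statistics (the numpy
    default), and the comparison is strict, so for continuous data ~10% of
    values are flagged while fully tied data flag nothing.
    """
    arr = np.asarray(loads, dtype=float)
    if arr.ndim != 1 or len(arr) < 10:
        raise ValueError("need at least 10 loads to define a top decile")
    if np.any(~((arr > 0.0) & (arr < 1.0))):
        raise ValueError("loads must lie strictly inside (0, 1)")
    return arr > np.quantile(arr, 0.9)


def estimate_paf(table: pd.DataFrame, exposure: str = "sbp",
                 timing: str = "concurrent", adjustment: str = "full",
                 threshold: float | None = None) -> PAFEstimate:
    """Adjusted PAF of top-decile WMH load for elevated SBP or DBP.

    The top decile is computed within the complete-case analysis sample of
    this call (cross-sectional or longitudinal), not on any external scale.
    Raises when either exposure arm is empty or the logistic fit separates.
    """
    if exposure not in EXPOSURE_THRESHOLDS:
        raise ValueError("exposure must be 'sbp' or 'dbp'")
    if adjustment not in ("none", "full"):
        raise ValueError("adjustment must be 'none' or 'full'")
    thr = EXPOSURE_THRESHOLDS[exposure] if threshold is None else float(threshold)

    # check the exposure arms before design construction: a single-arm
    # population must fail with the PAF-specific message, not a rank error
    bp_raw = table[_column(exposure, timing)].dropna()
    if (bp_raw > thr).sum() == 0:
        raise ValueError("no exposed participants; PAF undefined")
    if (bp_raw <= thr).sum() == 0:
        raise ValueError("no unexposed participants; PAF undefined")

    other = "dbp" if exposure == "sbp" else "sbp"
    if adjustment == "full":
        roles = [exposure, other, *FULL_ADJUSTMENT]
        if timing == "past":
            roles.append("time_diff")
    else:
        roles = [exposure]
    spec = ModelSpec(outcome="wmh_load", exposures=(exposure,),
                     adjustment="full", timing=timing, standardized=False)
    # reuse the model-design machinery on the raw (unstandardized) columns
    y_load, X, n = _build_design(table, spec, [r for r in dict.fromkeys(roles)])

    flags = top_decile_indicator(y_load.to_numpy())
    exposed = (X[exposure] > thr).to_numpy().astype(float)
    if exposed.sum() == 0:
        raise ValueError("no exposed participants; PAF undefined")
    if exposed.sum() == len(exposed):
        raise ValueError("no unexposed participants; PAF undefined")

    Xd = X.drop(columns=[exposure]).copy()
    Xd.insert(1, "exposed", exposed)
    try:
        res = sm.GLM(flags.astype(float), Xd,
                     family=sm.families.Binomial()).fit(maxiter=200)
    except Exception as err:  # statsmodels raises PerfectSeparationError and kin
        raise ValueError(f"logistic model failed (possible separation): {err}") from err
    if not np.all(np.isfinite(res.params)) or np.abs(res.params).max() > 50:
        raise ValueError("logistic model appears separated (diverging coefficients)")

    p_obs = float(res.predict(Xd).mean())
    X_cf = Xd.copy()
    X_cf["exposed"] = 0.0
    p_cf = float(res.predict(X_cf).mean())
    paf = (p_obs - p_cf) / p_obs
    return PAFEstimate(
        exposure=f"{exposure}>{thr:g}", timing=timing, adjustment=adjustment,
        paf=paf, n_cases=int(flags.sum()), n=n,
        prevalence_exposed=float(exposed.mean()))
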