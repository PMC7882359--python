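"""Regression-dilution-adjusted ("usual BP") analysis.

A single visit's BP overstates the spread of long-term BP, so a naive slope
of WMH on baseline BP is attenuated (regression dilution bias).  The classic
correction stratifies participants by their *baseline* BP band and replaces
each stratum's exposure value by its **usual BP** — the stratum mean of the
*follow-up* measurement — which is an unbiased estimate of the stratum's
long-term BP because the follow-up measurement error is independent of the
baseline-defined grouping.

Within each (baseline age group × baseline BP band) stratum the median WMH
load is expressed as a ratio to the reference stratum (lowest band within
the youngest age group); the log of that ratio is regressed on usual BP, and
the slope is reported as a multiplicative median-WMH ratio per 10 mmHg SBP
or 5 mmHg DBP.  Confidence intervals come from a non-parametric percentile
bootstrap that resamples participants and recomputes the whole pipeline
(strata, medians, regression) in every replicate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ingest
from .models import RATIO_UNITS

BAND_LABELS = {"sbp": ingest.SBP_BAND_LABELS, "dbp": ingest.DBP_BAND_LABELS}
AGE_GROUPS = ingest.AGE_LABELS["baseline"]


@dataclass
class StratumSummary:
    age_group: str
    bp_band: str
    which: str
    n: int
    usual_bp: float
    median_wmh: float
    ratio_to_reference: float
    log_ratio: float


@dataclass
class UsualBPFit:
    which: str
    scope: str                    # an age group, or "overall"
    slope_per_mmHg: float
    ratio_per_unit: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    seed: int | None = None
    n_strata: int = 0
    n_redrawn: int = 0


def _compact(analysis: pd.DataFrame, which: str, *, exclude_medicated: bool = False,
             usual_from: str = "followup") -> pd.DataFrame:
    """Minimal columns needed per participant for the stratified analysis."""
    sub = analysis[analysis["is_longitudinal"]]
    if exclude_medicated:
        sub = sub[~sub["antihypertensive_baseline"]]
    out = pd.DataFrame({
        "age_group": sub["age_group_baseline"].to_numpy(),
        "band": sub[f"bp_band_{which}_baseline"].to_numpy(),
        "usual_src_bp": sub[f"{which}_{usual_from}"].to_numpy(dtype=float),
        "load": sub["wmh_load"].to_numpy(dtype=float),
    }).dropna()
    out["age_group"] = pd.Categorical(out["age_group"], categories=AGE_GROUPS)
    out["band"] = pd.Categorical(out["band"], categories=BAND_LABELS[which])
    return out.reset_index(drop=True)


def _summarize(compact: pd.DataFrame, which: str, min_n: int) -> list[StratumSummary]:
    g = compact.groupby(["age_group", "band"], sort=False, observed=True)
    agg = g.agg(n=("load", "size"), usual_bp=("usual_src_bp", "mean"),
                median_wmh=("load", "median"))
    ref_key = (AGE_GROUPS[0], BAND_LABELS[which][0])
    if ref_key not in agg.index or agg.loc[ref_key, "n"] < min_n:
        raise ValueError(
            "reference stratum (youngest age group, lowest BP band) is empty "
            "or below min_n; the usual-BP analysis is undefined")
    agg = agg[agg["n"] >= min_n]
    ref_median = float(agg.loc[ref_key, "median_wmh"])
    out = []
    for ag in AGE_GROUPS:
        for band in BAND_LABELS[which]:
            if (ag, band) not in agg.index:
                continue
            row = agg.loc[(ag, band)]
            is_ref = (ag, band) == ref_key
            ratio = 1.0 if is_ref else float(row["median_wmh"]) / ref_median
            out.append(StratumSummary(
                age_group=ag, bp_band=band, which=which, n=int(row["n"]),
                usual_bp=float(row["usual_bp"]), median_wmh=float(row["median_wmh"]),
                ratio_to_reference=ratio,
                log_ratio=0.0 if is_ref else float(np.log(ratio))))
    return out


def build_strata(analysis: pd.DataFrame, which: str, *, min_n: int = 20,
                 exclude_medicated: bool = False,
                 usual_from: str = "followup") -> list[StratumSummary]:
    """One summary per baseline age group × baseline BP band with ≥ min_n members.

    ``usual_from='baseline'`` gives the *naive* variant (stratum mean of the
    same baseline measurement that defined the stratum) used to demonstrate
    regression dilution; the default uses the follow-up measurement.
    """
    if which not in BAND_LABELS:
        raise ValueError("which must be 'sbp' or 'dbp'")
    compact = _compact(analysis, which, exclude_medicated=exclude_medicated,
                       usual_from=usual_from)
    return _summarize(compact, which, min_n)


def fit_log_ratio_regression(strata: list[StratumSummary], scope: str = "overall",
                             weighted: bool = False) -> UsualBPFit:
    """Least squares of log median-WMH ratio on usual BP, unweighted by
    default; ``weighted=True`` weights strata by membership (sensitivity
    option).

    ``scope`` is "overall" (all strata, pooling age groups) or one age-group
    label.  The slope converts to a ratio per 10 mmHg (SBP) / 5 mmHg (DBP).
    """
    sel = [s for s in strata if scope == "overall" or s.age_group == scope]
    if len(sel) < 2:
        raise ValueError(f"need at least 2 strata in scope {scope!r}")
    x = np.array([s.usual_bp for s in sel])
    y = np.array([s.log_ratio for s in sel])
    if np.ptp(x) <= 0:
        raise ValueError("zero spread in usual BP across strata")
    w = np.array([s.n for s in sel], dtype=float) if weighted else None
    slope = _ols_slope(x, y, w)
    which = sel[0].which
    unit = RATIO_UNITS[which]
    return UsualBPFit(which=which, scope=scope, slope_per_mmHg=slope,
                      ratio_per_unit=float(np.exp(slope * unit)), n_strata=len(sel))


def _ols_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None) -> float:
    if w is None:
        w = np.ones_like(x)
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    xc = x - xm
    return float((w * xc) @ (y - ym) / ((w * xc) @ xc))


def bootstrap_ci(analysis: pd.DataFrame, estimator, n_boot: int = 1000,
                 seed: int = 0, *, max_failure_rate: float = 0.10,
                 return_diagnostics: bool = False):
    """Percentile bootstrap CI of a scalar estimator of the analysis table.

    Participants (rows) are resampled with replacement and the estimator is
    re-run on each replicate.  Replicates on which the estimator raises
    ``ValueError`` (e.g. an empty reference stratum) are redrawn; if more
    than ``max_failure_rate`` of the attempted replicates fail, the data are
    judged too fragile to bootstrap and an error is raised.  Deterministic
    given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    rng = np.random.default_rng(seed)
    n = len(analysis)
    values = np.empty(n_boot)
    failures = 0
    got = 0
    while got < n_boot:
        idx = rng.integers(0, n, n)
        try:
            values[got] = estimator(analysis.iloc[idx])
            got += 1
        except ValueError:
            failures += 1
            if failures > max_failure_rate * (n_boot + failures):
                raise ValueError(
                    f"estimator failed on {failures} bootstrap replicates "
                    f"(> {max_failure_rate:.0%} of attempts)")
    lo, hi = np.quantile(values, [0.025, 0.975])
    if return_diagnostics:
        return float(lo), float(hi), {"n_redrawn": failures}
    return float(lo), float(hi)


def fit_usual_bp(analysis: pd.DataFrame, which: str, *, n_boot: int = 1000,
                 seed: int = 0, min_n: int = 20, exclude_medicated: bool = False,
                 scopes=None) -> list[UsualBPFit]:
    """Point fits plus bootstrap CIs for every scope in one resampling pass.

    Scopes default to "overall" plus every baseline age group that yields a
    fit on the point data.  CIs are percentile intervals of the per-replicate
    ratio per unit; all scopes share the same resampled replicates.
    """
    compact = _compact(analysis, which, exclude_medicated=exclude_medicated)
    strata = _summarize(compact, which, min_n)
    if scopes is None:
        scopes = ["overall"]
        for ag in AGE_GROUPS:
            try:
                fit_log_ratio_regression(strata, ag)
                scopes.append(ag)
            except ValueError:
                pass
    point = {sc: fit_log_ratio_regression(strata, sc) for sc in scopes}

    rng = np.random.default_rng(seed)
    n = len(compact)
    slopes = {sc: np.empty(n_boot) for sc in scopes}
    failures = 0
    got = 0
    while got < n_boot:
        idx = rng.integers(0, n, n)
        sub = compact.iloc[idx]
        try:
            strata_b = _summarize(sub, which, min_n)
            rep = {sc: fit_log_ratio_regression(strata_b, sc).slope_per_mmHg
                   for sc in scopes}
        except ValueError:
            failures += 1
            if failures > 0.10 * (n_boot + failures):
                raise ValueError(
                    f"usual-BP estimator failed on {failures} bootstrap replicates")
            continue
        for sc in scopes:
            slopes[sc][got] = rep[sc]
        got += 1

    unit = RATIO_UNITS[which]
    out = []
    for sc in scopes:
        lo, hi = np.quantile(slopes[sc], [0.025, 0.975])
        fit = point[sc]
        fit.ci_low = float(np.exp(lo * unit))
        fit.ci_high = float(np.exp(hi * unit))
        fit.n_boot = n_boot
        fit.seed = seed
        fit.n_redrawn = failures
        out.append(fit)
    return out


def strata_to_frame(strata: list[StratumSummary]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in strata])


def fits_to_frame(fits: list[UsualBPFit]) -> pd.DataFrame:
    return pd.DataFrame([vars(f) for f in fits])
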