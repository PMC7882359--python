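"""Harmonize the two-visit cohort into the per-participant analysis table.

Responsibilities: choose a BP source per visit with the fixed preference
order automated > manual > pulse-wave analysis (PWA), average the paired
readings within a visit, compute the WMH load (WMH volume as a proportion of
total white-matter volume, or of total brain volume in the sensitivity
variant) and its logit, assign left-closed BP bands and age groups, and apply
the eligibility filters in a fixed, audited order.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import BP_SOURCES

# Left-closed band edges: value v falls in [edge[i], edge[i+1]).
SBP_BAND_EDGES = (120.0, 130.0, 140.0)
SBP_BAND_LABELS = ("<120", "120-130", "130-140", ">=140")
DBP_BAND_EDGES = (70.0, 80.0, 90.0)
DBP_BAND_LABELS = ("<70", "70-80", "80-90", ">=90")

AGE_EDGES = {"baseline": (50.0, 60.0), "followup": (60.0, 70.0)}
AGE_LABELS = {
    "baseline": ("<50", "50-60", ">=60"),
    "followup": ("<60", "60-70", ">=70"),
}
AGE_PLAUSIBLE = (30.0, 100.0)


def logit(p):
    """log(p / (1 − p)) for p strictly inside (0, 1); no clamping.

    Loads of exactly 0 or 1 indicate an upstream fault (the generator and the
    load definition both guarantee interior values) and raise rather than
    being imputed.
    """
    arr = np.asarray(p, dtype=float)
    if np.any(~((arr > 0.0) & (arr < 1.0))):
        raise ValueError("logit requires values strictly inside (0, 1)")
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) else out


def compute_wmh_load(wmh_volume, denom_volume):
    """WMH volume as a proportion of a reference volume (both mm³)."""
    w = np.asarray(wmh_volume, dtype=float)
    d = np.asarray(denom_volume, dtype=float)
    if np.any(w <= 0) or np.any(d <= 0):
        raise ValueError("volumes must be strictly positive")
    if np.any(w >= d):
        raise ValueError("WMH volume must be smaller than the reference volume")
    out = w / d
    return float(out) if np.isscalar(wmh_volume) else out


def _band(values, edges, labels):
    v = np.atleast_1d(np.asarray(values, dtype=float))
    idx = np.digitize(v, edges, right=False)  # left-closed: edge -> upper band
    return np.asarray(labels, dtype=object)[idx]


def assign_bp_band(value, which: str):
    """Left-closed BP band for a single value or array (``which``: sbp|dbp)."""
    edges, labels = ((SBP_BAND_EDGES, SBP_BAND_LABELS) if which == "sbp"
                     else (DBP_BAND_EDGES, DBP_BAND_LABELS))
    v = np.asarray(value, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v <= 0):
        raise ValueError(f"{which} values must be finite and positive")
    out = _band(v, edges, labels)
    return out[0] if np.isscalar(value) else out


def assign_age_group(age, scheme: str):
    """Left-closed age group under the baseline or follow-up scheme."""
    if scheme not in AGE_EDGES:
        raise ValueError(f"scheme must be 'baseline' or 'followup', got {scheme!r}")
    a = np.asarray(age, dtype=float)
    lo, hi = AGE_PLAUSIBLE
    if np.any(~np.isfinite(a)) or np.any((a < lo) | (a > hi)):
        raise ValueError(f"age outside plausible range [{lo}, {hi}]")
    out = _band(a, AGE_EDGES[scheme], AGE_LABELS[scheme])
    return out[0] if np.isscalar(age) else out


def select_bp_source(visit) -> tuple[float, float, str]:
    """Harmonized (SBP, DBP, source) for one visit row.

    Sources are tried in the preference order automated, manual, PWA; a
    source is usable when it carries at least one SBP and one DBP reading.
    The available readings (two, or a single one) are averaged within the
    visit.  Raises ``ValueError`` when no source is usable — callers treat
    that as missing BP and exclude the row.
    """
    for src in BP_SOURCES:
        s = [visit.get(f"sbp_{src}_{i}") for i in (1, 2)]
        d = [visit.get(f"dbp_{src}_{i}") for i in (1, 2)]
        s = [x for x in s if x is not None and np.isfinite(x)]
        d = [x for x in d if x is not None and np.isfinite(x)]
        if s and d:
            return float(np.mean(s)), float(np.mean(d)), src
    raise ValueError("no usable BP source for this visit")


def _select_bp_vectorized(df: pd.DataFrame, exclude_pwa: bool = False):
    """Vectorized source selection over visit rows.

    Returns (sbp, dbp, source, single_reading) arrays; NaN/None where no
    source is usable.
    """
    n = len(df)
    sbp = np.full(n, np.nan)
    dbp = np.full(n, np.nan)
    source = np.full(n, None, dtype=object)
    single = np.zeros(n, dtype=bool)
    sources = [s for s in BP_SOURCES if not (exclude_pwa and s == "pwa")]
    for src in sources:
        s1 = df[f"sbp_{src}_1"].to_numpy(dtype=float)
        s2 = df[f"sbp_{src}_2"].to_numpy(dtype=float)
        d1 = df[f"dbp_{src}_1"].to_numpy(dtype=float)
        d2 = df[f"dbp_{src}_2"].to_numpy(dtype=float)
        usable = (np.isfinite(s1) | np.isfinite(s2)) & (np.isfinite(d1) | np.isfinite(d2))
        take = usable & pd.isna(source)
        if not take.any():
            continue

        def _mean2(a, b):
            cnt = np.isfinite(a).astype(float) + np.isfinite(b)
            tot = np.nan_to_num(a) + np.nan_to_num(b)
            return np.where(cnt > 0, tot / np.maximum(cnt, 1.0), np.nan)

        sbp[take] = _mean2(s1, s2)[take]
        dbp[take] = _mean2(d1, d2)[take]
        source[take] = src
        n_read = (np.isfinite(s1).astype(int) + np.isfinite(s2)
                  + np.isfinite(d1) + np.isfinite(d2))
        single[take] = n_read[take] < 4
    return sbp, dbp, source, single


def apply_eligibility(visits: pd.DataFrame, *, brain_volume_denominator: bool = False,
                      exclude_pwa: bool = False) -> tuple[pd.DataFrame, dict]:
    """Derive the analysis table and an audit of rows removed at each filter.

    Filter order is fixed: missing WMH volume → exclusion diagnosis flag →
    missing follow-up BP (these three define the cross-sectional sample) →
    missing baseline BP (rows failing only this stay in the table with
    ``is_longitudinal = False``).

    Returns ``(analysis, audit)`` where ``analysis`` has one row per
    cross-sectionally eligible participant and ``audit`` maps each filter to
    the participant count it removed.
    """
    _check_schema(visits)
    base = visits[visits["visit"] == "baseline"].set_index("participant_id")
    follow = visits[visits["visit"] == "followup"].set_index("participant_id")
    audit: dict[str, int] = {"n_input_participants": follow.index.nunique()}

    # 1. missing WMH (or missing reference volume)
    has_wmh = follow["wmh_volume"].notna() & follow["wm_volume"].notna()
    if brain_volume_denominator:
        has_wmh &= follow["gm_volume"].notna() & follow["csf_volume"].notna()
    audit["missing_wmh"] = int((~has_wmh).sum())
    follow = follow[has_wmh]

    # 2. exclusion diagnoses
    excl = follow["exclusion_flag"].astype(bool)
    audit["exclusion_flag"] = int(excl.sum())
    follow = follow[~excl]

    # 3. follow-up BP
    sbp_f, dbp_f, src_f, single_f = _select_bp_vectorized(follow, exclude_pwa)
    ok = np.isfinite(sbp_f)
    audit["missing_followup_bp"] = int((~ok).sum())
    follow = follow[ok]
    sbp_f, dbp_f, src_f, single_f = sbp_f[ok], dbp_f[ok], src_f[ok], single_f[ok]

    # 4. baseline BP (longitudinal subset only)
    base = base.reindex(follow.index)
    have_base = base["visit"].notna()
    sbp_b = np.full(len(base), np.nan)
    dbp_b = np.full(len(base), np.nan)
    src_b = np.full(len(base), None, dtype=object)
    single_b = np.zeros(len(base), dtype=bool)
    if have_base.any():
        hb = have_base.to_numpy()
        sb, db, sr, sg = _select_bp_vectorized(base[hb], exclude_pwa)
        sbp_b[hb], dbp_b[hb], src_b[hb], single_b[hb] = sb, db, sr, sg
    is_long = np.isfinite(sbp_b)
    audit["missing_baseline_bp"] = int((~is_long).sum())

    denom = follow["wm_volume"].to_numpy(dtype=float)
    if brain_volume_denominator:
        denom = (follow["wm_volume"] + follow["gm_volume"]
                 + follow["csf_volume"]).to_numpy(dtype=float)
    load = compute_wmh_load(follow["wmh_volume"].to_numpy(dtype=float), denom)
    # primary (white-matter) load is always carried alongside the variant
    load_wm = compute_wmh_load(follow["wmh_volume"].to_numpy(dtype=float),
                               follow["wm_volume"].to_numpy(dtype=float))
    load_brain = np.where(
        follow["gm_volume"].notna() & follow["csf_volume"].notna(),
        follow["wmh_volume"].to_numpy(dtype=float)
        / (follow["wm_volume"] + follow["gm_volume"] + follow["csf_volume"]).to_numpy(dtype=float),
        np.nan)

    dates_f = pd.to_datetime(follow["visit_date"])
    dates_b = pd.to_datetime(base["visit_date"])
    time_diff = (dates_f.to_numpy() - dates_b.to_numpy()) / np.timedelta64(1, "D") / 365.25
    if np.any(np.nan_to_num(time_diff, nan=1.0) <= 0):
        bad = follow.index[np.nan_to_num(time_diff, nan=1.0) <= 0].tolist()
        raise ValueError(f"non-positive follow-up interval for participants {bad[:5]}")

    analysis = pd.DataFrame({
        "participant_id": follow.index,
        "age_baseline": base["age"].to_numpy(dtype=float),
        "age_followup": follow["age"].to_numpy(dtype=float),
        "sex": follow["sex"].to_numpy(),
        "smoking": follow["smoking"].to_numpy(),
        "diabetes": follow["diabetes"].astype(bool).to_numpy(),
        "antihypertensive_baseline": base["antihypertensive"].fillna(False).astype(bool).to_numpy(),
        "antihypertensive_followup": follow["antihypertensive"].astype(bool).to_numpy(),
        "centre": follow["centre"].to_numpy(),
        "asi_baseline": base["asi"].to_numpy(dtype=float),
        "asi_followup": follow["asi"].to_numpy(dtype=float),
        "sbp_baseline": sbp_b, "dbp_baseline": dbp_b,
        "sbp_followup": sbp_f, "dbp_followup": dbp_f,
        "bp_source_baseline": src_b, "bp_source_followup": src_f,
        "single_reading_baseline": single_b, "single_reading_followup": single_f,
        "time_diff": time_diff,
        "wmh_load": load if brain_volume_denominator else load_wm,
        "wmh_load_brainvol": load_brain,
        "is_longitudinal": is_long,
    }).reset_index(drop=True)
    analysis["wmh_logit"] = logit(analysis["wmh_load"].to_numpy())

    analysis["bp_band_sbp_followup"] = assign_bp_band(analysis["sbp_followup"].to_numpy(), "sbp")
    analysis["bp_band_dbp_followup"] = assign_bp_band(analysis["dbp_followup"].to_numpy(), "dbp")
    analysis["bp_band_sbp_baseline"] = _band_or_none(analysis["sbp_baseline"], "sbp")
    analysis["bp_band_dbp_baseline"] = _band_or_none(analysis["dbp_baseline"], "dbp")
    analysis["age_group_followup"] = assign_age_group(analysis["age_followup"].to_numpy(), "followup")
    analysis["age_group_baseline"] = _age_or_none(analysis["age_baseline"])

    audit["single_reading_visits"] = int(single_b.sum() + single_f.sum())
    audit["n_cross_sectional"] = int(len(analysis))
    audit["n_longitudinal"] = int(is_long.sum())
    return analysis, audit


def _band_or_none(values: pd.Series, which: str):
    out = np.full(len(values), None, dtype=object)
    v = values.to_numpy(dtype=float)
    ok = np.isfinite(v)
    if ok.any():
        out[ok] = assign_bp_band(v[ok], which)
    return out


def _age_or_none(values: pd.Series):
    out = np.full(len(values), None, dtype=object)
    v = values.to_numpy(dtype=float)
    ok = np.isfinite(v)
    if ok.any():
        out[ok] = assign_age_group(v[ok], "baseline")
    return out


def longitudinal_subset(analysis: pd.DataFrame) -> pd.DataFrame:
    """Rows eligible for the longitudinal (past-BP) analyses."""
    return analysis[analysis["is_longitudinal"]].reset_index(drop=True)


_REQUIRED = {"participant_id", "visit", "visit_date", "age", "sex", "smoking",
             "diabetes", "antihypertensive", "centre", "asi", "wmh_volume",
             "wm_volume", "gm_volume", "csf_volume", "exclusion_flag"}


def _check_schema(visits: pd.DataFrame) -> None:
    missing = _REQUIRED - set(visits.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    fu = visits["visit"] == "followup"
    wmh = visits.loc[fu, "wmh_volume"]
    wm = visits.loc[fu, "wm_volume"]
    both = wmh.notna() & wm.notna()
    bad = visits.loc[fu].index[both & ((wmh <= 0) | (wm <= 0) | (wmh >= wm))]
    if len(bad):
        raise ValueError(
            f"invalid WMH/WM volumes (nonpositive or WMH >= WM) at rows {bad.tolist()[:10]}")


def write_analysis(analysis: pd.DataFrame, path) -> None:
    analysis.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_analysis(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("diabetes", "antihypertensive_baseline", "antihypertensive_followup",
              "single_reading_baseline", "single_reading_followup", "is_longitudinal"):
        df[c] = df[c].astype(bool)
    return df
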