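"""Synthetic longitudinal blood-pressure / WMH cohort generator.

Emulates a UK-Biobank-shaped imaging subcohort: two assessment visits ~9 years
apart, paired seated BP readings per visit from one of three sources
(automated sphygmomanometer, manual, pulse-wave analysis), cardiovascular
covariates, and a follow-up MRI from which a white-matter-hyperintensity
(WMH) volume and tissue volumes are derived.

The data-generating model is deliberately minimal but reproduces the three
phenomena the downstream analyses depend on:

* **BP tracking with measurement error** — each participant has a latent
  ("usual") BP; visit-level readings are latent BP plus independent noise, so
  a single visit's reading is an error-prone proxy and naive slopes suffer
  regression dilution.
* **A log-linear usual-BP → WMH effect** — logit(WMH load) is linear in the
  latent follow-up BP with additive Gaussian noise; for small loads
  logit ≈ log, so the median WMH load rises multiplicatively with usual BP,
  which is exactly the estimand of the usual-BP stratified analysis.
* **Confounding by indication** — antihypertensive medication is assigned
  preferentially to participants with high *latent* BP, and treatment lowers
  measured BP while WMH continues to track the untreated latent exposure, so
  medicated participants carry more WMH than unmedicated ones at the same
  measured BP.

All randomness flows from a single integer seed through named sub-streams
(one per generation stage), so adding a stage never perturbs the draws of
earlier stages and identical configs yield byte-identical cohorts.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.special import expit, logit as _logit
from scipy.stats import truncnorm

from . import reference

SCHEMA_VERSION = "bpwmh.cohort/1"

BP_SOURCES = ("automated", "manual", "pwa")

#: Reading columns, one block of four per source.
READING_COLUMNS = tuple(
    f"{which}_{src}_{i}" for src in BP_SOURCES for which in ("sbp", "dbp") for i in (1, 2)
)

COHORT_COLUMNS = (
    "participant_id", "visit", "visit_date", "age", "sex", "smoking",
    "diabetes", "antihypertensive", "centre", "asi",
    *READING_COLUMNS,
    "wmh_volume", "wm_volume", "gm_volume", "csf_volume", "exclusion_flag",
)

# Fixed sub-stream keys: append-only so that existing stages keep their draws
# when a new stage is added.
_STAGE_KEYS = {
    "demographics": 0,
    "latent_bp": 1,
    "medication": 2,
    "readings": 3,
    "sources": 4,
    "wmh": 5,
    "volumes": 6,
    "dates": 7,
    "missingness": 8,
    "exclusion": 9,
}


def _stage_rng(seed: int, stage: str):
    return default_rng(SeedSequence(entropy=int(seed), spawn_key=(_STAGE_KEYS[stage],)))


_T1B = reference.COHORT_SUMMARY["longitudinal_baseline"]


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    Defaults are calibrated to the published subcohort summary
    (:mod:`bpwmh.reference`): BP means linear in age so the baseline and
    follow-up means are reproduced, covariate prevalences from the baseline
    column, conditional WMH effects from the fully adjusted per-unit ratios,
    and the median WMH load anchored at 0.0052.  Within-person visit-level BP
    variability and the tracking correlation are assumptions (no published
    value exists); see docs/methods.md.
    """

    n_participants: int = 10_000
    seed: int = 0

    # demographics
    age_range_years: tuple[float, float] = (40.0, 70.0)
    female_fraction: float = 0.53
    diabetes_rate: float = 0.025
    smoking_probs: dict = field(
        default_factory=lambda: {"never": 0.612, "ex": 0.326, "active": 0.062})
    centres: tuple[str, ...] = ("centre_A", "centre_B", "centre_C")
    asi_mean: float = _T1B["asi_mean"]
    asi_sd: float = _T1B["asi_sd"]
    asi_followup_shift: float = 0.54
    asi_followup_sd: float = 1.5

    # follow-up interval (years), normal truncated to bounds
    follow_up_years_mean: float = 9.0
    follow_up_years_sd: float = 1.6
    follow_up_years_bounds: tuple[float, float] = (4.0, 13.5)

    # latent (usual) BP: mean linear in current age (cross-sectional slope,
    # anchored at age 55) plus a within-person follow-up shift.  SBP rises
    # cross-sectionally with age (0.39 mmHg/yr reproduces the published
    # baseline->follow-up mean change over ~8.8 years); midlife DBP is
    # cross-sectionally flat, so its published -3.72 mmHg change is modelled
    # as a within-person follow-up shift instead.
    sbp_mean: float = _T1B["sbp_mean"]
    dbp_mean: float = _T1B["dbp_mean"]
    sbp_age_slope: float = 0.39   # mmHg per year
    dbp_age_slope: float = 0.0
    sbp_followup_shift: float = 0.0
    dbp_followup_shift: float = -3.72
    sbp_latent_sd: float = 16.0
    dbp_latent_sd: float = 9.0
    sbp_dbp_corr: float = 0.70
    bp_tracking_corr: float = 0.80
    bp_within_person_sd: float = 8.0  # per-reading noise, mmHg (assumption)

    # antihypertensive medication: logistic in latent baseline SBP;
    # treatment lowers measured BP but not the latent exposure driving WMH.
    med_logit_intercept: float = -2.1
    med_logit_slope_per_mmHg: float = 0.07
    treatment_sbp_reduction: float = 10.0
    treatment_dbp_reduction: float = 5.0

    # WMH model on the logit scale
    true_log_ratio_sbp_per_mmHg: float = math.log(
        reference.CONCURRENT_RATIO_PER_10MMHG_SBP) / 10.0
    true_log_ratio_dbp_per_mmHg: float = math.log(
        reference.CONCURRENT_RATIO_PER_5MMHG_DBP) / 5.0
    #: extra SBP slope (logit WMH per mmHg) for women, centred at sbp_mean so
    #: the female main effect is unchanged; 0 = no sex-specific BP effect
    true_sex_interaction_sbp_per_mmHg: float = 0.0
    wmh_logit_noise_sd: float = 1.2
    target_median_wmh_load: float = reference.MEDIAN_WMH_LOAD
    covariate_effects: dict = field(default_factory=lambda: {
        "age_per_year": 0.10,
        "female": 0.12,
        "diabetes": 0.45,
        "smoking_ex": 0.11,
        "smoking_active": 0.33,
        "asi_per_unit": 0.01,
        "time_diff_per_year": 0.10,
    })

    # tissue volumes (mm^3)
    wm_volume_mean: float = 540_000.0
    wm_volume_sd: float = 55_000.0
    gm_volume_mean: float = 600_000.0
    gm_volume_sd: float = 60_000.0
    csf_volume_mean: float = 350_000.0
    csf_volume_sd: float = 70_000.0

    # applied by inject_missingness
    source_probabilities: dict = field(default_factory=lambda: {
        "automated": 0.90, "manual": 0.07, "pwa": 0.03})
    missingness_rates: dict = field(default_factory=lambda: {
        "wmh_volume": 0.069, "bp_followup": 0.021, "bp_baseline": 0.0005})
    exclusion_rate: float = 0.0128

    def validate(self) -> None:
        if not isinstance(self.n_participants, (int, np.integer)) or self.n_participants < 0:
            raise ValueError(f"n_participants must be a nonnegative integer, got {self.n_participants!r}")
        probs = list(self.source_probabilities.values()) + list(
            self.missingness_rates.values()) + [
            self.exclusion_rate, self.female_fraction, self.diabetes_rate,
            *self.smoking_probs.values()]
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0,1]: {p}")
        if set(self.source_probabilities) != set(BP_SOURCES):
            raise ValueError("source_probabilities must have keys automated/manual/pwa")
        if abs(sum(self.source_probabilities.values()) - 1.0) > 1e-9:
            raise ValueError("source probabilities must sum to 1")
        if abs(sum(self.smoking_probs.values()) - 1.0) > 1e-9:
            raise ValueError("smoking probabilities must sum to 1")
        if not (0.0 <= self.bp_tracking_corr <= 1.0):
            raise ValueError("bp_tracking_corr must be in [0,1]")
        if not (-1.0 < self.sbp_dbp_corr < 1.0):
            raise ValueError("sbp_dbp_corr must be in (-1,1)")
        for name in ("bp_within_person_sd", "wmh_logit_noise_sd", "sbp_latent_sd",
                     "dbp_latent_sd", "follow_up_years_sd", "asi_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and nonnegative, got {v}")
        for f_ in dataclasses.fields(self):
            v = getattr(self, f_.name)
            if isinstance(v, float) and not np.isfinite(v):
                raise ValueError(f"non-finite config value for {f_.name}")
        if not (0.0 < self.target_median_wmh_load < 1.0):
            raise ValueError("target_median_wmh_load must be in (0,1)")

    def replace(self, **kw) -> "GeneratorConfig":
        return dataclasses.replace(self, **kw)


def _expected_wmh_linpred(cfg: GeneratorConfig) -> float:
    """Population-average linear predictor of logit load, excluding intercept.

    Used to anchor the intercept so the cohort median load lands near the
    configured target (the additive noise is symmetric, so the median of the
    logit is approximately the mean of the linear predictor).
    """
    ce = cfg.covariate_effects
    age_b = 0.5 * (cfg.age_range_years[0] + cfg.age_range_years[1])
    age_f = age_b + cfg.follow_up_years_mean
    e_sbp = cfg.sbp_mean + cfg.sbp_age_slope * (age_f - 55.0) + cfg.sbp_followup_shift
    e_dbp = cfg.dbp_mean + cfg.dbp_age_slope * (age_f - 55.0) + cfg.dbp_followup_shift
    sp = cfg.smoking_probs
    return (
        cfg.true_log_ratio_sbp_per_mmHg * e_sbp
        + cfg.true_log_ratio_dbp_per_mmHg * e_dbp
        + ce.get("age_per_year", 0.0) * age_f
        + ce.get("female", 0.0) * cfg.female_fraction
        + ce.get("diabetes", 0.0) * cfg.diabetes_rate
        + ce.get("smoking_ex", 0.0) * sp.get("ex", 0.0)
        + ce.get("smoking_active", 0.0) * sp.get("active", 0.0)
        + ce.get("asi_per_unit", 0.0) * (cfg.asi_mean + cfg.asi_followup_shift)
        + ce.get("time_diff_per_year", 0.0) * cfg.follow_up_years_mean
    )


def generate_cohort(config: GeneratorConfig) -> pd.DataFrame:
    """Draw a two-visit cohort; deterministic given ``config.seed``.

    Returns a long table with one baseline and one follow-up row per
    participant (imaging columns are present on follow-up rows only).
    ``exclusion_flag`` is False everywhere; :func:`inject_missingness` sets it.
    """
    config.validate()
    cfg = config
    n = int(cfg.n_participants)
    if n == 0:
        return _empty_cohort()
    seed = cfg.seed

    # --- demographics --------------------------------------------------
    rng = _stage_rng(seed, "demographics")
    age_b = rng.uniform(*cfg.age_range_years, size=n)
    female = rng.random(n) < cfg.female_fraction
    smoking_levels = np.array(sorted(cfg.smoking_probs))
    smoking_p = np.array([cfg.smoking_probs[k] for k in smoking_levels])
    smoking = rng.choice(smoking_levels, size=n, p=smoking_p)
    diabetes = rng.random(n) < cfg.diabetes_rate
    asi_b = np.clip(rng.normal(cfg.asi_mean, cfg.asi_sd, n), 0.5, None)
    asi_f = np.clip(asi_b + rng.normal(cfg.asi_followup_shift, cfg.asi_followup_sd, n),
                    0.5, None)
    centre = rng.choice(np.array(cfg.centres), size=n)
    lo, hi = cfg.follow_up_years_bounds
    m, s = cfg.follow_up_years_mean, cfg.follow_up_years_sd
    if s > 0:
        time_diff = truncnorm.rvs((lo - m) / s, (hi - m) / s, loc=m, scale=s,
                                  size=n, random_state=rng)
    else:
        time_diff = np.full(n, m)
    age_f = age_b + time_diff

    # --- latent (usual) BP ---------------------------------------------
    rng = _stage_rng(seed, "latent_bp")
    r = cfg.sbp_dbp_corr
    t = cfg.bp_tracking_corr
    z_s = rng.standard_normal(n)
    z_d = r * z_s + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    e_s = rng.standard_normal(n)
    e_d = r * e_s + math.sqrt(1.0 - r * r) * rng.standard_normal(n)
    w_s = t * z_s + math.sqrt(1.0 - t * t) * e_s
    w_d = t * z_d + math.sqrt(1.0 - t * t) * e_d
    lat_sbp_b = cfg.sbp_mean + cfg.sbp_age_slope * (age_b - 55.0) + cfg.sbp_latent_sd * z_s
    lat_dbp_b = cfg.dbp_mean + cfg.dbp_age_slope * (age_b - 55.0) + cfg.dbp_latent_sd * z_d
    lat_sbp_f = (cfg.sbp_mean + cfg.sbp_age_slope * (age_f - 55.0)
                 + cfg.sbp_followup_shift + cfg.sbp_latent_sd * w_s)
    lat_dbp_f = (cfg.dbp_mean + cfg.dbp_age_slope * (age_f - 55.0)
                 + cfg.dbp_followup_shift + cfg.dbp_latent_sd * w_d)

    # --- medication (confounding by indication) ------------------------
    rng = _stage_rng(seed, "medication")
    p_b = expit(cfg.med_logit_intercept
                + cfg.med_logit_slope_per_mmHg * (lat_sbp_b - cfg.sbp_mean))
    med_b = rng.random(n) < p_b
    p_init = expit(cfg.med_logit_intercept
                   + cfg.med_logit_slope_per_mmHg * (lat_sbp_f - cfg.sbp_mean))
    med_f = med_b | (rng.random(n) < p_init)
    # measured (treated) latent BP; WMH keeps tracking the untreated latent
    meas_sbp_b = lat_sbp_b - cfg.treatment_sbp_reduction * med_b
    meas_dbp_b = lat_dbp_b - cfg.treatment_dbp_reduction * med_b
    meas_sbp_f = lat_sbp_f - cfg.treatment_sbp_reduction * med_f
    meas_dbp_f = lat_dbp_f - cfg.treatment_dbp_reduction * med_f

    # --- visit readings -------------------------------------------------
    rng = _stage_rng(seed, "readings")
    sd = cfg.bp_within_person_sd
    readings = {}
    for visit, (ms, md) in (("b", (meas_sbp_b, meas_dbp_b)),
                            ("f", (meas_sbp_f, meas_dbp_f))):
        for i in (1, 2):
            readings[f"sbp_{visit}_{i}"] = ms + rng.normal(0.0, sd, n) if sd > 0 else ms.copy()
            readings[f"dbp_{visit}_{i}"] = md + rng.normal(0.0, sd, n) if sd > 0 else md.copy()

    # --- BP source per visit --------------------------------------------
    rng = _stage_rng(seed, "sources")
    src_p = np.array([cfg.source_probabilities[s] for s in BP_SOURCES])
    src_b = rng.choice(len(BP_SOURCES), size=n, p=src_p)
    src_f = rng.choice(len(BP_SOURCES), size=n, p=src_p)

    # --- WMH on the logit scale ------------------------------------------
    rng = _stage_rng(seed, "wmh")
    ce = cfg.covariate_effects
    smoking_ex = (smoking == "ex").astype(float)
    smoking_act = (smoking == "active").astype(float)
    intercept = _logit(cfg.target_median_wmh_load) - _expected_wmh_linpred(cfg)
    linpred = (
        intercept
        + cfg.true_log_ratio_sbp_per_mmHg * lat_sbp_f
        + cfg.true_log_ratio_dbp_per_mmHg * lat_dbp_f
        + cfg.true_sex_interaction_sbp_per_mmHg * (lat_sbp_f - cfg.sbp_mean) * female
        + ce.get("age_per_year", 0.0) * age_f
        + ce.get("female", 0.0) * female
        + ce.get("diabetes", 0.0) * diabetes
        + ce.get("smoking_ex", 0.0) * smoking_ex
        + ce.get("smoking_active", 0.0) * smoking_act
        + ce.get("asi_per_unit", 0.0) * asi_f
        + ce.get("time_diff_per_year", 0.0) * time_diff
    )
    noise = rng.normal(0.0, cfg.wmh_logit_noise_sd, n) if cfg.wmh_logit_noise_sd > 0 else 0.0
    wmh_load = expit(linpred + noise)

    # --- tissue volumes ---------------------------------------------------
    rng = _stage_rng(seed, "volumes")
    wm = np.clip(rng.normal(cfg.wm_volume_mean, cfg.wm_volume_sd, n), 2e5, None)
    gm = np.clip(rng.normal(cfg.gm_volume_mean, cfg.gm_volume_sd, n), 2e5, None)
    csf = np.clip(rng.normal(cfg.csf_volume_mean, cfg.csf_volume_sd, n), 5e4, None)
    wmh_volume = wmh_load * wm

    # --- dates -----------------------------------------------------------
    rng = _stage_rng(seed, "dates")
    d0 = np.datetime64("2006-03-13")
    base_date = d0 + rng.integers(0, 1675, size=n).astype("timedelta64[D]")
    fu_date = base_date + np.round(time_diff * 365.25).astype(int).astype("timedelta64[D]")

    # --- assemble long table ----------------------------------------------
    pid = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(female, "female", "male")
    nan = np.full(n, np.nan)

    def reading_block(visit_key: str, src_idx: np.ndarray) -> dict:
        block = {}
        for si, src in enumerate(BP_SOURCES):
            mask = src_idx == si
            for which in ("sbp", "dbp"):
                for i in (1, 2):
                    col = np.where(mask, readings[f"{which}_{visit_key}_{i}"], np.nan)
                    block[f"{which}_{src}_{i}"] = col
        return block

    base = pd.DataFrame({
        "participant_id": pid, "visit": "baseline", "visit_date": base_date,
        "age": age_b, "sex": sex, "smoking": smoking,
        "diabetes": diabetes, "antihypertensive": med_b, "centre": centre,
        "asi": asi_b, **reading_block("b", src_b),
        "wmh_volume": nan, "wm_volume": nan, "gm_volume": nan, "csf_volume": nan,
        "exclusion_flag": False,
    })
    follow = pd.DataFrame({
        "participant_id": pid, "visit": "followup", "visit_date": fu_date,
        "age": age_f, "sex": sex, "smoking": smoking,
        "diabetes": diabetes, "antihypertensive": med_f, "centre": centre,
        "asi": asi_f, **reading_block("f", src_f),
        "wmh_volume": wmh_volume, "wm_volume": wm, "gm_volume": gm,
        "csf_volume": csf, "exclusion_flag": False,
    })
    out = pd.concat([base, follow], ignore_index=True)
    out = out.sort_values(["participant_id", "visit"], kind="mergesort",
                          ignore_index=True)
    return out[list(COHORT_COLUMNS)]


def _empty_cohort() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=float) for c in COHORT_COLUMNS})
    for c in ("participant_id", "visit", "sex", "smoking", "centre"):
        df[c] = df[c].astype(object)
    df["visit_date"] = pd.Series(dtype="datetime64[s]")
    for c in ("diabetes", "antihypertensive", "exclusion_flag"):
        df[c] = df[c].astype(bool)
    return df


#: grouped aliases accepted in ``missingness_rates`` beside raw column names
_MISSING_GROUPS = {
    "bp_baseline": ("baseline", READING_COLUMNS),
    "bp_followup": ("followup", READING_COLUMNS),
    "bp_automated": (None, tuple(c for c in READING_COLUMNS if "automated" in c)),
    "bp_manual": (None, tuple(c for c in READING_COLUMNS if "manual" in c)),
    "bp_pwa": (None, tuple(c for c in READING_COLUMNS if "pwa" in c)),
    "second_reading": (None, tuple(c for c in READING_COLUMNS if c.endswith("_2"))),
}


def inject_missingness(table: pd.DataFrame, config: GeneratorConfig) -> pd.DataFrame:
    """Blank fields at the configured rates and set ``exclusion_flag``.

    Keys of ``config.missingness_rates`` are either cohort column names
    (blanked independently per row) or one of the grouped aliases
    ``bp_baseline`` / ``bp_followup`` (all readings of that visit),
    ``bp_automated`` / ``bp_manual`` / ``bp_pwa`` (that source everywhere),
    and ``second_reading``.  The exclusion flag is drawn once per participant
    at ``exclusion_rate`` and applied to both of their rows.
    Deterministic given ``config.seed``; unknown field names raise.
    """
    config.validate()
    out = table.copy()
    rng = _stage_rng(config.seed, "missingness")
    for key in sorted(config.missingness_rates):
        rate = config.missingness_rates[key]
        if key in _MISSING_GROUPS:
            visit, cols = _MISSING_GROUPS[key]
            mask = np.ones(len(out), dtype=bool) if visit is None else \
                (out["visit"] == visit).to_numpy()
            hit = mask & (rng.random(len(out)) < rate)
            out.loc[hit, list(cols)] = np.nan
        elif key in out.columns:
            hit = rng.random(len(out)) < rate
            out.loc[hit, key] = np.nan
        else:
            raise ValueError(f"unknown field in missingness_rates: {key!r}")
    if config.exclusion_rate > 0 and len(out):
        rng = _stage_rng(config.seed, "exclusion")
        pids = out["participant_id"].unique()
        flagged = set(pids[rng.random(len(pids)) < config.exclusion_rate])
        out["exclusion_flag"] = out["participant_id"].isin(flagged).to_numpy()
    return out


def simulate(config: GeneratorConfig) -> pd.DataFrame:
    """Generate and degrade a cohort in one call (the pipeline entry point)."""
    return inject_missingness(generate_cohort(config), config)


# ---------------------------------------------------------------- CSV I/O

def write_cohort(table: pd.DataFrame, path) -> None:
    """Write the cohort CSV with a versioned header comment."""
    with open(path, "w") as fh:
        fh.write(f"# schema: {SCHEMA_VERSION}\n")
        table.to_csv(fh, index=False, date_format="%Y-%m-%d",
                     float_format="%.10g", lineterminator="\n")


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", parse_dates=["visit_date"])
    for c in ("diabetes", "antihypertensive", "exclusion_flag"):
        df[c] = df[c].astype(bool)
    return df
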