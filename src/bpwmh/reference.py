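"""Published summary statistics of the UK Biobank neuroimaging subcohort.

These constants are the baseline/follow-up characteristics reported for the
~37 000 participants with both blood-pressure measurements and a quantified
white-matter-hyperintensity (WMH) volume.  They serve two purposes:

* calibration targets for the synthetic cohort generator
  (:mod:`bpwmh.simulate`), so that simulated cohorts have realistic BP
  distributions, smoking/diabetes prevalences and WMH-load medians; and
* internal-arithmetic cross-checks (pulse pressure = SBP − DBP, between-visit
  count deltas) exercised by the test suite and the acceptance script.

Values are mean (SD) unless the key says ``_n`` (a count).  Units: BP and
pulse pressure in mmHg, age in years.
"""

from __future__ import annotations

# Table of cohort characteristics: longitudinal sample at baseline and
# follow-up, the printed between-visit differences, and the (slightly larger)
# cross-sectional sample.
COHORT_SUMMARY = {
    "longitudinal_baseline": {
        "n": 37026,
        "age_mean": 55.29, "age_sd": 7.45,
        "female_n": 19624, "female_pct": 53.0,
        "diabetes_n": 908, "diabetes_pct": 2.5,
        "ex_smoker_n": 12057, "ex_smoker_pct": 32.6,
        "active_smoker_n": 2278, "active_smoker_pct": 6.2,
        "sbp_mean": 134.81, "sbp_sd": 17.66,
        "dbp_mean": 81.39, "dbp_sd": 9.92,
        "pp_mean": 53.42, "pp_sd": 12.29,
        "asi_mean": 9.07, "asi_sd": 2.91,
        "antihypertensive_n": 4757, "antihypertensive_pct": 14.6,
    },
    "longitudinal_followup": {
        "n": 37026,
        "age_mean": 64.12, "age_sd": 7.52,
        "ex_smoker_n": 12332, "ex_smoker_pct": 33.5,
        "active_smoker_n": 1255, "active_smoker_pct": 3.4,
        "sbp_mean": 138.26, "sbp_sd": 18.73,
        "dbp_mean": 77.66, "dbp_sd": 10.65,
        "pp_mean": 60.6, "pp_sd": 15.16,
        "asi_mean": 9.61, "asi_sd": 2.91,
        "antihypertensive_n": 8264, "antihypertensive_pct": 26.1,
    },
    "longitudinal_difference": {
        "age_mean": 8.84,
        "sbp_mean": 3.45,
        "dbp_mean": -3.72,
        "pp_mean": 7.17,
        "asi_mean": 0.48,
        "ex_smoker_n": 275,
        "active_smoker_n": -1023,
        "antihypertensive_n": 3507,
    },
    "cross_sectional": {
        "n": 37041,
        "age_mean": 64.12, "age_sd": 7.52,
        "female_n": 19635, "female_pct": 53.0,
        "diabetes_n": 1855, "diabetes_pct": 5.1,
        "ex_smoker_n": 12334, "ex_smoker_pct": 33.5,
        "active_smoker_n": 1256, "active_smoker_pct": 3.4,
        "sbp_mean": 138.26, "sbp_sd": 18.72,
        "dbp_mean": 77.66, "dbp_sd": 10.65,
        "pp_mean": 60.59, "pp_sd": 15.16,
        "asi_mean": 9.61, "asi_sd": 2.91,
        "antihypertensive_n": 8269, "antihypertensive_pct": 26.1,
    },
}

# Follow-up interval: median 9.07 years, observed range 4.28-13.49 years.
FOLLOW_UP_MEDIAN_YEARS = 9.07
FOLLOW_UP_RANGE_YEARS = (4.28, 13.49)

# WMH load (WMH volume / total white-matter volume): published median and range.
MEDIAN_WMH_LOAD = 0.0052
WMH_LOAD_RANGE = (0.000018, 0.187)
MEDIAN_WMH_VOLUME_MM3 = 2796.0

# Fully adjusted multiplicative WMH-load effects (per-unit, concurrent BP):
# used to calibrate the generator's conditional per-mmHg effects.
CONCURRENT_RATIO_PER_10MMHG_SBP = 1.041
CONCURRENT_RATIO_PER_5MMHG_DBP = 1.031

# Regression-dilution-adjusted ("usual BP") median-WMH ratios.
USUAL_RATIO_PER_10MMHG_SBP = 1.126
USUAL_RATIO_PER_5MMHG_DBP = 1.106


def pulse_pressure_mean(sample: str) -> float:
    """SBP minus DBP mean for one of the :data:`COHORT_SUMMARY` samples.

    Pulse pressure is definitionally SBP − DBP, so the mean pulse pressure of
    a sample must equal the difference of its SBP and DBP means (up to the
    precision the summary table was printed at).
    """
    row = COHORT_SUMMARY[sample]
    return row["sbp_mean"] - row["dbp_mean"]


def count_delta(field: str) -> int:
    """Follow-up minus baseline count for a categorical field (e.g. smoking)."""
    return (COHORT_SUMMARY["longitudinal_followup"][f"{field}_n"]
            - COHORT_SUMMARY["longitudinal_baseline"][f"{field}_n"])
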