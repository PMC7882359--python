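import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bpwmh import ingest, simulate

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def clean_config(**overrides) -> simulate.GeneratorConfig:
    """Generator config with every nuisance mechanism switched off.

    No covariate effects, no SBP/DBP cross-sectional age trends, no
    medication-induced BP reduction, no missingness or exclusions: WMH then
    depends only on latent BP (plus whatever the test re-enables), which
    makes recovery estimands exact.
    """
    base = dict(
        true_log_ratio_sbp_per_mmHg=0.0,
        true_log_ratio_dbp_per_mmHg=0.0,
        covariate_effects={},
        sbp_age_slope=0.0, dbp_age_slope=0.0,
        sbp_followup_shift=0.0, dbp_followup_shift=0.0,
        treatment_sbp_reduction=0.0, treatment_dbp_reduction=0.0,
        missingness_rates={}, exclusion_rate=0.0,
    )
    base.update(overrides)
    return simulate.GeneratorConfig(**base)


@pytest.fixture(scope="session")
def default_analysis():
    """A mid-sized cohort under the calibrated default generator."""
    cfg = simulate.GeneratorConfig(n_participants=12000, seed=41)
    analysis, audit = ingest.apply_eligibility(simulate.simulate(cfg))
    return analysis


@pytest.fixture(scope="session")
def small_cohort():
    cfg = simulate.GeneratorConfig(n_participants=800, seed=11)
    return simulate.simulate(cfg)


def synthetic_strata_table(slope: float, which: str = "sbp", n_per: int = 30,
                           ref_median: float = 0.005) -> pd.DataFrame:
    """Hand-built analysis table whose strata follow an exact log-linear law.

    Every member of a stratum shares the stratum's BP (baseline = follow-up,
    i.e. no measurement error) and WMH load ref_median·exp(slope·(BP − ref)),
    so the usual-BP regression must reproduce ``slope`` exactly.
    """
    bands = {"sbp": [110.0, 125.0, 135.0, 150.0], "dbp": [65.0, 75.0, 85.0, 95.0]}[which]
    other = {"sbp": 75.0, "dbp": 125.0}
    rows = []
    pid = 0
    for bp in bands:
        load = ref_median * np.exp(slope * (bp - bands[0]))
        for _ in range(n_per):
            rows.append({
                "participant_id": f"S{pid:05d}",
                "age_baseline": 45.0, "age_followup": 54.0,
                "sex": "female", "smoking": "never", "diabetes": False,
                "antihypertensive_baseline": False, "antihypertensive_followup": False,
                "centre": "centre_A", "asi_baseline": 9.0, "asi_followup": 9.5,
                f"{which}_baseline": bp, f"{which}_followup": bp,
                f"{'dbp' if which == 'sbp' else 'sbp'}_baseline": other[which],
                f"{'dbp' if which == 'sbp' else 'sbp'}_followup": other[which],
                "bp_source_baseline": "automated", "bp_source_followup": "automated",
                "time_diff": 9.0, "wmh_load": load,
                "wmh_load_brainvol": load / 3.0, "is_longitudinal": True,
            })
            pid += 1
    df = pd.DataFrame(rows)
    df["wmh_logit"] = ingest.logit(df["wmh_load"].to_numpy())
    df["bp_band_sbp_baseline"] = ingest.assign_bp_band(df["sbp_baseline"].to_numpy(), "sbp")
    df["bp_band_dbp_baseline"] = ingest.assign_bp_band(df["dbp_baseline"].to_numpy(), "dbp")
    df["bp_band_sbp_followup"] = ingest.assign_bp_band(df["sbp_followup"].to_numpy(), "sbp")
    df["bp_band_dbp_followup"] = ingest.assign_bp_band(df["dbp_followup"].to_numpy(), "dbp")
    df["age_group_baseline"] = ingest.assign_age_group(df["age_baseline"].to_numpy(), "baseline")
    df["age_group_followup"] = ingest.assign_age_group(df["age_followup"].to_numpy(), "followup")
    return df
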