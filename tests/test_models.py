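"""Association models: OLS oracle equivalence, standardization, ratios,
stratification, and sex interactions."""

import numpy as np
import pandas as pd
import pytest

from bpwmh import ingest, models, simulate
from conftest import clean_config


def _fixture_table(n=50, seed=0):
    """Small analysis-shaped table with a known linear structure."""
    rng = np.random.default_rng(seed)
    sbp = rng.normal(135, 15, n)
    dbp = 0.5 * sbp + rng.normal(10, 6, n)
    age = rng.uniform(45, 75, n)
    y = -5.0 + 0.004 * sbp + 0.006 * dbp + 0.08 * age + rng.normal(0, 1, n)
    return pd.DataFrame({
        "wmh_logit": y,
        "sbp_followup": sbp, "dbp_followup": dbp, "age_followup": age,
        "asi_followup": rng.normal(9, 3, n),
        "sex": rng.choice(["female", "male"], n),
        "smoking": rng.choice(["never", "ex", "active"], n),
        "diabetes": rng.random(n) < 0.2,
        "bp_source_followup": rng.choice(["automated", "manual"], n),
        "centre": rng.choice(["c1", "c2"], n),
        "time_diff": rng.uniform(5, 12, n),
    })


def _normal_equations(y, X):
    """Independent oracle: beta = (XᵀX)⁻¹ Xᵀ y via pseudo-inverse."""
    return np.linalg.pinv(X.T @ X) @ X.T @ y


@pytest.mark.parametrize("standardized", [False, True])
def test_ols_matches_normal_equations_oracle(standardized):
    table = _fixture_table(n=50)
    spec = models.ModelSpec(adjustment="full", timing="concurrent",
                            standardized=standardized)
    y, X, n = models._build_design(table, spec, models._roles_for(spec))
    expected = _normal_equations(y.to_numpy(), X.to_numpy())
    ests = {e.term: e.beta for e in models.fit_linear_model(table, spec)}
    for j, term in enumerate(X.columns):
        if term == "const":
            continue
        assert ests[term] == pytest.approx(expected[j], abs=1e-8)


class TestStandardize:
    def test_mean_zero_sd_one(self):
        table = _fixture_table()
        out = models.standardize(table, ["sbp_followup", "wmh_logit"])
        for v in ("sbp_followup", "wmh_logit"):
            assert out[v].mean() == pytest.approx(0.0, abs=1e-12)
            assert out[v].std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_location_invariance(self):
        table = _fixture_table()
        shifted = table.copy()
        shifted["sbp_followup"] = shifted["sbp_followup"] + 37.5
        a = models.standardize(table, ["sbp_followup"])["sbp_followup"]
        b = models.standardize(shifted, ["sbp_followup"])["sbp_followup"]
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_zero_variance_raises_with_name(self):
        table = _fixture_table()
        table["sbp_followup"] = 130.0
        with pytest.raises(ValueError, match="sbp_followup"):
            models.standardize(table, ["sbp_followup"])

    def test_standardized_simple_regression_equals_pearson_r(self):
        table = _fixture_table(n=80, seed=3)
        spec = models.ModelSpec(adjustment="unadjusted", exposures=("sbp",),
                                timing="concurrent", standardized=True)
        beta = models.fit_linear_model(table, spec)[0].beta
        r = np.corrcoef(table["sbp_followup"], table["wmh_logit"])[0, 1]
        assert beta == pytest.approx(r, abs=1e-10)


def test_noiseless_fit_has_exact_coefficient_and_zero_width_ci():
    n = 30
    table = _fixture_table(n)
    table["wmh_logit"] = 2.0 * table["sbp_followup"]
    spec = models.ModelSpec(adjustment="unadjusted", exposures=("sbp",),
                            timing="concurrent", standardized=False)
    est = models.fit_linear_model(table, spec)[0]
    assert est.beta == pytest.approx(2.0, abs=1e-10)
    assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-8)


def test_standardized_equals_per_mmhg_times_sd_ratio():
    table = _fixture_table(n=200, seed=5)
    spec_std = models.ModelSpec(adjustment="full", timing="concurrent", standardized=True)
    spec_raw = models.ModelSpec(adjustment="full", timing="concurrent", standardized=False)
    std = {e.term: e.beta for e in models.fit_linear_model(table, spec_std)}
    raw = {e.term: e.beta for e in models.fit_linear_model(table, spec_raw)}
    sd_y = table["wmh_logit"].std(ddof=1)
    for term, col in (("sbp", "sbp_followup"), ("dbp", "dbp_followup")):
        expected = raw[term] * table[col].std(ddof=1) / sd_y
        assert std[term] == pytest.approx(expected, abs=1e-10)


def test_orthogonal_covariate_leaves_exposure_beta_unchanged():
    rng = np.random.default_rng(8)
    n = 64
    x = np.repeat([120.0, 140.0], n // 2)
    z = np.tile([0.0, 1.0], n // 2)      # orthogonal to centred x by construction
    y = 0.01 * x + rng.normal(0, 0.5, n)
    base = pd.DataFrame({"wmh_logit": y, "sbp_followup": x, "age_followup": z})
    spec = models.ModelSpec(adjustment="unadjusted", exposures=("sbp",),
                            timing="concurrent", standardized=False)
    beta_alone = models.fit_linear_model(base, spec)[0].beta
    spec2 = models.ModelSpec(adjustment="age_sex", exposures=("sbp",),
                             timing="concurrent", standardized=False)
    base["sex"] = "female"
    # drop sex (constant) from the adjustment; keep orthogonal age
    y2, X2, _ = models._build_design(base, spec2, ["sbp", "age"])
    import statsmodels.api as sm
    beta_with = sm.OLS(y2, X2).fit().params["sbp"]
    assert beta_with == pytest.approx(beta_alone, abs=1e-10)


class TestEffectRatio:
    def test_null_effect(self):
        assert models.effect_ratio_per_unit(0.0, "sbp").beta == pytest.approx(1.0)

    def test_published_magnitude(self):
        est = models.effect_ratio_per_unit(0.00402, "sbp")
        assert est.beta == pytest.approx(1.0410, abs=5e-4)

    def test_dbp_unit_is_5(self):
        est = models.effect_ratio_per_unit(0.01, "dbp")
        assert est.beta == pytest.approx(np.exp(0.05))

    def test_monotone_in_beta(self):
        r = [models.effect_ratio_per_unit(b, "sbp").beta for b in (0.001, 0.002, 0.004)]
        assert r[0] < r[1] < r[2]

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            models.effect_ratio_per_unit(float("nan"), "sbp")

    def test_ci_transforms_monotonically(self):
        est = models.effect_ratio_per_unit(0.004, "sbp", ci=(0.002, 0.006))
        assert est.ci_low < est.beta < est.ci_high


class TestStratified:
    def test_identical_strata_identical_estimates(self):
        half = _fixture_table(n=60, seed=2)
        half["sex"] = "female"
        other = half.copy()
        other["sex"] = "male"
        table = pd.concat([half, other], ignore_index=True)
        spec = models.ModelSpec(adjustment="full", timing="concurrent")
        by_stratum, skipped = models.fit_stratified(table, spec, "sex")
        assert not skipped
        f = {e.term: e.beta for e in by_stratum["female"]}
        m = {e.term: e.beta for e in by_stratum["male"]}
        assert f.keys() == m.keys()
        for k in f:
            assert f[k] == pytest.approx(m[k], abs=1e-10)

    def test_pooled_beta_between_stratum_betas_under_shared_slope(self):
        rng = np.random.default_rng(4)
        n = 200
        x = rng.normal(130, 15, n)
        sex = np.where(rng.random(n) < 0.5, "female", "male")
        y = 0.01 * x + np.where(sex == "female", 1.0, -1.0) + rng.normal(0, 0.3, n)
        table = pd.DataFrame({"wmh_logit": y, "sbp_followup": x, "sex": sex})
        spec = models.ModelSpec(adjustment="unadjusted", exposures=("sbp",),
                                timing="concurrent", standardized=False)
        # pooled fit with the stratum intercept: its slope is a precision-
        # weighted average of the per-stratum slopes, hence lies between them
        import statsmodels.api as sm
        y, X, _ = models._build_design(table, spec, ["sbp", "sex"])
        pooled = sm.OLS(y, X).fit().params["sbp"]
        strata, _ = models.fit_stratified(table, spec, "sex")
        betas = [strata[s][0].beta for s in ("female", "male")]
        assert min(betas) - 1e-9 <= pooled <= max(betas) + 1e-9

    def test_duration_split_at_median(self):
        table = _fixture_table(n=100, seed=6)
        spec = models.ModelSpec(adjustment="unadjusted", exposures=("sbp",),
                                timing="past", standardized=False)
        table = table.rename(columns={
            "sbp_followup": "sbp_baseline", "dbp_followup": "dbp_baseline",
            "age_followup": "age_baseline", "asi_followup": "asi_baseline",
            "bp_source_followup": "bp_source_baseline"})
        by_stratum, _ = models.fit_stratified(table, spec, "duration")
        ns = {k: v[0].n for k, v in by_stratum.items()}
        assert abs(ns["short_followup"] - ns["long_followup"]) <= 1

    def test_age_confined_dbp_effect_recovered_in_youngest_stratum(self):
        """A DBP effect present only under age 50 at baseline shows up in that
        stratum's fully adjusted estimate and not beyond its CI elsewhere."""
        cfg = clean_config(n_participants=15_000, seed=77, bp_within_person_sd=0.0,
                           wmh_logit_noise_sd=0.6)
        cohort = simulate.generate_cohort(cfg)
        analysis, _ = ingest.apply_eligibility(cohort)
        young = analysis["age_group_baseline"] == "<50"
        delta = 0.02
        analysis["wmh_logit"] = analysis["wmh_logit"] + np.where(
            young, delta * (analysis["dbp_baseline"] - 80.0), 0.0)
        spec = models.ModelSpec(adjustment="full", timing="past", standardized=False)
        by_stratum, _ = models.fit_stratified(analysis, spec, "age_group")
        est = {s: {e.term: e for e in v} for s, v in by_stratum.items()}
        assert est["<50"]["dbp"].ci_low > delta / 2
        for s in ("50-60", ">=60"):
            assert abs(est[s]["dbp"].beta) < delta / 2


class TestInteraction:
    def test_duplicated_rows_give_exactly_zero(self):
        half = _fixture_table(n=60, seed=10)
        half["sex"] = "female"
        other = half.copy()
        other["sex"] = "male"
        table = pd.concat([half, other], ignore_index=True)
        spec = models.ModelSpec(adjustment="full", timing="concurrent")
        est = models.interaction_test(table, spec, exposure="sbp")
        assert est.beta == pytest.approx(0.0, abs=1e-10)

    def test_single_sex_table_raises(self):
        table = _fixture_table(n=40)
        table["sex"] = "female"
        spec = models.ModelSpec(adjustment="full", timing="concurrent")
        with pytest.raises(ValueError, match="both sexes"):
            models.interaction_test(table, spec, exposure="sbp")

    def test_recovers_generator_sex_difference(self):
        delta = 0.02
        cfg = clean_config(n_participants=15_000, seed=88, bp_within_person_sd=0.0,
                           true_log_ratio_sbp_per_mmHg=0.01,
                           true_sex_interaction_sbp_per_mmHg=delta,
                           wmh_logit_noise_sd=0.8)
        analysis, _ = ingest.apply_eligibility(simulate.generate_cohort(cfg))
        spec = models.ModelSpec(adjustment="full", timing="concurrent",
                                standardized=False)
        est = models.interaction_test(analysis, spec, exposure="sbp")
        assert est.ci_low <= delta <= est.ci_high
        assert est.beta == pytest.approx(delta, abs=0.005)


def test_rank_deficient_design_reports_collinear_columns():
    table = _fixture_table(n=40)
    table["dbp_followup"] = 2.0 * table["sbp_followup"]  # exact collinearity
    spec = models.ModelSpec(adjustment="full", timing="concurrent", standardized=False)
    with pytest.raises(ValueError, match="collinear"):
        models.fit_linear_model(table, spec)
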