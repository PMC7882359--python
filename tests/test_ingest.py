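"""Harmonization: source preference, load, logit, bands, eligibility audit."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bpwmh import ingest, simulate


def _visit(**readings):
    base = {f"{w}_{s}_{i}": np.nan
            for s in ("automated", "manual", "pwa") for w in ("sbp", "dbp") for i in (1, 2)}
    base.update(readings)
    return base


class TestSelectBPSource:
    def test_automated_preferred_over_manual(self):
        v = _visit(sbp_automated_1=135, dbp_automated_1=82,
                   sbp_manual_1=130, dbp_manual_1=80)
        assert ingest.select_bp_source(v) == (135.0, 82.0, "automated")

    def test_manual_preferred_over_pwa(self):
        v = _visit(sbp_manual_1=130, dbp_manual_1=80,
                   sbp_pwa_1=128, dbp_pwa_1=79)
        assert ingest.select_bp_source(v) == (130.0, 80.0, "manual")

    def test_within_visit_average(self):
        v = _visit(sbp_automated_1=120, sbp_automated_2=124,
                   dbp_automated_1=80, dbp_automated_2=84)
        sbp, dbp, src = ingest.select_bp_source(v)
        assert sbp == 122.0 and dbp == 82.0 and src == "automated"

    def test_no_source_raises(self):
        with pytest.raises(ValueError, match="no usable BP source"):
            ingest.select_bp_source(_visit())

    def test_pwa_never_chosen_when_another_source_exists(self):
        """Exhaustive over the 7 non-empty presence patterns."""
        for pattern in itertools.product([0, 1], repeat=3):
            if sum(pattern) == 0:
                continue
            readings = {}
            for present, src in zip(pattern, ("automated", "manual", "pwa")):
                if present:
                    readings[f"sbp_{src}_1"] = 120.0
                    readings[f"dbp_{src}_1"] = 70.0
            _, _, chosen = ingest.select_bp_source(_visit(**readings))
            if pattern[0]:
                assert chosen == "automated"
            elif pattern[1]:
                assert chosen == "manual"
            else:
                assert chosen == "pwa"


class TestWMHLoad:
    def test_published_median_arithmetic(self):
        assert ingest.compute_wmh_load(2796.0, 559200.0) == pytest.approx(0.005)

    @given(st.floats(min_value=1e3, max_value=1e7))
    def test_scale_invariance(self, volume):
        assert ingest.compute_wmh_load(0.01 * volume, volume) == pytest.approx(0.01)

    @pytest.mark.parametrize("w, d", [(-1.0, 100.0), (0.0, 100.0), (10.0, -5.0),
                                      (100.0, 100.0), (110.0, 100.0)])
    def test_invalid_volumes_raise(self, w, d):
        with pytest.raises(ValueError):
            ingest.compute_wmh_load(w, d)


class TestLogit:
    def test_symmetry_point(self):
        assert ingest.logit(0.5) == 0.0

    def test_published_median_value(self):
        assert ingest.logit(0.0052) == pytest.approx(-5.2538, abs=1e-4)

    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9))
    def test_antisymmetry(self, p):
        assert ingest.logit(p) + ingest.logit(1 - p) == pytest.approx(0.0, abs=1e-7)

    @given(st.floats(min_value=1e-9, max_value=1 - 1e-9),
           st.floats(min_value=1e-9, max_value=1 - 1e-9))
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted([a, b])
        if lo < hi:
            assert ingest.logit(lo) < ingest.logit(hi)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.1, 1.1])
    def test_domain_errors(self, p):
        with pytest.raises(ValueError):
            ingest.logit(p)


class TestBands:
    @pytest.mark.parametrize("value, which, band", [
        (70.0, "dbp", "70-80"),       # left-closed: boundary joins upper band
        (139.9, "sbp", "130-140"),
        (140.0, "sbp", ">=140"),
        (119.999, "sbp", "<120"),
        (69.999, "dbp", "<70"),
        (90.0, "dbp", ">=90"),
    ])
    def test_examples(self, value, which, band):
        assert ingest.assign_bp_band(value, which) == band

    def test_partition_and_ulp_edges(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(40, 220, 10_000)
        bands = ingest.assign_bp_band(values, "sbp")
        assert set(np.unique(bands)) <= set(ingest.SBP_BAND_LABELS)
        assert len(bands) == len(values)  # exactly one band each
        for edge in ingest.SBP_BAND_EDGES:
            below = ingest.assign_bp_band(np.nextafter(edge, -np.inf), "sbp")
            at = ingest.assign_bp_band(edge, "sbp")
            above = ingest.assign_bp_band(np.nextafter(edge, np.inf), "sbp")
            assert below != at and at == above

    @pytest.mark.parametrize("bad", [0.0, -5.0, float("nan"), float("inf")])
    def test_invalid_values_raise(self, bad):
        with pytest.raises(ValueError):
            ingest.assign_bp_band(bad, "sbp")


class TestAgeGroups:
    @pytest.mark.parametrize("age, scheme, group", [
        (49.9, "baseline", "<50"),
        (50.0, "baseline", "50-60"),
        (60.0, "baseline", ">=60"),
        (59.9, "followup", "<60"),
        (70.0, "followup", ">=70"),
        (65.0, "followup", "60-70"),
    ])
    def test_examples(self, age, scheme, group):
        assert ingest.assign_age_group(age, scheme) == group

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            ingest.assign_age_group(25.0, "baseline")
        with pytest.raises(ValueError):
            ingest.assign_age_group(105.0, "followup")


def _toy_cohort(n=10, excluded=(), missing_fu_bp=(), missing_base_bp=(),
                missing_wmh=()):
    rows = []
    for i in range(n):
        for visit, date, age in (("baseline", "2008-01-01", 50.0),
                                 ("followup", "2017-01-01", 59.0)):
            row = {
                "participant_id": f"T{i:03d}", "visit": visit,
                "visit_date": pd.Timestamp(date), "age": age,
                "sex": "female", "smoking": "never", "diabetes": False,
                "antihypertensive": False, "centre": "c1", "asi": 9.0,
                **{c: np.nan for c in simulate.READING_COLUMNS},
                "wmh_volume": np.nan, "wm_volume": np.nan,
                "gm_volume": np.nan, "csf_volume": np.nan,
                "exclusion_flag": i in excluded,
            }
            skip_bp = (visit == "followup" and i in missing_fu_bp) or \
                      (visit == "baseline" and i in missing_base_bp)
            if not skip_bp:
                row["sbp_automated_1"] = 130.0 + i
                row["dbp_automated_1"] = 80.0 + i
            if visit == "followup" and i not in missing_wmh:
                row.update(wmh_volume=2800.0, wm_volume=540_000.0,
                           gm_volume=600_000.0, csf_volume=350_000.0)
            rows.append(row)
    return pd.DataFrame(rows)


class TestEligibility:
    def test_toy_counts(self):
        cohort = _toy_cohort(n=10, excluded={0, 1}, missing_fu_bp={2})
        analysis, audit = ingest.apply_eligibility(cohort)
        assert audit["exclusion_flag"] == 2
        assert audit["missing_followup_bp"] == 1
        assert audit["n_cross_sectional"] == 7
        assert audit["n_longitudinal"] == 7

    def test_no_filters_identity(self):
        cohort = _toy_cohort(n=6)
        analysis, audit = ingest.apply_eligibility(cohort)
        assert audit["missing_wmh"] == audit["exclusion_flag"] == 0
        assert audit["missing_followup_bp"] == audit["missing_baseline_bp"] == 0
        assert len(analysis) == 6

    def test_cross_sectional_superset_of_longitudinal(self):
        cohort = _toy_cohort(n=12, missing_base_bp={3, 4})
        analysis, audit = ingest.apply_eligibility(cohort)
        assert audit["n_cross_sectional"] >= audit["n_longitudinal"]
        assert len(ingest.longitudinal_subset(analysis)) == audit["n_longitudinal"]
        # rows missing baseline BP stay in the cross-sectional table
        assert audit["n_cross_sectional"] - audit["n_longitudinal"] == 2

    def test_filter_order_missing_wmh_before_exclusion(self):
        # participant 0 has both missing WMH and the exclusion flag: it must be
        # counted once, at the first filter
        cohort = _toy_cohort(n=5, excluded={0}, missing_wmh={0})
        _, audit = ingest.apply_eligibility(cohort)
        assert audit["missing_wmh"] == 1
        assert audit["exclusion_flag"] == 0

    def test_time_diff_exact_days(self):
        analysis, _ = ingest.apply_eligibility(_toy_cohort(n=2))
        expected = (pd.Timestamp("2017-01-01") - pd.Timestamp("2008-01-01")).days / 365.25
        assert analysis["time_diff"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_invalid_wmh_volume_reported(self):
        cohort = _toy_cohort(n=3)
        cohort.loc[(cohort["visit"] == "followup") & (cohort["participant_id"] == "T001"),
                   "wmh_volume"] = 1e9
        with pytest.raises(ValueError, match="WMH"):
            ingest.apply_eligibility(cohort)

    def test_brain_volume_denominator_variant(self):
        cohort = _toy_cohort(n=4)
        a_wm, _ = ingest.apply_eligibility(cohort)
        a_bv, _ = ingest.apply_eligibility(cohort, brain_volume_denominator=True)
        expected = 2800.0 / (540_000.0 + 600_000.0 + 350_000.0)
        assert a_bv["wmh_load"].iloc[0] == pytest.approx(expected)
        assert a_wm["wmh_load_brainvol"].iloc[0] == pytest.approx(expected)
        assert a_wm["wmh_load"].iloc[0] == pytest.approx(2800.0 / 540_000.0)

    def test_exclude_pwa_drops_pwa_only_rows(self):
        cohort = _toy_cohort(n=4)
        fu0 = (cohort["visit"] == "followup") & (cohort["participant_id"] == "T000")
        cohort.loc[fu0, "sbp_automated_1"] = np.nan
        cohort.loc[fu0, "dbp_automated_1"] = np.nan
        cohort.loc[fu0, "sbp_pwa_1"] = 120.0
        cohort.loc[fu0, "dbp_pwa_1"] = 70.0
        _, audit_with = ingest.apply_eligibility(cohort)
        _, audit_without = ingest.apply_eligibility(cohort, exclude_pwa=True)
        assert audit_with["missing_followup_bp"] == 0
        assert audit_without["missing_followup_bp"] == 1
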