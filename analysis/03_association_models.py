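"""Linear models of logit WMH load on concurrent and past BP.

Reproduces the effect-table structure of the source analysis on the
synthetic cohort: unadjusted / age-sex / fully adjusted standardized
coefficients, per-unit multiplicative ratios (per 10 mmHg SBP, 5 mmHg DBP),
age-group / sex / follow-up-duration stratifications, and BP × sex
interaction terms.
"""

from pathlib import Path

import pandas as pd

from bpwmh import ingest, models

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "analysis"
RESULTS = ROOT / "results"


def main():
    analysis = ingest.read_analysis(SCRATCH / "analysis.csv")
    long = ingest.longitudinal_subset(analysis)

    frames = []
    for timing, table in (("concurrent", analysis), ("past", long)):
        exposures = ("sbp", "dbp", "asi", "age", "sex", "diabetes", "smoking")
        if timing == "past":
            exposures += ("time_diff",)
        for adjustment in ("unadjusted", "age_sex", "full"):
            spec = models.ModelSpec(
                exposures=exposures if adjustment != "full" else ("sbp", "dbp"),
                adjustment=adjustment, timing=timing, standardized=True)
            frames.append(models.estimates_to_frame(
                models.fit_linear_model(table, spec),
                timing=timing, adjustment=adjustment))
        raw = models.fit_linear_model(table, models.ModelSpec(
            adjustment="full", timing=timing, standardized=False))
        ratios = [models.effect_ratio_per_unit(e.beta, e.term,
                                               ci=(e.ci_low, e.ci_high), n=e.n)
                  for e in raw if e.term in ("sbp", "dbp")]
        frames.append(models.estimates_to_frame(ratios, timing=timing,
                                                adjustment="full"))
        for exposure in ("sbp", "dbp"):
            est = models.interaction_test(table, models.ModelSpec(
                adjustment="full", timing=timing), exposure=exposure)
            frames.append(models.estimates_to_frame([est], timing=timing,
                                                    adjustment="full"))
    estimates = pd.concat(frames, ignore_index=True)
    estimates.to_csv(RESULTS / "estimates.csv", index=False, float_format="%.6g")

    strat_frames = []
    for timing, table in (("concurrent", analysis), ("past", long)):
        for strata_def in ("age_group", "sex", "duration"):
            spec = models.ModelSpec(adjustment="full", timing=timing,
                                    standardized=True)
            by_stratum, skipped = models.fit_stratified(table, spec, strata_def)
            for stratum, ests in by_stratum.items():
                strat_frames.append(models.estimates_to_frame(
                    [e for e in ests if e.term in ("sbp", "dbp")],
                    timing=timing, strata_def=strata_def))
            for s in skipped:
                print(f"  [skipped stratum: {strata_def}={s}, {timing}]")
    pd.concat(strat_frames, ignore_index=True).to_csv(
        RESULTS / "estimates_stratified.csv", index=False, float_format="%.6g")

    full = estimates.query("adjustment == 'full' and scale == 'standardized'")
    print("fully adjusted standardized BP effects:")
    for _, r in full[full["term"].isin(["sbp", "dbp"])].iterrows():
        print(f"  {r['timing']:10s} {r['term']}: {r['beta']:+.3f} "
              f"({r['ci_low']:+.3f} to {r['ci_high']:+.3f}), n={r['n']}")
    ratios = estimates[estimates["scale"].str.startswith("ratio")]
    print("WMH-load ratios (fully adjusted, per 10 mmHg SBP / 5 mmHg DBP):")
    for _, r in ratios.iterrows():
        print(f"  {r['timing']:10s} {r['term']}: {r['beta']:.3f} "
              f"({r['ci_low']:.3f}-{r['ci_high']:.3f})")
    print(f"wrote {RESULTS / 'estimates.csv'} and estimates_stratified.csv")


if __name__ == "__main__":
    main()
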