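"""End-to-end orchestration: simulate → ingest → all analyses.

A single YAML-configurable run produces, under one output directory:
``cohort.csv``, ``analysis.csv``, ``audit.json``, ``estimates.csv``,
``paf.json``, ``usualbp.csv`` (+ ``usualbp_strata.csv``), ``treatment.csv``
(+ ``treatment_medians.csv``) and a ``manifest.json`` recording the seed and
a hash of the resolved configuration.  Given the same config and seed a run
is byte-identical (no timestamps are written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, ingest, models, paf, simulate, treatment, usual_bp

log = logging.getLogger("bpwmh")

ALL_STAGES = ("simulate", "ingest", "fit", "paf", "usualbp", "treatment")


@dataclass
class RunConfig:
    out_dir: str = "bpwmh_run"
    seed: int = 0
    n_participants: int = 5000
    stages: tuple = ALL_STAGES
    n_boot: int = 1000
    min_stratum_n: int = 20
    brain_volume_denominator: bool = False
    exclude_pwa: bool = False
    generator_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def generator_config(self) -> simulate.GeneratorConfig:
        return simulate.GeneratorConfig(
            n_participants=self.n_participants, seed=self.seed,
            **self.generator_overrides)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _derived_seed(seed: int, offset: int) -> int:
    return (int(seed) * 1_000_003 + offset) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Run the enabled stages; returns {artifact name: path}."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stages = set(config.stages)
    unknown = stages - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")

    cohort = analysis = None
    try:
        if "simulate" in stages:
            cohort = simulate.simulate(config.generator_config())
            simulate.write_cohort(cohort, out / "cohort.csv")
            artifacts["cohort"] = str(out / "cohort.csv")
            log.info("simulate: %d rows (%d participants)", len(cohort),
                     config.n_participants)

        if "ingest" in stages:
            if cohort is None:
                cohort = simulate.read_cohort(out / "cohort.csv")
            analysis, audit = ingest.apply_eligibility(
                cohort, brain_volume_denominator=config.brain_volume_denominator,
                exclude_pwa=config.exclude_pwa)
            ingest.write_analysis(analysis, out / "analysis.csv")
            (out / "audit.json").write_text(json.dumps(audit, indent=2) + "\n")
            artifacts["analysis"] = str(out / "analysis.csv")
            artifacts["audit"] = str(out / "audit.json")
            log.info("ingest: %d cross-sectional, %d longitudinal rows",
                     audit["n_cross_sectional"], audit["n_longitudinal"])

        needs_analysis = stages & {"fit", "paf", "usualbp", "treatment"}
        if needs_analysis and analysis is None:
            analysis = ingest.read_analysis(out / "analysis.csv")

        if "fit" in stages:
            frames = []
            for timing in ("concurrent", "past"):
                tbl = (analysis if timing == "concurrent"
                       else ingest.longitudinal_subset(analysis))
                for adjustment in ("unadjusted", "age_sex", "full"):
                    spec = models.ModelSpec(
                        exposures=("sbp", "dbp", "asi", "age", "sex", "diabetes",
                                   "smoking", "time_diff")
                        if adjustment != "full" else ("sbp", "dbp"),
                        adjustment=adjustment, timing=timing, standardized=True)
                    if timing == "concurrent":
                        spec.exposures = tuple(e for e in spec.exposures
                                               if e != "time_diff")
                    ests = models.fit_linear_model(tbl, spec)
                    frames.append(models.estimates_to_frame(
                        ests, timing=timing, adjustment=adjustment))
                # per-unit multiplicative ratios from the unstandardized full model
                raw = models.fit_linear_model(
                    tbl, models.ModelSpec(adjustment="full", timing=timing,
                                          standardized=False))
                ratios = [models.effect_ratio_per_unit(
                    e.beta, e.term, ci=(e.ci_low, e.ci_high), n=e.n)
                    for e in raw if e.term in ("sbp", "dbp")]
                frames.append(models.estimates_to_frame(
                    ratios, timing=timing, adjustment="full"))
            pd.concat(frames, ignore_index=True).to_csv(
                out / "estimates.csv", index=False, float_format="%.10g",
                lineterminator="\n")
            artifacts["estimates"] = str(out / "estimates.csv")
            log.info("fit: wrote estimates.csv")

        if "paf" in stages:
            results = {}
            for timing in ("concurrent", "past"):
                tbl = (analysis if timing == "concurrent"
                       else ingest.longitudinal_subset(analysis))
                for exposure in ("sbp", "dbp"):
                    est = paf.estimate_paf(tbl, exposure=exposure, timing=timing,
                                           adjustment="full")
                    results[f"{exposure}_{timing}"] = dataclasses.asdict(est)
            (out / "paf.json").write_text(json.dumps(results, indent=2) + "\n")
            artifacts["paf"] = str(out / "paf.json")
            log.info("paf: wrote paf.json")

        if "usualbp" in stages:
            fit_rows, strata_rows = [], []
            for which in ("sbp", "dbp"):
                fits = usual_bp.fit_usual_bp(
                    analysis, which, n_boot=config.n_boot,
                    seed=_derived_seed(config.seed, 1), min_n=config.min_stratum_n)
                fit_rows.append(usual_bp.fits_to_frame(fits))
                strata_rows.append(usual_bp.strata_to_frame(
                    usual_bp.build_strata(analysis, which,
                                          min_n=config.min_stratum_n)))
            pd.concat(fit_rows, ignore_index=True).to_csv(
                out / "usualbp.csv", index=False, float_format="%.10g",
                lineterminator="\n")
            pd.concat(strata_rows, ignore_index=True).to_csv(
                out / "usualbp_strata.csv", index=False, float_format="%.10g",
                lineterminator="\n")
            artifacts["usualbp"] = str(out / "usualbp.csv")
            artifacts["usualbp_strata"] = str(out / "usualbp_strata.csv")
            log.info("usualbp: wrote usualbp.csv")

        if "treatment" in stages:
            frames, medians = [], []
            for timing in ("past", "concurrent"):
                ests, med = treatment.compare_to_reference(analysis, timing)
                frames.append(models.estimates_to_frame(ests, timing=timing))
                med.insert(0, "timing", timing)
                medians.append(med)
            pd.concat(frames, ignore_index=True).to_csv(
                out / "treatment.csv", index=False, float_format="%.10g",
                lineterminator="\n")
            pd.concat(medians, ignore_index=True).to_csv(
                out / "treatment_medians.csv", index=False, float_format="%.10g",
                lineterminator="\n")
            artifacts["treatment"] = str(out / "treatment.csv")
            artifacts["treatment_medians"] = str(out / "treatment_medians.csv")
            log.info("treatment: wrote treatment.csv")
    except Exception as err:
        raise RuntimeError(f"pipeline stage failed: {err}") from err

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "config_sha256": config.config_hash(),
        "artifacts": sorted(artifacts),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str) + "\n")
    artifacts["manifest"] = str(out / "manifest.json")
    return artifacts
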