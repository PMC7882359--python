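# Example pipeline configuration for `bpwmh run --config docs/run_example.yaml`.
# All stages, demo-sized cohort; artifacts land in the output directory.
out_dir: scratch/run_demo
seed: 13
n_participants: 5000
n_boot: 500
min_stratum_n: 20
brain_volume_denominator: false
exclude_pwa: false
stages: [simulate, ingest, fit, paf, usualbp, treatment]
# generator_overrides accepts any GeneratorConfig field, e.g.:
# generator_overrides:
#   bp_tracking_corr: 0.85
#   exclusion_rate: 0.0
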