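# Demo pipeline: a 2,000-patient synthetic cohort calibrated to the packaged
# reference summary, all sixteen model configurations, 200 permutations per
# disparity cell. Run with:
#   sepsis-audit run-all --config configs/demo.yaml --out demo_bundle
cohort_source:
  synthetic:
    n_patients: 2000
models: null          # null = all sixteen configurations
train_fraction: 0.7
n_boot: 200
n_perm: 200
ci_level: 0.95
alpha: 0.05
seed: 0
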