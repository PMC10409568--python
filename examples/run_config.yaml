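# Three-condition virtual-lesion run on a synthetic cohort.
# Usage: lesionkit run --config examples/run_config.yaml --ci
cohort:
  n_subjects: 3
  seed: 42
lesion_sites: [L31]
fraction: 0.25
duration: 200.0
transient: 20.0
alpha: 0.05
seed: 7
out_dir: scratch/run42
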