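# Small end-to-end pipeline configuration:
#   queueflow run --config examples/run.yaml
# Simulates one MRI-like scheduled facility for 120 operating days, runs 5
# stepwise replicates on 3-month train / 1-week test windows, scores the
# forest importances, and writes the bundle (logs, matrices, frequencies,
# transfer ratios, report.md) to out_dir.
facilities:
  - archetype: mri_scheduled
    n_days: 120
out_dir: scratch/run-demo
seed: 11
replicates: 5
n_max: 10
folds: 10
top_k: 10
train_months: 3
test_days: 7
reference_days: 28
rf_grid:
  - {max_features: 28, max_depth: 16, n_estimators: 50}
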