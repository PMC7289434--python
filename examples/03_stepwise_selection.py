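"""Repeated forward-stepwise selection on a simulated scheduled facility.

Runs 5 replicates of the six-month-train / two-week-test stepwise protocol
on an ultrasound-like facility and prints the selection frequencies: the
features chosen most often are overwhelmingly congestion-group, and the
testing percentage error falls from 100% (intercept only) to a plateau as
features are added.
"""

import numpy as np

import queueflow as qf

config = qf.facility_archetype("ultrasound_scheduled", n_days=300, seed=2)
log, _ = qf.generate_log(config)
stats = qf.estimate_duration_stats(log, reference_days=90)
matrix = qf.featurize_log(log, stats=stats, slot_minutes=config.slot_minutes,
                          n_servers=config.n_servers, start=stats.reference_end)
print(f"feature matrix: {len(matrix)} visits")

splits = qf.make_splits(matrix, 5, seed=0)
paths = []
for spec in splits:
    train, test = qf.split_frames(matrix, spec)
    paths.append(qf.forward_stepwise(train, test, n_max=10, folds=10, seed=spec.seed))

summary = qf.selection_frequency(paths)
catalog = qf.build_catalog()
print("\nmost frequently selected features:")
for name in summary.top(10):
    print(f"  {name:28s} {summary.frequency_percent(name):5.0f}%  ({catalog.group(name)})")

curve = np.mean([qf.testing_percentage_error(p) for p in paths], axis=0)
print("\nmean testing percentage error by model size:")
print("  " + "  ".join(f"{v:5.1f}" for v in curve))
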