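"""Feature-set algebra and cross-facility transfer on the published sets.

Intersects the shipped stepwise-LR and random-forest union selections
(8 features in common), filters the forest union for a walk-in facility
(12 survive under the arrival-as-schedule proxy), and measures on synthetic
data how much worse a noise feature set predicts than the true drivers.
"""

import queueflow as qf
from queueflow.synthetic import planted_linear_matrix
from queueflow.transfer import reference_feature_set

catalog = qf.build_catalog()
lr = reference_feature_set("lr_union_scheduled")
rf = reference_feature_set("rf_union_scheduled")

common = qf.intersect_sets(lr, rf, catalog)
print(f"LR union ({len(lr)}) ∩ RF union ({len(rf)}) = {len(common)} features:")
for name in common.features:
    print(f"  {name}")

kept = qf.applicable_subset(rf, "walkin", catalog, policy="proxy")
print(f"\nRF union restricted to a walk-in facility: {len(kept)} features "
      f"(dropped: {sorted(set(rf.features) - set(kept.features))})")

matrix = planted_linear_matrix(n_rows=4000, n_features=8, noise_sd=0.5, seed=3)
splits = qf.make_splits(matrix, 5, seed=0, train_months=2, test_days=7)
result = qf.transfer_ratio(
    matrix,
    transferred=qf.FeatureSet("noise", ["f6", "f7"]),
    optimal=qf.FeatureSet("true", ["f1"]),
    splits=splits,
)
print(f"\nnoise-set transfer ratio vs true driver: {result.ratio:.2f} "
      f"(1.00 = equal; >1 = worse)")
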