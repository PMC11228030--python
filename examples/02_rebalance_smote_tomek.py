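"""Rebalance an imbalanced cohort with SMOTE oversampling + Tomek cleaning.

SMOTE grows each minority class to the majority count by interpolating
between same-class nearest neighbors; Tomek-link removal then deletes
mutually-nearest cross-class pairs that blur the class boundary.
"""

from wvcnn import ResamplingConfig, SyntheticSpec, generate_dataset, smote_tomek

bundle = generate_dataset(
    SyntheticSpec(n_features=20, n_informative=10, effect_size=0.8, seed=3)
)
print("before:", {n: int(c) for n, c in
                  zip(bundle.labels.class_names, bundle.labels.counts())})

res = smote_tomek(bundle, ResamplingConfig(k_neighbors=5, seed=3))
after = res.as_bundle()
print("after: ", {n: int(c) for n, c in
                  zip(after.labels.class_names, after.labels.counts())})
print(f"synthetic samples: {int(res.is_synthetic.sum())}")
print(f"removed by Tomek cleaning: {len(res.removed_original_indices)}")

# Every class is grown to the majority count (74); any samples removed
# afterwards were boundary-overlap pairs with conflicting labels.
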