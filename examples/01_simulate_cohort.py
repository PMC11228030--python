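"""Generate a synthetic leukemia-like cohort and inspect its structure.

The generator emulates a seven-subtype microarray study: unbalanced class
counts (74/51/22/17/46/53/18), log-scale intensities around 2.6-7.4, and a
chosen number of class-informative probes.
"""

from wvcnn import SyntheticSpec, generate_dataset, signal_plan

spec = SyntheticSpec(n_features=2000, n_informative=300, effect_size=2.5, seed=7)
bundle = generate_dataset(spec)
plan = signal_plan(spec)

print(f"samples:  {bundle.n_samples}")
print(f"probes:   {bundle.n_features} ({spec.n_informative} informative)")
print("class counts:", {n: int(c) for n, c in
                        zip(bundle.labels.class_names, bundle.labels.counts())})
print(f"intensity range: {bundle.expression.values.min():.2f}"
      f" .. {bundle.expression.values.max():.2f}")
print(f"first informative probe: {bundle.expression.feature_ids[plan.informative_features[0]]}"
      f" (elevated in class {bundle.labels.class_names[plan.assigned_classes[0]]})")

# The counts mirror the emulated cohort's imbalance; the informative probes
# are the signal the downstream chi-square selection should recover.
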