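import numpy as np
import pytest

from wvcnn import (
    DatasetBundle,
    ExpressionMatrix,
    LabelVector,
    SyntheticSpec,
    generate_dataset,
)

# Two-sample excerpt of the cohort's raw intensity layout: three probes,
# both samples labeled with the same subtype.
TABLE3_VALUES = {
    "1053_at": (5.009216, 5.415108),
    "1007_s_at": (7.409521, 7.177109),
    "AFFXTrpnXM_at": (2.608381, 2.634063),
}


@pytest.fixture
def cohort_excerpt() -> DatasetBundle:
    features = list(TABLE3_VALUES)
    values = np.array(list(zip(*TABLE3_VALUES.values())))
    expr = ExpressionMatrix(values, features, ["BCELL_ALL_1", "BCELL_ALL_2"])
    labels = LabelVector([0, 0], ["BCELL_ALL"])
    return DatasetBundle(expr, labels)


def random_bundle(
    rng: np.random.Generator,
    n_samples: int = 10,
    n_features: int = 20,
    n_classes: int = 2,
) -> DatasetBundle:
    """Small random labeled bundle with every class present."""
    n_classes = min(n_classes, n_samples)
    values = rng.uniform(0.0, 10.0, size=(n_samples, n_features))
    labels = np.concatenate(
        [np.arange(n_classes), rng.integers(n_classes, size=n_samples - n_classes)]
    )
    rng.shuffle(labels)
    expr = ExpressionMatrix(
        values,
        [f"probe_{i}_at" for i in range(n_features)],
        [f"S{i}" for i in range(n_samples)],
    )
    return DatasetBundle(expr, LabelVector(labels, [f"C{i}" for i in range(n_classes)]))


@pytest.fixture
def small_synthetic() -> DatasetBundle:
    """Three balanced-ish classes, 60 features, 10 of them informative."""
    spec = SyntheticSpec(
        class_counts=[20, 15, 10],
        n_features=60,
        n_informative=10,
        effect_size=3.0,
        seed=42,
    )
    return generate_dataset(spec)
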