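"""Synthetic microarray generator with controllable class structure.

The generator emulates the shape of a pediatric-leukemia subtype microarray
study: seven unbalanced classes (74/51/22/17/46/53/18 samples), 22,283
probe-set features on a log-like intensity scale of roughly 2.6-7.4, and a
configurable subset of class-informative probes.  Each informative probe
separates exactly one class from the rest by an upward mean shift of
``effect_size`` within-class standard deviations, with classes assigned
round-robin so every class is recoverable by feature selection.
Non-informative probes share one baseline mean across classes.  All values
carry Gaussian noise (sd ``noise_sd``) and are clipped at zero, since
hybridization intensities are nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import DatasetBundle, ExpressionMatrix, LabelVector, ValidationError

#: Subtype vocabulary of the emulated leukemia cohort, in cohort order.
LEUKEMIA_SUBTYPES = [
    "B-CELL-ALL",
    "B-CELL-ALL-HYPERDIP",
    "B-CELL-ALL-TCF3-PBX1",
    "B-CELL-ALL-MLL",
    "B-CELL-ALL-T-ALL",
    "B-CELL-ALL-ETV6-RUNX1",
    "B-CELL-ALL-HYPO",
]

_LEUKEMIA_COUNTS = [74, 51, 22, 17, 46, 53, 18]


def leukemia_class_counts() -> list[int]:
    """Per-class sample counts of the emulated leukemia cohort.

    Returns the seven subtype counts (74, 51, 22, 17, 46, 53, 18; 281
    samples in total) in the same order as :data:`LEUKEMIA_SUBTYPES`.
    """
    return list(_LEUKEMIA_COUNTS)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    class_counts
        Samples per class; defaults to the leukemia cohort profile.
    n_features
        Total probe count (default 22,283).
    n_informative
        Number of class-discriminative probes (default 300), placed at
        random positions among the features.
    effect_size
        Mean shift of the separated class, in units of ``noise_sd``.
    baseline_range
        Uniform range for per-probe baseline means, default (2.6, 7.4)
        matching the visible range of log-scale microarray intensities.
    noise_sd
        Within-class standard deviation of every probe.
    class_names
        Optional explicit vocabulary; defaults to the leukemia subtype
        names when ``class_counts`` has seven entries, else ``CLASS_<i>``.
    seed
        Single seed driving all sampling through one generator stream.
    """

    class_counts: list[int] = field(default_factory=leukemia_class_counts)
    n_features: int = 22283
    n_informative: int = 300
    effect_size: float = 2.5
    baseline_range: tuple[float, float] = (2.6, 7.4)
    noise_sd: float = 0.4
    class_names: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.class_counts):
            raise ValidationError("class counts must be nonnegative")
        if sum(self.class_counts) == 0:
            raise ValidationError("zero total samples")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValidationError("need 0 <= n_informative <= n_features")
        if self.effect_size < 0:
            raise ValidationError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        lo, hi = self.baseline_range
        if not lo <= hi:
            raise ValidationError("baseline_range must be (low, high)")

    def resolved_class_names(self) -> list[str]:
        if self.class_names is not None:
            if len(self.class_names) != len(self.class_counts):
                raise ValidationError("class_names length mismatch")
            return list(self.class_names)
        if len(self.class_counts) == len(LEUKEMIA_SUBTYPES):
            return list(LEUKEMIA_SUBTYPES)
        return [f"CLASS_{i}" for i in range(len(self.class_counts))]


@dataclass
class SignalPlan:
    """Ground truth of a generated cohort: which probes carry signal.

    ``informative_features[i]`` is shifted upward for samples of class
    ``assigned_classes[i]``; ``baselines`` holds every probe's baseline mean.
    """

    informative_features: np.ndarray
    assigned_classes: np.ndarray
    baselines: np.ndarray


def _draw_plan(spec: SyntheticSpec, rng: np.random.Generator) -> SignalPlan:
    lo, hi = spec.baseline_range
    baselines = rng.uniform(lo, hi, size=spec.n_features)
    informative = np.sort(
        rng.choice(spec.n_features, size=spec.n_informative, replace=False)
    )
    n_classes = len(spec.class_counts)
    assigned = np.arange(spec.n_informative, dtype=np.int64) % n_classes
    return SignalPlan(informative, assigned, baselines)


def signal_plan(spec: SyntheticSpec) -> SignalPlan:
    """Return the ground-truth signal layout a spec's seed produces."""
    return _draw_plan(spec, np.random.default_rng(spec.seed))


def generate_dataset(spec: SyntheticSpec) -> DatasetBundle:
    """Generate a labeled expression matrix from ``spec``.

    Fully reproducible: the same spec (same seed) yields bit-identical
    matrices.  The signal layout is exactly :func:`signal_plan`'s output
    for the same spec.
    """
    rng = np.random.default_rng(spec.seed)
    plan = _draw_plan(spec, rng)
    class_names = spec.resolved_class_names()
    n_total = sum(spec.class_counts)

    labels = np.repeat(np.arange(len(spec.class_counts)), spec.class_counts)
    means = np.tile(plan.baselines, (n_total, 1))
    shift = spec.effect_size * spec.noise_sd
    for feat, cls in zip(plan.informative_features, plan.assigned_classes):
        means[labels == cls, feat] += shift

    values = means + rng.normal(0.0, spec.noise_sd, size=means.shape)
    np.maximum(values, 0.0, out=values)  # intensities are nonnegative

    sample_ids = []
    for cls, count in enumerate(spec.class_counts):
        sample_ids.extend(f"{class_names[cls]}_{i + 1}" for i in range(count))
    feature_ids = [f"SYN_{i:05d}_at" for i in range(spec.n_features)]

    return DatasetBundle(
        ExpressionMatrix(values, feature_ids, sample_ids),
        LabelVector(labels, class_names),
    )
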