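"""Core in-memory containers for labeled gene-expression data.

An :class:`ExpressionMatrix` holds hybridization intensities as a dense
``n_samples x n_features`` float array together with probe-set feature
identifiers (e.g. ``"1053_at"``) and unique sample identifiers.  A
:class:`LabelVector` carries 0-based class indices against a fixed, ordered
class vocabulary.  :class:`DatasetBundle` ties the two together and is the
object every pipeline stage consumes and produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ValidationError(ValueError):
    """Raised when data violates a structural invariant."""


class ConfigurationError(ValueError):
    """Raised when a configuration value is inconsistent or missing."""


@dataclass
class ExpressionMatrix:
    """Dense samples-by-features intensity matrix with aligned identifiers.

    Parameters
    ----------
    values
        2-D float array of shape ``(n_samples, n_features)``.  Must be free
        of NaN/inf after construction; loading either fails or imputes,
        never silently propagates missing values.
    feature_ids
        Ordered, unique probe identifiers, one per column.
    sample_ids
        Ordered, unique sample identifiers, one per row.
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValidationError("expression values must be a 2-D array")
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        n_samples, n_features = self.values.shape
        if len(self.feature_ids) != n_features:
            raise ValidationError(
                f"{len(self.feature_ids)} feature ids for {n_features} columns"
            )
        if len(self.sample_ids) != n_samples:
            raise ValidationError(
                f"{len(self.sample_ids)} sample ids for {n_samples} rows"
            )
        if len(set(self.feature_ids)) != n_features:
            raise ValidationError("feature ids must be unique")
        if len(set(self.sample_ids)) != n_samples:
            raise ValidationError("duplicate sample ids")
        if not np.isfinite(self.values).all():
            raise ValidationError("expression matrix contains NaN or inf")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelVector:
    """Per-sample class indices against an ordered class vocabulary."""

    labels: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1:
            raise ValidationError("labels must be a 1-D array")
        self.class_names = [str(c) for c in self.class_names]
        if len(set(self.class_names)) != len(self.class_names):
            raise ValidationError("class names must be unique")
        if self.labels.size and (
            self.labels.min() < 0 or self.labels.max() >= len(self.class_names)
        ):
            raise ValidationError("label index outside class vocabulary")

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def counts(self) -> np.ndarray:
        """Per-class sample counts in vocabulary order."""
        return np.bincount(self.labels, minlength=self.n_classes)

    def as_names(self) -> list[str]:
        return [self.class_names[i] for i in self.labels]


@dataclass
class DatasetBundle:
    """A labeled expression matrix: the unit of work for the pipeline."""

    expression: ExpressionMatrix
    labels: LabelVector

    def __post_init__(self) -> None:
        if self.expression.n_samples != len(self.labels.labels):
            raise ValidationError(
                "expression and labels disagree on sample count: "
                f"{self.expression.n_samples} vs {len(self.labels.labels)}"
            )

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    @property
    def n_features(self) -> int:
        return self.expression.n_features

    @property
    def n_classes(self) -> int:
        return self.labels.n_classes

    def subset_samples(self, indices: np.ndarray) -> "DatasetBundle":
        """Return a new bundle restricted to ``indices`` (order preserved)."""
        indices = np.asarray(indices, dtype=np.int64)
        expr = ExpressionMatrix(
            self.expression.values[indices],
            self.expression.feature_ids,
            [self.expression.sample_ids[i] for i in indices],
        )
        labels = LabelVector(self.labels.labels[indices], self.labels.class_names)
        return DatasetBundle(expr, labels)

    def subset_features(self, indices: np.ndarray) -> "DatasetBundle":
        """Return a new bundle restricted to the given feature columns."""
        indices = np.asarray(indices, dtype=np.int64)
        expr = ExpressionMatrix(
            self.expression.values[:, indices],
            [self.expression.feature_ids[i] for i in indices],
            self.expression.sample_ids,
        )
        return DatasetBundle(expr, self.labels)
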