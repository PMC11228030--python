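"""Class rebalancing: SMOTE oversampling combined with Tomek-link cleaning.

SMOTE grows each minority class to a target count by interpolating between
a random class member ``x`` and one of its k nearest same-class neighbors
``x_nn``: the synthetic point is ``x + lambda * (x_nn - x)`` with
``lambda ~ Uniform[0, 1]``.  A Tomek link is a pair of mutually nearest
neighbors carrying different labels; deleting link members after
oversampling cleans class-boundary overlap.  Detection runs once, after
SMOTE, on the augmented set.

Distances are Euclidean on raw feature values by default; an optional
``standardize`` flag computes neighborhoods in per-feature z-score space
(interpolation still happens on the raw scale, which is equivalent for the
convex combination itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .datatypes import (
    ConfigurationError,
    DatasetBundle,
    ExpressionMatrix,
    LabelVector,
    ValidationError,
)


@dataclass
class ResamplingConfig:
    """Knobs for SMOTE and Tomek-link cleaning.

    ``k_neighbors`` defaults to 5 (canonical SMOTE) and is capped at
    ``class_size - 1`` with a warning for tiny classes.  ``link_removal``
    defaults to deleting both members of every link; ``remove_majority_only``
    deletes only the member of the currently larger class (ties keep both).
    """

    k_neighbors: int = 5
    target_policy: str = "equalize_to_majority"
    explicit_counts: list[int] | None = None
    link_removal: str = "remove_both"
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ConfigurationError("k_neighbors must be >= 1")
        if self.target_policy not in ("equalize_to_majority", "explicit_counts"):
            raise ConfigurationError(f"unknown target_policy {self.target_policy!r}")
        if (self.explicit_counts is not None) != (
            self.target_policy == "explicit_counts"
        ):
            raise ConfigurationError(
                "explicit_counts required iff target_policy == 'explicit_counts'"
            )
        if self.link_removal not in ("remove_both", "remove_majority_only"):
            raise ConfigurationError(f"unknown link_removal {self.link_removal!r}")


@dataclass
class ResampledDataset:
    """Rebalanced data with provenance.

    ``is_synthetic`` flags SMOTE-created rows; ``parents`` holds, per row,
    the two pre-resampling sample indices it interpolates (``(-1, -1)`` for
    originals); ``removed_original_indices`` lists positions, in the
    augmented pre-removal array, deleted by Tomek cleaning.
    """

    expression: ExpressionMatrix
    labels: LabelVector
    is_synthetic: np.ndarray
    parents: np.ndarray
    removed_original_indices: list[int] = field(default_factory=list)

    def as_bundle(self) -> DatasetBundle:
        return DatasetBundle(self.expression, self.labels)


def _distance_space(X: np.ndarray, standardize: bool) -> np.ndarray:
    if not standardize:
        return X
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _class_targets(counts: np.ndarray, config: ResamplingConfig) -> np.ndarray:
    if config.target_policy == "equalize_to_majority":
        return np.full_like(counts, counts.max())
    targets = np.asarray(config.explicit_counts, dtype=np.int64)
    if targets.shape != counts.shape:
        raise ConfigurationError(
            f"explicit_counts has {targets.size} entries for {counts.size} classes"
        )
    return targets


def smote_oversample(
    bundle: DatasetBundle, config: ResamplingConfig | None = None
) -> ResampledDataset:
    """Grow every minority class to its target count by SMOTE interpolation.

    Originals are retained unchanged; synthetic rows are appended grouped by
    class, in class-index order.  Deterministic under a fixed seed.
    """
    config = config or ResamplingConfig()
    X = bundle.expression.values
    y = bundle.labels.labels
    counts = bundle.labels.counts()
    targets = _class_targets(counts, config)
    if (targets < counts).any():
        cls = int(np.argmax(targets < counts))
        raise ValidationError(
            f"target count {targets[cls]} below current count {counts[cls]} for "
            f"class {bundle.labels.class_names[cls]!r}: SMOTE never undersamples"
        )

    Xd = _distance_space(X, config.standardize)
    rng = np.random.default_rng(config.seed)

    new_rows: list[np.ndarray] = []
    new_labels: list[int] = []
    new_parents: list[tuple[int, int]] = []
    for cls in range(bundle.n_classes):
        n_syn = int(targets[cls] - counts[cls])
        if n_syn == 0:
            continue
        members = np.flatnonzero(y == cls)
        if members.size < 2:
            raise ValidationError(
                f"class {bundle.labels.class_names[cls]!r} has {members.size} "
                "sample(s); SMOTE needs at least 2 to interpolate"
            )
        k = min(config.k_neighbors, members.size - 1)
        if k < config.k_neighbors:
            warnings.warn(
                f"class {bundle.labels.class_names[cls]!r}: k_neighbors capped "
                f"at {k} (class size {members.size})",
                stacklevel=2,
            )
        dists = cdist(Xd[members], Xd[members])
        np.fill_diagonal(dists, np.inf)
        # stable sort: equal distances resolve to the lower sample index
        neighbor_order = np.argsort(dists, axis=1, kind="stable")[:, :k]
        for _ in range(n_syn):
            i = int(rng.integers(members.size))
            j = int(neighbor_order[i, int(rng.integers(k))])
            lam = rng.random()
            new_rows.append(X[members[i]] + lam * (X[members[j]] - X[members[i]]))
            new_labels.append(cls)
            new_parents.append((int(members[i]), int(members[j])))

    n_orig = bundle.n_samples
    if new_rows:
        values = np.vstack([X, np.array(new_rows)])
        labels = np.concatenate([y, np.array(new_labels, dtype=np.int64)])
    else:
        values = X.copy()
        labels = y.copy()
    is_syn = np.zeros(len(values), dtype=bool)
    is_syn[n_orig:] = True
    parents = np.full((len(values), 2), -1, dtype=np.int64)
    if new_parents:
        parents[n_orig:] = np.array(new_parents, dtype=np.int64)

    syn_counter: dict[int, int] = {}
    sample_ids = list(bundle.expression.sample_ids)
    for cls in new_labels:
        syn_counter[cls] = syn_counter.get(cls, 0) + 1
        sample_ids.append(
            f"{bundle.labels.class_names[cls]}_smote_{syn_counter[cls]}"
        )

    return ResampledDataset(
        ExpressionMatrix(values, bundle.expression.feature_ids, sample_ids),
        LabelVector(labels, bundle.labels.class_names),
        is_syn,
        parents,
        [],
    )


def find_tomek_links(
    bundle: DatasetBundle, standardize: bool = False
) -> list[tuple[int, int]]:
    """All unordered index pairs that form Tomek links.

    A pair (i, j) is a link when j is i's single nearest neighbor, i is j's
    single nearest neighbor (Euclidean, over all samples regardless of
    class), and their labels differ.  Nearest-neighbor ties resolve to the
    lower sample index.  Returns an empty list when no links exist.
    """
    X = _distance_space(bundle.expression.values, standardize)
    y = bundle.labels.labels
    n = len(X)
    if n < 2:
        return []
    dists = cdist(X, X)
    np.fill_diagonal(dists, np.inf)
    nn = dists.argmin(axis=1)  # argmin takes the first (lowest-index) minimum
    links = []
    for i in range(n):
        j = int(nn[i])
        if i < j and nn[j] == i and y[i] != y[j]:
            links.append((i, j))
    return links


def smote_tomek(
    bundle: DatasetBundle, config: ResamplingConfig | None = None
) -> ResampledDataset:
    """SMOTE oversampling followed by one pass of Tomek-link cleaning."""
    config = config or ResamplingConfig()
    over = smote_oversample(bundle, config)
    augmented = over.as_bundle()
    links = find_tomek_links(augmented, standardize=config.standardize)

    counts = augmented.labels.counts()
    to_remove: set[int] = set()
    for i, j in links:
        if config.link_removal == "remove_both":
            to_remove.update((i, j))
        else:
            ci, cj = augmented.labels.labels[i], augmented.labels.labels[j]
            if counts[ci] > counts[cj]:
                to_remove.add(i)
            elif counts[cj] > counts[ci]:
                to_remove.add(j)
            # tie: both kept

    keep = np.array(
        [i for i in range(augmented.n_samples) if i not in to_remove], dtype=np.int64
    )
    kept = augmented.subset_samples(keep)
    return ResampledDataset(
        kept.expression,
        kept.labels,
        over.is_synthetic[keep],
        over.parents[keep],
        sorted(to_remove),
    )
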