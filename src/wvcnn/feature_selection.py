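"""Chi-square feature ranking and top-k selection.

The chi-square score of a probe measures dependence between that probe and
the class label as sum((O - E)^2 / E) over feature-state x class cells,
where O is observed mass and E its expectation under independence.  Two
discretizations are offered:

``mass`` (default)
    Each probe's nonnegative intensity is treated as mass: observed per
    class is the probe's sum over that class's samples, expected is total
    mass times the class sample fraction.  This is the convention of
    mainstream feature-selection toolkits for continuous nonnegative data.

``binarized``
    Each probe is thresholded at its own median into a presence indicator
    and the score is the chi-square statistic of the resulting
    2 x n_classes contingency table (for two classes this reduces to the
    classic four-cell formula n(ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import DatasetBundle, ValidationError


@dataclass
class FeatureScores:
    """Per-feature nonnegative chi-square statistics with aligned ids."""

    scores: np.ndarray
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if len(self.scores) != len(self.feature_ids):
            raise ValidationError("scores and feature ids differ in length")
        if not np.isfinite(self.scores).all() or (self.scores < 0).any():
            raise ValidationError("chi-square scores must be finite and >= 0")


def _chi2_mass(X: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    if (X < 0).any():
        raise ValidationError(
            "mass-mode chi-square needs nonnegative values; use mode='binarized'"
        )
    n = len(X)
    # observed per-class mass: (n_classes, n_features)
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    observed = onehot.T @ X
    class_frac = onehot.sum(axis=0) / n
    expected = class_frac[:, None] * X.sum(axis=0)[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    return terms.sum(axis=0)


def _chi2_binarized(X: np.ndarray, y: np.ndarray, n_classes: int) -> np.ndarray:
    n = len(X)
    present = X > np.median(X, axis=0)  # (n, n_features) presence indicator
    onehot = np.zeros((n, n_classes))
    onehot[np.arange(n), y] = 1.0
    n11 = onehot.T @ present  # (n_classes, n_features): present & in class
    class_counts = onehot.sum(axis=0)[:, None]
    present_tot = present.sum(axis=0)[None, :]
    n01 = class_counts - n11  # absent & in class
    row1 = np.broadcast_to(present_tot, n11.shape)
    row0 = n - row1
    scores = np.zeros(X.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        for obs, row_tot in ((n11, row1), (n01, row0)):
            expected = row_tot * class_counts / n
            scores += np.where(
                expected > 0, (obs - expected) ** 2 / expected, 0.0
            ).sum(axis=0)
    return scores


def chi2_scores(bundle: DatasetBundle, mode: str = "mass") -> FeatureScores:
    """Score every feature's dependence on the class label.

    Zero-variance features score 0 (observed equals expected); they are not
    an error.  ``mass`` mode raises if any value is negative.
    """
    if bundle.n_classes < 2 or len(np.unique(bundle.labels.labels)) < 2:
        raise ValidationError("chi-square scoring needs at least 2 classes present")
    X = bundle.expression.values
    y = bundle.labels.labels
    if mode == "mass":
        scores = _chi2_mass(X, y, bundle.n_classes)
    elif mode == "binarized":
        scores = _chi2_binarized(X, y, bundle.n_classes)
    else:
        raise ValidationError(f"unknown chi-square mode {mode!r}")
    # guard tiny negative round-off
    return FeatureScores(np.maximum(scores, 0.0), bundle.expression.feature_ids)


def select_top_k(scores: FeatureScores, k: int) -> np.ndarray:
    """Indices of the k largest scores, descending; ties by ascending index.

    Returns exactly ``k`` indices into ``scores.feature_ids``.
    """
    n = len(scores.scores)
    if not 1 <= k <= n:
        raise ValidationError(f"k={k} outside [1, {n}]")
    # stable sort on -score keeps ascending index order among ties
    order = np.argsort(-scores.scores, kind="stable")
    return order[:k]
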