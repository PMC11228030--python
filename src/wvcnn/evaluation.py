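"""Stratified splitting, confusion-matrix metrics, and k-fold evaluation.

The 85:15 train/test split reproduces the cohort bookkeeping convention:
the test set holds ``ceil(n * fraction)`` samples (281 samples at 15% give
238 train / 43 test), allocated per class by largest-remainder rounding so
every class's test share is within one sample of the global fraction.

Metrics derive from the confusion matrix via per-class one-vs-rest counts:
accuracy = (TP + TN) / (TP + TN + FP + FN) (equivalently trace / total),
precision = TP / (TP + FP), recall = TP / (TP + FN), and
F1 = 2 * precision * recall / (precision + recall), averaged macro
(default) or weighted by class support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .datatypes import DatasetBundle, LabelVector, ValidationError


@dataclass
class ConfusionMatrix:
    """Integer count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        n = len(self.class_names)
        if self.counts.shape != (n, n):
            raise ValidationError(
                f"confusion matrix shape {self.counts.shape} for {n} classes"
            )
        if (self.counts < 0).any():
            raise ValidationError("confusion counts must be >= 0")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricsReport:
    """Aggregate and per-class classification metrics."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str
    per_class: dict[str, dict[str, float]]
    confusion: ConfusionMatrix | None = None

    def to_dict(self) -> dict:
        out = {
            "accuracy": round(self.accuracy, 4),
            "precision": round(self.precision, 4),
            "recall": round(self.recall, 4),
            "f1": round(self.f1, 4),
            "averaging": self.averaging,
            "per_class": {
                c: {k: round(v, 4) for k, v in d.items()}
                for c, d in self.per_class.items()
            },
        }
        if self.confusion is not None:
            out["confusion"] = self.confusion.counts.tolist()
        return out


def stratified_split(
    labels: LabelVector, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test split.

    Returns disjoint (train_indices, test_indices) covering all samples.
    The total test count is ``ceil(n * test_fraction)``; per-class test
    counts follow largest-remainder rounding of proportional shares.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValidationError("test_fraction must lie in (0, 1)")
    y = labels.labels
    n = len(y)
    counts = labels.counts()
    if (counts == 0).any():
        empty = [c for c, k in zip(labels.class_names, counts) if k == 0]
        warnings.warn(f"classes with zero samples: {empty}", stacklevel=2)

    n_test = ceil(n * test_fraction)
    ideal = counts * n_test / n
    alloc = np.floor(ideal).astype(np.int64)
    remainder = ideal - alloc
    short = n_test - alloc.sum()
    # largest remainders first; ties to the larger class, then lower index
    order = sorted(
        range(len(counts)), key=lambda c: (-remainder[c], -counts[c], c)
    )
    for c in order[: int(short)]:
        alloc[c] += 1
    alloc = np.minimum(alloc, counts)
    # redistribute anything clipped by tiny classes
    deficit = n_test - alloc.sum()
    for c in order:
        while deficit > 0 and alloc[c] < counts[c]:
            alloc[c] += 1
            deficit -= 1

    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for c in range(len(counts)):
        members = np.flatnonzero(y == c)
        perm = rng.permutation(members)
        test_idx.extend(perm[: alloc[c]])
        train_idx.extend(perm[alloc[c] :])
    return np.sort(np.array(train_idx, dtype=np.int64)), np.sort(
        np.array(test_idx, dtype=np.int64)
    )


def confusion(true: LabelVector, predicted: LabelVector) -> ConfusionMatrix:
    """Count matrix of true class (row) vs predicted class (column)."""
    if len(true.labels) != len(predicted.labels):
        raise ValidationError(
            f"length mismatch: {len(true.labels)} true vs "
            f"{len(predicted.labels)} predicted"
        )
    if true.class_names != predicted.class_names:
        raise ValidationError("true and predicted label vocabularies differ")
    n = true.n_classes
    counts = np.zeros((n, n), dtype=np.int64)
    np.add.at(counts, (true.labels, predicted.labels), 1)
    return ConfusionMatrix(counts, true.class_names)


def metrics(cm: ConfusionMatrix, averaging: str = "macro") -> MetricsReport:
    """Accuracy, precision, recall and F1 from a confusion matrix.

    Per-class scores use one-vs-rest TP/FP/FN/TN; a class with zero
    predicted positives contributes precision 0 (flagged in its per-class
    entry as ``degenerate``).
    """
    if averaging not in ("macro", "weighted"):
        raise ValidationError(f"unknown averaging {averaging!r}")
    c = cm.counts
    total = cm.total
    if total == 0:
        raise ValidationError("empty confusion matrix")
    tp = np.diag(c).astype(np.float64)
    fp = c.sum(axis=0) - tp
    fn = c.sum(axis=1) - tp
    support = c.sum(axis=1).astype(np.float64)

    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        recall = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(
            precision + recall > 0,
            2 * precision * recall / (precision + recall),
            0.0,
        )

    per_class = {}
    for i, name in enumerate(cm.class_names):
        per_class[name] = {
            "precision": float(precision[i]),
            "recall": float(recall[i]),
            "f1": float(f1[i]),
            "support": float(support[i]),
            "degenerate": float(tp[i] + fp[i] == 0),
        }

    if averaging == "macro":
        agg = lambda v: float(v.mean())
    else:
        w = support / support.sum()
        agg = lambda v: float((v * w).sum())

    return MetricsReport(
        accuracy=float(np.trace(c) / total),
        precision=agg(precision),
        recall=agg(recall),
        f1=agg(f1),
        averaging=averaging,
        per_class=per_class,
        confusion=cm,
    )


def mean_report(reports: list[MetricsReport]) -> MetricsReport:
    """Unweighted mean of fold reports (per-class entries averaged too)."""
    if not reports:
        raise ValidationError("no reports to average")
    names = list(reports[0].per_class)
    per_class = {
        c: {
            k: float(np.mean([r.per_class[c][k] for r in reports]))
            for k in reports[0].per_class[c]
        }
        for c in names
    }
    return MetricsReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        averaging=reports[0].averaging,
        per_class=per_class,
        confusion=None,
    )


def stratified_folds(
    labels: LabelVector, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified k-fold partition as (train, test) index pairs."""
    if k < 2:
        raise ValidationError("k must be >= 2")
    y = labels.labels
    if k > len(y):
        raise ValidationError(f"k={k} exceeds {len(y)} samples")
    if (labels.counts() < k).any():
        warnings.warn(
            "some classes have fewer samples than folds; stratification degrades",
            stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def kfold_cv(
    bundle: DatasetBundle,
    pipeline_config,
    k: int = 5,
    seed: int = 0,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Run the full pipeline independently on each of k stratified folds.

    In strict (leakage-free) mode, resampling and feature selection are
    refit on each fold's training portion only; ``leakage_mode="pooled"``
    instead resamples and selects on the whole dataset once, before
    folding.  Returns the k fold reports and their unweighted mean.
    """
    from .pipeline import fit_and_evaluate  # cycle-free late import

    cfg = pipeline_config
    if cfg.leakage_mode == "pooled":
        bundle = _preprocess_whole(bundle, cfg)

    reports = []
    for fold_i, (train_idx, test_idx) in enumerate(
        stratified_folds(bundle.labels, k, seed)
    ):
        train = bundle.subset_samples(train_idx)
        test = bundle.subset_samples(test_idx)
        report, _ = fit_and_evaluate(
            train, test, cfg, seed=seed + fold_i, preprocessed=(cfg.leakage_mode == "pooled")
        )
        reports.append(report)
    return reports, mean_report(reports)


def _preprocess_whole(bundle: DatasetBundle, cfg) -> DatasetBundle:
    from .feature_selection import chi2_scores, select_top_k
    from .resampling import smote_tomek

    res = smote_tomek(bundle, cfg.resampling)
    full = res.as_bundle()
    scores = chi2_scores(full, mode=cfg.selection_mode)
    keep = select_top_k(scores, cfg.k_features)
    return full.subset_features(np.sort(keep))
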