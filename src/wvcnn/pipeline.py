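"""End-to-end orchestration: load -> split -> rebalance -> select -> train -> evaluate.

One :class:`PipelineConfig` drives the whole run.  In the default strict
(leakage-free) protocol the data are split first and SMOTE-Tomek plus
chi-square selection are fitted on the training portion only; the
``pooled`` protocol instead rebalances and selects on the full dataset
before splitting, reproducing the bookkeeping in which resampled totals
appear on both sides of the split.  Every artifact records the resolved
configuration and seed so a run is always recoverable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from .datatypes import ConfigurationError, DatasetBundle, ValidationError
from .ensemble import (
    EnsembleModel,
    EnsembleWeights,
    TrainingConfig,
    save_model,
    train_ensemble,
)
from .evaluation import MetricsReport, confusion, metrics, stratified_split
from .feature_selection import chi2_scores, select_top_k
from .io_data import read_dataset
from .resampling import ResamplingConfig, smote_tomek

logger = logging.getLogger("wvcnn")


class PipelineStageError(RuntimeError):
    """Wraps a failure with the name of the stage that raised it."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Resolved settings for one pipeline run."""

    input_path: str | None = None
    layout: str = "samples_as_rows"
    label_column: str = "type"
    resampling: ResamplingConfig = field(default_factory=ResamplingConfig)
    k_features: int = 300
    selection_mode: str = "mass"
    fit_on: str = "after_split"  # or "before_split"
    training: TrainingConfig = field(default_factory=TrainingConfig)
    weights: EnsembleWeights = field(default_factory=EnsembleWeights)
    test_fraction: float = 0.15
    kfold_k: int = 5
    averaging: str = "macro"
    leakage_mode: str = "strict"  # or "pooled"
    seed: int = 0
    output_dir: str = "wvcnn_run"

    def __post_init__(self) -> None:
        if self.fit_on not in ("after_split", "before_split"):
            raise ConfigurationError(f"unknown fit_on {self.fit_on!r}")
        if self.leakage_mode not in ("strict", "pooled"):
            raise ConfigurationError(f"unknown leakage_mode {self.leakage_mode!r}")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs: dict = {}
        if "resampling" in raw:
            kwargs["resampling"] = ResamplingConfig(**raw.pop("resampling"))
        if "training" in raw:
            kwargs["training"] = TrainingConfig(**raw.pop("training"))
        if "weights" in raw:
            kwargs["weights"] = EnsembleWeights(tuple(raw.pop("weights")))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)

    def resolved(self) -> dict:
        out = dataclasses.asdict(self)
        out["weights"] = list(self.weights.weights)
        return out


def _reseeded(cfg: PipelineConfig, seed: int) -> PipelineConfig:
    """Derive per-stage seeds from one run seed (kept below 2**31)."""
    return dataclasses.replace(
        cfg,
        resampling=dataclasses.replace(cfg.resampling, seed=(seed * 3 + 1) % (2**31)),
        training=dataclasses.replace(cfg.training, seed=(seed * 3 + 2) % (2**31)),
        seed=seed,
    )


def fit_and_evaluate(
    train: DatasetBundle,
    test: DatasetBundle,
    cfg: PipelineConfig,
    seed: int | None = None,
    preprocessed: bool = False,
) -> tuple[MetricsReport, dict]:
    """Fit the rebalance/select/train stages on ``train``, score ``test``.

    With ``preprocessed=True`` the inputs are taken as already rebalanced
    and feature-selected, and only training and scoring run.
    """
    cfg = _reseeded(cfg, cfg.seed if seed is None else seed)
    info: dict = {"seed": cfg.seed}
    if not preprocessed:
        res = smote_tomek(train, cfg.resampling)
        train = res.as_bundle()
        info["post_resampling_samples"] = train.n_samples
        info["tomek_removed"] = len(res.removed_original_indices)
        scores = chi2_scores(train, mode=cfg.selection_mode)
        keep = np.sort(select_top_k(scores, cfg.k_features))
        info["selected_features"] = [train.expression.feature_ids[i] for i in keep]
        info["selected_indices"] = keep
        train = train.subset_features(keep)
        test = test.subset_features(keep)
    model = train_ensemble(train, cfg.training, cfg.weights)
    predicted = model.predict(test.expression.values)
    report = metrics(confusion(test.labels, predicted), cfg.averaging)
    info["model"] = model
    return report, info


def run_pipeline(
    config: PipelineConfig, bundle: DatasetBundle | None = None
) -> dict:
    """Execute the full pipeline and write artifacts to ``config.output_dir``.

    Returns a summary dict (also written as ``run_summary.json``) holding
    the resolved config, per-stage sample/feature counts and the metrics.
    """
    cfg = config
    os.makedirs(cfg.output_dir, exist_ok=True)
    log_path = os.path.join(cfg.output_dir, "run.log")
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    stage_counts: dict = {}
    try:
        stage = "load"
        if bundle is None:
            if cfg.input_path is None:
                raise ConfigurationError("no input path and no in-memory bundle")
            bundle = read_dataset(cfg.input_path, cfg.layout, cfg.label_column)
        logger.info(
            "loaded %d samples x %d features, %d classes",
            bundle.n_samples, bundle.n_features, bundle.n_classes,
        )
        stage_counts["original_samples"] = bundle.n_samples
        stage_counts["original_features"] = bundle.n_features
        if cfg.k_features > bundle.n_features:
            raise ConfigurationError(
                f"k_features={cfg.k_features} exceeds {bundle.n_features} features"
            )

        if cfg.leakage_mode == "pooled":
            stage = "resample"
            rcfg = _reseeded(cfg, cfg.seed).resampling
            res = smote_tomek(bundle, rcfg)
            whole = res.as_bundle()
            stage_counts["post_resampling_samples"] = whole.n_samples
            stage_counts["tomek_removed"] = len(res.removed_original_indices)
            stage = "select"
            scores = chi2_scores(whole, mode=cfg.selection_mode)
            keep = np.sort(select_top_k(scores, cfg.k_features))
            selected_ids = [whole.expression.feature_ids[i] for i in keep]
            whole = whole.subset_features(keep)
            stage_counts["selected_features"] = whole.n_features
            stage = "split"
            train_idx, test_idx = stratified_split(
                whole.labels, cfg.test_fraction, cfg.seed
            )
            train, test = whole.subset_samples(train_idx), whole.subset_samples(test_idx)
            stage = "train"
            report, info = fit_and_evaluate(train, test, cfg, preprocessed=True)
        else:
            stage = "split"
            train_idx, test_idx = stratified_split(
                bundle.labels, cfg.test_fraction, cfg.seed
            )
            train = bundle.subset_samples(train_idx)
            test = bundle.subset_samples(test_idx)
            stage = "train"
            report, info = fit_and_evaluate(train, test, cfg)
            stage_counts["post_resampling_samples"] = info["post_resampling_samples"]
            stage_counts["tomek_removed"] = info["tomek_removed"]
            stage_counts["selected_features"] = len(info["selected_features"])
            selected_ids = info["selected_features"]
        stage_counts["train_samples"] = train.n_samples
        stage_counts["test_samples"] = test.n_samples

        stage = "write"
        _write_artifacts(cfg, report, selected_ids, info, stage_counts)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        logger.error("stage %s failed: %s", stage, exc)
        raise PipelineStageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    summary = {
        "config": cfg.resolved(),
        "stage_counts": stage_counts,
        "metrics": report.to_dict(),
    }
    with open(os.path.join(cfg.output_dir, "run_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary


def _write_artifacts(cfg, report, selected_ids, info, stage_counts) -> None:
    out = cfg.output_dir
    with open(os.path.join(out, "metrics.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    cm = report.confusion
    with open(os.path.join(out, "confusion.csv"), "w") as fh:
        fh.write("," + ",".join(cm.class_names) + "\n")
        for name, row in zip(cm.class_names, cm.counts):
            fh.write(name + "," + ",".join(str(v) for v in row) + "\n")
    with open(os.path.join(out, "selected_features.tsv"), "w") as fh:
        for fid in selected_ids:
            fh.write(f"{fid}\n")
    save_model(info["model"], os.path.join(out, "model"))
    logger.info("stage counts: %s", stage_counts)
    logger.info("resolved config: %s", cfg.resolved())
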