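"""Weighted soft-voting ensemble of three small 1-D CNN members.

The ensemble (WV-CNN) fuses three convolutional members, ECN-1/2/3, each
fed the selected features as a length-k single-channel sequence:

* ECN-1: conv1d(4 filters, kernel 3, ReLU) -> flatten -> dense(6, ReLU)
  -> dense(n_classes, softmax)
* ECN-2: conv1d(3, 3, ReLU) -> flatten -> dense(8, ReLU) -> dropout(0.3)
  -> dense(n_classes, softmax)
* ECN-3: conv1d(5, 3, ReLU) -> flatten -> dense(n_classes, softmax)

Each member trains independently with Adam (learning rate 0.001, beta1 0.9,
beta2 0.999, epsilon 1e-7, no decay, no AMSGrad) and categorical
cross-entropy.  Member probabilities p_i are fused by a fixed-weight soft
vote, P_ens = sum_i W_i p_i with W = (0.4, 0.3, 0.3), and the predicted
class is argmax(P_ens).  A hard (weighted majority) vote is available as an
option; the soft vote is the default because the fusion is defined on
probability distributions.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .datatypes import ConfigurationError, DatasetBundle, LabelVector, ValidationError
from . import nn

DEFAULT_WEIGHTS = (0.4, 0.3, 0.3)
MEMBER_NAMES = ("ECN1", "ECN2", "ECN3")


@dataclass
class LayerSpec:
    """Declarative description of one member layer."""

    kind: str  # conv1d | flatten | dense | dropout
    filters: int | None = None
    neurons: int | str | None = None  # int or "len(classes)"
    kernel: int | None = None
    rate: float | None = None
    activation: str | None = None


@dataclass
class TrainingConfig:
    """Optimizer constants, training budget and input normalization.

    Adam constants follow the ensemble's parametric setting; epochs and
    batch size default to a small-data regime (100 epochs, batches of 16,
    no early stopping).  Normalization is fitted on training data only;
    per-feature min-max is the default because bounded inputs stabilize
    small convolutional models.
    """

    learning_rate: float = 0.001
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-7
    decay: float = 0.0
    amsgrad: bool = False
    epochs: int = 100
    batch_size: int = 16
    seed: int = 0
    normalization: str = "minmax_train"
    output_activation: str = "softmax"

    def __post_init__(self) -> None:
        for name in ("learning_rate", "beta1", "beta2", "epsilon"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.epochs < 1:
            raise ConfigurationError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if self.normalization not in ("minmax_train", "zscore_train", "none"):
            raise ConfigurationError(f"unknown normalization {self.normalization!r}")
        if self.output_activation not in ("softmax", "sigmoid"):
            raise ConfigurationError(
                f"unknown output_activation {self.output_activation!r}"
            )
        if self.amsgrad or self.decay:
            raise ConfigurationError("AMSGrad and decay are fixed off")


@dataclass
class EnsembleWeights:
    """Fixed soft-voting weights; nonnegative, summing to 1."""

    weights: tuple[float, float, float] = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if (w < 0).any():
            raise ValidationError("ensemble weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"ensemble weights sum to {w.sum()}, not 1")
        self.weights = tuple(float(x) for x in w)


def build_architecture(member: str, n_classes: int) -> list[LayerSpec]:
    """Layer plan of one ensemble member.

    ``member`` is one of ``"ECN1"``, ``"ECN2"``, ``"ECN3"``.
    """
    if n_classes < 2:
        raise ValidationError("need at least 2 classes")
    out = LayerSpec("dense", neurons="len(classes)", activation="softmax")
    if member == "ECN1":
        return [
            LayerSpec("conv1d", filters=4, kernel=3, activation="relu"),
            LayerSpec("flatten"),
            LayerSpec("dense", neurons=6, activation="relu"),
            out,
        ]
    if member == "ECN2":
        return [
            LayerSpec("conv1d", filters=3, kernel=3, activation="relu"),
            LayerSpec("flatten"),
            LayerSpec("dense", neurons=8, activation="relu"),
            LayerSpec("dropout", rate=0.3),
            out,
        ]
    if member == "ECN3":
        return [
            LayerSpec("conv1d", filters=5, kernel=3, activation="relu"),
            LayerSpec("flatten"),
            out,
        ]
    raise ValidationError(f"unknown ensemble member {member!r}")


def _instantiate(
    specs: list[LayerSpec],
    input_len: int,
    n_classes: int,
    output_activation: str,
    rng: np.random.Generator,
) -> nn.SequentialNet:
    layers: list[nn.Layer] = []
    width = input_len  # flattened width tracker
    channels = 1
    for spec in specs:
        if spec.kind == "conv1d":
            layers.append(nn.Conv1D(spec.filters, spec.kernel, rng))
            width = width - spec.kernel + 1
            channels = spec.filters
        elif spec.kind == "flatten":
            layers.append(nn.Flatten())
            width = width * channels
            channels = 1
        elif spec.kind == "dense":
            units = n_classes if spec.neurons == "len(classes)" else int(spec.neurons)
            act = spec.activation
            if spec.neurons == "len(classes)":
                act = output_activation
            layers.append(nn.Dense(width, units, act, rng))
            width = units
        elif spec.kind == "dropout":
            layers.append(nn.Dropout(spec.rate))
        else:
            raise ValidationError(f"unknown layer kind {spec.kind!r}")
    return nn.SequentialNet(layers, rng)


@dataclass
class Normalizer:
    """Per-feature affine transform fitted on training data only."""

    kind: str
    offset: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray, kind: str) -> "Normalizer":
        if kind == "minmax_train":
            lo, hi = X.min(axis=0), X.max(axis=0)
            scale = hi - lo
            scale[scale == 0] = 1.0
            return cls(kind, lo, scale)
        if kind == "zscore_train":
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
            return cls(kind, X.mean(axis=0), sd)
        return cls("none", np.zeros(X.shape[1]), np.ones(X.shape[1]))

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.offset) / self.scale


@dataclass
class EnsembleModel:
    """Three trained members plus voting weights and fitted preprocessing."""

    members: list[nn.SequentialNet]
    weights: EnsembleWeights
    normalizer: Normalizer
    class_names: list[str]
    feature_ids: list[str]
    architectures: dict[str, list[LayerSpec]] = field(default_factory=dict)

    def member_probabilities(self, X: np.ndarray) -> list[np.ndarray]:
        Xn = self.normalizer.transform(np.asarray(X, dtype=np.float64))
        return [m.predict_proba(Xn) for m in self.members]

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return weighted_vote(self.member_probabilities(X), self.weights)

    def predict(self, X: np.ndarray, voting: str = "soft") -> LabelVector:
        if voting == "soft":
            return predict_classes(self.predict_proba(X), self.class_names)
        if voting != "hard":
            raise ConfigurationError(f"unknown voting mode {voting!r}")
        probs = self.member_probabilities(X)
        tally = np.zeros_like(probs[0])
        for w, p in zip(self.weights.weights, probs):
            hot = np.zeros_like(p)
            hot[np.arange(len(p)), p.argmax(axis=1)] = 1.0
            tally += w * hot
        return LabelVector(tally.argmax(axis=1), self.class_names)


def weighted_vote(
    member_probs: list[np.ndarray], weights: EnsembleWeights
) -> np.ndarray:
    """Convex combination of member probability matrices.

    Rows of the result remain probability distributions whenever the inputs'
    rows do and the weights sum to 1.
    """
    if len(member_probs) != len(weights.weights):
        raise ValidationError(
            f"{len(member_probs)} probability matrices for "
            f"{len(weights.weights)} weights"
        )
    mats = [np.asarray(p, dtype=np.float64) for p in member_probs]
    shapes = {m.shape for m in mats}
    if len(shapes) != 1:
        raise ValidationError(f"member probability shapes differ: {shapes}")
    out = np.zeros_like(mats[0])
    for w, p in zip(weights.weights, mats):
        out += w * p
    return out


def predict_classes(
    ens_probs: np.ndarray, class_names: list[str] | None = None
) -> LabelVector:
    """Per-row argmax; exact ties resolve to the lowest class index."""
    ens_probs = np.asarray(ens_probs, dtype=np.float64)
    idx = ens_probs.argmax(axis=1)
    if class_names is None:
        class_names = [str(i) for i in range(ens_probs.shape[1])]
    return LabelVector(idx, class_names)


def train_ensemble(
    train: DatasetBundle,
    config: TrainingConfig | None = None,
    weights: EnsembleWeights | None = None,
) -> EnsembleModel:
    """Fit normalization and the three members on the training bundle.

    Members train in fixed order with decorrelated seeds (seed, seed+1,
    seed+2), so the whole fit is reproducible from ``config.seed``.
    """
    config = config or TrainingConfig()
    weights = weights or EnsembleWeights()
    if train.n_features < 3:
        raise ValidationError("feature length must be >= kernel size (3)")
    if len(np.unique(train.labels.labels)) < 2:
        raise ValidationError("training set contains a single class")

    X = train.expression.values
    y = train.labels.labels
    n_classes = train.n_classes
    normalizer = Normalizer.fit(X, config.normalization)
    Xn = normalizer.transform(X)
    targets = np.zeros((len(y), n_classes))
    targets[np.arange(len(y)), y] = 1.0

    members = []
    architectures = {}
    for offset, name in enumerate(MEMBER_NAMES):
        specs = build_architecture(name, n_classes)
        rng = np.random.default_rng(config.seed + offset)
        net = _instantiate(
            specs, train.n_features, n_classes, config.output_activation, rng
        )
        optimizer = nn.Adam(
            net.params,
            learning_rate=config.learning_rate,
            beta1=config.beta1,
            beta2=config.beta2,
            epsilon=config.epsilon,
        )
        net.fit(Xn, targets, config.epochs, config.batch_size, optimizer)
        members.append(net)
        architectures[name] = specs

    return EnsembleModel(
        members,
        weights,
        normalizer,
        train.labels.class_names,
        train.expression.feature_ids,
        architectures,
    )


def save_model(model: EnsembleModel, directory: str) -> None:
    """Persist the ensemble: a JSON manifest plus per-member weight arrays."""
    os.makedirs(directory, exist_ok=True)
    manifest = {
        "class_names": model.class_names,
        "feature_ids": model.feature_ids,
        "weights": list(model.weights.weights),
        "normalizer": {
            "kind": model.normalizer.kind,
            "offset": model.normalizer.offset.tolist(),
            "scale": model.normalizer.scale.tolist(),
        },
        "architectures": {
            name: [vars(s) for s in specs]
            for name, specs in model.architectures.items()
        },
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)
    for name, net in zip(MEMBER_NAMES, model.members):
        arrays = {f"p{i}": p for i, p in enumerate(net.params)}
        np.savez(os.path.join(directory, f"{name}.npz"), **arrays)


def load_model(directory: str) -> EnsembleModel:
    with open(os.path.join(directory, "manifest.json")) as fh:
        manifest = json.load(fh)
    norm = Normalizer(
        manifest["normalizer"]["kind"],
        np.asarray(manifest["normalizer"]["offset"]),
        np.asarray(manifest["normalizer"]["scale"]),
    )
    n_classes = len(manifest["class_names"])
    n_features = len(manifest["feature_ids"])
    members = []
    architectures = {}
    for name in MEMBER_NAMES:
        specs = [LayerSpec(**d) for d in manifest["architectures"][name]]
        architectures[name] = specs
        out_act = specs[-1].activation or "softmax"
        net = _instantiate(
            specs, n_features, n_classes, out_act, np.random.default_rng(0)
        )
        with np.load(os.path.join(directory, f"{name}.npz")) as data:
            for i, p in enumerate(net.params):
                p[...] = data[f"p{i}"]
        members.append(net)
    return EnsembleModel(
        members,
        EnsembleWeights(tuple(manifest["weights"])),
        norm,
        manifest["class_names"],
        manifest["feature_ids"],
        architectures,
    )
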