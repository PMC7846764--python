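"""CNN tissue classifier: architecture, training loop, and evaluation metrics.

The network is four back-to-back convolutional blocks (3x3 conv preserving
spatial size, batch norm, ReLU) with 2x2 floor-mode max pooling after the
second and fourth blocks, a flattened embedding, one hidden dense layer and
a softmax over classes.  On a 138-sided input with 256 final channels the
flattened embedding is 34 * 34 * 256 = 295,936 elements.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    Flatten,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
    cross_entropy_grad,
    softmax,
)
from .preprocess import LabeledDataset

logger = logging.getLogger(__name__)

__all__ = [
    "CNNSpec",
    "TrainConfig",
    "ClassMetrics",
    "embedding_size",
    "build_model",
    "train",
    "predict",
    "predict_proba",
    "f1",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class CNNSpec:
    """Architecture description; defaults follow the full-scale model."""

    side: int = 138
    n_classes: int = 47
    conv_channels: tuple[int, int, int, int] = (32, 64, 128, 256)
    kernel: int = 3
    fc_hidden: int = 512

    def __post_init__(self) -> None:
        if self.side < 4:
            raise ValueError("side must be >= 4 (two pooling stages)")
        if len(self.conv_channels) != 4:
            raise ValueError("exactly four convolutional blocks are required")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")

    def to_json(self) -> str:
        return json.dumps(
            {
                "side": self.side,
                "n_classes": self.n_classes,
                "conv_channels": list(self.conv_channels),
                "kernel": self.kernel,
                "fc_hidden": self.fc_hidden,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "CNNSpec":
        d = json.loads(text)
        d["conv_channels"] = tuple(d["conv_channels"])
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """``input_dropout`` masks that fraction of input pixels per training
    example (replaced by the per-pixel training mean, i.e. the feature is
    made uninformative), an augmentation that forces the network to spread
    its reliance across redundant marker genes instead of memorizing a
    minimal subset."""

    epochs: int = 30
    batch_size: int = 64
    lr: float = 1e-3
    val_fraction: float = 0.1
    patience: int = 5
    input_dropout: float = 0.25
    seed: int = 0


@dataclass
class ClassMetrics:
    """Per-class precision/recall/F1, macro average, and a confusion matrix
    whose rows are true classes and columns predicted classes."""

    class_names: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    macro_f1: float
    confusion: np.ndarray
    undefined_classes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "macro_f1": self.macro_f1,
            "per_class": {
                name: {
                    "precision": float(p),
                    "recall": float(r),
                    "f1": float(f),
                }
                for name, p, r, f in zip(
                    self.class_names, self.precision, self.recall, self.f1
                )
            },
            "undefined_classes": self.undefined_classes,
        }


def embedding_size(side: int, channels: int) -> int:
    """Flattened feature length after the two 2x pooling stages (floor mode)."""
    if side < 4:
        raise ValueError("side must be >= 4")
    spatial = (side // 2) // 2
    if spatial == 0:
        raise ValueError(f"side={side} collapses to zero spatial extent")
    return spatial * spatial * channels


def build_model(spec: CNNSpec, seed: int = 0) -> Sequential:
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    c1, c2, c3, c4 = spec.conv_channels
    layers = [
        Conv2d(1, c1, rng, spec.kernel), BatchNorm2d(c1), ReLU(),
        Conv2d(c1, c2, rng, spec.kernel), BatchNorm2d(c2), ReLU(),
        MaxPool2d(),
        Conv2d(c2, c3, rng, spec.kernel), BatchNorm2d(c3), ReLU(),
        Conv2d(c3, c4, rng, spec.kernel), BatchNorm2d(c4), ReLU(),
        MaxPool2d(),
        Flatten(),
        Linear(embedding_size(spec.side, c4), spec.fc_hidden, rng), ReLU(),
        Linear(spec.fc_hidden, spec.n_classes, rng),
    ]
    return Sequential(layers)


def _as_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _encode_labels(labels: np.ndarray, class_names: list[str]) -> np.ndarray:
    lut = {name: i for i, name in enumerate(class_names)}
    return np.array([lut[l] for l in labels], dtype=np.int64)


def predict_proba(model: Sequential, images: np.ndarray, batch_size: int = 256) -> np.ndarray:
    x = images[:, None, :, :] if images.ndim == 3 else images
    out = []
    for start in range(0, len(x), batch_size):
        out.append(softmax(model.forward(x[start : start + batch_size], train=False)))
    return np.vstack(out)


def predict(model: Sequential, images: np.ndarray, class_names: list[str]) -> np.ndarray:
    idx = predict_proba(model, images).argmax(axis=1)
    return np.array([class_names[i] for i in idx], dtype=object)


def train(
    model: Sequential,
    images: np.ndarray,
    labels: np.ndarray,
    class_names: list[str],
    config: TrainConfig | None = None,
) -> dict:
    """Train with Adam + cross entropy; early stop on validation macro-F1.

    A stratified ``val_fraction`` of the provided (training) samples is held
    back for the early-stopping signal.  Returns a history dict with
    per-epoch ``loss`` and ``val_macro_f1``.  Deterministic given the seed
    (up to BLAS threading, which is stable in practice on a fixed machine).
    """
    config = config or TrainConfig()
    rng = np.random.default_rng(config.seed)
    x = images[:, None, :, :].astype(np.float32) if images.ndim == 3 else images
    y = _encode_labels(labels, class_names)

    # Stratified validation carve-out.
    val_mask = np.zeros(len(y), dtype=bool)
    for c in range(len(class_names)):
        idx = np.flatnonzero(y == c)
        n_val = max(1, int(round(config.val_fraction * len(idx))))
        val_mask[rng.choice(idx, size=min(n_val, len(idx) - 1), replace=False)] = True
    x_tr, y_tr = x[~val_mask], y[~val_mask]
    x_val, y_val = x[val_mask], y[val_mask]

    opt = Adam(model, lr=config.lr)
    pixel_mean = x_tr.mean(axis=0, keepdims=True).astype(np.float32)
    history: dict = {"loss": [], "val_macro_f1": []}
    best_f1, best_state, stale = -1.0, None, 0
    for epoch in range(config.epochs):
        losses = []
        for batch in _as_batches(len(y_tr), config.batch_size, rng):
            xb = x_tr[batch]
            if config.input_dropout > 0:
                mask = rng.random(xb.shape) < config.input_dropout
                xb = np.where(mask, pixel_mean, xb)
            logits = model.forward(xb, train=True)
            loss, dlogits = cross_entropy_grad(logits, y_tr[batch])
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}; reduce the "
                    "learning rate or check the input scaling"
                )
            model.zero_grad()
            model.backward(dlogits)
            if config.lr > 0:
                opt.step()
            losses.append(loss)
        if config.input_dropout > 0:
            _recalibrate_batchnorm(model, x_tr, config.batch_size)
        proba = predict_proba(model, x_val)
        pred = np.array([class_names[i] for i in proba.argmax(axis=1)], dtype=object)
        truth = np.array([class_names[i] for i in y_val], dtype=object)
        val_f1 = evaluate_predictions(truth, pred, class_names).macro_f1
        history["loss"].append(float(np.mean(losses)))
        history["val_macro_f1"].append(float(val_f1))
        logger.info("epoch %d loss=%.4f val_macro_f1=%.4f", epoch, history["loss"][-1], val_f1)
        if val_f1 > best_f1:
            best_f1, stale = val_f1, 0
            best_state = [
                {k: v.copy() for k, v in layer.state().items()} for layer in model.layers
            ]
        else:
            stale += 1
            if stale >= config.patience:
                break
    if best_state is not None:
        for layer, saved in zip(model.layers, best_state):
            for k, v in layer.state().items():
                v[...] = saved[k]
    return history


def _recalibrate_batchnorm(model: Sequential, x: np.ndarray, batch_size: int) -> None:
    """Refresh batch-norm running statistics on clean (un-masked) inputs.

    Training with input masking shifts the activation statistics; without
    this pass, eval-mode normalization would mismatch clean inputs.
    Forward passes in train mode update only the running stats, never the
    weights.
    """
    from ._nn import BatchNorm2d

    bns = [l for l in model.layers if isinstance(l, BatchNorm2d)]
    saved_momentum = [bn.momentum for bn in bns]
    for bn in bns:
        bn.momentum = 0.2
    for start in range(0, len(x), batch_size):
        model.forward(x[start : start + batch_size], train=True)
    for bn, m in zip(bns, saved_momentum):
        bn.momentum = m


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0 <= precision <= 1 and 0 <= recall <= 1):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def evaluate_predictions(
    true_labels: np.ndarray, pred_labels: np.ndarray, class_names: list[str]
) -> ClassMetrics:
    """Metrics from label vectors (rows of the confusion matrix = true class)."""
    n = len(class_names)
    lut = {name: i for i, name in enumerate(class_names)}
    confusion = np.zeros((n, n), dtype=np.int64)
    for t, p in zip(true_labels, pred_labels):
        confusion[lut[t], lut[p]] += 1
    tp = np.diag(confusion).astype(float)
    pred_n = confusion.sum(axis=0).astype(float)
    true_n = confusion.sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(pred_n > 0, tp / pred_n, 0.0)
        recall = np.where(true_n > 0, tp / true_n, 0.0)
    f1s = np.array([f1(p, r) for p, r in zip(precision, recall)])
    undefined = [class_names[i] for i in range(n) if true_n[i] == 0]
    if undefined:
        logger.warning("classes absent from the evaluation set: %s", undefined)
    defined = true_n > 0
    macro = float(f1s[defined].mean()) if defined.any() else 0.0
    return ClassMetrics(
        class_names=list(class_names),
        precision=precision,
        recall=recall,
        f1=f1s,
        macro_f1=macro,
        confusion=confusion,
        undefined_classes=undefined,
    )


def evaluate(model: Sequential, dataset: LabeledDataset) -> ClassMetrics:
    """Evaluate on the dataset's test split only."""
    test = dataset.subset(dataset.split == "test")
    pred = predict(model, test.images, dataset.class_names)
    return evaluate_predictions(test.labels, pred, dataset.class_names)


def save_model(model: Sequential, spec: CNNSpec, directory: str | Path) -> None:
    """Architecture descriptor as JSON, weights alongside (npz)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "architecture.json").write_text(spec.to_json())
    model.save(directory / "weights.npz")


def load_model(directory: str | Path) -> tuple[Sequential, CNNSpec]:
    directory = Path(directory)
    spec = CNNSpec.from_json((directory / "architecture.json").read_text())
    model = build_model(spec)
    model.load(directory / "weights.npz")
    return model, spec
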