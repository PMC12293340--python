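"""CNN construction, balanced-minibatch sampling, pre-training and transfer.

The classifier is a compact two-block CNN (conv 3x3 -> pool, twice, then a
dense layer and a 2-way softmax) trained with SGD (momentum 0.9, learning
rate 0.001) on cross-entropy — the configuration used throughout is held
in :class:`TrainConfig`.

Pre-training runs on abundant cell-line-like crops, where the tumor class
is the minority (roughly 1:3.4 against healthy cells in the emulated
conditions); the balanced-minibatch sampler counters that imbalance by
building every batch half-and-half, resampling the minority class with
replacement within an epoch.  Transfer then fine-tunes *all* layers on a
handful of clinical-like crops — down to a single image — starting from
the pre-trained weights.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np

from . import nn
from .synthgen import LabeledCrop

__all__ = [
    "TrainConfig",
    "CnnModel",
    "TrainingDivergedError",
    "DEFAULT_ARCH",
    "build_model",
    "balanced_minibatches",
    "all_data_batches",
    "pretrain",
    "fine_tune",
    "predict",
    "accuracy",
    "examples_to_arrays",
    "grid_search",
]

EPOCH_GRID = (2, 6, 12, 25, 50, 100, 300)  # the epoch counts enumerated for model selection


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer / training-loop settings.

    Defaults are the fixed hyperparameters of the training recipe:
    learning rate 0.001, SGD with momentum 0.9, cross-entropy loss.
    ``epochs`` is typically drawn from :data:`EPOCH_GRID` but any
    non-negative count is accepted.  ``sampling_mode`` selects between
    balanced minibatches and plain full-data minibatches.  ``iteration``
    is the number of independent training repetitions used when selecting
    a pre-trained model.
    """

    learning_rate: float = 0.001
    momentum: float = 0.9
    epochs: int = 25
    sampling_mode: Literal["balanced_minibatch", "all_data"] = "balanced_minibatch"
    batch_size: int = 32
    iteration: int = 20
    input_mode: Literal["composite", "channels"] = "composite"
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.sampling_mode == "balanced_minibatch" and self.batch_size % 2:
            raise ValueError("batch_size must be even for balanced minibatches")
        if self.sampling_mode not in ("balanced_minibatch", "all_data"):
            raise ValueError(f"unknown sampling_mode {self.sampling_mode!r}")


DEFAULT_ARCH: tuple[dict, ...] = (
    {"type": "conv", "filters": 16, "kernel": 3},
    {"type": "relu"},
    {"type": "pool"},
    {"type": "conv", "filters": 32, "kernel": 3},
    {"type": "relu"},
    {"type": "pool"},
    {"type": "flatten"},
    {"type": "dense", "units": 64},
    {"type": "relu"},
    {"type": "dropout", "rate": 0.25},
    {"type": "dense", "units": 2},
)


class CnnModel:
    """A seeded, fully specified CNN with its training history.

    The architecture is data: a sequence of layer dicts, so alternate
    structures are a config edit away.  ``history`` accumulates one record
    per epoch across pre-training and fine-tuning phases.
    """

    def __init__(self, input_shape: tuple[int, int, int],
                 arch: Sequence[dict] = DEFAULT_ARCH, seed: int = 0):
        self.input_shape = tuple(input_shape)
        self.arch = [dict(layer) for layer in arch]
        self.seed = seed
        self.history: list[dict] = []
        ss = np.random.SeedSequence([seed])
        init_ss, drop_ss = ss.spawn(2)
        init_rng = np.random.default_rng(init_ss)
        self._dropout_rng = np.random.default_rng(drop_ss)
        self.layers = self._build(init_rng)

    def _build(self, rng: np.random.Generator) -> list:
        layers: list = []
        shape: tuple = self.input_shape  # (c, h, w) until flattened
        for spec in self.arch:
            kind = spec["type"]
            if kind == "conv":
                if len(shape) != 3:
                    raise ValueError("conv layer after flatten")
                c, h, w = shape
                k = spec.get("kernel", 3)
                if h < k or w < k:
                    raise ValueError(f"input {h}x{w} smaller than kernel {k}")
                layers.append(nn.Conv2D(c, spec["filters"], k, rng))
                shape = (spec["filters"], h - k + 1, w - k + 1)
            elif kind == "relu":
                layers.append(nn.ReLU())
            elif kind == "pool":
                c, h, w = shape
                layers.append(nn.MaxPool2())
                shape = (c, h // 2, w // 2)
            elif kind == "flatten":
                layers.append(nn.Flatten())
                shape = (int(np.prod(shape)),)
            elif kind == "dense":
                if len(shape) != 1:
                    raise ValueError("dense layer requires flattened input")
                layers.append(nn.Dense(shape[0], spec["units"], rng))
                shape = (spec["units"],)
            elif kind == "dropout":
                layers.append(nn.Dropout(spec.get("rate", 0.25), self._dropout_rng))
            else:
                raise ValueError(f"unknown layer type {kind!r}")
        if shape != (2,):
            raise ValueError(f"architecture must end in a 2-way output, got {shape}")
        return layers

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        out = x.astype(np.float32, copy=False)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def backward(self, grad: np.ndarray) -> None:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)

    def predict_proba(self, x: np.ndarray, batch_size: int = 512) -> np.ndarray:
        probs = []
        for i in range(0, len(x), batch_size):
            probs.append(nn.softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(probs) if probs else np.empty((0, 2))

    # -- bookkeeping -------------------------------------------------------
    def clone(self) -> "CnnModel":
        return copy.deepcopy(self)

    @property
    def n_params(self) -> int:
        return sum(p.size for layer in self.layers for p, _ in layer.params())

    def param_shapes(self) -> list[tuple[int, ...]]:
        return [p.shape for layer in self.layers for p, _ in layer.params()]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for layer in self.layers for p, _ in layer.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        flat = [p for layer in self.layers for p, _ in layer.params()]
        if len(flat) != len(weights):
            raise ValueError("weight count mismatch")
        for p, w in zip(flat, weights):
            if p.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p[:] = w


def build_model(input_shape: tuple[int, int, int] = (1, 32, 32),
                arch_spec: Sequence[dict] | None = None, seed: int = 0) -> CnnModel:
    """Initialize a model; identical seeds give identical parameters."""
    return CnnModel(input_shape, arch_spec if arch_spec is not None else DEFAULT_ARCH, seed)


# ---------------------------------------------------------------------------
# Samplers


def balanced_minibatches(labels: np.ndarray, batch_size: int,
                         rng: np.random.Generator) -> Iterator[np.ndarray]:
    """One epoch of class-balanced minibatch index arrays.

    Every batch holds exactly batch_size/2 examples of each class.  The
    majority class is swept once (reshuffled and resampled only to fill
    the final batch); the minority class is reshuffled and reused with
    replacement as it runs out.  Epoch length is
    ceil(2 * majority_count / batch_size) batches.
    """
    if batch_size % 2:
        raise ValueError("batch_size must be even")
    labels = np.asarray(labels)
    idx0, idx1 = np.flatnonzero(labels == 0), np.flatnonzero(labels == 1)
    if len(idx0) == 0:
        raise ValueError("class 0 (non-tumor) absent from the training pool")
    if len(idx1) == 0:
        raise ValueError("class 1 (tumor) absent from the training pool")
    half = batch_size // 2
    maj, mino = (idx0, idx1) if len(idx0) >= len(idx1) else (idx1, idx0)
    n_batches = math.ceil(len(maj) / half)

    def stream(pool: np.ndarray, need: int) -> np.ndarray:
        parts = []
        got = 0
        while got < need:
            parts.append(rng.permutation(pool))
            got += len(pool)
        return np.concatenate(parts)[:need]

    maj_order = stream(maj, n_batches * half)
    min_order = stream(mino, n_batches * half)
    for b in range(n_batches):
        batch = np.concatenate(
            [maj_order[b * half : (b + 1) * half], min_order[b * half : (b + 1) * half]]
        )
        yield rng.permutation(batch)


def all_data_batches(labels: np.ndarray, batch_size: int,
                     rng: np.random.Generator) -> Iterator[np.ndarray]:
    """One epoch of plain shuffled minibatches over the full pool."""
    order = rng.permutation(len(labels))
    for i in range(0, len(order), batch_size):
        yield order[i : i + batch_size]


# ---------------------------------------------------------------------------
# Example conversion


def examples_to_arrays(
    examples: Sequence[LabeledCrop] | tuple[np.ndarray, np.ndarray],
    input_mode: str = "composite",
) -> tuple[np.ndarray, np.ndarray]:
    """(X, y) arrays from labeled crops; X is NCHW float32 in [0, 1].

    ``composite`` feeds the single-channel brightness image (the default
    classifier input); ``channels`` feeds the raw tri-channel stack.
    """
    if isinstance(examples, tuple):
        x, y = examples
        return x.astype(np.float32, copy=False), np.asarray(y)
    if len(examples) == 0:
        return np.empty((0, 1, 1, 1), dtype=np.float32), np.empty(0, dtype=np.int64)
    if input_mode == "composite":
        from .segment import compose_brightness

        xs = [
            (lc.crop.composite if lc.crop.composite is not None
             else compose_brightness(lc.crop, lc.crop.weights))[None, ...]
            for lc in examples
        ]
    elif input_mode == "channels":
        xs = [lc.crop.channel_stack() for lc in examples]
    else:
        raise ValueError(f"unknown input_mode {input_mode!r}")
    x = np.stack(xs).astype(np.float32)
    y = np.array([lc.label for lc in examples], dtype=np.int64)
    return x, y


# ---------------------------------------------------------------------------
# Training


def _train(model: CnnModel, x: np.ndarray, y: np.ndarray,
           config: TrainConfig, phase: str) -> CnnModel:
    config.validate()
    if config.epochs == 0 or len(x) == 0:
        return model
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, len(model.history)]))
    opt = nn.SGDMomentum(model.layers, config.learning_rate, config.momentum)
    sampler = (
        balanced_minibatches
        if config.sampling_mode == "balanced_minibatch"
        else all_data_batches
    )
    batch_size = min(config.batch_size, 2 * ((len(x) + 1) // 2))
    for epoch in range(config.epochs):
        losses, n_correct, n_seen = [], 0, 0
        for idx in sampler(y, batch_size, rng):
            logits = model.forward(x[idx], train=True)
            loss, grad = nn.cross_entropy_grad(logits, y[idx])
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at {phase} epoch {epoch}"
                )
            model.backward(grad)
            opt.step()
            losses.append(loss)
            n_correct += int((logits.argmax(axis=1) == y[idx]).sum())
            n_seen += len(idx)
        model.history.append(
            dict(phase=phase, epoch=epoch, loss=float(np.mean(losses)),
                 accuracy=n_correct / max(1, n_seen))
        )
    return model


def _require_both_classes(y: np.ndarray) -> None:
    for cls, name in ((0, "non-tumor"), (1, "tumor")):
        if not np.any(y == cls):
            raise ValueError(f"class {name} absent from the training pool")


def pretrain(model: CnnModel,
             cellline_examples: Sequence[LabeledCrop] | tuple[np.ndarray, np.ndarray],
             config: TrainConfig) -> CnnModel:
    """Train a copy of ``model`` on the cell-line domain.

    Returns a new model; the input model is left untouched.  With
    ``epochs=0`` the copy's predictions equal the initialization's.
    """
    x, y = examples_to_arrays(cellline_examples, config.input_mode)
    _require_both_classes(y)
    return _train(model.clone(), x, y, config, phase="pretrain")


def fine_tune(pretrained: CnnModel,
              clinical_train: Sequence[LabeledCrop] | tuple[np.ndarray, np.ndarray],
              config: TrainConfig,
              freeze_feature_layers: bool = False) -> CnnModel:
    """Transfer: continue training from pre-trained weights on clinical crops.

    All layers are updated by default (``freeze_feature_layers`` zeroes
    convolutional updates when set).  The training set may be arbitrarily
    small — a single image is valid — and fine-tuning with zero examples
    returns an unchanged copy of the pre-trained model.  Because tiny
    transfer sets may hold a single class, the sampler falls back to
    ``all_data`` when balance is impossible.
    """
    x, y = examples_to_arrays(clinical_train, config.input_mode)
    model = pretrained.clone()
    if len(x) == 0 or config.epochs == 0:
        return model
    cfg = config
    if cfg.sampling_mode == "balanced_minibatch" and (not np.any(y == 0) or not np.any(y == 1)):
        cfg = replace(cfg, sampling_mode="all_data")
    if freeze_feature_layers:
        frozen = [l for l in model.layers if isinstance(l, nn.Conv2D)]
        saved = [(l, [p.copy() for p, _ in l.params()]) for l in frozen]
        out = _train(model, x, y, cfg, phase="finetune")
        for layer, params in saved:
            for (p, _), old in zip(layer.params(), params):
                p[:] = old
        return out
    return _train(model, x, y, cfg, phase="finetune")


def predict(model: CnnModel,
            examples: Sequence[LabeledCrop] | tuple[np.ndarray, np.ndarray] | np.ndarray,
            input_mode: str = "composite") -> tuple[np.ndarray, np.ndarray]:
    """(labels, probabilities) for a batch of examples.

    Decision is argmax over the 2-way softmax; an exact tie resolves to
    class 0 (non-tumor).
    """
    if isinstance(examples, np.ndarray):
        x = examples
    else:
        x, _ = examples_to_arrays(examples, input_mode)
    if len(x) == 0:
        raise ValueError("empty example list")
    probs = model.predict_proba(x)
    return probs.argmax(axis=1), probs


def accuracy(predicted: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of correct predictions, in [0, 1]."""
    predicted, truth = np.asarray(predicted), np.asarray(truth)
    if predicted.size == 0 or predicted.shape != truth.shape:
        raise ValueError("predictions and truth must be same-length and non-empty")
    return float((predicted == truth).mean())


def grid_search(train_examples, val_examples, base_config: TrainConfig,
                grid: dict[str, list], input_shape: tuple[int, int, int] = (1, 32, 32),
                arch_spec: Sequence[dict] | None = None) -> tuple[TrainConfig, list[dict]]:
    """Exhaustive search over user-supplied hyperparameter grids.

    ``grid`` maps TrainConfig field names to candidate lists; every
    combination is trained from a fresh seed-matched initialization and
    scored on the validation examples.  Returns the best config and the
    per-combination records.
    """
    import itertools

    keys = sorted(grid)
    records: list[dict] = []
    best_cfg, best_acc = base_config, -1.0
    xv, yv = examples_to_arrays(val_examples, base_config.input_mode)
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base_config, **dict(zip(keys, combo)))
        model = build_model(input_shape, arch_spec, seed=cfg.seed)
        trained = pretrain(model, train_examples, cfg)
        labels, _ = predict(trained, xv)
        acc = accuracy(labels, yv)
        records.append({**dict(zip(keys, combo)), "val_accuracy": acc})
        if acc > best_acc:
            best_cfg, best_acc = cfg, acc
    return best_cfg, records
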