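"""The eight phantom-scoring CNN architectures.

All eight networks share the same recipe applied at increasing depth:
an initial 5x5 convolution with 30 filters, then 3x3 convolutions whose
channel count steps 30 -> 45 -> 60 and +20 per block thereafter, each
block being convolution + batch normalization + ReLU with 3x3/stride-2
max pooling on the early blocks.  Dropout is 30% between blocks and 50%
before the single fully connected layer feeding the 17-way softmax.
Depth runs from three convolutional blocks (CNN1) to ten (CNN8); the
number of pooled blocks is fixed per architecture so the head sees
feature maps of 15x15, 7x7 or 3x3 at the canonical 128x128 input.

``count_parameters`` reproduces the published trainable-parameter totals
for CNN1 and CNN3-CNN8 exactly.  CNN2's published total is 160 below
this reconstruction (one 80-channel normalization's affine parameters);
the block list here follows the published layer table, so the
discrepancy surfaces as a documented 387,062 vs 386,902.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classes import CLASS_NAMES, NONV, position_to_class
from .errors import InvalidArchitectureError, InvalidArgumentError
from .nn import (BatchNorm2d, Conv2d, Dense, Dropout, Flatten, MaxPool3s2,
                 ReLU, Sequential, SGDMomentum, cross_entropy, softmax)

N_CLASSES = 17
CHANNEL_PROGRESSION = (30, 45, 60, 80, 100, 120, 140, 160, 180, 200)

#: architecture name -> (number of conv blocks, number of pooled blocks)
ARCHITECTURE_TABLE = {
    "CNN1": (3, 3),
    "CNN2": (4, 3),
    "CNN3": (5, 4),
    "CNN4": (6, 5),
    "CNN5": (7, 5),
    "CNN6": (8, 4),
    "CNN7": (9, 4),
    "CNN8": (10, 4),
}


@dataclass(frozen=True)
class ConvBlock:
    """One convolution + (norm) + activation + (pool) unit with trailing dropout."""

    out_channels: int
    kernel_size: int
    norm: bool = True
    pool: bool = True
    dropout_after: float | None = None


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one network column."""

    name: str
    blocks: tuple[ConvBlock, ...]
    n_classes: int = N_CLASSES
    input_size: int = 128


def spec_for(name: str, input_size: int = 128) -> ArchitectureSpec:
    """The named architecture (CNN1..CNN8) as a block list."""
    if name not in ARCHITECTURE_TABLE:
        raise InvalidArgumentError(f"unknown architecture {name!r}")
    n_blocks, n_pooled = ARCHITECTURE_TABLE[name]
    blocks = []
    for i in range(n_blocks):
        if i == 0:
            dropout = None  # no dropout between the first two blocks
        elif i == n_blocks - 1:
            dropout = 0.5  # before the fully connected layer
        else:
            dropout = 0.3
        blocks.append(ConvBlock(
            out_channels=CHANNEL_PROGRESSION[i],
            kernel_size=5 if i == 0 else 3,
            norm=True,
            pool=i < n_pooled,
            dropout_after=dropout,
        ))
    return ArchitectureSpec(name=name, blocks=tuple(blocks),
                            input_size=input_size)


def _pooled(size: int) -> int:
    return (size - 3) // 2 + 1


def feature_map_sizes(spec: ArchitectureSpec) -> list[int]:
    """Spatial size entering each block, plus the head's input size.

    Raises ``InvalidArchitectureError`` if pooling drives a dimension
    below the 3x3 window.
    """
    s = spec.input_size
    sizes = []
    for block in spec.blocks:
        sizes.append(s)
        if block.pool:
            if s < 3:
                raise InvalidArchitectureError(
                    f"feature map {s} too small to pool in {spec.name}")
            s = _pooled(s)
    sizes.append(s)
    return sizes


def count_parameters(spec: ArchitectureSpec, in_channels: int = 1) -> int:
    """Trainable parameters: conv weights + biases, two affine parameters
    per normalized channel, and the fully connected head."""
    total = 0
    ch = in_channels
    for block in spec.blocks:
        k = block.kernel_size
        total += k * k * ch * block.out_channels + block.out_channels
        if block.norm:
            total += 2 * block.out_channels
        ch = block.out_channels
    head = feature_map_sizes(spec)[-1]
    total += head * head * ch * spec.n_classes + spec.n_classes
    return total


def build(spec: ArchitectureSpec, seed: int = 0) -> Sequential:
    """Instantiate a trainable network for single-channel square input."""
    sizes = feature_map_sizes(spec)  # validates the pooling schedule
    if sizes[-1] < 1:
        raise InvalidArchitectureError("head input collapsed below 1 pixel")
    rng = np.random.default_rng(seed)
    drop_rng = np.random.default_rng(seed + 1)
    layers = []
    ch = 1
    for block in spec.blocks:
        layers.append(Conv2d(ch, block.out_channels, block.kernel_size, rng))
        if block.norm:
            layers.append(BatchNorm2d(block.out_channels))
        layers.append(ReLU())
        if block.pool:
            layers.append(MaxPool3s2())
        if block.dropout_after:
            layers.append(Dropout(block.dropout_after, drop_rng))
        ch = block.out_channels
    layers.append(Flatten())
    layers.append(Dense(sizes[-1] * sizes[-1] * ch, spec.n_classes, rng))
    return Sequential(layers, seed=seed)


@dataclass
class TrainConfig:
    """Optimization settings; defaults follow the published training run."""

    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 2736
    epochs: int = 300  # 400 for CNN1 in the published run
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.momentum, self.batch_size,
               self.epochs) < 0 or self.batch_size < 1 or self.epochs < 1:
            raise InvalidArgumentError("training settings must be positive")


def default_epochs(name: str) -> int:
    return 400 if name == "CNN1" else 300


@dataclass
class Prediction:
    """One softmax output: the 17 class probabilities and the top class."""

    class_distribution: np.ndarray
    top_class: str


def _accuracy(model: Sequential, x: np.ndarray, y: np.ndarray,
              batch: int = 256) -> float:
    correct = 0
    for i in range(0, len(x), batch):
        probs = model.predict_proba(x[i:i + batch])
        correct += int((probs.argmax(axis=1) == y[i:i + batch]).sum())
    return correct / len(x)


def train(model: Sequential, train_data: tuple[np.ndarray, np.ndarray],
          val_data: tuple[np.ndarray, np.ndarray],
          config: TrainConfig) -> tuple[Sequential, list[dict]]:
    """SGD-with-momentum training; the checkpoint with the highest
    validation accuracy (evaluated every epoch) is restored at the end.

    Returns the model and a per-epoch history of mean training loss and
    validation accuracy.  Iterations per epoch = floor(|train| / batch).
    """
    x_train, y_train = train_data
    x_val, y_val = val_data
    if config.batch_size > len(x_train):
        raise InvalidArgumentError("batch size exceeds the training set")
    iters = len(x_train) // config.batch_size
    rng = np.random.default_rng(config.seed)
    opt = SGDMomentum(model.parameters(), config.learning_rate, config.momentum)
    best_state, best_acc = model.state(), -1.0
    history = []
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(x_train))
        losses = []
        for it in range(iters):
            idx = order[it * config.batch_size:(it + 1) * config.batch_size]
            logits = model.forward(x_train[idx], train=True)
            loss, dlogits = cross_entropy(logits, y_train[idx])
            model.backward(dlogits)
            opt.step(model.gradients())
            losses.append(loss)
        val_acc = _accuracy(model, x_val, y_val)
        history.append({"epoch": epoch,
                        "train_loss": float(np.mean(losses)) if losses else math.nan,
                        "val_accuracy": val_acc})
        if val_acc > best_acc:
            best_acc = val_acc
            best_state = model.state()
    model.load_state(best_state)
    return model, history


def predict(model: Sequential, sub, mode: str = "strict",
            ) -> tuple[int, Prediction]:
    """Classify one sub-image and reduce to a binary visibility call.

    ``strict``: visible only when the top class is the sub-image's own
    position class (the network both detects and recognizes the target).
    ``lenient``: visible whenever the top class is any target class.
    """
    if mode not in ("strict", "lenient"):
        raise InvalidArgumentError("mode must be 'strict' or 'lenient'")
    x = np.asarray(sub.pixels, dtype=np.float64)[None, None]
    probs = model.predict_proba(x)[0]
    top = CLASS_NAMES[int(probs.argmax())]
    if mode == "strict":
        visible = int(top == position_to_class(sub.position))
    else:
        visible = int(top != NONV)
    return visible, Prediction(class_distribution=probs, top_class=top)
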