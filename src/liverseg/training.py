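"""Network training: SGD with momentum, step learning-rate schedule,
class-weighted cross-entropy and on-the-fly augmentation.

The optimizer follows the reference protocol for this pipeline: stochastic
gradient descent with momentum 0.9, initial learning rate 0.001, dropped by a
factor of 0.1 every five epochs, for 20 epochs in total.  One epoch is one
pass over the filtered (undersampled) training slice list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .metrics import dice
from .network import SegmentationNetwork
from .sampling import AugmentParams, ClassWeights, SliceStack, augment, build_stack

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    initial_lr: float = 0.001
    momentum: float = 0.9
    lr_drop_factor: float = 0.1
    lr_drop_every: int = 5  # epochs
    epochs: int = 20
    batch_size: int = 4
    rng_seed: int = 0
    class_weights: ClassWeights | None = None  # None -> computed from the training labels
    augment: AugmentParams = field(default_factory=AugmentParams)
    use_augmentation: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.lr_drop_factor < 1:
            raise ValueError(f"lr_drop_factor must be in (0, 1), got {self.lr_drop_factor}")
        if self.epochs < 1:
            raise ValueError(f"epochs must be >= 1, got {self.epochs}")
        if not 0 <= self.momentum < 1:
            raise ValueError(f"momentum must be in [0, 1), got {self.momentum}")
        if self.lr_drop_every < 1:
            raise ValueError("lr_drop_every must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch record of loss, learning rate and validation Dice."""

    loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    val_dice_liver: list[float] = field(default_factory=list)
    val_dice_tumor: list[float] = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        return [
            {
                "epoch": i + 1,
                "loss": self.loss[i],
                "learning_rate": self.learning_rate[i],
                "val_dice_liver": self.val_dice_liver[i] if self.val_dice_liver else float("nan"),
                "val_dice_tumor": self.val_dice_tumor[i] if self.val_dice_tumor else float("nan"),
            }
            for i in range(len(self.loss))
        ]


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Step schedule: ``lr0 * factor ** floor((epoch - 1) / drop_every)`` (1-based)."""
    if epoch < 1:
        raise ValueError(f"epoch is 1-based, got {epoch}")
    return cfg.initial_lr * cfg.lr_drop_factor ** ((epoch - 1) // cfg.lr_drop_every)


def loss(scores, label: np.ndarray, w: ClassWeights) -> float:
    """Class-weighted pixelwise cross-entropy of a score map against a label map."""
    arr = scores.scores if hasattr(scores, "scores") else np.asarray(scores)
    label = np.asarray(label)
    if arr.shape[1:] != label.shape:
        raise ValueError(f"score map shape {arr.shape[1:]} does not match label {label.shape}")
    t = nn.weighted_cross_entropy(nn.Tensor(arr[None]), label[None], w.as_array(arr.shape[0]))
    return float(t.data)


@dataclass
class TrainingSample:
    """One 2.5D training unit: a normalized volume, a slice index and its label map."""

    volume: object  # NormalizedVolume
    labels: np.ndarray  # full 3D label array aligned with the volume
    slice_index: int


def _epoch_rng(seed: int, epoch: int) -> np.random.Generator:
    # independent substream per epoch
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(epoch,)))


def _validation_dice(network, val_samples, k: int) -> tuple[float, float]:
    """Mean per-slice Dice over validation samples, without post-processing."""
    liver, tumor = [], []
    for s in val_samples:
        stack = build_stack(s.volume, s.slice_index, k)
        pred = network.predict_batch(stack.planes[None])[0]
        truth = s.labels[:, :, s.slice_index]
        liver.append(dice(pred == 1, truth == 1))
        tumor.append(dice(pred == 2, truth == 2))
    return float(np.mean(liver)), float(np.mean(tumor))


def train(
    network: SegmentationNetwork,
    train_samples: list[TrainingSample],
    val_samples: list[TrainingSample],
    cfg: TrainConfig,
) -> tuple[SegmentationNetwork, TrainHistory]:
    """Train ``network`` in place; returns it with the per-epoch history.

    Fully reproducible given ``cfg.rng_seed``: sample order and augmentation
    draws come from per-epoch substreams of that seed.
    """
    if not train_samples:
        raise ValueError("empty training set")
    if cfg.class_weights is None:
        label_slices = [s.labels[:, :, s.slice_index] for s in train_samples]
        from .sampling import compute_class_weights

        weights = compute_class_weights(label_slices)
    else:
        weights = cfg.class_weights
    warr = weights.as_array(network.cfg.num_classes)
    k = network.cfg.in_planes
    opt = nn.SGD(network.layers(), momentum=cfg.momentum)
    history = TrainHistory()
    for epoch in range(1, cfg.epochs + 1):
        lr = lr_at_epoch(cfg, epoch)
        rng = _epoch_rng(cfg.rng_seed, epoch)
        order = rng.permutation(len(train_samples))
        epoch_losses = []
        for start in range(0, len(order), cfg.batch_size):
            batch_idx = order[start : start + cfg.batch_size]
            planes, targets = [], []
            for i in batch_idx:
                s = train_samples[int(i)]
                stack = build_stack(s.volume, s.slice_index, k)
                label = s.labels[:, :, s.slice_index]
                if cfg.use_augmentation:
                    stack, label = augment(stack, label, cfg.augment, rng)
                planes.append(stack.planes)
                targets.append(label)
            scores = network.forward_scores(np.stack(planes), training=True)
            batch_loss = nn.weighted_cross_entropy(scores, np.stack(targets), warr)
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch starting {start}"
                )
            batch_loss.backward()
            opt.step(lr)
            epoch_losses.append(float(batch_loss.data))
        history.loss.append(float(np.mean(epoch_losses)))
        history.learning_rate.append(lr)
        if val_samples:
            dl, dt = _validation_dice(network, val_samples, k)
            history.val_dice_liver.append(dl)
            history.val_dice_tumor.append(dt)
        logger.info(
            "epoch %d/%d lr=%g loss=%.4f", epoch, cfg.epochs, lr, history.loss[-1]
        )
    return network, history
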