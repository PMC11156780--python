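"""Dice-BCE loss and the optimization loop.

The loss combines a soft Dice overlap term with binary cross-entropy,

    L(x, y) = [1 - 2 sum(x*y) / (sum(x) + sum(y))]
              - (1/N) sum(y*log x + (1-y)*log(1-x)),

with x the sigmoid prediction, y the binary target and N the voxel count.
Training runs a fixed number of epochs with Adam (no early stopping); the
learning rate is halved every ``lr_halving_period`` epochs (reference values:
60 epochs, initial rate 7e-5, halved every 20).  Validation loss is computed
after every epoch with dropout disabled, and the parameters are written to the
checkpoint only when the validation loss reaches a new minimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .nn import Adam
from .unet3d import UNet3D, load_checkpoint, save_checkpoint

__all__ = ["TrainConfig", "dice_bce_loss", "dice_bce_loss_grad",
           "learning_rate_at", "train_model"]

_CLAMP = 1e-7


@dataclass
class TrainConfig:
    epochs: int = 60
    initial_lr: float = 7e-5
    lr_halving_period: int = 20
    batch_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1 or self.lr_halving_period < 1 or self.batch_size < 1:
            raise ValueError("epochs, lr_halving_period and batch_size must be >= 1")
        if not self.initial_lr > 0:
            raise ValueError("initial_lr must be positive")


def _as_pred_target(prediction, target) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(prediction, dtype=np.float64)
    y = np.asarray(getattr(target, "data", target), dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"prediction shape {x.shape} != target shape {y.shape}")
    return x, y


def dice_bce_loss(prediction, target, epsilon: float = _CLAMP) -> float:
    """Dice term plus mean binary cross-entropy; 0 for a perfect binary
    prediction, independent of the voxel count for constant fields."""
    x, y = _as_pred_target(prediction, target)
    s = x.sum() + y.sum()
    dice_term = 1.0 - (2.0 * (x * y).sum() / s if s > 0 else 1.0)
    xc = np.clip(x, epsilon, 1.0 - epsilon)
    bce = -(y * np.log(xc) + (1.0 - y) * np.log(1.0 - xc)).mean()
    return float(dice_term + bce)


def dice_bce_loss_grad(prediction, target,
                       epsilon: float = _CLAMP) -> tuple[float, np.ndarray]:
    """Loss and its gradient with respect to the prediction."""
    x, y = _as_pred_target(prediction, target)
    n = x.size
    s = x.sum() + y.sum()
    inter = (x * y).sum()
    if s > 0:
        dice_term = 1.0 - 2.0 * inter / s
        g_dice = -2.0 * y / s + 2.0 * inter / (s * s)
    else:
        dice_term, g_dice = 0.0, np.zeros_like(x)
    xc = np.clip(x, epsilon, 1.0 - epsilon)
    bce = -(y * np.log(xc) + (1.0 - y) * np.log(1.0 - xc)).mean()
    g_bce = -(y / xc - (1.0 - y) / (1.0 - xc)) / n
    return float(dice_term + bce), (g_dice + g_bce).astype(np.float32)


def learning_rate_at(cfg: TrainConfig, epoch: int) -> float:
    """lr(e) = initial_lr * 0.5 ** floor(e / halving_period)."""
    return cfg.initial_lr * 0.5 ** (epoch // cfg.lr_halving_period)


def _epoch_loss(model: UNet3D, pairs, train: bool = False) -> float:
    losses = [dice_bce_loss(model.forward(x, train=False)[0], y) for x, y in pairs]
    return float(np.mean(losses))


def train_model(model: UNet3D, train_pairs, val_pairs, cfg: TrainConfig,
                checkpoint_path) -> pd.DataFrame:
    """Fit ``model`` on (input-channels, target) pairs.

    ``train_pairs``/``val_pairs`` are sequences of ``(x, y)`` with ``x`` shaped
    (C, X, Y, Z) and ``y`` a binary target (X, Y, Z).  Returns the training log
    (epoch, train_loss, val_loss, lr, checkpoint_saved); the checkpoint on disk
    holds the parameters of the epoch with minimal validation loss, and those
    parameters are restored into ``model`` before returning.
    """
    train_pairs = list(train_pairs)
    val_pairs = list(val_pairs)
    if not train_pairs:
        raise ValueError("training set is empty")
    if not val_pairs:
        raise ValueError("validation set is empty")
    checkpoint_path = Path(checkpoint_path)
    rng = np.random.default_rng(cfg.seed)
    optimizer = Adam(model.layers(), lr=cfg.initial_lr)
    best_val = np.inf
    rows = []
    for epoch in range(cfg.epochs):
        optimizer.lr = learning_rate_at(cfg, epoch)
        order = rng.permutation(len(train_pairs))
        epoch_losses = []
        optimizer.zero_grad()
        pending = 0
        for idx in order:
            x, y = train_pairs[idx]
            pred = model.forward(np.asarray(x, dtype=np.float32), train=True)
            loss, g = dice_bce_loss_grad(pred[0], y)
            epoch_losses.append(loss)
            model.backward(g[None] / cfg.batch_size)
            pending += 1
            if pending == cfg.batch_size:
                optimizer.step()
                optimizer.zero_grad()
                pending = 0
        if pending:
            optimizer.step()
            optimizer.zero_grad()
        val_loss = _epoch_loss(model, val_pairs)
        saved = val_loss < best_val
        if saved:
            best_val = val_loss
            save_checkpoint(model, checkpoint_path,
                            extra={"epoch": epoch, "val_loss": val_loss})
        rows.append({"epoch": epoch, "train_loss": float(np.mean(epoch_losses)),
                     "val_loss": val_loss, "lr": optimizer.lr,
                     "checkpoint_saved": bool(saved)})
    best_model, _ = load_checkpoint(checkpoint_path)
    for layer, best_layer in zip(model.layers(), best_model.layers()):
        for name in layer.params:
            layer.params[name][...] = best_layer.params[name]
    return pd.DataFrame(rows)
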