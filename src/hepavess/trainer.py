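"""Training: soft Dice loss, plateau LR decay, early stopping.

The objective is the soft Dice loss evaluated on raw predicted probabilities
(no thresholding):

    loss = 1 - (2 sum(p * t) + s) / (sum(p) + sum(t) + s)

computed per sample, averaged over the batch (one foreground class). The
optimizer is Adam starting at lr 1e-4; the learning rate is multiplied by 0.2
when the validation loss has not improved for two consecutive epochs, and
training stops early after four successive non-improving epochs. "Improved"
means strictly below the best seen minus ``min_delta``. The parameters with
the best validation loss are returned. Given a seed, training is bit
reproducible.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import Adam
from .patches import PatchSet
from .resdense_unet import UNet

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "TrainingDiverged",
    "soft_dice_loss",
    "soft_dice_grad",
    "ReduceLROnPlateau",
    "EarlyStopping",
    "train",
]


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes NaN/Inf during optimization."""


@dataclasses.dataclass
class TrainConfig:
    lr_init: float = 1e-4
    batch_size: int = 32
    plateau_factor: float = 0.2
    plateau_patience: int = 2
    early_stop_patience: int = 4
    max_epochs: int = 100
    min_delta: float = 1e-5
    smooth: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.plateau_factor < 1):
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patiences must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclasses.dataclass
class TrainHistory:
    train_loss: list[float] = dataclasses.field(default_factory=list)
    val_loss: list[float] = dataclasses.field(default_factory=list)
    lr: list[float] = dataclasses.field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _batch_sums(pred: np.ndarray, target: np.ndarray):
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if pred.min() < -1e-6 or pred.max() > 1 + 1e-6:
        raise ValueError("predictions must lie in [0, 1]")
    if pred.ndim == 2:
        pred, target = pred[None], target[None]
    n = pred.shape[0]
    p = pred.reshape(n, -1)
    t = target.reshape(n, -1)
    inter = (p * t).sum(axis=1)
    return p, t, inter


def soft_dice_loss(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> float:
    """1 - soft Dice, per sample, averaged over the batch. In [0, 1]."""
    p, t, inter = _batch_sums(pred, target)
    dice = (2.0 * inter + smooth) / (p.sum(axis=1) + t.sum(axis=1) + smooth)
    return float(np.mean(1.0 - dice))


def soft_dice_grad(pred: np.ndarray, target: np.ndarray, smooth: float = 1.0) -> np.ndarray:
    """Gradient of :func:`soft_dice_loss` w.r.t. ``pred`` (same shape)."""
    shape = np.asarray(pred).shape
    p, t, inter = _batch_sums(pred, target)
    num = 2.0 * inter + smooth
    den = p.sum(axis=1) + t.sum(axis=1) + smooth
    # d(1 - num/den)/dp_i = -(2 t_i den - num) / den^2
    g = -(2.0 * t * den[:, None] - num[:, None]) / den[:, None] ** 2
    return (g / p.shape[0]).reshape(shape).astype(np.float32)


class ReduceLROnPlateau:
    """Multiply the LR by ``factor`` after ``patience`` consecutive epochs
    without validation improvement; the counter resets after a reduction."""

    def __init__(self, lr: float, factor: float = 0.2, patience: int = 2,
                 min_delta: float = 1e-5) -> None:
        self.lr = lr
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.count = 0

    def step(self, val_loss: float) -> bool:
        """Feed one epoch's validation loss; returns True if the LR dropped."""
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.count = 0
            return False
        self.count += 1
        if self.count >= self.patience:
            self.lr *= self.factor
            self.count = 0
            return True
        return False


class EarlyStopping:
    """Stop after ``patience`` successive epochs without improvement."""

    def __init__(self, patience: int = 4, min_delta: float = 1e-5) -> None:
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self.count = 0
        self.epoch = -1

    def step(self, val_loss: float) -> bool:
        """Feed one epoch's validation loss; returns True if training should stop."""
        self.epoch += 1
        if val_loss < self.best - self.min_delta:
            self.best = val_loss
            self.best_epoch = self.epoch
            self.count = 0
            return False
        self.count += 1
        return self.count >= self.patience


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(data, PatchSet):
        return data.arrays()
    x, y = data
    x = np.asarray(x, dtype=np.float32)
    y = np.asarray(y, dtype=np.float32)
    if x.ndim == 3:
        x, y = x[:, None], y[:, None]
    return x, y


def _epoch_loss(model: UNet, x: np.ndarray, y: np.ndarray, batch: int, smooth: float) -> float:
    losses, weights = [], []
    for i in range(0, len(x), batch):
        xb, yb = x[i : i + batch], y[i : i + batch]
        pred = model.forward(xb, train=False)
        losses.append(soft_dice_loss(pred, yb, smooth))
        weights.append(len(xb))
    return float(np.average(losses, weights=weights))


def train(model: UNet, train_data, val_data, cfg: TrainConfig | None = None):
    """Optimize ``model`` on the training patches; returns ``(model, history)``
    with the best-validation parameters restored in the model.

    ``train_data`` / ``val_data`` are :class:`PatchSet` s (sampled from
    disjoint volumes) or ``(images, masks)`` array pairs.
    """
    cfg = cfg or TrainConfig()
    x_tr, y_tr = _as_arrays(train_data)
    x_va, y_va = _as_arrays(val_data)
    if len(x_tr) == 0 or len(x_va) == 0:
        raise ValueError("training and validation sets must be nonempty")

    rng = np.random.default_rng(cfg.seed)
    params = model.parameters()
    opt = Adam(params, lr=cfg.lr_init)
    plateau = ReduceLROnPlateau(cfg.lr_init, cfg.plateau_factor,
                                cfg.plateau_patience, cfg.min_delta)
    stopper = EarlyStopping(cfg.early_stop_patience, cfg.min_delta)
    history = TrainHistory()
    best_state = model.state_dict()
    best_val = np.inf

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(len(x_tr))
        epoch_losses, weights = [], []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            pred = model.forward(xb, train=True)
            loss = soft_dice_loss(pred, yb, cfg.smooth)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite training loss at epoch {epoch}, step {i // cfg.batch_size}"
                )
            opt.zero_grad()
            model.backward(soft_dice_grad(pred, yb, cfg.smooth))
            opt.step()
            epoch_losses.append(loss)
            weights.append(len(idx))
        train_loss = float(np.average(epoch_losses, weights=weights))
        val_loss = _epoch_loss(model, x_va, y_va, cfg.batch_size, cfg.smooth)
        if not np.isfinite(val_loss):
            raise TrainingDiverged(f"non-finite validation loss at epoch {epoch}")

        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.lr.append(opt.lr)

        if val_loss < best_val - cfg.min_delta:
            best_val = val_loss
            best_state = model.state_dict()
            history.best_epoch = epoch

        if plateau.step(val_loss):
            opt.lr = plateau.lr
        if stopper.step(val_loss):
            history.stop_reason = (
                f"early stop: no improvement for {cfg.early_stop_patience} epochs"
            )
            break
    else:
        history.stop_reason = f"reached max_epochs={cfg.max_epochs}"

    model.load_state_dict(best_state)
    model.history = history.to_dict()
    return model, history
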