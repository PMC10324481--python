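"""Optimization loop: losses, learning-rate schedule, Adam/AdamW, training.

The objective is voxel-wise mean-squared error between the predicted and true
normalized density maps, optionally augmented by ``w * (1 - CC)`` where CC is
the Pearson correlation of the two maps — the combined loss keeps the weight
heavily in favor of the MSE term (default w = 0.1).

The learning rate follows a two-phase exponential decay: ``phase1_decay`` per
epoch for the first ``phase1_epochs`` epochs, ``phase2_decay`` per epoch
afterwards.  Gradient accumulation multiplies the effective batch size
without growing memory.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import PattersonUNet

__all__ = [
    "TrainConfig",
    "TrainLog",
    "mse_loss",
    "pearson_cc_flat",
    "combined_loss",
    "combined_loss_grad",
    "lr_at_epoch",
    "Adam",
    "train",
    "DATASET1_PROFILE",
    "DATASET2_PROFILE",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters."""

    optimizer: str = "adam"  # "adam" | "adamw"
    weight_decay: float = 0.0  # decoupled (AdamW) decay
    base_lr: float = 1e-3
    phase1_decay: float = 0.86
    phase1_epochs: int = 12
    phase2_decay: float = 0.9991
    batch_size: int = 4
    accumulation_factor: int = 1
    epochs: int = 100
    loss_cc_weight: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "adamw"):
            raise ValueError("optimizer must be 'adam' or 'adamw'")
        if not (0.0 < self.phase1_decay <= 1.0 and 0.0 < self.phase2_decay <= 1.0):
            raise ValueError("decays must lie in (0, 1]")
        if self.batch_size < 1 or self.epochs < 1 or self.accumulation_factor < 1:
            raise ValueError("batch size, epochs and accumulation must be >= 1")
        if self.loss_cc_weight < 0:
            raise ValueError("loss_cc_weight must be >= 0")


#: Optimization presets matching the two published experiments.
DATASET1_PROFILE = TrainConfig(optimizer="adam", weight_decay=0.0,
                               phase1_decay=0.86, phase1_epochs=12,
                               phase2_decay=0.9991, epochs=1000,
                               batch_size=146, accumulation_factor=3,
                               loss_cc_weight=0.0)
DATASET2_PROFILE = TrainConfig(optimizer="adamw", weight_decay=3e-2,
                               phase1_decay=0.91, phase1_epochs=18,
                               phase2_decay=0.9989, epochs=200,
                               batch_size=58, accumulation_factor=16,
                               loss_cc_weight=0.1)


@dataclass
class TrainLog:
    """One record per completed epoch."""

    records: list[dict] = field(default_factory=list)

    def append(self, **kwargs) -> None:
        self.records.append(kwargs)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over all voxels of the squared difference."""
    pred, target = np.asarray(pred), np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


def pearson_cc_flat(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two flattened arrays."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0.0:
        raise ValueError("correlation undefined for constant input")
    return float(np.dot(xc, yc) / denom)


def combined_loss(pred: np.ndarray, target: np.ndarray, w: float = 0.1) -> float:
    """MSE + w * (1 - CC).  A constant target contributes no CC term."""
    loss = mse_loss(pred, target)
    if w > 0.0:
        target = np.asarray(target)
        if np.ptp(target) == 0.0 or np.ptp(np.asarray(pred)) == 0.0:
            import warnings

            warnings.warn("constant map: CC term of the loss set to 0",
                          stacklevel=2)
        else:
            loss += w * (1.0 - pearson_cc_flat(pred, target))
    return float(loss)


def combined_loss_grad(pred: np.ndarray, target: np.ndarray,
                       w: float = 0.1) -> np.ndarray:
    """Gradient of :func:`combined_loss` with respect to ``pred``."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    n = pred.size
    grad = 2.0 * (pred - target) / n
    if w > 0.0 and np.ptp(target) > 0.0 and np.ptp(pred) > 0.0:
        xc = (pred - pred.mean()).ravel()
        yc = (target - target.mean()).ravel()
        nx, ny = np.linalg.norm(xc), np.linalg.norm(yc)
        cc = float(np.dot(xc, yc) / (nx * ny))
        dcc = (yc / (nx * ny) - cc * xc / nx**2).reshape(pred.shape)
        grad -= w * dcc
    return grad


# ---------------------------------------------------------------------------
# schedule and optimizer
# ---------------------------------------------------------------------------


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Two-phase exponential decay (0-based epoch)."""
    if epoch < 0:
        raise ValueError("epoch must be >= 0")
    p1 = config.phase1_epochs
    return float(
        config.base_lr
        * config.phase1_decay ** min(epoch, p1)
        * config.phase2_decay ** max(0, epoch - p1)
    )


class Adam:
    """Adam / AdamW (decoupled weight decay) over a parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0,
                 decoupled: bool = False):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decoupled = decoupled
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and not self.decoupled:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            if self.weight_decay and self.decoupled:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def _median_cc(model: PattersonUNet, patterson: np.ndarray,
               density: np.ndarray, batch_size: int) -> float:
    ccs = []
    for start in range(0, len(patterson), batch_size):
        xb = patterson[start:start + batch_size, None]
        pred = model.forward(xb, training=False)[:, 0]
        for p, t in zip(pred, density[start:start + batch_size]):
            ccs.append(pearson_cc_flat(p, t))
    return float(np.median(ccs))


def train(model: PattersonUNet, dataset, config: TrainConfig,
          validate: bool = True) -> tuple[PattersonUNet, TrainLog]:
    """Train in place; returns (best-validation model, per-epoch log).

    ``dataset`` is a :class:`pattnet.dataset.Dataset`; all examples must
    share one grid shape (mini-batches are dense arrays).  The model state
    with the highest validation median CC is retained and returned; when
    validation is disabled the final state is returned.
    """
    xtr, ytr = dataset.split_arrays("train")
    xva, yva = dataset.split_arrays("validation")
    if len(xtr) == 0:
        raise ValueError("training split is empty")
    if validate and len(xva) == 0:
        raise ValueError("validation split is empty (pass validate=False to skip)")
    shapes = {a.shape[1:] for a in (xtr, ytr) if len(a)}
    if len(shapes) != 1:
        raise ValueError("all examples must share one grid shape")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.base_lr,
               weight_decay=config.weight_decay,
               decoupled=(config.optimizer == "adamw"))
    log = TrainLog()
    best_cc = -np.inf
    best_state = None
    w = config.loss_cc_weight

    for epoch in range(config.epochs):
        opt.lr = lr_at_epoch(config, epoch)
        order = rng.permutation(len(xtr))
        losses = []
        model.zero_grad()
        n_accum = 0
        n_steps = 0
        n_batches = int(np.ceil(len(xtr) / config.batch_size))
        for bi in range(n_batches):
            sel = order[bi * config.batch_size:(bi + 1) * config.batch_size]
            xb = xtr[sel][:, None]
            yb = ytr[sel][:, None]
            pred = model.forward(xb, training=True)
            losses.append(combined_loss(pred, yb, w))
            model.backward(combined_loss_grad(pred, yb, w))
            n_accum += 1
            if n_accum == config.accumulation_factor or bi == n_batches - 1:
                for p in model.parameters():
                    p.grad /= n_accum
                opt.step()
                model.zero_grad()
                n_accum = 0
                n_steps += 1
        record = {
            "epoch": epoch,
            "lr": opt.lr,
            "train_loss": float(np.mean(losses)),
            "opt_steps": n_steps,
        }
        if validate:
            va_losses = [
                combined_loss(
                    model.forward(xva[i:i + 1, None], training=False),
                    yva[i:i + 1, None], w)
                for i in range(len(xva))
            ]
            med_cc = _median_cc(model, xva, yva, config.batch_size)
            record["val_loss"] = float(np.mean(va_losses))
            record["val_median_cc"] = med_cc
            if med_cc > best_cc:
                best_cc = med_cc
                best_state = copy.deepcopy(model.state_arrays())
        log.append(**record)

    if validate and best_state is not None:
        model.load_state_arrays(best_state)
    return model, log
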