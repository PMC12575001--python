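"""Model training and transfer learning.

Losses operate per nucleotide position.  Label rows are one-hot over
(none, acceptor, donor); the all-zero row marks padding and is masked out
of every loss (reduction: mean over non-padding positions).  Training uses
AdamW with a per-epoch learning rate from either a multistep schedule
(0.5 decay at every epoch from the sixth onward) or cosine annealing with
warm restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import cos, pi

import numpy as np

from .dataset import EncodedDataset
from .model import SpliceModel, softmax
from .nn import AdamW

__all__ = [
    "TrainConfig",
    "TrainLog",
    "cross_entropy_loss",
    "focal_loss",
    "scheduler_lr",
    "train",
    "transfer",
    "slice_windows_to_flank",
]

_EPS = 1e-12


@dataclass
class TrainConfig:
    loss: str = "cross_entropy"  # {"cross_entropy", "focal"}
    gamma: float = 2.0
    lr: float = 1e-3
    scheduler: str = "multistep"  # {"multistep", "cosine_warm_restarts"}
    T_0: int = 5
    eta_min: float = 1e-5
    epochs: int = 10
    patience: int = 2
    val_fraction: float = 0.1
    batch_size: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.loss not in ("cross_entropy", "focal"):
            raise ValueError("loss must be 'cross_entropy' or 'focal'")
        if self.scheduler not in ("multistep", "cosine_warm_restarts"):
            raise ValueError(
                "scheduler must be 'multistep' or 'cosine_warm_restarts'"
            )
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")
        if not (0 < self.val_fraction < 1):
            raise ValueError("val_fraction must be in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class TrainLog:
    seed: int
    loss: str
    reduction: str = "mean over non-padding positions"
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int | None = None
    stopped_early: bool = False


def _masked_stats(target: np.ndarray) -> tuple[np.ndarray, int]:
    mask = target.sum(axis=-1) > 0
    return mask, int(mask.sum())


def cross_entropy_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean over non-padding positions of -sum_c I_c log P_c."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mask, n = _masked_stats(target)
    if n == 0:
        warnings.warn("all positions are padding; loss is 0", stacklevel=2)
        return 0.0
    ll = (target * np.log(np.clip(pred, _EPS, 1.0))).sum(axis=-1)
    return float(-(ll * mask).sum() / n)


def focal_loss(pred: np.ndarray, target: np.ndarray, gamma: float = 2.0) -> float:
    """Mean over non-padding positions of -I_c (1 - P_c)^gamma log P_c.

    At gamma = 0 this is exactly the cross-entropy loss.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    mask, n = _masked_stats(target)
    if n == 0:
        warnings.warn("all positions are padding; loss is 0", stacklevel=2)
        return 0.0
    p_t = (target * pred).sum(axis=-1)
    p_t = np.clip(p_t, _EPS, 1.0)
    term = -((1.0 - p_t) ** gamma) * np.log(p_t)
    return float((term * mask).sum() / n)


def loss_and_grad(
    logits: np.ndarray,
    target: np.ndarray,
    loss: str = "cross_entropy",
    gamma: float = 2.0,
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the logits."""
    probs = softmax(logits).astype(np.float64)
    target = np.asarray(target, dtype=np.float64)
    mask, n = _masked_stats(target)
    if n == 0:
        return 0.0, np.zeros_like(logits)
    if loss == "cross_entropy":
        value = cross_entropy_loss(probs, target)
        dlogits = (probs - target) * mask[..., None] / n
    elif loss == "focal":
        value = focal_loss(probs, target, gamma)
        p_t = np.clip((target * probs).sum(axis=-1), _EPS, 1.0)
        one_m = np.clip(1.0 - p_t, _EPS, 1.0)
        # d/dp_t of -(1-p_t)^g log(p_t)
        dL_dpt = gamma * one_m ** (gamma - 1) * np.log(p_t) - one_m**gamma / p_t
        # dp_t/dz_j = p_t * (I_j - p_j)
        coef = (dL_dpt * p_t * mask)[..., None] / n
        dlogits = coef * (target - probs)
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return value, dlogits.astype(np.float32)


def scheduler_lr(config: TrainConfig, epoch: float) -> float:
    """Learning rate at a (1-based, possibly fractional) epoch.

    multistep: lr * 0.5^(milestones passed), milestones at every epoch
    from the sixth onward.  cosine_warm_restarts: cosine interpolation from
    lr to eta_min over each T_0-epoch cycle, restarting at the cycle end
    (the trough, eta_min, is approached as the cycle completes).
    """
    if epoch < 1:
        raise ValueError("epoch index starts at 1")
    if config.scheduler == "multistep":
        n_decays = max(0, int(epoch) - 5)
        return config.lr * 0.5**n_decays
    t_cur = (epoch - 1) % config.T_0
    return config.eta_min + (config.lr - config.eta_min) * (
        1 + cos(pi * t_cur / config.T_0)
    ) / 2


def slice_windows_to_flank(X: np.ndarray, flank: int) -> np.ndarray:
    """Trim dataset windows (built with 5000 nt context per side) down to
    the flank/2-per-side context a given model consumes."""
    width = X.shape[1]
    core = width - 2 * 5000
    if core <= 0:
        raise ValueError("windows are narrower than the dataset flank")
    half = flank // 2
    return X[:, 5000 - half : 5000 + core + half, :]


def _val_loss(
    model: SpliceModel,
    X: np.ndarray,
    Y: np.ndarray,
    config: TrainConfig,
    batch_size: int = 16,
) -> float:
    losses, weights = [], []
    for i in range(0, len(X), batch_size):
        probs = model.forward(X[i : i + batch_size], training=False)
        yb = Y[i : i + batch_size]
        n = (yb.sum(axis=-1) > 0).sum()
        if n == 0:
            continue
        if config.loss == "focal":
            losses.append(focal_loss(probs, yb, config.gamma))
        else:
            losses.append(cross_entropy_loss(probs, yb))
        weights.append(n)
    if not weights:
        return 0.0
    return float(np.average(losses, weights=weights))


def train(
    model: SpliceModel,
    train_ds: EncodedDataset,
    config: TrainConfig,
) -> tuple[SpliceModel, TrainLog]:
    """Train with a seeded 90/10 train/validation split of the segments,
    early stopping on validation loss, returning the best-validation
    checkpoint."""
    if config.epochs < 1:
        raise ValueError("at least one epoch is required")
    if len(train_ds) == 0:
        raise ValueError("training dataset is empty")
    X_all, Y_all = train_ds.stacked()
    X_all = slice_windows_to_flank(X_all, model.config.flank)

    rng = np.random.default_rng(config.seed)
    n = len(X_all)
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.val_fraction * n)))
    if n_val >= n:
        raise ValueError("dataset too small for a validation split")
    val_idx, tr_idx = perm[:n_val], perm[n_val:]

    opt = AdamW(model.parameters(), lr=config.lr)
    log = TrainLog(seed=config.seed, loss=config.loss)
    best_val = np.inf
    best_state = None
    bad_epochs = 0

    for epoch in range(1, config.epochs + 1):
        lr = scheduler_lr(config, epoch)
        opt.lr = lr
        order = rng.permutation(len(tr_idx))
        epoch_losses, epoch_weights = [], []
        for i in range(0, len(order), config.batch_size):
            idx = tr_idx[order[i : i + config.batch_size]]
            xb, yb = X_all[idx], Y_all[idx]
            logits = model.forward_logits(xb, training=True)
            value, dlogits = loss_and_grad(
                logits, yb, config.loss, config.gamma
            )
            if not np.isfinite(value):
                raise RuntimeError(
                    f"loss diverged (non-finite) at epoch {epoch}; try a "
                    f"lower learning rate"
                )
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(value)
            epoch_weights.append((yb.sum(axis=-1) > 0).sum())
        train_loss = float(np.average(epoch_losses, weights=epoch_weights))
        val_loss = _val_loss(model, X_all[val_idx], Y_all[val_idx], config)
        log.epochs.append(
            {
                "epoch": epoch,
                "lr": lr,
                "train_loss": train_loss,
                "val_loss": val_loss,
            }
        )
        if val_loss < best_val:
            best_val = val_loss
            best_state = model.state_arrays()
            best_state = {k: v.copy() for k, v in best_state.items()}
            log.best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                log.stopped_early = True
                break
    if best_state is not None:
        model.load_state_arrays(best_state)
    return model, log


def transfer(
    pretrained: SpliceModel,
    target_ds: EncodedDataset,
    config: TrainConfig,
    unfreeze: str | int = "all",
    flank: int | None = None,
) -> tuple[SpliceModel, TrainLog]:
    """Fine-tune a pretrained model on a new dataset.

    unfreeze: "all" trains every layer; an integer k trains only the last
    k layer groups (k=1 is the final 3-channel projection; k=0 is a no-op
    that returns the pretrained weights unchanged).
    """
    if flank is not None and pretrained.config.flank != flank:
        raise ValueError(
            f"pretrained model flank {pretrained.config.flank} does not "
            f"match requested flank {flank}"
        )
    model = pretrained.copy()
    if unfreeze == "all":
        model.set_trainable(None)
    else:
        k = int(unfreeze)
        if k < 0:
            raise ValueError("unfreeze must be 'all' or a non-negative int")
        model.set_trainable(k)
        if k == 0:
            log = TrainLog(seed=config.seed, loss=config.loss)
            return model, log
    return train(model, target_ds, config)
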