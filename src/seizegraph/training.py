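"""Optimization loop: Adam, cosine-annealed learning rate, early stopping on
validation loss, and the two EEG-specific augmentations.

Class imbalance is handled exactly by augmentation (no loss re-weighting):

* amplitude scaling — each clip is scaled by ``u ~ Uniform(0.8, 1.2)``.
  Because the spectral features are log-amplitudes, scaling the raw signal
  by ``u`` is identical to adding ``log(u)`` to every (unnormalized) feature
  bin, so the augmentation can run in feature space after featurization
  without re-running any FFT (exact away from the log epsilon floor).
* midline reflection — with some probability the channel rows are permuted
  by the left/right homolog pairing of the montage (an involution).

The loss is binary cross-entropy on the sigmoid output, computed from the
logits for numerical stability.  "No improvement for `patience` consecutive
validation epochs" stops training; the returned model carries the weights of
the best validation epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam, Tensor
from .evaluation import auc
from .model import SeizureGraphModel
from .preprocess import FeatureTensor, NormalizationStats, fit_normalization

__all__ = ["TrainConfig", "augment_batch", "augment_signal",
           "cosine_lr", "bce_loss", "train", "TrainingHistory"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization recipe."""

    lr: float = 1e-4
    batch_size: int = 20
    max_epochs: int = 50
    patience: int = 5
    cosine_schedule: bool = True
    cosine_period: int | None = None      # default: max_epochs
    amp_scale_range: tuple[float, float] = (0.8, 1.2)
    midline_reflection_prob: float = 0.5
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        lo, hi = self.amp_scale_range
        if not lo < hi:
            raise ValueError("amp_scale_range low must be < high")
        if not 0.0 <= self.midline_reflection_prob <= 1.0:
            raise ValueError("midline_reflection_prob must be in [0, 1]")


@dataclass
class TrainingHistory:
    """Per-epoch log of the run."""

    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_loss: float = np.inf
    stopped_early: bool = False

    def to_csv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.epochs).to_csv(path, index=False)


def cosine_lr(epoch: int, base_lr: float, period: int) -> float:
    """Cosine annealing: base_lr at epoch 0, decaying to 0 at ``period``."""
    frac = min(max(epoch, 0), period) / max(period, 1)
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * frac))


def augment_signal(samples: np.ndarray, rng: np.random.Generator,
                   amp_scale_range=(0.8, 1.2),
                   reflection_perm: np.ndarray | None = None,
                   reflection_prob: float = 0.5) -> np.ndarray:
    """Raw-signal-domain augmentation of one clip (channels x time)."""
    u = rng.uniform(*amp_scale_range)
    out = samples * u
    if reflection_perm is not None and rng.random() < reflection_prob:
        out = out[reflection_perm]
    return out


def augment_batch(X: np.ndarray, config: TrainConfig,
                  rng: np.random.Generator,
                  reflection_perm: np.ndarray | None = None) -> np.ndarray:
    """Feature-space augmentation of an unnormalized log-feature batch.

    X: (B, N, C, T) log-amplitude features *before* z-normalization.  Labels
    are untouched (both augmentations are label-preserving).  Raises if
    reflection is requested without a pair permutation.
    """
    lo, hi = config.amp_scale_range
    u = rng.uniform(lo, hi, size=X.shape[0])
    out = X + np.log(u)[:, None, None, None]
    if config.midline_reflection_prob > 0:
        if reflection_perm is None:
            raise ValueError("midline reflection requested but no pair map given")
        flip = rng.random(X.shape[0]) < config.midline_reflection_prob
        out[flip] = out[flip][:, reflection_perm]
    return out


def bce_loss(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits: mean(softplus(z) - y*z)."""
    y = np.asarray(y, dtype=np.float64)
    return (logits.softplus() - logits * Tensor(y)).mean()


def _epoch_loss(model: SeizureGraphModel, X: np.ndarray, y: np.ndarray,
                batch_size: int) -> tuple[float, np.ndarray]:
    losses, probs = [], []
    for i in range(0, len(y), batch_size):
        logits = model.forward_logits(X[i:i + batch_size])
        losses.append(bce_loss(logits, y[i:i + batch_size]).data * len(
            y[i:i + batch_size]))
        probs.append(1.0 / (1.0 + np.exp(-logits.data)))
    return float(np.sum(losses) / len(y)), np.concatenate(probs)


def train(model: SeizureGraphModel,
          train_X: np.ndarray, train_y: np.ndarray,
          val_X: np.ndarray, val_y: np.ndarray,
          config: TrainConfig,
          reflection_perm: np.ndarray | None = None,
          stats: NormalizationStats | None = None,
          ) -> tuple[SeizureGraphModel, TrainingHistory, NormalizationStats]:
    """Fit the model; returns (best model, history, normalization stats).

    ``train_X`` / ``val_X`` are *unnormalized* log-feature tensors of shape
    (B, N, C, T); normalization statistics are fitted here on the training
    split only (pass ``stats`` to reuse precomputed training statistics).
    Augmentation runs per epoch on the training batch before normalization.
    """
    if len(train_y) == 0 or len(val_y) == 0:
        raise ValueError("empty training or validation split")
    if stats is None:
        stats = fit_normalization(
            [FeatureTensor(X=x, label=int(l))
             for x, l in zip(train_X, train_y)])
    mean, sd = stats.mean[None], stats.sd[None]
    val_Xn = (val_X - mean) / sd

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    period = config.cosine_period or config.max_epochs
    history = TrainingHistory()
    best_state = copy.deepcopy(model.state_arrays())
    bad_epochs = 0

    for epoch in range(config.max_epochs):
        lr = cosine_lr(epoch, config.lr, period) if config.cosine_schedule \
            else config.lr
        opt.lr = lr
        order = rng.permutation(len(train_y))
        Xa = augment_batch(train_X[order], config, rng, reflection_perm) \
            if config.augment else train_X[order].copy()
        Xa = (Xa - mean) / sd
        ya = train_y[order]
        train_losses = []
        for i in range(0, len(ya), config.batch_size):
            xb, yb = Xa[i:i + config.batch_size], ya[i:i + config.batch_size]
            opt.zero_grad()
            loss = bce_loss(model.forward_logits(xb), yb)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training loss diverged (NaN/Inf) at epoch {epoch}")
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data) * len(yb))
        val_loss, val_probs = _epoch_loss(model, val_Xn, val_y,
                                          config.batch_size)
        try:
            val_auc = auc(val_y, val_probs)
        except ValueError:
            val_auc = float("nan")
        history.epochs.append({
            "epoch": epoch, "lr": lr,
            "train_loss": float(np.sum(train_losses) / len(ya)),
            "val_loss": val_loss, "val_auc": val_auc,
        })
        if val_loss < history.best_val_loss - 1e-12:
            history.best_val_loss = val_loss
            history.best_epoch = epoch
            best_state = copy.deepcopy(model.state_arrays())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                history.stopped_early = True
                break

    model.load_state_arrays(best_state)
    return model, history, stats
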