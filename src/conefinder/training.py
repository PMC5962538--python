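"""Training: Generalised Dice Loss, minibatch sampling, RMSProp, early stop.

Cone pixels are a small minority of a split-detection frame, so a plain
cross-entropy objective has a trivial local optimum -- label everything
background. The Generalised Dice Loss (GDL) weights each class by the
inverse square of its volume,

    GDL = 1 - 2 * (sum_x w_x sum_i x_i * xhat_i)
              / (sum_x w_x sum_i (x_i + xhat_i)),   w_x = 1 / (sum_i x_i)^2,

with x ranging over {background, cone}, which keeps the rare class's
contribution on the same footing as the majority's. A class absent from the
truth gets weight 0 (its terms vanish) so the loss stays finite on
background-only crops. Batch loss is the mean of per-image GDLs.

Training draws minibatches of random square crops, mean-centres each crop
(the variance is left untouched), and minimises the GDL with RMSProp.
Early stopping monitors the GDL on full validation images and keeps the
parameters of the best epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import NetworkParams, backward_batch, forward_batch

__all__ = [
    "TrainingConfig",
    "TrainingHistory",
    "preprocess",
    "generalised_dice_loss",
    "cross_entropy_loss",
    "sample_minibatch",
    "train",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of one training run.

    Defaults follow the regime the network was designed for: minibatches of 8
    random 128 x 128 crops, RMSProp with learning rate 0.001, decay 0.9,
    momentum 0, and early stopping with a patience of 20 epochs. ``epoch_size``
    (optimiser steps per epoch) defaults to
    ceil(total training pixels / (batch_size * crop_size^2)), i.e. roughly one
    pass over the training pixels per epoch.
    """

    batch_size: int = 8
    crop_size: int = 128
    learning_rate: float = 0.001
    rms_decay: float = 0.9
    momentum: float = 0.0
    rms_epsilon: float = 1e-10
    patience: int = 20
    epoch_size: int | None = None
    max_epochs: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.patience < 1 or self.max_epochs < 1:
            raise ValueError("batch_size, patience, max_epochs must be >= 1")
        if self.momentum != 0.0:
            raise ValueError("only momentum = 0 is supported")


@dataclass
class TrainingHistory:
    """Per-epoch metrics and the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_dice: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_epoch: int = -1


def preprocess(image: np.ndarray) -> np.ndarray:
    """Centre an image by subtracting its scalar mean (variance untouched)."""
    img = np.asarray(image, dtype=np.float32)
    if img.size == 0:
        raise ValueError("empty image")
    return img - img.mean(dtype=np.float64).astype(np.float32)


def _gdl_terms(pred: np.ndarray, truth: np.ndarray):
    """Per-image weights, intersection and total terms of the GDL."""
    axes = tuple(range(pred.ndim - 1))
    vol = truth.sum(axis=axes, dtype=np.float64)          # (2,)
    w = np.where(vol > 0, 1.0 / np.maximum(vol, 1) ** 2, 0.0)
    inter = (truth * pred).sum(axis=axes, dtype=np.float64)
    total = (truth + pred).sum(axis=axes, dtype=np.float64)
    return w, inter, total


def generalised_dice_loss(pred: np.ndarray, truth: np.ndarray,
                          return_grad: bool = False):
    """Generalised Dice Loss for one image or the mean over a batch.

    Parameters
    ----------
    pred : (h, w, 2) or (B, h, w, 2) class probabilities.
    truth : one-hot mask of the same shape.
    return_grad : also return d(loss)/d(pred).
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    batched = pred.ndim == 4
    preds = pred if batched else pred[None]
    truths = truth if batched else truth[None]

    losses = np.empty(preds.shape[0])
    grad = np.zeros_like(preds) if return_grad else None
    for b in range(preds.shape[0]):
        w, inter, total = _gdl_terms(preds[b], truths[b])
        num = (w * inter).sum()
        den = (w * total).sum()
        if den == 0:
            losses[b] = 0.0
            continue
        losses[b] = 1.0 - 2.0 * num / den
        if return_grad:
            # d/dpred_i of (1 - 2 num/den): num' = w_x * x_i, den' = w_x
            grad[b] = -2.0 * (w * truths[b] * den - num * w) / den ** 2
    loss = float(losses.mean())
    if not return_grad:
        return loss
    grad /= preds.shape[0]
    if not batched:
        grad = grad[0]
    return loss, grad


def cross_entropy_loss(pred: np.ndarray, truth: np.ndarray,
                       return_grad: bool = False):
    """Unweighted per-pixel cross-entropy (reference baseline only).

    Kept as a comparison objective to demonstrate the class-imbalance failure
    mode that motivates the GDL; not a supported training path.
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    eps = 1e-12
    per_pixel = -(truth * np.log(pred + eps)).sum(axis=-1)
    loss = float(per_pixel.mean())
    if not return_grad:
        return loss
    n_pixels = per_pixel.size
    grad = -(truth / (pred + eps)) / n_pixels
    return loss, grad


def _as_pairs(dataset):
    """Normalise a dataset to (image, one-hot mask) pairs."""
    pairs = []
    for item in dataset:
        if hasattr(item, "image") and hasattr(item, "mask"):
            pairs.append((np.asarray(item.image), np.asarray(item.mask)))
        else:
            img, mask = item
            pairs.append((np.asarray(img), np.asarray(mask)))
    return pairs


def sample_minibatch(dataset, crop_size: int, batch_size: int,
                     rng: np.random.Generator):
    """Draw a minibatch of random square crops.

    Images are chosen uniformly, offsets uniformly over valid positions; each
    image crop is mean-centred (the mask crop is taken from the same window).
    Returns ``(x, y)`` with shapes (B, c, c, 1) float32 and (B, c, c, 2)
    float32.
    """
    pairs = _as_pairs(dataset)
    for idx, (img, _) in enumerate(pairs):
        if img.shape[0] < crop_size or img.shape[1] < crop_size:
            raise ValueError(
                f"image {idx} of shape {img.shape} is smaller than the "
                f"{crop_size} px crop")
    x = np.empty((batch_size, crop_size, crop_size, 1), dtype=np.float32)
    y = np.empty((batch_size, crop_size, crop_size, 2), dtype=np.float32)
    for b in range(batch_size):
        img, mask = pairs[rng.integers(len(pairs))]
        r0 = int(rng.integers(img.shape[0] - crop_size + 1))
        c0 = int(rng.integers(img.shape[1] - crop_size + 1))
        crop = img[r0:r0 + crop_size, c0:c0 + crop_size]
        x[b, ..., 0] = preprocess(crop)
        y[b] = mask[r0:r0 + crop_size, c0:c0 + crop_size]
    return x, y


class _RMSProp:
    """RMSProp with zero momentum: s <- d*s + (1-d)*g^2; p -= lr*g/(sqrt(s)+eps)."""

    def __init__(self, params: NetworkParams, lr: float, decay: float,
                 eps: float):
        self.lr, self.decay, self.eps = lr, decay, eps
        self.state = {name: np.zeros_like(arr) for name, arr in params.arrays()}

    def step(self, params: NetworkParams, grads: dict[str, np.ndarray]) -> None:
        for name, arr in params.arrays():
            g = grads[name].astype(arr.dtype)
            s = self.state[name]
            s *= self.decay
            s += (1.0 - self.decay) * g * g
            arr -= self.lr * g / (np.sqrt(s) + self.eps)


def _hard_dice(pred: np.ndarray, truth: np.ndarray) -> float:
    """Pixelwise segmentation Dice of the thresholded cone channel."""
    p = pred[..., 1] >= 0.5
    t = truth[..., 1] >= 0.5
    denom = p.sum() + t.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (p & t).sum() / denom)


def evaluate_loss(params: NetworkParams, val_pairs) -> tuple[float, float]:
    """Mean GDL and mean hard segmentation Dice over full validation images."""
    losses, dices = [], []
    for img, mask in val_pairs:
        x = preprocess(img)[None, ..., None]
        probs, _ = forward_batch(x, params)
        losses.append(generalised_dice_loss(probs[0], mask.astype(np.float64)))
        dices.append(_hard_dice(probs[0], mask))
    return float(np.mean(losses)), float(np.mean(dices))


def train(train_set, val_set, config: TrainingConfig,
          params: NetworkParams | None = None,
          loss_fn=generalised_dice_loss,
          log=None) -> tuple[NetworkParams, TrainingHistory]:
    """Train the segmentation network with early stopping.

    Each epoch runs ``epoch_size`` RMSProp steps on random crops, then scores
    the GDL on the full validation images; training stops once the validation
    loss has not improved for ``config.patience`` epochs (or at
    ``config.max_epochs``) and the best epoch's parameters are returned.
    """
    from .network import init_params  # local import to avoid cycle at import time

    train_pairs = _as_pairs(train_set)
    val_pairs = _as_pairs(val_set)
    if not train_pairs or not val_pairs:
        raise ValueError("train and validation sets must be non-empty")

    rng = np.random.default_rng(config.seed)
    if params is None:
        params = init_params(int(rng.integers(2**31 - 1)))
    params = params.copy()

    epoch_size = config.epoch_size
    if epoch_size is None:
        total_px = sum(img.size for img, _ in train_pairs)
        epoch_size = max(1, int(np.ceil(
            total_px / (config.batch_size * config.crop_size ** 2))))

    opt = _RMSProp(params, config.learning_rate, config.rms_decay,
                   config.rms_epsilon)
    history = TrainingHistory()
    best_loss = np.inf
    best_params = params.copy()

    for epoch in range(config.max_epochs):
        ep_losses = []
        for _ in range(epoch_size):
            x, y = sample_minibatch(train_pairs, config.crop_size,
                                    config.batch_size, rng)
            probs, cache = forward_batch(x, params, want_cache=True)
            loss, dprobs = loss_fn(probs, y.astype(np.float64),
                                   return_grad=True)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}")
            grads = backward_batch(dprobs.astype(np.float32), cache, params)
            opt.step(params, grads)
            ep_losses.append(loss)
        val_loss, val_dice = evaluate_loss(params, val_pairs)
        history.train_loss.append(float(np.mean(ep_losses)))
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
        if log:
            log(f"epoch {epoch}: train {history.train_loss[-1]:.4f} "
                f"val {val_loss:.4f} dice {val_dice:.4f}")
        if val_loss < best_loss:
            best_loss = val_loss
            history.best_epoch = epoch
            best_params = params.copy()
        elif epoch - history.best_epoch >= config.patience:
            history.stopped_epoch = epoch
            break
    if history.stopped_epoch < 0:
        history.stopped_epoch = len(history.train_loss) - 1
    return best_params, history
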