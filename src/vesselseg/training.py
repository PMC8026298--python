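"""Weighted cross-entropy training with Adam and poly learning-rate decay.

The optimizer follows the reference configuration for this architecture:
Adam with lr0 = 1e-3, beta1 = 0.5, beta2 = 0.999, and an epoch-level poly
schedule lr = lr0 * (1 - epoch/max_epochs)**0.9.  Class weights default to
inverse class frequency computed on the training split.  The sample set is
split 80/20 into train/validation deterministically under the seed, and the
checkpoint with the best validation Dice is retained.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import metrics, nn
from .autodiff import Tensor
from .network import SCANet, forward_batch


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 1e-3
    beta1: float = 0.5
    beta2: float = 0.999
    max_epochs: int = 200
    power: float = 0.9
    batch_size: int = 8
    class_weights: tuple | None = None        # None -> inverse frequency
    val_fraction: float = 0.2
    seed: int = 0
    literal_schedule: bool = False            # audit flag, see poly_lr

    def __post_init__(self):
        if self.lr0 < 0:
            raise ValueError("lr0 must be >= 0")
        if not (0 <= self.beta1 < 1 and 0 <= self.beta2 < 1):
            raise ValueError("betas must lie in [0, 1)")
        if self.power <= 0 or self.max_epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid schedule parameters")
        if self.class_weights is not None and min(self.class_weights) <= 0:
            raise ValueError("class_weights must be positive")


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    train_loss: float
    val_dsc: float


@dataclass
class TrainLog:
    records: list = field(default_factory=list)

    def to_csv(self) -> str:
        lines = ["epoch,lr,train_loss,val_dsc"]
        for r in self.records:
            lines.append(f"{r.epoch},{r.lr:.10g},{r.train_loss:.10g},{r.val_dsc:.10g}")
        return "\n".join(lines)


def poly_lr(epoch: int, config: TrainConfig) -> float:
    """Polynomial decay lr0 * (1 - epoch/max_epochs)**power.

    ``literal_schedule`` evaluates the alternative parenthesization
    lr0 * (1 - (epoch - 1/max_epochs)**power) for auditability; it is not
    monotone and not the default.
    """
    if epoch < 0 or epoch > config.max_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {config.max_epochs}]")
    if config.literal_schedule:
        return config.lr0 * (1.0 - (epoch - 1.0 / config.max_epochs) ** config.power)
    return config.lr0 * (1.0 - epoch / config.max_epochs) ** config.power


def weighted_cross_entropy(logits, mask, weights=(1.0, 1.0)) -> Tensor:
    """Mean over pixels of -w[c(p)] * log softmax-probability of true class.

    ``logits``: Tensor or array (N, n_classes, H, W); ``mask``: (N, H, W)
    with values in {0, 1}.
    """
    logits = ad.astensor(logits)
    mask = np.asarray(mask)
    if not np.all(np.isin(np.unique(mask), (0, 1))):
        raise ValueError("mask must contain only 0/1 values")
    n_classes = logits.shape[1]
    if mask.shape != (logits.shape[0], logits.shape[2], logits.shape[3]):
        raise ValueError(f"mask shape {mask.shape} incompatible with logits {logits.shape}")
    weights = np.asarray(weights, dtype=np.float64)
    onehot = np.zeros(logits.shape, dtype=logits.dtype)
    for c in range(n_classes):
        onehot[:, c] = (mask == c)
    wmap = onehot * weights.reshape(1, -1, 1, 1)
    lsm = ad.log_softmax(logits, axis=1)
    per_pixel = ad.mul(ad.astensor((-wmap).astype(logits.dtype)), lsm)
    inv_n = np.asarray(1.0 / mask.size, dtype=logits.dtype)
    return ad.mul(ad.tsum(per_pixel), inv_n)


def inverse_frequency_weights(masks) -> tuple:
    """Per-class weights w_c = total / (n_classes * count_c), mean-one style."""
    total = 0
    fg = 0
    for m in masks:
        m = np.asarray(m)
        total += m.size
        fg += int(m.sum())
    bg = total - fg
    fg = max(fg, 1)
    bg = max(bg, 1)
    return (total / (2.0 * bg), total / (2.0 * fg))


class Adam:
    """Standard Adam with bias correction over a parameter list."""

    def __init__(self, params, beta1=0.5, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, lr: float):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= (lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.data.dtype)


def split_train_val(n: int, val_fraction: float, seed: int):
    """Deterministic 80/20-style split; returns (train_idx, val_idx)."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n))) if n > 1 else 0
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def _as_batch(samples, idx, augment_config=None, aug_rng=None):
    chosen = [samples[i] for i in idx]
    if augment_config is not None:
        from .pipeline import augment
        chosen = [augment(s, augment_config, rng=aug_rng) for s in chosen]
    x = np.stack([s.image for s in chosen]).astype(nn.DTYPE)[:, None]
    y = np.stack([s.mask for s in chosen]).astype(np.int64)
    return x, y


def validation_dsc(net: SCANet, samples, idx, threshold=0.5, batch_size=8) -> float:
    total = metrics.ConfusionCounts(0, 0, 0, 0)
    for lo in range(0, len(idx), batch_size):
        chunk = idx[lo:lo + batch_size]
        x, y = _as_batch(samples, chunk)
        probs = forward_batch(net, x)
        for p, t in zip(probs, y):
            total = total + metrics.confusion(p >= threshold, t)
    return metrics.dsc(total)


def train(net: SCANet, data, config: TrainConfig, start_epoch: int = 0,
          augment_config=None):
    """Train on a list of VesselSamples; returns (net, TrainLog).

    The network ends up loaded with the best-validation-Dice parameters.
    ``start_epoch`` lets a resumed run continue epoch numbering (the poly
    schedule is a function of the absolute epoch).  With ``augment_config``
    set, fresh geometric augmentation is drawn for every training sample in
    every epoch (deterministic under the seed); validation stays unaugmented.
    """
    data = list(data)
    if not data:
        raise ValueError("empty dataset")
    train_idx, val_idx = split_train_val(len(data), config.val_fraction, config.seed)
    if len(train_idx) == 0:
        train_idx = np.arange(len(data))
    weights = config.class_weights
    if weights is None:
        weights = inverse_frequency_weights([data[i].mask for i in train_idx])

    optimizer = Adam(net.parameters(), beta1=config.beta1, beta2=config.beta2)
    log = TrainLog()
    best = (-1.0, None)
    shuffle_rng = np.random.default_rng(config.seed + 1)

    for epoch in range(start_epoch, config.max_epochs):
        lr = poly_lr(epoch, config)
        order = shuffle_rng.permutation(train_idx)
        aug_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, epoch, 0xA06]))
        net.train()
        losses = []
        for lo in range(0, len(order), config.batch_size):
            batch = order[lo:lo + config.batch_size]
            x, y = _as_batch(data, batch, augment_config, aug_rng)
            logits = net(Tensor(x))
            loss = weighted_cross_entropy(logits, y, weights)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch {lo // config.batch_size}")
            loss.backward()
            optimizer.step(lr)
            losses.append(loss.item())
        val = (validation_dsc(net, data, val_idx, batch_size=config.batch_size)
               if len(val_idx) else float("nan"))
        log.records.append(EpochRecord(epoch=epoch, lr=lr,
                                       train_loss=float(np.mean(losses)), val_dsc=val))
        if len(val_idx) and val > best[0]:
            best = (val, copy.deepcopy(net.state_dict()))
    if best[1] is not None:
        net.load_state_dict(best[1])
    return net, log
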