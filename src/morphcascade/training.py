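"""Unsupervised training of the cascade with Adam and exponential lr decay.

The loss (similarity + lam x smoothness) is computed only on the *final*
warped image and final accumulated/composed field — intermediate cascade
outputs receive no direct supervision, which couples the cascades into a
single objective.  After every epoch the image-similarity term alone is
evaluated on held-out validation pairs and the checkpoint is kept whenever
it improves; the regularization term never enters checkpoint selection.

The learning rate decays as  lr(ep) = base_lr * exp(-decay * ep / EP_max),
i.e. from 3e-4 at epoch 0 to 3e-4 * e^-3 at the final epoch with the
defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .losses import LossConfig, multiscale_ncc_t, total_loss_t
from .network import CascadeModel
from .volume_io import Volume


@dataclass
class TrainConfig:
    """Optimization schedule; defaults follow the full-scale recipe."""

    epochs: int = 500
    iters_per_epoch: int = 100
    batch_size: int = 2
    base_lr: float = 3e-4
    lr_decay_rate: float = 3.0
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1 or self.iters_per_epoch < 1:
            raise ValueError("epochs, iterations and batch size must be >= 1")


#: CPU-friendly profile exercising every code path in minutes, not days.
DESK_PROFILE = TrainConfig(epochs=15, iters_per_epoch=10, batch_size=1)


def lr_schedule(ep: int, cfg: TrainConfig) -> float:
    """Exponentially decaying learning rate at epoch `ep`."""
    if not 0 <= ep <= cfg.epochs:
        raise ValueError(f"epoch {ep} outside [0, {cfg.epochs}]")
    return cfg.base_lr * math.exp(-cfg.lr_decay_rate * ep / cfg.epochs)


class Adam:
    """Standard Adam over a flat list of parameter tensors."""

    def __init__(self, params: list[ad.Tensor], beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
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
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class TrainingDiverged(RuntimeError):
    """Raised when the loss becomes non-finite."""


def _pair_tensors(moving: Volume, fixed: Volume):
    return (ad.Tensor(moving.data[None].astype(np.float32)),
            ad.Tensor(fixed.data[None].astype(np.float32)))


def validation_similarity(model: CascadeModel, pairs, loss_cfg: LossConfig,
                          ) -> float:
    """Mean multi-scale similarity term over validation pairs (no reg term)."""
    vals = []
    for moving, fixed in pairs:
        mt, ft = _pair_tensors(moving, fixed)
        warped, _, _ = model.forward(mt, ft)
        vals.append(float(multiscale_ncc_t(
            ft, warped, loss_cfg.patch_sizes, loss_cfg.epsilon).data))
    return float(np.mean(vals))


def train(train_pairs, model: CascadeModel, loss_cfg: LossConfig,
          cfg: TrainConfig, val_pairs=None, log: list | None = None,
          ) -> CascadeModel:
    """Minimize the registration loss over (moving, fixed) volume pairs.

    `train_pairs` is a non-empty sequence of (moving, fixed) Volumes; pairs
    are sampled uniformly per iteration.  Returns the model carrying the
    best-validation parameters (the model is updated in place; the best
    parameter snapshot is restored at the end).  Deterministic under
    `cfg.seed` on a single device.
    """
    train_pairs = list(train_pairs)
    if not train_pairs:
        raise ValueError("no training pairs supplied")
    if val_pairs is None:
        val_pairs = train_pairs
    rng = np.random.default_rng([cfg.seed, 0x77A17])
    opt = Adam(model.parameters())
    best_val = math.inf
    best_snapshot = None
    for ep in range(cfg.epochs):
        lr = lr_schedule(ep, cfg)
        ep_loss = 0.0
        for _ in range(cfg.iters_per_epoch):
            opt.zero_grad()
            batch_loss = 0.0
            idx = rng.integers(0, len(train_pairs), size=cfg.batch_size)
            for i in idx:
                moving, fixed = train_pairs[i]
                mt, ft = _pair_tensors(moving, fixed)
                warped, _, final = model.forward(mt, ft)
                loss = total_loss_t(ft, warped, final, loss_cfg)
                if cfg.batch_size > 1:
                    loss = ad.scale(loss, 1.0 / cfg.batch_size)
                value = loss.item()
                if not math.isfinite(value):
                    raise TrainingDiverged(
                        f"non-finite loss at epoch {ep}: {value}")
                loss.backward()
                batch_loss += value
            opt.step(lr)
            ep_loss += batch_loss
        val = validation_similarity(model, val_pairs, loss_cfg)
        if log is not None:
            log.append({"epoch": ep, "lr": lr,
                        "train_loss": ep_loss / cfg.iters_per_epoch,
                        "val_similarity": val})
        if val < best_val:
            best_val = val
            best_snapshot = [{k: t.data.copy() for k, t in p.items()}
                             for p in model.params]
    if best_snapshot is not None:
        for p, snap in zip(model.params, best_snapshot):
            for k in p:
                p[k].data = snap[k]
    return model
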