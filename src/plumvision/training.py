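"""Training orchestration: momentum SGD wrapped by SWA, with either the
weight-biased softmax loss or plain softmax cross-entropy.

Defaults follow the defect-classification study's settings: batch size 32,
initial learning rate 0.1, SWA learning rate 0.05, weight decay 1e-4,
momentum 0.9.  Training is deterministic given the seed (initialisation,
shuffling and the synthetic data all draw from it).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DefectNet, NetworkSpec, build_network
from .swa import CycleSchedule, SWAState, cycle_ends, cyclic_lr, finalize, swa_update
from .wsoftmax import WSoftmaxLoss, softmax_cross_entropy

__all__ = ["TrainConfig", "TrainHistory", "train", "standardize",
           "Standardizer"]


@dataclass
class SWAConfig:
    enabled: bool = True
    start_epoch: int = 1          # first epoch (1-based) with cyclic LR + snapshots
    cycle_steps: int | None = None  # None -> one epoch of steps
    alpha1: float = 0.1
    alpha2: float = 0.05
    n_cycles: int = 10            # snapshots retained at most


@dataclass
class TrainConfig:
    batch_size: int = 32
    base_lr: float = 0.1
    weight_decay: float = 1e-4
    momentum: float = 0.9
    epochs: int = 100
    loss: str = "wsoftmax"        # "wsoftmax" | "softmax"
    gamma: float = 1.0
    guard: bool = True            # negative-bias floor during training
    seed: int = 0
    swa: SWAConfig = field(default_factory=SWAConfig)

    def __post_init__(self):
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be positive")
        if self.base_lr <= 0 or self.weight_decay < 0:
            raise ValueError("base_lr must be positive, weight_decay >= 0")
        if self.loss not in ("wsoftmax", "softmax"):
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class TrainHistory:
    epoch_loss: list[float] = field(default_factory=list)
    epoch_lr: list[float] = field(default_factory=list)
    snapshots: list[int] = field(default_factory=list)  # global step of each


@dataclass
class Standardizer:
    """Per-channel standardisation constants computed from the training split.

    Maps 8-bit (N, 3, H, W) images to [0, 1] and standardises each channel.
    """

    mean: np.ndarray
    std: np.ndarray

    def __call__(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32) / 255.0
        return ((x - self.mean[None, :, None, None])
                / self.std[None, :, None, None]).astype(np.float32)


def standardize(images: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Standardise 8-bit training images; returns the transform for test time."""
    x = np.asarray(images, dtype=np.float32) / 255.0
    mean = x.mean(axis=(0, 2, 3))
    std = x.std(axis=(0, 2, 3))
    std[std < 1e-6] = 1.0
    st = Standardizer(mean, std)
    return st(images), st


class _SGD:
    """Momentum SGD with decoupled-from-nothing, classic L2 weight decay."""

    def __init__(self, params: dict[str, np.ndarray], momentum: float, wd: float):
        self.params = params
        self.momentum = momentum
        self.wd = wd
        self.vel = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        for k, p in self.params.items():
            g = grads[k] + self.wd * p
            v = self.vel[k]
            v *= self.momentum
            v += g
            p -= lr * v


def _loss_step(net: DefectNet, xb: np.ndarray, yb: np.ndarray,
               cfg: TrainConfig, wloss: WSoftmaxLoss | None) -> float:
    feats = net.features(xb)
    if cfg.loss == "wsoftmax":
        loss = wloss.forward(feats, yb, net.head.W)
        dX, dW = wloss.backward()
    else:
        loss, dX, dW = softmax_cross_entropy(feats, yb, net.head.W)
    net.head.dW[...] = dW.astype(np.float32)
    net.backward_from_features(dX.astype(np.float32))
    return loss


def train(cfg: TrainConfig, images: np.ndarray, labels: np.ndarray,
          net: DefectNet | None = None, spec: NetworkSpec | None = None,
          log=None) -> tuple[DefectNet, TrainHistory, Standardizer]:
    """Train the classifier on 8-bit (N, 3, H, W) images with integer labels.

    Returns the SWA-finalised model (or the plain model when SWA is off), the
    per-epoch history, and the standardisation constants to apply at test
    time.
    """
    images = np.asarray(images)
    labels = np.asarray(labels)
    if len(images) == 0:
        raise ValueError("empty training set")
    if len(images) != len(labels):
        raise ValueError("images and labels differ in length")

    rng = np.random.default_rng(cfg.seed)
    if net is None:
        net = build_network(spec or NetworkSpec(),
                            seed=int(rng.integers(2**31)))
    x, st = standardize(images)
    n = len(x)
    steps_per_epoch = max(1, (n + cfg.batch_size - 1) // cfg.batch_size)

    sw = cfg.swa
    sched = CycleSchedule(alpha1=sw.alpha1, alpha2=sw.alpha2,
                          c=sw.cycle_steps or steps_per_epoch)
    state = SWAState()
    opt = _SGD(net.named_params(), cfg.momentum, cfg.weight_decay)
    wloss = (WSoftmaxLoss(cfg.gamma, guard=cfg.guard)
             if cfg.loss == "wsoftmax" else None)
    net.cosine_head = cfg.loss == "wsoftmax"
    hist = TrainHistory()

    step = 0          # global step counter
    cyc = 0           # 1-based step counter inside the SWA phase
    net.set_mode(True)
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        losses = []
        lr = cfg.base_lr
        for s in range(steps_per_epoch):
            idx = order[s * cfg.batch_size: (s + 1) * cfg.batch_size]
            if idx.size == 0:
                continue
            step += 1
            in_swa = sw.enabled and epoch >= sw.start_epoch
            if in_swa:
                cyc += 1
                lr = cyclic_lr(sched, cyc)
            loss = _loss_step(net, x[idx], labels[idx], cfg, wloss)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, step {s + 1}")
            opt.step(net.named_grads(), lr)
            losses.append(loss)
            if (in_swa and cycle_ends(sched, cyc)
                    and state.n_models < sw.n_cycles):
                swa_update(state, net.named_params(), step=step)
        hist.epoch_loss.append(float(np.mean(losses)))
        hist.epoch_lr.append(float(lr))
        if log is not None:
            log(f"epoch {epoch:3d}  lr {lr:.4f}  loss {hist.epoch_loss[-1]:.4f}")

    hist.snapshots = list(state.snapshot_steps)
    if sw.enabled and state.n_models > 0:
        net.swa_pending = True
        batches = (x[i: i + cfg.batch_size]
                   for i in range(0, n, cfg.batch_size))
        finalize(net, state, batches)
    net.set_mode(False)
    return net, hist, st
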