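"""Stochastic weight averaging with a cyclic learning rate.

The learning rate descends linearly from ``alpha1`` to ``alpha2`` within each
cycle of ``c`` steps and repeats:

    t(i)     = (mod(i-1, c) + 1) / c
    alpha(i) = (1 - t(i)) * alpha1 + t(i) * alpha2

At the end of each cycle the current weights are folded into a running
average

    w_swa <- (w_swa * n_models + w) / (n_models + 1)

so after k snapshots ``w_swa`` is their arithmetic mean.  Only two weight
sets live in memory during training: the model being optimised and the
average.  The averaged model's batch-norm running statistics are stale by
construction and must be recomputed with one pass over the training data
before it can predict (``finalize``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import DefectNet

__all__ = ["CycleSchedule", "SWAState", "cyclic_lr", "swa_update", "finalize"]


@dataclass
class CycleSchedule:
    """Cyclic learning-rate parameters (alpha1 >= alpha2 > 0, c >= 1)."""

    alpha1: float = 0.1
    alpha2: float = 0.05
    c: int = 1

    def __post_init__(self):
        if not (self.alpha1 >= self.alpha2 > 0):
            raise ValueError("require alpha1 >= alpha2 > 0")
        if self.c < 1:
            raise ValueError("cycle length c must be >= 1")


def cyclic_lr(sched: CycleSchedule, i: int) -> float:
    """Learning rate at 1-based step i; alpha(i) lies in [alpha2, alpha1)."""
    if i < 1:
        raise ValueError("step counter i is 1-based")
    t = ((i - 1) % sched.c + 1) / sched.c
    return (1.0 - t) * sched.alpha1 + t * sched.alpha2


def cycle_ends(sched: CycleSchedule, i: int) -> bool:
    """True when step i is the last step of a cycle (t(i) = 1)."""
    return (i - 1) % sched.c + 1 == sched.c


@dataclass
class SWAState:
    """Running arithmetic mean of snapshot weight sets."""

    w_swa: dict[str, np.ndarray] | None = None
    n_models: int = 0
    snapshot_steps: list[int] = field(default_factory=list)


def swa_update(state: SWAState, weights: dict[str, np.ndarray],
               step: int | None = None) -> SWAState:
    """Fold the current weights into the running average (in place)."""
    if state.n_models == 0:
        state.w_swa = {k: np.array(v, dtype=np.float64) for k, v in weights.items()}
    else:
        if set(state.w_swa) != set(weights):
            raise ValueError("snapshot parameter names do not match the average")
        n = state.n_models
        for k, v in weights.items():
            if state.w_swa[k].shape != v.shape:
                raise ValueError(f"shape mismatch for {k}")
            state.w_swa[k] = (state.w_swa[k] * n + v) / (n + 1)
    state.n_models += 1
    if step is not None:
        state.snapshot_steps.append(step)
    return state


def finalize(net: DefectNet, state: SWAState, train_batches) -> DefectNet:
    """Install the averaged weights and recompute batch-norm statistics.

    ``train_batches`` is an iterable of (N, 3, H, W) arrays — normally the
    training loader replayed once.  The running mean/variance of every BN
    layer is rebuilt from equally weighted batch statistics under the
    averaged weights; afterwards the model is flagged ready for prediction.
    """
    if state.n_models == 0:
        raise ValueError("no snapshots to finalize: n_models = 0")
    net.load_params({k: v.astype(np.float32) for k, v in state.w_swa.items()})
    bns = net.bn_layers()
    for bn in bns:
        bn.start_stat_collection()
    net.set_mode(False)
    for bn in bns:
        bn.collecting = True
    seen = False
    for batch in train_batches:
        seen = True
        net.forward(np.asarray(batch, dtype=np.float32))
    if not seen:
        raise ValueError("finalize needs at least one training batch")
    for bn in bns:
        bn.finish_stat_collection()
    net.swa_pending = False
    return net
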