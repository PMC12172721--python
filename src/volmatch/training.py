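"""Shared optimization machinery: Adam, the learning-rate schedule, and the
epoch loop with validation-loss checkpointing.

Training minimizes cross-entropy by mini-batch Adam.  The learning rate is
reduced by a factor of 0.75 whenever the validation loss has not improved
by more than 0.0001 for more than four epochs, and model weights are
checkpointed each time the validation loss reaches a new minimum; the
checkpoint, not the final state, is what gets evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .nn import Param

__all__ = ["Adam", "ScheduleState", "step_schedule", "FitRecord", "fit_loop"]


class Adam:
    """Adam optimizer over a list of :class:`~volmatch.nn.Param`."""

    def __init__(self, params: list[Param], beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


@dataclass(frozen=True)
class ScheduleState:
    """Reduce-on-plateau learning-rate schedule state."""

    lr: float
    best_loss: float = np.inf
    stale_epochs: int = 0
    threshold: float = 1e-4
    patience: int = 4
    factor: float = 0.75


def step_schedule(state: ScheduleState, val_loss: float) -> ScheduleState:
    """Advance the schedule by one epoch's validation loss.

    An improvement counts only if strictly larger than ``threshold``; after
    more than ``patience`` consecutive non-improving epochs the learning
    rate is multiplied by ``factor`` and the counter resets.
    """
    if not np.isfinite(val_loss):
        raise ValueError("non-finite validation loss")
    if val_loss < state.best_loss - state.threshold:
        return replace(state, best_loss=val_loss, stale_epochs=0)
    stale = state.stale_epochs + 1
    if stale > state.patience:
        return replace(state, lr=state.lr * state.factor, stale_epochs=0)
    return replace(state, stale_epochs=stale)


@dataclass
class FitRecord:
    """Training history plus the minimum-validation-loss checkpoint."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr_history: list[float] = field(default_factory=list)
    checkpoint: list[np.ndarray] | None = None
    checkpoint_val_loss: float = np.inf
    checkpoint_epoch: int = -1
    n_updates: int = 0


def fit_loop(
    trainable,
    X: np.ndarray,
    y: np.ndarray,
    *,
    epochs: int,
    lr: float = 1e-4,
    batch_size: int = 16,
    validation: tuple[np.ndarray, np.ndarray] | None = None,
    rng: np.random.Generator | None = None,
    use_schedule: bool = True,
) -> FitRecord:
    """Mini-batch Adam loop shared by the linear and CNN classifiers.

    ``trainable`` must expose ``params()``, ``zero_grad()``,
    ``loss_and_grad(Xb, yb)``, ``eval_loss(Xv, yv)``, ``get_state()`` and
    ``set_state()``.  When a validation set is given, the plateau schedule
    and min-validation-loss checkpointing are applied; otherwise the final
    state is checkpointed.
    """
    if len(X) == 0:
        raise ValueError("empty training set")
    if validation is not None and len(validation[0]) == 0:
        raise ValueError("empty validation set")
    rng = rng or np.random.default_rng(0)
    n = len(X)
    record = FitRecord()
    sched = ScheduleState(lr=lr)
    opt = Adam(trainable.params())
    for epoch in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            trainable.zero_grad()
            loss = trainable.loss_and_grad(X[idx], y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}")
            opt.step(sched.lr)
            record.n_updates += 1
            losses.append(loss)
        record.train_loss.append(float(np.mean(losses)))
        record.lr_history.append(sched.lr)
        if validation is not None:
            vl = trainable.eval_loss(*validation)
            record.val_loss.append(vl)
            if vl < record.checkpoint_val_loss:
                record.checkpoint = trainable.get_state()
                record.checkpoint_val_loss = vl
                record.checkpoint_epoch = epoch
            sched = step_schedule(sched, vl)
    if record.checkpoint is None:
        record.checkpoint = trainable.get_state()
        record.checkpoint_epoch = epochs - 1
    return record
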