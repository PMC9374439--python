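"""Maximum-likelihood training loop with validation-based early stopping."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .autograd import Tensor
from .layers import Adam

__all__ = ["TrainConfig", "TrainResult", "fit_mle"]


@dataclass
class TrainConfig:
    """Hyperparameters shared by both estimator components.

    Defaults follow common neural simulation-based-inference practice:
    Adam at 5e-4, minibatches of 128, a 90/10 train/validation split,
    plateau-triggered learning-rate halving, and early stopping after 20
    epochs without validation improvement.
    """

    lr: float = 5e-4
    batch_size: int = 128
    val_fraction: float = 0.1
    patience: int = 20
    max_epochs: int = 300
    lr_patience: int = 5
    lr_decay: float = 0.5
    min_lr: float = 1e-5
    clip_grad_norm: float = 5.0
    weight_averaging: bool = True
    seed: int = 0


@dataclass
class TrainResult:
    train_losses: list[float] = field(default_factory=list)
    val_losses: list[float] = field(default_factory=list)
    best_epoch: int = 0
    best_val_loss: float = np.inf


def fit_mle(
    loss_fn: Callable[[np.ndarray], Tensor],
    parameters: list[Tensor],
    get_state: Callable[[], dict],
    set_state: Callable[[dict], None],
    n_data: int,
    config: TrainConfig,
) -> TrainResult:
    """Minimize the mean negative log-likelihood over minibatches.

    ``loss_fn(indices)`` must return the scalar mean loss over the given
    data indices as an autodiff Tensor.  The best-validation-loss state is
    restored before returning.
    """
    rng = np.random.default_rng(config.seed)
    perm = rng.permutation(n_data)
    n_val = max(1, int(round(config.val_fraction * n_data)))
    val_idx = perm[:n_val]
    train_idx = perm[n_val:]
    if len(train_idx) == 0:
        raise ValueError("not enough data for a train/validation split")

    opt = Adam(parameters, lr=config.lr)
    result = TrainResult()
    best_state = get_state()
    epochs_since_best = 0
    # stochastic weight averaging over the plateau phase: once the step
    # size has decayed, per-epoch iterates orbit the same basin and their
    # average generalizes better than any single snapshot
    swa_sum: list[np.ndarray] | None = None
    swa_count = 0

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(order), config.batch_size):
            batch = train_idx[order[start:start + config.batch_size]]
            opt.zero_grad()
            loss = loss_fn(batch)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data}; "
                    f"loss trace so far: {result.train_losses}"
                )
            loss.backward()
            if config.clip_grad_norm:
                total = np.sqrt(sum(float(np.sum(p.grad**2))
                                    for p in parameters if p.grad is not None))
                if total > config.clip_grad_norm:
                    scale = config.clip_grad_norm / total
                    for p in parameters:
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            epoch_losses.append(float(loss.data))
        result.train_losses.append(float(np.mean(epoch_losses)))

        val_loss = float(loss_fn(val_idx).data)
        result.val_losses.append(val_loss)
        if config.weight_averaging and opt.lr <= config.lr * 0.3:
            if swa_sum is None:
                swa_sum = [p.data.copy() for p in parameters]
            else:
                for acc, p in zip(swa_sum, parameters):
                    acc += p.data
            swa_count += 1
        if val_loss < result.best_val_loss:
            result.best_val_loss = val_loss
            result.best_epoch = epoch
            best_state = get_state()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
            if epochs_since_best >= config.patience:
                break
            # reduce the step size on a validation plateau
            if epochs_since_best % config.lr_patience == 0:
                opt.lr = max(opt.lr * config.lr_decay, config.min_lr)

    set_state(best_state)
    if swa_sum is not None and swa_count >= 5:
        # adopt the averaged weights only if they validate at least as well
        current = [p.data.copy() for p in parameters]
        for p, acc in zip(parameters, swa_sum):
            p.data = acc / swa_count
        swa_val = float(loss_fn(val_idx).data)
        if swa_val <= result.best_val_loss:
            result.best_val_loss = swa_val
            result.val_losses.append(swa_val)
        else:
            for p, cur in zip(parameters, current):
                p.data = cur
    return result
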