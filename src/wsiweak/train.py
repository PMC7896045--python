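"""Training schedule shared by the whole-slide and instance classifiers.

The schedule follows the study protocol: Adam with an initial learning
rate that decays (once) by 10x when the validation loss has not improved
for ``patience_epochs`` epochs, an "epoch" being a fixed number of
optimiser steps rather than a full data pass, and only the weights
achieving the lowest validation loss being kept.

Defaults in :class:`TrainConfig` record the reference protocol
(batch 8, lr 2e-5 -> 2e-6, patience 24, 100 steps/epoch).  Desk-scale
experiments override them with values suited to a small from-scratch
network; the ``n_gpus`` field exists only to document the sqrt(#GPUs)
learning-rate scaling used under synchronous data parallelism and is inert
in this single-process implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nn import Adam, SmallConvNet, EPS_LOG

__all__ = ["TrainConfig", "train", "evaluate"]


@dataclass
class TrainConfig:
    batch_size: int = 8
    lr_initial: float = 2e-5
    lr_decayed: float = 2e-6
    patience_epochs: int = 24
    steps_per_epoch: int = 100
    max_epochs: int = 30
    seed: int = 0
    checkpoint_rule: str = "lowest_val_loss"
    n_gpus: int = 1  # documentation only: lr_initial *= sqrt(n_gpus) when >1

    def __post_init__(self):
        if self.lr_decayed >= self.lr_initial:
            raise ValueError("lr_decayed must be < lr_initial")
        if self.patience_epochs < 1:
            raise ValueError("patience_epochs must be >= 1")

    @property
    def effective_lr_initial(self) -> float:
        return self.lr_initial * math.sqrt(self.n_gpus)


def _batch_loss_acc(model: SmallConvNet, x, y_onehot, batch=32):
    probs = model.predict_proba(x, batch=batch)
    p = np.clip(probs, EPS_LOG, 1.0)
    loss = float(-(y_onehot * np.log(p)).sum(axis=1).mean())
    acc = float((probs.argmax(1) == y_onehot.argmax(1)).mean())
    return loss, acc


def evaluate(model: SmallConvNet, x, y_onehot):
    """Mean cross-entropy loss and accuracy on a held-out array pair."""
    return _batch_loss_acc(model, x, y_onehot)


def train(model: SmallConvNet, sample_batch, val_data, cfg: TrainConfig):
    """Optimise ``model`` under the epoch/patience/checkpoint schedule.

    Parameters
    ----------
    sample_batch : callable(rng, batch_size) -> (x, y_onehot)
        Draws one (optionally augmented) training minibatch.
    val_data : (x, y_onehot)
        Fixed validation arrays evaluated once per epoch.

    Returns
    -------
    (model, curves) : the model carrying the lowest-validation-loss weights
    and a DataFrame with per-epoch train/val loss and accuracy.
    """
    xv, yv = val_data
    if len(xv) == 0:
        raise ValueError("validation set is empty")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(lr=cfg.effective_lr_initial)
    best_loss = np.inf
    best_weights = model.get_weights()
    epochs_since_best = 0
    decayed = False
    rows = []
    for epoch in range(cfg.max_epochs):
        losses = []
        accs = []
        for _ in range(cfg.steps_per_epoch):
            xb, yb = sample_batch(rng, cfg.batch_size)
            if len(xb) == 0:
                raise ValueError("empty training batch")
            loss, grads, probs = model.loss_and_grads(xb, yb)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            opt.step(model.params, grads)
            losses.append(loss)
            accs.append(float((probs.argmax(1) == yb.argmax(1)).mean()))
        val_loss, val_acc = _batch_loss_acc(model, xv, yv)
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_loss": val_loss,
                "train_acc": float(np.mean(accs)),
                "val_acc": val_acc,
                "lr": opt.lr,
            }
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_weights = model.get_weights()
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if not decayed and epochs_since_best >= cfg.patience_epochs:
            opt.lr = cfg.lr_decayed
            decayed = True
    model.set_weights(best_weights)
    return model, pd.DataFrame(rows)
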