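"""Mini-batch RMSprop training of the forecast network.

The loss is the mean squared error of the predicted glucose change ΔBG
against the label (mg/dL)², optimised with RMSprop (decay 0.9, learning
rate 0.001 by default), global-norm gradient clipping and early stopping
on validation RMSE.  Two-phase transfer learning first fits a generalised
model on a corpus combining the target subject with donor shares, then
fine-tunes all weights on the target subject alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import model as drnn
from .preprocess import build_transfer_corpus
from .simulate import SubjectSeries
from .windowing import (
    WindowSet,
    apply_scaler,
    batch_iter,
    concat_window_sets,
    fit_scaler,
    make_windows,
    split_train_val,
)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "RMSprop",
    "loss",
    "train",
    "transfer_train",
    "clip_gradients",
]


@dataclass(frozen=True)
class TrainConfig:
    learning_rate: float = 0.001
    rmsprop_decay: float = 0.9
    rmsprop_epsilon: float = 1e-8
    batch_size: int = 512
    max_epochs: int = 200
    patience: int = 10
    grad_clip_norm: float = 5.0
    seed: int = 0
    phase2_epochs: int = 50
    shuffle: bool = True

    def validate(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if not 0.0 < self.rmsprop_decay < 1.0:
            raise ValueError("rmsprop_decay must lie in (0, 1)")
        if self.batch_size < 1 or self.max_epochs < 0 or self.patience < 1:
            raise ValueError("invalid batch_size / max_epochs / patience")
        if self.grad_clip_norm <= 0:
            raise ValueError("grad_clip_norm must be > 0")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    val_rmse: list[float] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_rmse(self) -> float:
        return self.val_rmse[self.best_epoch] if self.val_rmse else float("nan")


class RMSprop:
    """Textbook RMSprop: E[g²] ← ρ E[g²] + (1-ρ) g²; θ ← θ - lr g/(√E + ε).

    Operates on a flat name -> array parameter dict, in place, so the
    same optimizer serves the recurrent network and the MLP baseline.
    """

    def __init__(self, params: dict[str, np.ndarray], decay: float = 0.9,
                 epsilon: float = 1e-8):
        self.decay = decay
        self.epsilon = epsilon
        self.accum = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray], lr: float) -> None:
        for k, p in params.items():
            g = grads[k]
            acc = self.accum[k]
            acc *= self.decay
            acc += (1.0 - self.decay) * g * g
            p -= lr * g / (np.sqrt(acc) + self.epsilon)


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients so their global L2 norm is at most max_norm."""
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale
    return total


def loss(model: drnn.DRNNModel, inputs: np.ndarray, labels: np.ndarray) -> float:
    """Mean over the batch of (predicted ΔBG − label)²."""
    if len(labels) == 0:
        raise ValueError("empty batch")
    pred = drnn.delta_bg(model, inputs)
    return float(np.mean((pred - labels) ** 2))


def _val_rmse(model: drnn.DRNNModel, ws: WindowSet) -> float:
    pred = drnn.delta_bg(model, ws.inputs)
    return float(np.sqrt(np.mean((pred - ws.labels) ** 2)))


def train(
    model: drnn.DRNNModel,
    train_ws: WindowSet,
    val_ws: WindowSet,
    config: TrainConfig,
) -> tuple[drnn.DRNNModel, TrainHistory]:
    """Optimise in place and return the best-validation snapshot.

    Early stopping: training ends once validation RMSE has not improved
    for ``patience`` consecutive epochs; the returned model is the
    checkpoint with the lowest validation RMSE seen.
    """
    config.validate()
    history = TrainHistory()
    best = model.copy()
    best_val = np.inf
    stale = 0
    opt = RMSprop(model.params(), config.rmsprop_decay, config.rmsprop_epsilon)
    params = model.params()
    for epoch in range(config.max_epochs):
        epoch_losses = []
        for idx in batch_iter(
            train_ws, config.batch_size, config.seed, epoch, config.shuffle
        ):
            batch_loss, grads = drnn.loss_and_grads(
                model, train_ws.inputs[idx], train_ws.labels[idx]
            )
            if not np.isfinite(batch_loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting {idx[0]}"
                )
            clip_gradients(grads, config.grad_clip_norm)
            opt.step(params, grads, config.learning_rate)
            epoch_losses.append(batch_loss)
        history.train_loss.append(float(np.mean(epoch_losses)))
        v = _val_rmse(model, val_ws)
        history.val_rmse.append(v)
        if v < best_val:
            best_val = v
            best = model.copy()
            history.best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    if history.best_epoch < 0:  # max_epochs == 0
        history.best_epoch = -1
        return model.copy(), history
    return best, history


def windows_from_series(
    pieces: list[SubjectSeries],
    seq_len: int = 12,
    horizon_slots: int = 6,
    val_frac: float = 0.1,
    scaler=None,
) -> tuple[WindowSet, WindowSet]:
    """Window each piece, concatenate, fit/apply the scaler, split.

    The validation split is chronological within the concatenated order;
    when ``scaler`` is None it is fitted on the training windows only.
    """
    ws = concat_window_sets(
        [make_windows(p, seq_len, horizon_slots) for p in pieces]
    )
    train_raw, val_raw = split_train_val(ws, val_frac)
    if scaler is None:
        scaler = fit_scaler(train_raw)
    return apply_scaler(train_raw, scaler), apply_scaler(val_raw, scaler)


def transfer_train(
    target: SubjectSeries,
    donors: list[SubjectSeries],
    config: TrainConfig,
    seq_len: int = 12,
    horizon_slots: int = 6,
    val_frac: float = 0.1,
    model: drnn.DRNNModel | None = None,
    dtype=np.float64,
) -> tuple[drnn.DRNNModel, TrainHistory, TrainHistory]:
    """Two-phase transfer learning.

    Phase 1 trains on the combined corpus (all of the target + the final
    contiguous share of each donor); phase 2 fine-tunes every weight on
    the target subject alone for up to ``phase2_epochs`` epochs with the
    same early-stopping rule.  With ``phase2_epochs == 0`` the phase-1
    model is returned unchanged.
    """
    corpus = build_transfer_corpus(target, donors)
    tr1, va1 = windows_from_series(corpus, seq_len, horizon_slots, val_frac)
    _cast(tr1, dtype)
    _cast(va1, dtype)
    if model is None:
        model = drnn.DRNNModel.init(
            input_size=tr1.inputs.shape[-1], seed=config.seed, dtype=dtype
        )
    model1, hist1 = train(model, tr1, va1, config)
    if config.phase2_epochs == 0:
        return model1, hist1, TrainHistory()
    tr2, va2 = windows_from_series(
        [target], seq_len, horizon_slots, val_frac, scaler=tr1.scaler
    )
    _cast(tr2, dtype)
    _cast(va2, dtype)
    cfg2 = replace(config, max_epochs=config.phase2_epochs)
    model2, hist2 = train(model1.copy(), tr2, va2, cfg2)
    return model2, hist1, hist2


def _cast(ws: WindowSet, dtype) -> None:
    ws.inputs = ws.inputs.astype(dtype, copy=False)
    ws.labels = ws.labels.astype(dtype, copy=False)
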