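"""Classical comparison forecasters: ARX(3), NNPG and RBF-kernel SVR.

All three consume the same sliding windows as the recurrent model and
forecast 30 minutes ahead, so metric differences between methods isolate
the predictor rather than the data path.

* ARX — autoregressive model with exogenous inputs: ordinary least
  squares of the future glucose value on the last ``order`` lags of each
  input channel plus an intercept.
* NNPG — a conventional feed-forward network for glucose prediction:
  three fully connected layers (tanh hidden layers of 64 and 32 units,
  linear output) on the flattened window, trained on ΔBG with the same
  RMSprop/early-stopping contract as the recurrent model (learning rate
  0.001, batch size 32).
* SVR — epsilon-insensitive support-vector regression with an RBF kernel
  (C = 100, γ = 0.01) on standardised ΔBG targets, delegated to
  scikit-learn.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVR as _SkSVR

from .training import RMSprop, TrainConfig, TrainHistory, clip_gradients
from .windowing import WindowSet, batch_iter

__all__ = [
    "ARXModel",
    "arx_fit",
    "arx_predict",
    "NNPGModel",
    "nnpg_train",
    "nnpg_predict",
    "SVRModel",
    "svr_train",
    "svr_predict",
]


# ---------------------------------------------------------------- ARX ----

@dataclass
class ARXModel:
    """Least-squares coefficients over lagged channels plus intercept."""

    coeffs: np.ndarray          # [order * C + 1]
    order: int
    rank_deficient: bool = False


def _arx_design(windows: WindowSet, order: int) -> np.ndarray:
    lags = windows.inputs[:, -order:, :]          # [n, order, C]
    flat = lags.reshape(len(windows), -1)
    return np.hstack([flat, np.ones((len(windows), 1))])


def arx_fit(windows: WindowSet, order: int = 3) -> ARXModel:
    """Fit ŷ_T (absolute mg/dL) on the last ``order`` lags of each channel.

    Rank-deficient designs fall back to the minimum-norm least-squares
    solution and are flagged (and warned about).
    """
    n_features = order * windows.inputs.shape[-1] + 1
    if len(windows) < n_features:
        raise ValueError(
            f"need at least {n_features} windows to fit ARX({order}), "
            f"got {len(windows)}"
        )
    A = _arx_design(windows, order)
    y = windows.labels + windows.last_glucose      # absolute future BG
    coeffs, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    deficient = rank < A.shape[1]
    if deficient:
        warnings.warn("ARX design is rank deficient; minimum-norm solution used")
    return ARXModel(coeffs=coeffs, order=order, rank_deficient=deficient)


def arx_predict(model: ARXModel, windows: WindowSet) -> np.ndarray:
    """Absolute glucose forecasts in mg/dL."""
    return _arx_design(windows, model.order) @ model.coeffs


# --------------------------------------------------------------- NNPG ----

@dataclass
class NNPGModel:
    """Three fully connected layers on the flattened window."""

    params: dict[str, np.ndarray]
    history: TrainHistory = field(default_factory=TrainHistory)

    @classmethod
    def init(cls, n_in: int, h1: int = 64, h2: int = 32, seed: int = 0) -> "NNPGModel":
        rng = np.random.default_rng(seed)

        def u(n_out, n_inp):
            s = 1.0 / np.sqrt(n_inp)
            return rng.uniform(-s, s, (n_out, n_inp))

        # zero output layer: the untrained forecast is persistence
        return cls(
            params={
                "W1": u(h1, n_in), "b1": np.zeros(h1),
                "W2": u(h2, h1), "b2": np.zeros(h2),
                "W3": np.zeros((1, h2)), "b3": np.zeros(1),
            }
        )


def _nnpg_forward(p: dict[str, np.ndarray], X: np.ndarray):
    a1 = np.tanh(X @ p["W1"].T + p["b1"])
    a2 = np.tanh(a1 @ p["W2"].T + p["b2"])
    out = a2 @ p["W3"].T + p["b3"]      # linear output
    return out[:, 0], (a1, a2)


def nnpg_loss_and_grads(p: dict[str, np.ndarray], X: np.ndarray, y: np.ndarray):
    pred, (a1, a2) = _nnpg_forward(p, X)
    resid = pred - y
    B = len(y)
    loss = float(np.mean(resid**2))
    d3 = (2.0 * resid / B)[:, None]               # [B, 1]
    grads = {
        "W3": d3.T @ a2, "b3": d3.sum(axis=0),
    }
    d2 = (d3 @ p["W3"]) * (1 - a2**2)
    grads["W2"] = d2.T @ a1
    grads["b2"] = d2.sum(axis=0)
    d1 = (d2 @ p["W2"]) * (1 - a1**2)
    grads["W1"] = d1.T @ X
    grads["b1"] = d1.sum(axis=0)
    return loss, grads


def nnpg_train(
    train_ws: WindowSet,
    val_ws: WindowSet,
    config: TrainConfig | None = None,
) -> NNPGModel:
    """Train on ΔBG with RMSprop (lr 0.001, batch 32) and early stopping."""
    if config is None:
        config = TrainConfig(batch_size=32)
    config.validate()
    Xtr = train_ws.inputs.reshape(len(train_ws), -1)
    Xva = val_ws.inputs.reshape(len(val_ws), -1)
    model = NNPGModel.init(Xtr.shape[1], seed=config.seed)
    p = model.params
    opt = RMSprop(p, config.rmsprop_decay, config.rmsprop_epsilon)
    best = {k: v.copy() for k, v in p.items()}
    best_val, stale = np.inf, 0
    hist = model.history
    for epoch in range(config.max_epochs):
        losses = []
        for idx in batch_iter(train_ws, config.batch_size, config.seed, epoch,
                              config.shuffle):
            l, grads = nnpg_loss_and_grads(p, Xtr[idx], train_ws.labels[idx])
            if not np.isfinite(l):
                raise FloatingPointError(f"non-finite NNPG loss at epoch {epoch}")
            clip_gradients(grads, config.grad_clip_norm)
            opt.step(p, grads, config.learning_rate)
            losses.append(l)
        hist.train_loss.append(float(np.mean(losses)))
        pred, _ = _nnpg_forward(p, Xva)
        v = float(np.sqrt(np.mean((pred - val_ws.labels) ** 2)))
        hist.val_rmse.append(v)
        if v < best_val:
            best_val, stale = v, 0
            best = {k: v_.copy() for k, v_ in p.items()}
            hist.best_epoch = epoch
        else:
            stale += 1
            if stale >= config.patience:
                break
    model.params = best
    return model


def nnpg_predict(model: NNPGModel, windows: WindowSet) -> np.ndarray:
    """Absolute forecasts: predicted ΔBG + current glucose."""
    X = windows.inputs.reshape(len(windows), -1)
    pred, _ = _nnpg_forward(model.params, X)
    return pred + windows.last_glucose


# ---------------------------------------------------------------- SVR ----

@dataclass
class SVRModel:
    svr: _SkSVR
    y_mean: float
    y_scale: float


def svr_train(
    windows: WindowSet,
    C: float = 100.0,
    gamma: float = 0.01,
    epsilon: float = 0.1,
) -> SVRModel:
    """RBF-kernel SVR on standardised ΔBG targets (C=100, γ=0.01)."""
    X = windows.inputs.reshape(len(windows), -1)
    y = windows.labels
    y_mean = float(y.mean())
    y_scale = float(y.std()) or 1.0
    svr = _SkSVR(kernel="rbf", C=C, gamma=gamma, epsilon=epsilon, cache_size=1000)
    svr.fit(X, (y - y_mean) / y_scale)
    return SVRModel(svr=svr, y_mean=y_mean, y_scale=y_scale)


def svr_predict(model: SVRModel, windows: WindowSet) -> np.ndarray:
    """Absolute forecasts: predicted ΔBG + current glucose."""
    X = windows.inputs.reshape(len(windows), -1)
    delta = model.svr.predict(X) * model.y_scale + model.y_mean
    return delta + windows.last_glucose
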