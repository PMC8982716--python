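"""Dilated recurrent network for sequence-to-one glucose forecasting.

Each layer is a vanilla tanh RNN cell

    h_t = tanh(W_rec h_{t-d} + W_in x_t + b)

whose recurrent edge skips d-1 timesteps (dilation d).  Layers are
stacked with exponentially increasing dilations (default [1, 2, 4]);
layer l consumes layer l-1's output at the *same* timestep, so dilation
affects only the recurrent edge.  States before the window start are
zero.  Only the top layer's final state feeds an affine head, whose
output is the predicted glucose change ΔBG over the horizon; the
forecast is ΔBG + x_T (many-to-one regression).

Forward and backward passes are written directly in numpy: the network
is small (three layers of 32 tanh units over 12 steps), so explicit
backpropagation-through-time is both transparent and fast enough, and
its gradients are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CellParams",
    "DRNNModel",
    "vanilla_step",
    "dilated_forward",
    "forward_states",
    "predict",
    "loss_and_grads",
    "param_count",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass
class CellParams:
    """Weights of one vanilla RNN layer.

    ``W_rec`` is hidden-to-hidden (applied to the dilated state),
    ``W_in`` maps the layer input (the data for layer 1, the previous
    layer's output above), ``b`` is the bias.
    """

    W_rec: np.ndarray  # [n, n]
    W_in: np.ndarray   # [n, m]
    b: np.ndarray      # [n]

    @property
    def hidden_size(self) -> int:
        return self.W_rec.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_in.shape[1]


@dataclass
class DRNNModel:
    """Stack of dilated vanilla-RNN layers plus an affine forecast head."""

    layers: list[CellParams]
    dilations: tuple[int, ...]
    head_w: np.ndarray  # [n]
    head_b: np.ndarray  # scalar, kept as shape-(1,) array

    def __post_init__(self) -> None:
        if len(self.layers) != len(self.dilations):
            raise ValueError("one dilation per layer required")

    @classmethod
    def init(
        cls,
        input_size: int = 4,
        hidden_size: int = 32,
        dilations: tuple[int, ...] = (1, 2, 4),
        seed: int = 0,
        dtype=np.float64,
    ) -> "DRNNModel":
        """Seeded uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) weights, zero
        biases and a zero head (so the untrained forecast is persistence).

        ``dtype`` controls the working precision: float64 for exact
        gradient verification, float32 for faster large experiments.
        """
        rng = np.random.default_rng(seed)
        layers = []
        m = input_size
        for _ in dilations:
            s_in = 1.0 / np.sqrt(m)
            s_rec = 1.0 / np.sqrt(hidden_size)
            layers.append(
                CellParams(
                    W_rec=rng.uniform(
                        -s_rec, s_rec, (hidden_size, hidden_size)
                    ).astype(dtype),
                    W_in=rng.uniform(-s_in, s_in, (hidden_size, m)).astype(dtype),
                    b=np.zeros(hidden_size, dtype=dtype),
                )
            )
            m = hidden_size
        return cls(
            layers=layers,
            dilations=tuple(dilations),
            head_w=np.zeros(hidden_size, dtype=dtype),
            head_b=np.zeros(1, dtype=dtype),
        )

    def params(self) -> dict[str, np.ndarray]:
        """Flat name -> array views, shared with the optimizer."""
        out: dict[str, np.ndarray] = {}
        for i, cell in enumerate(self.layers):
            out[f"layer{i}.W_rec"] = cell.W_rec
            out[f"layer{i}.W_in"] = cell.W_in
            out[f"layer{i}.b"] = cell.b
        out["head.w"] = self.head_w
        out["head.b"] = self.head_b
        return out

    def n_params(self) -> int:
        return sum(a.size for a in self.params().values())

    def copy(self) -> "DRNNModel":
        return DRNNModel(
            layers=[
                CellParams(c.W_rec.copy(), c.W_in.copy(), c.b.copy())
                for c in self.layers
            ],
            dilations=self.dilations,
            head_w=self.head_w.copy(),
            head_b=self.head_b.copy(),
        )


def vanilla_step(cell: CellParams, h_prev: np.ndarray, x_t: np.ndarray) -> np.ndarray:
    """One vanilla-cell update h_t = tanh(W_rec h_prev + W_in x_t + b).

    Accepts single vectors or [batch, dim] arrays.
    """
    if h_prev.shape[-1] != cell.hidden_size or x_t.shape[-1] != cell.input_size:
        raise ValueError(
            f"shape mismatch: h {h_prev.shape}, x {x_t.shape} for cell "
            f"(n={cell.hidden_size}, m={cell.input_size})"
        )
    return np.tanh(h_prev @ cell.W_rec.T + x_t @ cell.W_in.T + cell.b)


def forward_states(model: DRNNModel, X: np.ndarray) -> list[np.ndarray]:
    """All hidden states for a batch: returns per-layer arrays [B, T, n].

    X is [B, T, m].  States at t - d < 0 are zero.
    """
    if X.ndim != 3:
        raise ValueError("X must be [batch, T, channels]")
    B, T, _ = X.shape
    if T < 1:
        raise ValueError("window must contain at least one timestep")
    states: list[np.ndarray] = []
    inp = X
    for cell, d in zip(model.layers, model.dilations):
        n = cell.hidden_size
        # input projection for the whole sequence in one GEMM; only the
        # dilated recurrent term needs the sequential loop
        proj = inp.reshape(B * T, -1) @ cell.W_in.T + cell.b
        proj = proj.reshape(B, T, n)
        H = np.zeros((B, T, n), dtype=proj.dtype)
        for t in range(T):
            if t - d >= 0:
                H[:, t, :] = np.tanh(proj[:, t, :] + H[:, t - d, :] @ cell.W_rec.T)
            else:
                H[:, t, :] = np.tanh(proj[:, t, :])
        states.append(H)
        inp = H
    return states


def dilated_forward(model: DRNNModel, window: np.ndarray) -> np.ndarray:
    """Top layer's final state h_T^L for a single window [T, m]."""
    states = forward_states(model, window[None, :, :])
    return states[-1][0, -1, :]


def predict(model: DRNNModel, h_top: np.ndarray, x_T_glucose) -> np.ndarray:
    """Forecast ŷ_T = (W_FC h + b_FC) + x_T; the affine part is ΔBG."""
    delta = h_top @ model.head_w + model.head_b[0]
    return delta + x_T_glucose


def predict_batch(model: DRNNModel, X: np.ndarray, x_T: np.ndarray) -> np.ndarray:
    """Forecast in mg/dL for a batch of (scaled) windows."""
    states = forward_states(model, X)
    return predict(model, states[-1][:, -1, :], x_T)


def delta_bg(model: DRNNModel, X: np.ndarray) -> np.ndarray:
    """Predicted ΔBG for a batch of windows."""
    states = forward_states(model, X)
    return states[-1][:, -1, :] @ model.head_w + model.head_b[0]


def loss_and_grads(
    model: DRNNModel, X: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean squared ΔBG error and its gradients via BPTT.

    The gradient of L = mean_b (ΔBG_b - y_b)^2 flows from the head into
    the top layer's final state, then backwards through each layer's
    dilated recurrence and down through the layer-to-layer connections.
    """
    B, T, _ = X.shape
    states = forward_states(model, X)
    h_top = states[-1][:, -1, :]
    pred = h_top @ model.head_w + model.head_b[0]
    resid = pred - y
    loss = float(np.mean(resid**2))

    grads = {k: np.zeros_like(v) for k, v in model.params().items()}
    dpred = 2.0 * resid / B  # [B]
    grads["head.w"][:] = h_top.T @ dpred
    grads["head.b"][:] = dpred.sum()

    L = len(model.layers)
    # accumulated dL/dh per layer, filled top-down
    GH = [np.zeros_like(states[l]) for l in range(L)]
    GH[-1][:, -1, :] = np.outer(dpred, model.head_w)
    for l in range(L - 1, -1, -1):
        cell, d = model.layers[l], model.dilations[l]
        inp = states[l - 1] if l > 0 else X
        A = np.empty_like(states[l])  # pre-activation gradients per step
        for t in range(T - 1, -1, -1):
            a = GH[l][:, t, :] * (1.0 - states[l][:, t, :] ** 2)  # tanh'
            A[:, t, :] = a
            if t - d >= 0:  # only the recurrent edge needs the loop
                GH[l][:, t - d, :] += a @ cell.W_rec
        n = A.shape[-1]
        if T > d:
            grads[f"layer{l}.W_rec"] += (
                A[:, d:, :].reshape(-1, n).T
                @ states[l][:, :-d, :].reshape(-1, n)
            )
        grads[f"layer{l}.W_in"] += (
            A.reshape(-1, n).T @ inp.reshape(B * T, -1)
        )
        grads[f"layer{l}.b"] += A.sum(axis=(0, 1))
        if l > 0:
            GH[l - 1] += A @ cell.W_in
    return loss, grads


def param_count(cell_type: str, n: int, m: int) -> int:
    """Parameters per recurrent state for the standard cell types.

    vanilla: n^2 + m n + n; LSTM multiplies by 4, GRU by 3.
    """
    if n < 1 or m < 1:
        raise ValueError("n and m must be >= 1")
    base = n * n + m * n + n
    factors = {"vanilla": 1, "lstm": 4, "gru": 3}
    if cell_type not in factors:
        raise ValueError(f"unknown cell type {cell_type!r}")
    return factors[cell_type] * base


def save_checkpoint(model: DRNNModel, path: str, manifest_extra: dict | None = None) -> None:
    """Write ``path.npz`` (key -> array) and ``path.json`` (manifest)."""
    np.savez(path + ".npz", **model.params())
    manifest = {
        "dilations": list(model.dilations),
        "hidden_size": model.layers[0].hidden_size,
        "input_size": model.layers[0].input_size,
        "n_layers": len(model.layers),
        "n_params": model.n_params(),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(path + ".json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def load_checkpoint(path: str) -> tuple[DRNNModel, dict]:
    with open(path + ".json") as fh:
        manifest = json.load(fh)
    arrs = np.load(path + ".npz")
    layers = [
        CellParams(
            W_rec=arrs[f"layer{i}.W_rec"],
            W_in=arrs[f"layer{i}.W_in"],
            b=arrs[f"layer{i}.b"],
        )
        for i in range(manifest["n_layers"])
    ]
    model = DRNNModel(
        layers=layers,
        dilations=tuple(manifest["dilations"]),
        head_w=arrs["head.w"],
        head_b=arrs["head.b"],
    )
    return model, manifest
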