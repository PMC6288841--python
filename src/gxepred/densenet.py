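"""Densely connected feedforward regression network, implemented from scratch.

A multilayer perceptron with ReLU hidden layers, inverted dropout during
training, mean-squared-error loss, and mini-batch Adam (or plain SGD).
Inputs are standardised per feature and targets standardised using
training-set statistics only.  Because the output layer is also ReLU,
standardised training targets are shifted to be non-negative before
training and the shift is inverted at prediction; a ``linear`` output
activation is available when negative raw outputs are preferable.

Everything — initialisation, dropout, shuffling — is driven by explicit
seeds, and the prediction path consumes no randomness at all.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z: (z > 0).astype(float)),
    "linear": (lambda z: z, lambda z: np.ones_like(z)),
}


def _act(name: str):
    try:
        return _ACTIVATIONS[name]
    except KeyError:
        raise ValueError(f"unknown activation {name!r}; choose from {sorted(_ACTIVATIONS)}") from None


@dataclass
class NetConfig:
    """Architecture and training hyperparameters.

    n_units applies to every hidden layer; dropout_rate is the fraction of
    hidden activations zeroed per training pass (0.3 by default).
    """

    n_layers: int = 1
    n_units: int = 50
    n_epochs: int = 50
    dropout_rate: float = 0.3
    hidden_activation: str = "relu"
    output_activation: str = "relu"
    batch_size: int = 32
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 1:
            raise ValueError("need at least one hidden layer")
        if self.n_units < 1:
            raise ValueError("need at least one unit per hidden layer")
        if self.n_epochs < 0:
            raise ValueError("n_epochs must be non-negative")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        _act(self.hidden_activation)
        _act(self.output_activation)
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError("optimizer must be 'adam' or 'sgd'")


@dataclass
class NetworkState:
    """Weights, biases and the standardisation applied around the raw network."""

    weights: list[np.ndarray]  # layer k: (fan_in, fan_out)
    biases: list[np.ndarray]
    hidden_activation: str
    output_activation: str
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float = 0.0
    y_scale: float = 1.0
    y_shift: float = 0.0  # applied to standardised targets so a ReLU output can reach them

    @property
    def n_features(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_hidden_layers(self) -> int:
        return len(self.weights) - 1

    def copy(self) -> "NetworkState":
        return copy.deepcopy(self)


def init_network(n_features: int, cfg: NetConfig) -> NetworkState:
    """Glorot-uniform weights, zero biases; fully determined by cfg.seed."""
    if n_features < 1:
        raise ValueError("need at least one input feature")
    rng = np.random.default_rng(cfg.seed)
    dims = [n_features] + [cfg.n_units] * cfg.n_layers + [1]
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return NetworkState(
        weights=weights,
        biases=biases,
        hidden_activation=cfg.hidden_activation,
        output_activation=cfg.output_activation,
        x_mean=np.zeros(n_features),
        x_scale=np.ones(n_features),
    )


def dropout_mask(n_units: int, rate: float, rng: np.random.Generator | int) -> np.ndarray:
    """Inverted-dropout mask: zeros with probability ``rate``, survivors scaled by 1/(1-rate)."""
    if not (0.0 <= rate < 1.0):
        raise ValueError("dropout rate must lie in [0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if rate == 0.0:
        return np.ones(n_units)
    keep = rng.random(n_units) >= rate
    return keep.astype(float) / (1.0 - rate)


def _standardize_x(state: NetworkState, X: np.ndarray) -> np.ndarray:
    return (X - state.x_mean) / state.x_scale


def _forward_raw(state: NetworkState, Xstd: np.ndarray, masks: list[np.ndarray] | None = None):
    """Forward pass in standardised space; returns per-layer caches for backprop."""
    hid_f, _ = _act(state.hidden_activation)
    out_f, _ = _act(state.output_activation)
    A = Xstd
    pre, post = [], []
    for k in range(state.n_hidden_layers):
        Z = A @ state.weights[k] + state.biases[k]
        A = hid_f(Z)
        if masks is not None:
            if masks[k].shape[-1] != A.shape[-1]:
                raise ValueError(
                    f"dropout mask for layer {k} has {masks[k].shape[-1]} units, layer has {A.shape[-1]}"
                )
            A = A * masks[k]
        pre.append(Z)
        post.append(A)
    Zout = A @ state.weights[-1] + state.biases[-1]
    return out_f(Zout), pre, post, Zout


def forward(state: NetworkState, x: np.ndarray, dropout_masks: list[np.ndarray] | None = None) -> np.ndarray | float:
    """Predict on a feature vector (or row matrix), de-standardising the output.

    ``dropout_masks`` — one mask per hidden layer — are only ever supplied
    during training; prediction runs maskless and deterministic.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != state.n_features:
        raise ValueError(f"expected {state.n_features} features, got {X.shape[1]}")
    if dropout_masks is not None and len(dropout_masks) != state.n_hidden_layers:
        raise ValueError("need one dropout mask per hidden layer")
    out, *_ = _forward_raw(state, _standardize_x(state, X), dropout_masks)
    y = (out[:, 0] - state.y_shift) * state.y_scale + state.y_mean
    return float(y[0]) if single else y


def _loss_and_grads(state: NetworkState, Xstd: np.ndarray, z: np.ndarray, masks=None):
    """MSE loss and analytic gradients in standardised space (the backprop core)."""
    _, hid_d = _act(state.hidden_activation)
    _, out_d = _act(state.output_activation)
    nb = Xstd.shape[0]
    out, pre, post, Zout = _forward_raw(state, Xstd, masks)
    err = out[:, 0] - z
    loss = float(np.mean(err**2))
    dZout = (2.0 / nb) * err[:, None] * out_d(Zout)
    gW = [None] * len(state.weights)
    gb = [None] * len(state.biases)
    A_last = post[-1] if post else Xstd
    gW[-1] = A_last.T @ dZout
    gb[-1] = dZout.sum(axis=0)
    dA = dZout @ state.weights[-1].T
    for k in range(state.n_hidden_layers - 1, -1, -1):
        if masks is not None:
            dA = dA * masks[k]
        dZ = dA * hid_d(pre[k])
        A_in = post[k - 1] if k > 0 else Xstd
        gW[k] = A_in.T @ dZ
        gb[k] = dZ.sum(axis=0)
        dA = dZ @ state.weights[k].T
    return loss, gW, gb


def train_network(
    state: NetworkState, X: np.ndarray, y: np.ndarray, cfg: NetConfig
) -> tuple[NetworkState, list[float]]:
    """Mini-batch gradient descent on MSE for exactly cfg.n_epochs epochs.

    Returns a trained copy of ``state`` plus the per-epoch mean training
    loss (standardised scale).  Per-epoch shuffling and all dropout masks
    come from one generator seeded with cfg.seed, so the whole schedule is
    reproducible and a longer run prefixes a shorter one.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X rows must match the length of y")
    if X.shape[0] == 0:
        raise ValueError("empty training set")
    if cfg.n_epochs == 0:
        return state, []
    st = state.copy()
    st.x_mean = X.mean(axis=0)
    scale = X.std(axis=0)
    st.x_scale = np.where(scale > 0, scale, 1.0)
    st.y_mean = float(y.mean())
    ysd = float(y.std())
    st.y_scale = ysd if ysd > 0 else 1.0
    z = (y - st.y_mean) / st.y_scale
    if st.output_activation == "relu":
        st.y_shift = max(0.0, -float(z.min()))
        z = z + st.y_shift
    else:
        st.y_shift = 0.0
    Xstd = _standardize_x(st, X)

    rng = np.random.default_rng(cfg.seed)
    lr = cfg.learning_rate
    if cfg.optimizer == "adam":
        b1, b2, eps = 0.9, 0.999, 1e-8
        mW = [np.zeros_like(w) for w in st.weights]
        vW = [np.zeros_like(w) for w in st.weights]
        mb = [np.zeros_like(b) for b in st.biases]
        vb = [np.zeros_like(b) for b in st.biases]
        t = 0
    trace: list[float] = []
    n = X.shape[0]
    for _epoch in range(cfg.n_epochs):
        order = rng.permutation(n)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            masks = None
            if cfg.dropout_rate > 0:
                masks = [
                    np.stack([dropout_mask(cfg.n_units, cfg.dropout_rate, rng) for _ in batch])
                    for _ in range(st.n_hidden_layers)
                ]
            loss, gW, gb = _loss_and_grads(st, Xstd[batch], z[batch], masks)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}; lower the learning rate"
                )
            if cfg.optimizer == "adam":
                t += 1
                for k in range(len(st.weights)):
                    mW[k] = b1 * mW[k] + (1 - b1) * gW[k]
                    vW[k] = b2 * vW[k] + (1 - b2) * gW[k] ** 2
                    mb[k] = b1 * mb[k] + (1 - b1) * gb[k]
                    vb[k] = b2 * vb[k] + (1 - b2) * gb[k] ** 2
                    mw_hat = mW[k] / (1 - b1**t)
                    vw_hat = vW[k] / (1 - b2**t)
                    mb_hat = mb[k] / (1 - b1**t)
                    vb_hat = vb[k] / (1 - b2**t)
                    st.weights[k] -= lr * mw_hat / (np.sqrt(vw_hat) + eps)
                    st.biases[k] -= lr * mb_hat / (np.sqrt(vb_hat) + eps)
            else:
                for k in range(len(st.weights)):
                    st.weights[k] -= lr * gW[k]
                    st.biases[k] -= lr * gb[k]
            epoch_loss += loss
            n_batches += 1
        trace.append(epoch_loss / n_batches)
    return st, trace


def predict_net(state: NetworkState, X: np.ndarray) -> np.ndarray:
    """Deterministic forward pass without dropout, on the original target scale."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    return np.asarray(forward(state, X))
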