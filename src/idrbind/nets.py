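"""Small numpy neural networks for per-residue binary classification.

Two architectures are provided:

* :class:`MLP` — the production model: one hidden layer with ReLU (and
  optional inverted dropout), a single sigmoid output unit, trained with
  binary cross-entropy.  With a 1025-dimensional input (ProtT5 embedding
  plus disorder bit) and 612 hidden units this is the published
  architecture.
* :class:`ConvNet` — an experimental 1-D convolutional variant operating
  on whole proteins (two same-padded conv layers, per-residue linear
  head).

Both expose ``predict_proba`` (deterministic, dropout off) and
``loss_and_grads`` for the :class:`Adam` optimizer.  Weight
initialisation is uniform with fan-in scaling and fully seeded, making
training bit-reproducible on one machine.  Losses are computed from
logits (log-sum-exp form) for numerical stability.
"""

from __future__ import annotations

import numpy as np

__all__ = ["MLP", "ConvNet", "Adam", "bce_from_logits"]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy computed stably from logits."""
    # softplus(z) - y*z == -[y*log p + (1-y)*log(1-p)]
    sp = np.logaddexp(0.0, logits)
    return float(np.mean(sp - y * logits))


def _fan_in_uniform(rng: np.random.Generator, fan_in: int, shape) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Adam:
    """Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MLP:
    """input -> hidden (ReLU, optional dropout) -> 1 (sigmoid)."""

    def __init__(self, input_dim: int, hidden_units: int,
                 dropout: float = 0.0, rng: np.random.Generator | None = None):
        if not (0.0 <= dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        rng = rng or np.random.default_rng()
        self.input_dim = input_dim
        self.hidden_units = hidden_units
        self.dropout = dropout
        self.params: dict[str, np.ndarray] = {
            "W1": _fan_in_uniform(rng, input_dim, (input_dim, hidden_units)),
            "b1": _fan_in_uniform(rng, input_dim, hidden_units),
            "W2": _fan_in_uniform(rng, hidden_units, (hidden_units, 1)),
            "b2": _fan_in_uniform(rng, hidden_units, 1),
        }

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def logits(self, X: np.ndarray, *, train: bool = False,
               rng: np.random.Generator | None = None) -> np.ndarray:
        h = np.maximum(X @ self.params["W1"] + self.params["b1"], 0.0)
        if train and self.dropout > 0.0:
            keep = rng.random(h.shape) >= self.dropout
            h = h * keep / (1.0 - self.dropout)
        return (h @ self.params["W2"] + self.params["b2"]).ravel()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Per-residue binding probabilities; deterministic (dropout off)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"feature width {X.shape[1] if X.ndim == 2 else X.shape} "
                f"does not match input_dim {self.input_dim}"
            )
        return _sigmoid(self.logits(X))

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """BCE loss and gradients on one residue batch (dropout active)."""
        n = X.shape[0]
        z1 = X @ self.params["W1"] + self.params["b1"]
        h = np.maximum(z1, 0.0)
        drop_scale = None
        if self.dropout > 0.0:
            keep = rng.random(h.shape) >= self.dropout
            drop_scale = keep / (1.0 - self.dropout)
            h = h * drop_scale
        logits = (h @ self.params["W2"] + self.params["b2"]).ravel()
        loss = bce_from_logits(logits, y)
        dlogits = (_sigmoid(logits) - y)[:, None] / n
        grads = {
            "W2": h.T @ dlogits,
            "b2": dlogits.sum(axis=0),
        }
        dh = dlogits @ self.params["W2"].T
        if drop_scale is not None:
            dh = dh * drop_scale
        dz1 = dh * (z1 > 0)
        grads["W1"] = X.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        return loss, grads

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()


def _conv1d_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Same-padded 1-D convolution: x (L, Cin), W (k, Cin, Cout) -> (L, Cout)."""
    k = W.shape[0]
    pad = k // 2
    xp = np.pad(x, ((pad, k - 1 - pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=0)  # (L, Cin, k)
    return np.einsum("lik,kio->lo", windows, W) + b


def _conv1d_backward(x: np.ndarray, W: np.ndarray, dy: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    k = W.shape[0]
    pad = k // 2
    xp = np.pad(x, ((pad, k - 1 - pad), (0, 0)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, k, axis=0)
    dW = np.einsum("lik,lo->kio", windows, dy)
    db = dy.sum(axis=0)
    # dx: full correlation of dy with W
    dyp = np.pad(dy, ((k - 1 - pad, pad), (0, 0)))
    dy_windows = np.lib.stride_tricks.sliding_window_view(dyp, k, axis=0)  # (L, Cout, k)
    Wf = W[::-1]  # flip taps
    dx = np.einsum("lok,kio->li", dy_windows, Wf)
    return dx, dW, db


class ConvNet:
    """Two same-padded 1-D conv layers + per-residue linear head (sigmoid).

    Operates on one protein at a time (``L x input_dim``).  Experimental:
    kept for the architecture comparison, not the production model.
    """

    def __init__(self, input_dim: int, channels: tuple[int, int] = (128, 32),
                 kernel_size: int = 5, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        c1, c2 = channels
        k = kernel_size
        self.input_dim = input_dim
        self.kernel_size = k
        self.channels = channels
        self.params: dict[str, np.ndarray] = {
            "W1": _fan_in_uniform(rng, input_dim * k, (k, input_dim, c1)),
            "b1": np.zeros(c1),
            "W2": _fan_in_uniform(rng, c1 * k, (k, c1, c2)),
            "b2": np.zeros(c2),
            "W3": _fan_in_uniform(rng, c2, (c2, 1)),
            "b3": np.zeros(1),
        }

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def _forward(self, X: np.ndarray):
        p = self.params
        z1 = _conv1d_forward(X, p["W1"], p["b1"])
        h1 = np.maximum(z1, 0.0)
        z2 = _conv1d_forward(h1, p["W2"], p["b2"])
        h2 = np.maximum(z2, 0.0)
        logits = (h2 @ p["W3"] + p["b3"]).ravel()
        return z1, h1, z2, h2, logits

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError("feature width does not match input_dim")
        return _sigmoid(self._forward(X)[-1])

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None,
                       mask: np.ndarray | None = None
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """BCE on one protein; optional per-residue mask restricts the loss."""
        p = self.params
        z1, h1, z2, h2, logits = self._forward(X)
        if mask is None:
            w = np.ones_like(y)
        else:
            w = np.asarray(mask, dtype=float)
            if w.sum() == 0:
                raise ValueError("loss mask selects no residues")
        total = w.sum()
        sp = np.logaddexp(0.0, logits)
        loss = float(np.sum(w * (sp - y * logits)) / total)
        dlogits = (w * (_sigmoid(logits) - y))[:, None] / total
        grads = {"W3": h2.T @ dlogits, "b3": dlogits.sum(axis=0)}
        dh2 = dlogits @ p["W3"].T
        dz2 = dh2 * (z2 > 0)
        dh1, grads["W2"], grads["b2"] = _conv1d_backward(h1, p["W2"], dz2)
        dz1 = dh1 * (z1 > 0)
        _, grads["W1"], grads["b1"] = _conv1d_backward(X, p["W1"], dz1)
        return loss, grads

    def get_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = state[k].copy()
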