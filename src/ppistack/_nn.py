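"""Minimal NumPy neural-network layers with explicit forward/backward passes.

Each layer keeps its parameters in ``self.params`` and accumulates gradients
in ``self.grads`` (same keys). ``forward`` caches whatever ``backward``
needs; layers are therefore stateful within one forward/backward pair.
Shapes follow the batch-first convention: sequences are ``(B, L, C)``.

The gradient implementations are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Linear",
    "BatchNorm1d",
    "ReLU",
    "Dropout",
    "Conv1dSame",
    "MaxPool1dSame",
    "MaskedMultiHeadAttention",
    "Adam",
    "sigmoid",
]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def zero_grad(self) -> None:
        for k in self.params:
            self.grads[k] = np.zeros_like(self.params[k])


class Linear(Layer):
    """Affine map ``y = x W^T + b`` on the trailing axis."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 scale: float | None = None) -> None:
        super().__init__()
        std = scale if scale is not None else np.sqrt(2.0 / d_in)
        self.params = {
            "W": rng.normal(0.0, std, size=(d_out, d_in)),
            "b": np.zeros(d_out),
        }
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] += dy.T @ self._x
        self.grads["b"] += dy.sum(axis=0)
        return dy @ self.params["W"]


class BatchNorm1d(Layer):
    """Batch normalization over the batch axis of ``(B, C)`` inputs.

    Training mode normalizes by batch statistics and updates running
    moments; evaluation mode uses the running moments (standard inference
    behavior).
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.params = {"gamma": np.ones(dim), "beta": np.zeros(dim)}
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps
        self.zero_grad()

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv_std
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        self.grads["gamma"] += (dy * xhat).sum(axis=0)
        self.grads["beta"] += dy.sum(axis=0)
        g = dy * self.params["gamma"]
        if not self._training:
            return g * inv_std
        return inv_std * (g - g.mean(axis=0) - xhat * (g * xhat).mean(axis=0))


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; active only when a training rng is supplied."""

    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        if rng is None or self.rate == 0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Conv1dSame(Layer):
    """1-D convolution, stride 1, zero padding preserving sequence length.

    Input ``(B, L, C_in)`` -> output ``(B, L, C_out)``. The kernel weight
    has shape ``(k, C_in, C_out)``.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        if kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd for symmetric same-padding")
        std = np.sqrt(2.0 / (c_in * kernel_size))
        self.params = {
            "W": rng.normal(0.0, std, size=(kernel_size, c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.k = kernel_size
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] == 0:
            raise ValueError("empty sequence")
        B, L, C = x.shape
        p = self.k // 2
        xp = np.zeros((B, L + 2 * p, C))
        xp[:, p : p + L] = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.k,), axis=1)
        # win: (B, L, C, k) -> einsum over kernel and input channels
        self._win = win
        self._shape = (B, L, C, p)
        return np.einsum("blck,kco->blo", win, self.params["W"]) + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C, p = self._shape
        self.grads["W"] += np.einsum("blck,blo->kco", self._win, dy)
        self.grads["b"] += dy.sum(axis=(0, 1))
        dxp = np.zeros((B, L + 2 * p, C))
        W = self.params["W"]
        for kk in range(self.k):
            dxp[:, kk : kk + L] += np.einsum("blo,co->blc", dy, W[kk])
        return dxp[:, p : p + L]


class MaxPool1dSame(Layer):
    """Max pooling along the sequence, stride 1, length-preserving padding."""

    def __init__(self, size: int) -> None:
        super().__init__()
        if size % 2 == 0:
            raise ValueError("pool size must be odd for symmetric same-padding")
        self.size = size

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, L, C = x.shape
        p = self.size // 2
        xp = np.full((B, L + 2 * p, C), -np.inf)
        xp[:, p : p + L] = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (self.size,), axis=1)
        self._argmax = win.argmax(axis=3)  # (B, L, C)
        self._shape = (B, L, C, p)
        return win.max(axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, L, C, p = self._shape
        dxp = np.zeros((B, L + 2 * p, C))
        for kk in range(self.size):
            sel = self._argmax == kk
            dxp[:, kk : kk + L] += dy * sel
        return dxp[:, p : p + L]


class MaskedMultiHeadAttention(Layer):
    """Multi-head self-attention with a large-penalty mask on padded keys.

    Per head ``h``: queries/keys/values are linear projections of the input
    rows, energies are ``K Q^T / sqrt(d_m)`` with ``-penalty`` added at
    padded key positions, weights are the softmax over keys (each output
    position's weights sum to 1), and the head output is the
    weight-averaged values. Head outputs are concatenated without a final
    output projection.
    """

    def __init__(self, d_model: int, n_heads: int, head_dim: int,
                 rng: np.random.Generator, penalty: float = 1e9) -> None:
        super().__init__()
        std = 1.0 / np.sqrt(d_model)
        self.params = {
            name: rng.normal(0.0, std, size=(n_heads, head_dim, d_model))
            for name in ("Wq", "Wk", "Wv")
        }
        self.n_heads, self.head_dim, self.penalty = n_heads, head_dim, penalty
        self.zero_grad()

    def forward(self, z: np.ndarray, pad_mask: np.ndarray) -> np.ndarray:
        if pad_mask.all(axis=1).any():
            raise ValueError("a sample has all positions padded")
        Wq, Wk, Wv = self.params["Wq"], self.params["Wk"], self.params["Wv"]
        Q = np.einsum("hmd,bld->bhlm", Wq, z)
        K = np.einsum("hmd,bld->bhlm", Wk, z)
        V = np.einsum("hmd,bld->bhlm", Wv, z)
        scale = 1.0 / np.sqrt(self.head_dim)
        # E[b,h,i,j]: energy of key position i for query position j
        E = np.einsum("bhim,bhjm->bhij", K, Q) * scale
        E = E - self.penalty * pad_mask[:, None, :, None]
        E -= E.max(axis=2, keepdims=True)
        expE = np.exp(E)
        W = expE / expE.sum(axis=2, keepdims=True)  # softmax over keys i
        H = np.einsum("bhij,bhim->bhjm", W, V)  # (B, H, L, d_m)
        B, L = z.shape[0], z.shape[1]
        self._cache = (z, Q, K, V, W, scale)
        self.last_weights = W
        return H.transpose(0, 2, 1, 3).reshape(B, L, self.n_heads * self.head_dim)

    def backward(self, dA: np.ndarray) -> np.ndarray:
        z, Q, K, V, W, scale = self._cache
        B, L, _ = z.shape
        dH = dA.reshape(B, L, self.n_heads, self.head_dim).transpose(0, 2, 1, 3)
        dV = np.einsum("bhij,bhjm->bhim", W, dH)
        dW = np.einsum("bhjm,bhim->bhij", dH, V)
        # softmax backward along the key axis i
        dE = W * (dW - (W * dW).sum(axis=2, keepdims=True))
        dK = np.einsum("bhij,bhjm->bhim", dE, Q) * scale
        dQ = np.einsum("bhij,bhim->bhjm", dE, K) * scale
        for name, dP, P in (("Wq", dQ, Q), ("Wk", dK, K), ("Wv", dV, V)):
            self.grads[name] += np.einsum("bhlm,bld->hmd", dP, z)
        dz = (
            np.einsum("bhlm,hmd->bld", dQ, self.params["Wq"])
            + np.einsum("bhlm,hmd->bld", dK, self.params["Wk"])
            + np.einsum("bhlm,hmd->bld", dV, self.params["Wv"])
        )
        return dz


class Adam:
    """Adam with the standard default moments (0.9, 0.999, eps 1e-8)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [ly for ly in layers if ly.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for ly, m, v in zip(self.layers, self.m, self.v):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m[k] = self.beta1 * m[k] + (1 - self.beta1) * g
                v[k] = self.beta2 * v[k] + (1 - self.beta2) * g * g
                p -= self.lr * (m[k] / b1t) / (np.sqrt(v[k] / b2t) + self.eps)

    def zero_grad(self) -> None:
        for ly in self.layers:
            ly.zero_grad()
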