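"""The base site-prediction network.

One base classifier processes the hybrid feature of a residue along two
paths. The context path runs the windowed context matrix ``f_ctx`` through
a three-stage convolution block (1-D conv, kernel 5, same padding -> ReLU
-> max pool, size 3, stride 1, same padding; 8 kernels per stage), then a
masked multi-head self-attention (4 heads, 16 dims per head) whose padded
key positions receive a large negative energy penalty, concatenates the
conv output and attention output rowwise and average-pools over the
non-padded positions into ``f_agg`` (dim 8 + 4*16 = 72). The targeted
residue feature ``f_tr`` passes through untouched and is concatenated with
``f_agg`` into the protein representation ``f_prot``, which the predictor
head (FC 1024 -> batch norm -> ReLU -> dropout 0.5 -> FC 256 -> batch norm
-> ReLU -> dropout -> FC 1 -> sigmoid) maps to an interaction-site
probability.

Padded context rows are zeroed at entry, masked out of the attention and
excluded from the average pooling, so the output is invariant to their
content.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._nn import (
    Adam,
    BatchNorm1d,
    Conv1dSame,
    Dropout,
    Linear,
    MaskedMultiHeadAttention,
    MaxPool1dSame,
    ReLU,
    sigmoid,
)
from .features import FFMOD_DIMS

__all__ = ["PPINetConfig", "SiteNet"]

#: energy penalty added at padded attention keys
MASK_PENALTY = 1e9


@dataclass
class PPINetConfig:
    """Architecture hyperparameters of one base network.

    The defaults are the reference configuration: 3 convolution stages with
    kernel size 5 and 8 kernels each, pool size 3 (stride 1), 4 attention
    heads of dimension 16, fully connected sizes 1024/256/1, dropout 0.5.
    ``use_attention=False`` gives the convolution-only ablation (no
    attention); ``n_heads=1`` gives the single-head ablation.
    """

    ffmod: int = 0
    window: int = 32
    conv_layers: int = 3
    kernel_size: int = 5
    n_kernels: int = 8
    pool_size: int = 3
    n_heads: int = 4
    head_dim: int = 16
    fc_sizes: tuple[int, ...] = (1024, 256, 1)
    dropout_rate: float = 0.5
    use_attention: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ffmod not in FFMOD_DIMS:
            raise ValueError(f"ffmod must be 0, 1 or 2, got {self.ffmod}")
        if self.window < 1:
            raise ValueError("window half-width must be >= 1")
        if self.fc_sizes[-1] != 1:
            raise ValueError("final fully connected layer must have 1 unit")

    @property
    def input_dim(self) -> int:
        """Dimension of f_tr (and of each context row)."""
        return FFMOD_DIMS[self.ffmod]

    @property
    def agg_dim(self) -> int:
        """Dimension of f_agg: conv channels plus concatenated heads."""
        if not self.use_attention:
            return self.n_kernels
        return self.n_kernels + self.n_heads * self.head_dim

    @property
    def predictor_input_dim(self) -> int:
        return self.agg_dim + self.input_dim


class SiteNet:
    """A trained (or trainable) base classifier; parameters in NumPy arrays."""

    def __init__(self, config: PPINetConfig) -> None:
        self.config = config
        rng = np.random.default_rng(config.seed)
        c = config
        self.conv_stages = []
        c_in = c.input_dim
        for _ in range(c.conv_layers):
            self.conv_stages.append(
                (Conv1dSame(c_in, c.n_kernels, c.kernel_size, rng), ReLU(),
                 MaxPool1dSame(c.pool_size))
            )
            c_in = c.n_kernels
        self.attention = (
            MaskedMultiHeadAttention(c.n_kernels, c.n_heads, c.head_dim, rng,
                                     penalty=MASK_PENALTY)
            if c.use_attention
            else None
        )
        self.fc = []
        d_in = c.predictor_input_dim
        for i, d_out in enumerate(c.fc_sizes):
            last = i == len(c.fc_sizes) - 1
            self.fc.append(
                {
                    "linear": Linear(d_in, d_out, rng, scale=0.01 if last else None),
                    "bn": None if last else BatchNorm1d(d_out),
                    "relu": None if last else ReLU(),
                    "dropout": None if last else Dropout(c.dropout_rate),
                }
            )
            d_in = d_out
        self.trained = False

    # --- layer bookkeeping ------------------------------------------------

    def layers(self) -> list:
        out = []
        for conv, relu, pool in self.conv_stages:
            out += [conv, relu, pool]
        if self.attention is not None:
            out.append(self.attention)
        for blk in self.fc:
            out += [ly for ly in blk.values() if ly is not None]
        return out

    # --- forward components (usable standalone) ---------------------------

    def conv_block_forward(self, f_ctx: np.ndarray) -> np.ndarray:
        """Context matrix ``(B, L, d_in)`` -> conv features ``(B, L, D)``."""
        x = np.asarray(f_ctx, dtype=float)
        squeeze = x.ndim == 2
        if squeeze:
            x = x[None]
        for conv, relu, pool in self.conv_stages:
            x = pool.forward(relu.forward(conv.forward(x)))
        return x[0] if squeeze else x

    def masked_multihead_attention(self, Z: np.ndarray, pad_mask: np.ndarray) -> np.ndarray:
        """Conv features ``(B, L, D)`` -> concatenated head outputs."""
        if self.attention is None:
            raise RuntimeError("this model was built without attention")
        Z = np.asarray(Z, dtype=float)
        squeeze = Z.ndim == 2
        if squeeze:
            Z, pad_mask = Z[None], np.asarray(pad_mask, bool)[None]
        A = self.attention.forward(Z, np.asarray(pad_mask, bool))
        return A[0] if squeeze else A

    @staticmethod
    def aggregate(Z: np.ndarray, A: np.ndarray | None, pad_mask: np.ndarray) -> np.ndarray:
        """Rowwise concat of conv and attention features, then the mean over
        non-padded rows."""
        Z = np.asarray(Z, dtype=float)
        squeeze = Z.ndim == 2
        if squeeze:
            Z = Z[None]
            A = None if A is None else np.asarray(A, float)[None]
            pad_mask = np.asarray(pad_mask, bool)[None]
        S = Z if A is None else np.concatenate([Z, A], axis=2)
        valid = ~np.asarray(pad_mask, bool)
        n_valid = valid.sum(axis=1)
        if (n_valid == 0).any():
            raise ValueError("a sample has no non-padded rows")
        f_agg = (S * valid[:, :, None]).sum(axis=1) / n_valid[:, None]
        return f_agg[0] if squeeze else f_agg

    def predictor_forward(
        self,
        f_prot: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        return_logit: bool = False,
    ) -> np.ndarray:
        """Protein representation -> interaction-site probability."""
        x = np.asarray(f_prot, dtype=float)
        squeeze = x.ndim == 1
        if squeeze:
            x = x[None]
        if x.shape[1] != self.config.predictor_input_dim:
            raise ValueError(
                f"predictor input dim {x.shape[1]} != {self.config.predictor_input_dim}"
            )
        for blk in self.fc:
            x = blk["linear"].forward(x)
            if blk["bn"] is not None:
                x = blk["bn"].forward(x, training)
                x = blk["relu"].forward(x)
                x = blk["dropout"].forward(x, rng if training else None)
        logit = x[:, 0]
        out = logit if return_logit else sigmoid(logit)
        return out[0] if squeeze else out

    def forward(
        self,
        f_ctx: np.ndarray,
        pad_mask: np.ndarray,
        f_tr: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        return_logit: bool = False,
    ) -> np.ndarray:
        """Full forward pass on a batch ``(B, 2W+1, d)`` -> probabilities ``(B,)``."""
        f_ctx = np.asarray(f_ctx, dtype=float)
        pad_mask = np.asarray(pad_mask, dtype=bool)
        f_tr = np.asarray(f_tr, dtype=float)
        squeeze = f_ctx.ndim == 2
        if squeeze:
            f_ctx, pad_mask, f_tr = f_ctx[None], pad_mask[None], f_tr[None]
        if f_tr.shape[1] != self.config.input_dim:
            raise ValueError(
                f"f_tr dim {f_tr.shape[1]} does not match ffmod {self.config.ffmod} "
                f"(expected {self.config.input_dim})"
            )
        # padded rows carry no content into the conv receptive field
        f_ctx = f_ctx * ~pad_mask[:, :, None]
        self._valid = ~pad_mask
        Z = self.conv_block_forward(f_ctx)
        A = self.attention.forward(Z, pad_mask) if self.attention is not None else None
        f_agg = self.aggregate(Z, A, pad_mask)
        f_prot = np.concatenate([f_agg, f_tr], axis=1)
        out = self.predictor_forward(f_prot, training=training, rng=rng,
                                     return_logit=return_logit)
        return out[0] if squeeze else out

    def predict(self, f_ctx, pad_mask, f_tr, batch_size: int = 1024) -> np.ndarray:
        """Evaluation-mode probabilities, computed in mini-batches."""
        outs = []
        for k in range(0, len(f_tr), batch_size):
            outs.append(self.forward(f_ctx[k : k + batch_size],
                                     pad_mask[k : k + batch_size],
                                     f_tr[k : k + batch_size]))
        return np.concatenate(outs) if outs else np.empty(0)

    # --- training step ----------------------------------------------------

    def loss_and_grads(
        self,
        f_ctx: np.ndarray,
        pad_mask: np.ndarray,
        f_tr: np.ndarray,
        y: np.ndarray,
        rng: np.random.Generator,
        eps: float = 1e-7,
    ) -> float:
        """One training-mode forward/backward; gradients accumulate in layers."""
        y = np.asarray(y, dtype=float)
        logit = self.forward(f_ctx, pad_mask, f_tr, training=True, rng=rng,
                             return_logit=True)
        p = sigmoid(logit)
        pc = np.clip(p, eps, 1 - eps)
        loss = float(-np.mean(y * np.log(pc) + (1 - y) * np.log(1 - pc)))
        dlogit = (p - y) / len(y)
        self._backward(dlogit)
        return loss

    def _backward(self, dlogit: np.ndarray) -> None:
        dx = dlogit[:, None]
        for blk in reversed(self.fc):
            if blk["bn"] is not None:
                dx = blk["dropout"].backward(dx)
                dx = blk["relu"].backward(dx)
                dx = blk["bn"].backward(dx)
            dx = blk["linear"].backward(dx)
        d_agg = dx[:, : self.config.agg_dim]
        valid = self._valid
        n_valid = valid.sum(axis=1)
        dS = (d_agg[:, None, :] / n_valid[:, None, None]) * valid[:, :, None]
        D = self.config.n_kernels
        dZ = dS[:, :, :D].copy()
        if self.attention is not None:
            dA = dS[:, :, D:]
            dZ += self.attention.backward(np.ascontiguousarray(dA))
        for conv, relu, pool in reversed(self.conv_stages):
            dZ = conv.backward(relu.backward(pool.backward(dZ)))

    def make_optimizer(self, lr: float = 1e-3) -> Adam:
        return Adam(self.layers(), lr=lr)

    # --- serialization ----------------------------------------------------

    def save(self, path) -> None:
        """Write parameters plus the embedded config to an ``.npz`` checkpoint."""
        import json

        arrays = {}
        for i, ly in enumerate(self.layers()):
            for k, v in ly.params.items():
                arrays[f"layer{i}:{k}"] = v
            if isinstance(ly, BatchNorm1d):
                arrays[f"layer{i}:running_mean"] = ly.running_mean
                arrays[f"layer{i}:running_var"] = ly.running_var
        cfg = asdict(self.config)
        cfg["fc_sizes"] = list(cfg["fc_sizes"])
        np.savez(path, __config__=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "SiteNet":
        import json

        data = np.load(path)
        cfg = json.loads(bytes(data["__config__"]).decode())
        cfg["fc_sizes"] = tuple(cfg["fc_sizes"])
        net = cls(PPINetConfig(**cfg))
        for i, ly in enumerate(net.layers()):
            for k in ly.params:
                ly.params[k] = data[f"layer{i}:{k}"]
            if isinstance(ly, BatchNorm1d):
                ly.running_mean = data[f"layer{i}:running_mean"]
                ly.running_var = data[f"layer{i}:running_var"]
        net.trained = True
        return net
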