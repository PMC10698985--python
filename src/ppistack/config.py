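"""Default hyperparameter configuration and YAML config loading.

The defaults mirror the reference settings: encoder dimensions (Seq 20,
Den 20, PhyChem 21, HyIn 2, PSSM 20, K-PseAA 30 with max correlation level
10), the network (3 conv stages, kernel 5, 8 kernels, pool 3, 4 heads of
dim 16, FC 1024/256/1, dropout 0.5) and training (Adam, lr 0.001, batch
64, max epoch 50, decision threshold 0.5).
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

__all__ = ["default_config", "load_config"]

_DEFAULTS = {
    "features": {
        "window": 32,
        "encoders": {
            "Seq": {"dimension": 20},
            "Den": {"dimension": 20},
            "PhyChem": {"dimension": 21},
            "HyIn": {"dimension": 2},
            "PSSM": {"dimension": 20},
            "K-PseAA": {"dimension": 30, "max_correlation_level": 10, "K": 10, "w": 0.05},
        },
    },
    "model": {
        "conv_layers": 3,
        "kernel_size": [5, 5, 5],
        "n_kernels": [8, 8, 8],
        "conv_strides": [1, 1, 1],
        "pool_size": [3, 3, 3],
        "pool_strides": [1, 1, 1],
        "n_heads": 4,
        "head_dim": 16,
        "fc_sizes": [1024, 256, 1],
        "fc_activations": ["ReLU", "ReLU", "Sigmoid"],
        "dropout_rate": 0.5,
    },
    "training": {
        "optimizer": "adam",
        "learning_rate": 0.001,
        "batch_size": 64,
        "max_epochs": 50,
        "trailing_window": 3,
        "patience": 5,
        "threshold": 0.5,
    },
    "stacking": {"rule": "logistic_regression", "n_base_models": 3},
}


def default_config() -> dict:
    return copy.deepcopy(_DEFAULTS)


def _merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        cfg = _merge(cfg, user)
    return cfg
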