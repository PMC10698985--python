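"""Training loop for one base network: loss, early stopping, round-robin
balanced subsets with per-epoch subsampling.

Training minimizes the mean binary cross-entropy with Adam. Each epoch
draws one of the M balanced subsets (round-robin) and subsamples its
negatives down to the positive count, shuffles, and steps over mini-batches
of 64. Validation loss is monitored after every epoch; training stops when
the trailing-3-epoch mean validation loss has strictly increased for 5
consecutive epochs, or at the epoch cap (50 by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .balancing import BalancedSubsetPlan, build_balanced_subsets, epoch_subsample
from .features import featurize_dataset
from .io import ProteinRecord
from .model import PPINetConfig, SiteNet

__all__ = [
    "TrainConfig",
    "cross_entropy_loss",
    "early_stop_check",
    "train_ppinet",
]


@dataclass
class TrainConfig:
    """Optimizer and stopping-rule settings (reference defaults)."""

    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 50
    trailing_window: int = 3
    patience: int = 5
    threshold: float = 0.5
    seed: int = 0
    balance: bool = True


def cross_entropy_loss(y, y_pred, eps: float = 1e-7) -> float:
    """Mean binary cross-entropy; predictions clipped to [eps, 1-eps]."""
    y = np.asarray(y, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_pred.shape}")
    p = np.clip(y_pred, eps, 1 - eps)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def early_stop_check(
    loss_history,
    max_epochs: int = 50,
    trailing_window: int = 3,
    patience: int = 5,
) -> bool:
    """True when the trailing-window mean loss has strictly increased for
    ``patience`` consecutive epochs, or the epoch cap is reached.

    Ties do not count as increases.
    """
    history = list(loss_history)
    if len(history) >= max_epochs:
        return True
    if len(history) < trailing_window + patience:
        return False
    means = [
        float(np.mean(history[t - trailing_window + 1 : t + 1]))
        for t in range(trailing_window - 1, len(history))
    ]
    recent = means[-(patience + 1) :]
    return all(b > a for a, b in zip(recent, recent[1:]))


def _eval_loss(net: SiteNet, data, batch_size: int = 2048) -> float:
    ctx, mask, tr, y = data
    preds = net.predict(ctx, mask, tr, batch_size=batch_size)
    return cross_entropy_loss(y, preds)


def train_ppinet(
    train_records: list[ProteinRecord],
    ffmod: int,
    plan: BalancedSubsetPlan | None = None,
    config: TrainConfig | None = None,
    net_config: PPINetConfig | None = None,
    val_records: list[ProteinRecord] | None = None,
    log_path: str | Path | None = None,
) -> tuple[SiteNet, dict]:
    """Train one base network on the residues of ``train_records``.

    ``plan=None`` with ``config.balance=True`` builds the balanced-subset
    plan from the training labels; with ``config.balance=False`` every
    epoch uses the full (imbalanced) training set. Validation records, when
    given, drive the early-stopping rule; otherwise the training loss is
    monitored. Fully deterministic for a fixed seed.
    """
    if not train_records:
        raise ValueError("empty training set")
    config = config or TrainConfig()
    net_config = net_config or PPINetConfig(ffmod=ffmod, seed=config.seed)
    if net_config.ffmod != ffmod:
        raise ValueError("net_config.ffmod disagrees with ffmod argument")

    tr, ctx, mask, y, _ = featurize_dataset(train_records, net_config.window, ffmod)
    train_data = (ctx, mask, tr, y)
    if config.balance and plan is None:
        plan = build_balanced_subsets(y, seed=config.seed)
    subsets = plan.subsets if plan is not None else None

    val_data = None
    if val_records:
        vtr, vctx, vmask, vy, _ = featurize_dataset(val_records, net_config.window, ffmod)
        val_data = (vctx, vmask, vtr, vy)

    net = SiteNet(net_config)
    optimizer = net.make_optimizer(lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA11CE]))

    history: dict = {"train_loss": [], "val_loss": [], "monitor_loss": [],
                     "subset_id": [], "stopped_epoch": None}
    log_rows = []
    for epoch in range(config.max_epochs):
        if subsets is not None:
            subset_id = epoch % len(subsets)
            idx = epoch_subsample(subsets[subset_id], y, config.seed, epoch)
        else:
            subset_id = -1
            idx = np.arange(len(y))
        idx = rng.permutation(idx)
        epoch_losses = []
        for k in range(0, len(idx), config.batch_size):
            b = idx[k : k + config.batch_size]
            if len(b) < 2:
                continue  # batch statistics need at least two samples
            optimizer.zero_grad()
            loss = net.loss_and_grads(ctx[b], mask[b], tr[b], y[b], rng)
            optimizer.step()
            epoch_losses.append(loss)
        train_loss = float(np.mean(epoch_losses))
        val_loss = _eval_loss(net, val_data) if val_data else None
        monitor = val_loss if val_loss is not None else train_loss
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        history["monitor_loss"].append(monitor)
        history["subset_id"].append(subset_id)
        stop = early_stop_check(
            history["monitor_loss"],
            max_epochs=config.max_epochs,
            trailing_window=config.trailing_window,
            patience=config.patience,
        )
        log_rows.append((epoch, subset_id, train_loss, val_loss, stop))
        if stop:
            break
    history["stopped_epoch"] = len(history["train_loss"]) - 1
    net.trained = True

    if log_path is not None:
        with Path(log_path).open("w") as fh:
            fh.write("epoch\tsubset_id\ttrain_loss\tval_loss\tstop\n")
            for epoch, sid, tl, vl, stop in log_rows:
                vl_s = "" if vl is None else f"{vl:.6f}"
                fh.write(f"{epoch}\t{sid}\t{tl:.6f}\t{vl_s}\t{int(stop)}\n")
    return net, history
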