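"""Majority-class partitioning for imbalanced site labels.

Non-interaction sites (the majority class) are shuffled and split into
``M = max(1, floor(n_neg / n_pos))`` near-equal parts. Each part combined
with all interaction sites forms one training subset whose
negative/positive ratio is strictly below 2 whenever ``n_neg >= n_pos``.
Training cycles through the subsets round-robin, one per epoch, and each
epoch additionally subsamples the subset's negatives down to the positive
count, so after M epochs every negative has been eligible once while every
positive has been seen M times.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "BalancedSubsetPlan",
    "compute_partition_count",
    "build_balanced_subsets",
    "epoch_subsample",
    "export_plan_tsv",
]


def compute_partition_count(n_neg: int, n_pos: int) -> int:
    """Number of majority-class parts, ``max(1, floor(n_neg / n_pos))``.

    Flooring (rather than rounding up) keeps every per-subset
    negative/positive ratio below 2: each part has at most
    ``ceil(n_neg / M) <= n_neg/M + 1 < 2 * n_pos`` negatives.
    """
    if n_pos < 1:
        raise ValueError("need at least one positive sample")
    return max(1, n_neg // n_pos)


@dataclass
class BalancedSubsetPlan:
    """M disjoint negative parts and the M training subsets they induce."""

    M: int
    positives: np.ndarray
    negative_parts: list[np.ndarray]
    seed: int

    def __post_init__(self) -> None:
        sizes = [len(p) for p in self.negative_parts]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("negative part sizes must differ by at most 1")
        flat = np.concatenate(self.negative_parts) if self.negative_parts else np.empty(0)
        if len(np.unique(flat)) != len(flat):
            raise ValueError("negative parts overlap")

    @property
    def subsets(self) -> list[np.ndarray]:
        """Subset m = all positives + negative part m."""
        return [np.concatenate([self.positives, part]) for part in self.negative_parts]


def build_balanced_subsets(labels, seed: int = 0) -> BalancedSubsetPlan:
    """Shuffle negatives with ``seed`` and split them into M near-equal parts."""
    labels = np.asarray(labels)
    positives = np.flatnonzero(labels == 1)
    negatives = np.flatnonzero(labels == 0)
    if len(positives) == 0 or len(negatives) == 0:
        raise ValueError("both classes must be present to build balanced subsets")
    M = compute_partition_count(len(negatives), len(positives))
    rng = np.random.default_rng(seed)
    shuffled = rng.permutation(negatives)
    parts = [np.sort(p) for p in np.array_split(shuffled, M)]
    return BalancedSubsetPlan(M=M, positives=positives, negative_parts=parts, seed=seed)


def epoch_subsample(subset: np.ndarray, labels, seed: int, epoch: int) -> np.ndarray:
    """Subsample a subset's negatives (without replacement) to the positive
    count; all positives are retained. The draw differs per epoch."""
    labels = np.asarray(labels)
    subset = np.asarray(subset)
    pos = subset[labels[subset] == 1]
    neg = subset[labels[subset] == 0]
    if len(neg) > len(pos):
        rng = np.random.default_rng(np.random.SeedSequence([seed, epoch]))
        neg = rng.choice(neg, size=len(pos), replace=False)
    return np.concatenate([pos, neg])


def export_plan_tsv(plan: BalancedSubsetPlan, path) -> None:
    """Audit export: one row per (sample index, subset id, role)."""
    with Path(path).open("w") as fh:
        fh.write("sample_index\tsubset_id\trole\n")
        for m, part in enumerate(plan.negative_parts):
            for idx in plan.positives:
                fh.write(f"{idx}\t{m}\tpositive\n")
            for idx in part:
                fh.write(f"{idx}\t{m}\tnegative\n")
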