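"""Synthetic labeled protein datasets with a planted interaction motif.

The generator emulates the shape of interaction-site benchmarks: many
sequences, a minority of residues labeled 1, labels attached per residue.
Sequences are drawn from a background residue distribution (uniform by
default); a short motif is planted at seeded non-overlapping positions at
a rate tuned to the target positive prevalence, residues covered by a
planted motif are labeled 1, and labels are then flipped independently
with a configurable noise rate. Mock PSSMs give motif positions an
elevated log-odds score for the motif residue over a noisy near-zero
background, and serialize to the PSI-BLAST ASCII layout that the PSSM
parser reads back.

What this emulates — a learnable sequence-local signal at a controlled
class imbalance — is what the pipeline's mechanism tests need; it does not
emulate structural context, evolutionary profiles, or the label
correlations of real interfaces.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._tables import AA_INDEX, AMINO_ACIDS
from .io import ProteinRecord, write_labeled_sequences, write_pssm

__all__ = ["SyntheticConfig", "generate_dataset", "generate_mock_pssm", "write_dataset_files"]


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic benchmark.

    Defaults: 200 sequences of 60-120 residues, a 5-residue motif, uniform
    background, 15% target positive prevalence (the imbalance regime of
    typical interaction-site benchmarks, ~10-18% positives), no label
    noise, and an 8-point PSSM signal at motif positions.

    ``decoy_motif_ratio`` plants additional *unlabeled* motif occurrences
    (that many per labeled one). Decoys make the positive class genuinely
    ambiguous — the feature pattern alone no longer determines the label —
    which is the regime where class-prior rebalancing matters; without
    them the planted signal is separable enough that balanced and
    unbalanced training converge to the same recall.
    """

    n_sequences: int = 200
    length_range: tuple[int, int] = (60, 120)
    motif: str = "WCHKR"
    background: np.ndarray | None = None
    target_prevalence: float = 0.15
    noise_rate: float = 0.0
    decoy_motif_ratio: float = 0.0
    pssm_signal: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.target_prevalence < 0.5:
            raise ValueError("target_prevalence must be in (0, 0.5)")
        if not set(self.motif) <= set(AMINO_ACIDS):
            raise ValueError("motif must use standard residues")
        if len(self.motif) >= self.length_range[0]:
            raise ValueError("motif must be shorter than the minimum sequence length")
        if not 0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must be in [0, 0.5)")
        if self.decoy_motif_ratio < 0:
            raise ValueError("decoy_motif_ratio must be >= 0")
        if self.background is not None:
            self.background = np.asarray(self.background, dtype=float)
            if self.background.shape != (20,) or not np.isclose(self.background.sum(), 1.0):
                raise ValueError("background must be a 20-vector summing to 1")


def generate_dataset(config: SyntheticConfig) -> list[ProteinRecord]:
    """Generate labeled records; fully reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    background = (
        config.background if config.background is not None else np.full(20, 1 / 20)
    )
    k = len(config.motif)
    records = []
    for n in range(config.n_sequences):
        L = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
        seq = rng.choice(list(AMINO_ACIDS), size=L, p=background)
        labels = np.zeros(L, dtype=np.int8)
        # expected motif count so that coverage matches the target prevalence
        target = config.target_prevalence * L / k
        n_motifs = int(np.floor(target)) + int(rng.random() < target % 1)
        d_target = config.decoy_motif_ratio * n_motifs
        n_decoys = int(np.floor(d_target)) + int(rng.random() < d_target % 1)
        occupied = np.zeros(L, dtype=bool)
        placed = placed_decoys = 0
        for _ in range(50 * max(1, n_motifs + n_decoys)):
            if placed == n_motifs and placed_decoys == n_decoys:
                break
            start = int(rng.integers(0, L - k + 1))
            if occupied[max(0, start - k + 1) : start + k].any():
                continue
            seq[start : start + k] = list(config.motif)
            occupied[start : start + k] = True
            if placed < n_motifs:
                labels[start : start + k] = 1
                placed += 1
            else:
                placed_decoys += 1  # unlabeled decoy occurrence
        if config.noise_rate > 0:
            flips = rng.random(L) < config.noise_rate
            labels[flips] = 1 - labels[flips]
        records.append(ProteinRecord(f"syn{n:04d}", "".join(seq), labels))
    return records


def generate_mock_pssm(
    record: ProteinRecord,
    config: SyntheticConfig,
    path: str | Path | None = None,
) -> np.ndarray:
    """Integer mock PSSM: noisy near-zero background, with the motif
    residue's column boosted by ``config.pssm_signal`` at planted motif
    positions (located by scanning for the motif string). Optionally
    serialized to PSI-BLAST ASCII at ``path``.
    """
    rec_key = zlib.crc32(record.id.encode()) & 0x7FFFFFFF
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, rec_key]))
    L = len(record)
    matrix = rng.integers(-2, 3, size=(L, 20)).astype(float)
    k = len(config.motif)
    start = record.sequence.find(config.motif)
    while start != -1:
        for off, aa in enumerate(config.motif):
            matrix[start + off, AA_INDEX[aa]] += round(config.pssm_signal)
        start = record.sequence.find(config.motif, start + k)
    if path is not None:
        write_pssm(matrix, record.sequence, path)
    return matrix


def attach_mock_pssms(records: list[ProteinRecord], config: SyntheticConfig) -> None:
    """Set ``record.pssm`` in place for every record."""
    for rec in records:
        rec.pssm = generate_mock_pssm(rec, config)


def write_dataset_files(config: SyntheticConfig, outdir: str | Path) -> Path:
    """Write a triplet-format dataset plus one PSSM file per record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = generate_dataset(config)
    write_labeled_sequences(records, outdir / "dataset.txt", format="triplet")
    pssm_dir = outdir / "pssm"
    pssm_dir.mkdir(exist_ok=True)
    for rec in records:
        generate_mock_pssm(rec, config, path=pssm_dir / f"{rec.id}.pssm")
    return outdir
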