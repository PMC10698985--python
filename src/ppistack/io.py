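"""Reading and writing sequences, per-residue labels, PSSMs and predictions.

Two on-disk dataset layouts are supported:

* ``triplet`` — three lines per record: a ``>id`` header, the sequence, and a
  string of ``'0'``/``'1'`` per-residue labels (``1`` marks an interaction
  site).
* ``fasta+tsv`` — a FASTA file plus a two-column TSV mapping record id to the
  label string.

PSSMs are read from PSI-BLAST ASCII output (the first 20 log-odds columns).
Non-standard residue letters other than ``'X'`` are rejected at read time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from ._tables import ALPHABET

__all__ = [
    "ProteinRecord",
    "DatasetSplit",
    "MalformedRecordError",
    "read_labeled_sequences",
    "write_labeled_sequences",
    "parse_pssm",
    "write_pssm",
    "split_dataset",
    "write_predictions",
    "site_counts",
    "interaction_site_percentage",
]


class MalformedRecordError(ValueError):
    """An input record violates the format contract."""


@dataclass
class ProteinRecord:
    """A protein sequence with per-residue binary interaction-site labels.

    ``labels[i] == 1`` means residue ``i`` lies in an interaction interface.
    ``pssm``, when present, holds one 20-score row per residue.
    """

    id: str
    sequence: str
    labels: np.ndarray
    pssm: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int8)
        bad = set(self.sequence) - set(ALPHABET)
        if bad:
            raise MalformedRecordError(
                f"record {self.id!r}: non-standard residue letters {sorted(bad)}"
            )
        if len(self.labels) != len(self.sequence):
            raise MalformedRecordError(
                f"record {self.id!r}: {len(self.labels)} labels for "
                f"{len(self.sequence)} residues"
            )
        if not np.isin(self.labels, (0, 1)).all():
            raise MalformedRecordError(f"record {self.id!r}: labels must be 0/1")
        if self.pssm is not None:
            self.pssm = np.asarray(self.pssm, dtype=float)
            if self.pssm.shape != (len(self.sequence), 20):
                raise MalformedRecordError(
                    f"record {self.id!r}: PSSM shape {self.pssm.shape} does not "
                    f"match ({len(self.sequence)}, 20)"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DatasetSplit:
    """Sequence-level split: every record id is in exactly one part."""

    train: list[str]
    validation: list[str]
    test: list[str]
    ratio: tuple[int, int, int] = (3, 1, 1)

    def __post_init__(self) -> None:
        parts = [self.train, self.validation, self.test]
        ids = [i for part in parts for i in part]
        if len(ids) != len(set(ids)):
            raise ValueError("split parts overlap or contain duplicate ids")


def _labels_from_string(label_str: str, rec_id: str, seq: str) -> np.ndarray:
    if len(label_str) != len(seq):
        raise MalformedRecordError(
            f"record {rec_id!r}: label string length {len(label_str)} != "
            f"sequence length {len(seq)}"
        )
    if set(label_str) - {"0", "1"}:
        raise MalformedRecordError(f"record {rec_id!r}: labels must be '0'/'1'")
    return np.frombuffer(label_str.encode(), dtype=np.uint8) - ord("0")


def read_labeled_sequences(
    path: str | Path,
    format: str = "triplet",
    labels_path: str | Path | None = None,
) -> list[ProteinRecord]:
    """Read labeled sequences from ``triplet`` or ``fasta+tsv`` layout.

    For ``fasta+tsv``, ``labels_path`` defaults to ``<path>.labels.tsv``.
    """
    path = Path(path)
    if format == "triplet":
        return _read_triplet(path)
    if format == "fasta+tsv":
        labels_path = (
            Path(labels_path) if labels_path else path.with_suffix(path.suffix + ".labels.tsv")
        )
        return _read_fasta_tsv(path, labels_path)
    raise ValueError(f"unknown format {format!r}; expected 'triplet' or 'fasta+tsv'")


def _read_triplet(path: Path) -> list[ProteinRecord]:
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    lines = [ln for ln in lines if ln.strip()]
    if len(lines) % 3:
        raise MalformedRecordError(
            f"{path}: {len(lines)} non-empty lines; triplet files have 3 per record"
        )
    records = []
    for k in range(0, len(lines), 3):
        header, seq, labels = lines[k], lines[k + 1].strip(), lines[k + 2].strip()
        if not header.startswith(">"):
            raise MalformedRecordError(f"{path}: expected '>' header, got {header!r}")
        rec_id = header[1:].split()[0]
        records.append(
            ProteinRecord(rec_id, seq, _labels_from_string(labels, rec_id, seq))
        )
    return records


def _read_fasta_tsv(fasta_path: Path, labels_path: Path) -> list[ProteinRecord]:
    label_map: dict[str, str] = {}
    for ln in Path(labels_path).read_text().splitlines():
        if not ln.strip() or ln.startswith("#"):
            continue
        rec_id, label_str = ln.split("\t")[:2]
        label_map[rec_id] = label_str.strip()
    records = []
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(seq_rec.seq).upper()
        if seq_rec.id not in label_map:
            raise MalformedRecordError(f"record {seq_rec.id!r}: no labels in {labels_path}")
        records.append(
            ProteinRecord(
                seq_rec.id, seq, _labels_from_string(label_map[seq_rec.id], seq_rec.id, seq)
            )
        )
    return records


def write_labeled_sequences(
    records: Iterable[ProteinRecord],
    path: str | Path,
    format: str = "triplet",
    labels_path: str | Path | None = None,
) -> None:
    """Write records in the layout read back by :func:`read_labeled_sequences`."""
    path = Path(path)
    records = list(records)
    if format == "triplet":
        with path.open("w") as fh:
            for rec in records:
                labels = "".join(str(int(v)) for v in rec.labels)
                fh.write(f">{rec.id}\n{rec.sequence}\n{labels}\n")
    elif format == "fasta+tsv":
        labels_path = (
            Path(labels_path) if labels_path else path.with_suffix(path.suffix + ".labels.tsv")
        )
        with path.open("w") as fh:
            for rec in records:
                fh.write(f">{rec.id}\n{rec.sequence}\n")
        with Path(labels_path).open("w") as fh:
            for rec in records:
                fh.write(f"{rec.id}\t" + "".join(str(int(v)) for v in rec.labels) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


# --- PSI-BLAST ASCII PSSM -------------------------------------------------

_PSSM_ROW = re.compile(r"^\s*(\d+)\s+([A-Za-z*-])\s+(.*)$")


def parse_pssm(path: str | Path) -> np.ndarray:
    """Parse a PSI-BLAST ASCII PSSM into an ``L x 20`` log-odds matrix.

    Only the first 20 score columns are kept; the weighted-frequency block
    and the trailing statistics are ignored. Rows must be consecutively
    numbered from 1.
    """
    rows: list[list[float]] = []
    expected_idx = 1
    for line in Path(path).read_text().splitlines():
        m = _PSSM_ROW.match(line)
        if not m:
            if rows and line.strip() == "":
                break  # end of the matrix block
            continue
        idx = int(m.group(1))
        if idx != expected_idx:
            raise MalformedRecordError(
                f"{path}: residue rows not consecutive at row {idx} "
                f"(expected {expected_idx})"
            )
        fields = m.group(3).split()
        if len(fields) < 20:
            raise MalformedRecordError(
                f"{path}: row {idx} has {len(fields)} score columns, expected >= 20"
            )
        try:
            rows.append([float(v) for v in fields[:20]])
        except ValueError as exc:
            raise MalformedRecordError(f"{path}: non-numeric cell in row {idx}") from exc
        expected_idx += 1
    if not rows:
        raise MalformedRecordError(f"{path}: no PSSM rows found")
    return np.asarray(rows, dtype=float)


def write_pssm(matrix: np.ndarray, sequence: str, path: str | Path) -> None:
    """Serialize an ``L x 20`` score matrix in PSI-BLAST ASCII layout."""
    matrix = np.asarray(matrix)
    if matrix.shape != (len(sequence), 20):
        raise ValueError(f"matrix shape {matrix.shape} does not match sequence")
    from ._tables import AMINO_ACIDS

    header = (
        "\nLast position-specific scoring matrix computed, weighted, ignoring "
        "sequence weights\n"
        "            " + "  ".join(AMINO_ACIDS) + "\n"
    )
    with Path(path).open("w") as fh:
        fh.write(header)
        for i, (aa, row) in enumerate(zip(sequence, matrix), start=1):
            scores = " ".join(f"{v:6.0f}" if float(v).is_integer() else f"{v:8.3f}" for v in row)
            fh.write(f"{i:5d} {aa}  {scores}\n")
        fh.write("\n                      K         Lambda\n")
        fh.write("Standard Ungapped    0.1347     0.3176\n")


# --- splitting ------------------------------------------------------------


def split_dataset(
    records: Sequence[ProteinRecord],
    ratio: tuple[int, int, int] = (3, 1, 1),
    seed: int = 0,
) -> DatasetSplit:
    """Random seeded sequence-level train/validation/test split.

    Sequences are shuffled, floor-sized buckets are filled in order
    train, validation, test, and the remainders go to train first, so no
    part deviates from the exact ratio by more than one sequence. All
    residues of one sequence land in the same part (no residue leakage).
    """
    n = len(records)
    total = sum(ratio)
    if n < len(ratio):
        raise ValueError(f"need at least {len(ratio)} records, got {n}")
    rng = np.random.default_rng(seed)
    ids = [rec.id for rec in records]
    if len(set(ids)) != n:
        raise ValueError("duplicate record ids")
    order = rng.permutation(n)
    sizes = [n * r // total for r in ratio]
    for i in range(n - sum(sizes)):
        sizes[i % 3] += 1
    shuffled = [ids[i] for i in order]
    train = shuffled[: sizes[0]]
    val = shuffled[sizes[0] : sizes[0] + sizes[1]]
    test = shuffled[sizes[0] + sizes[1] :]
    return DatasetSplit(train=train, validation=val, test=test, ratio=tuple(ratio))


def write_predictions(
    path: str | Path,
    rows: Iterable[tuple[str, int, float, int]],
) -> None:
    """Write per-residue predictions as TSV: id, position (0-based), score, call."""
    with Path(path).open("w") as fh:
        fh.write("id\tposition\tscore\tcall\n")
        for rec_id, pos, score, call in rows:
            fh.write(f"{rec_id}\t{pos}\t{score:.6f}\t{call}\n")


def site_counts(records: Iterable[ProteinRecord]) -> tuple[int, int]:
    """Return (n_interaction_sites, n_non_interaction_sites)."""
    n_pos = n_neg = 0
    for rec in records:
        p = int(rec.labels.sum())
        n_pos += p
        n_neg += len(rec) - p
    return n_pos, n_neg


def interaction_site_percentage(n_pos: int, n_neg: int) -> float:
    """Interaction sites as a percentage of all residues."""
    total = n_pos + n_neg
    if total == 0:
        raise ValueError("no residues")
    return 100.0 * n_pos / total
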