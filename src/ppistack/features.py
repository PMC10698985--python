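"""Per-residue feature encoders, their pairwise combinations, and
sliding-window context extraction.

Six encoders are implemented:

========  ====  =============================================================
name      dim   description
========  ====  =============================================================
Seq       20    one-hot over the 20 standard residues
Den       20    entropy density: -p_u log2 p_u of each residue's whole-
                sequence frequency (the same vector for every position)
PhyChem   21    physicochemical property lookup (bundled table)
HyIn      2     hydrophilicity / hydropathy index lookup
PSSM      20    PSSM row squashed by the logistic function
K-PseAA   30    pseudo amino acid composition of the length-(2K+1)
                subsequence centred on the target: 20 composition terms plus
                lambda sequence-order correlation terms
========  ====  =============================================================

The encoders are combined in three fixed pairs ("feature-forming modules"):
ffmod 0 = Seq + Den (dim 40), ffmod 1 = PhyChem + HyIn (dim 23),
ffmod 2 = PSSM + K-PseAA (dim 50). For each residue the targeted-residue
vector ``f_tr`` and the windowed context matrix ``f_ctx`` (rows = residues
``i-W .. i+W``, zero rows with a pad mask beyond the sequence ends) are
produced. ``'X'`` encodes as zeros everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tables import AA_INDEX, ALPHABET, AMINO_ACIDS, hyin_table, phychem_table, pseaa_property_table
from .io import ProteinRecord

__all__ = [
    "EncoderSpec",
    "ResidueFeatureSet",
    "FFMOD_DIMS",
    "FFMOD_ENCODERS",
    "encode_one_hot",
    "encode_entropy_density",
    "encode_phychem",
    "encode_hyin",
    "encode_pssm_row",
    "encode_kpseaa",
    "build_targeted_feature",
    "build_context_matrix",
    "featurize_record",
    "featurize_dataset",
]

#: encoder pairs of the three feature-forming modules, in fixed order
FFMOD_ENCODERS = {0: ("Seq", "Den"), 1: ("PhyChem", "HyIn"), 2: ("PSSM", "K-PseAA")}
#: dimension of f_tr per ffmod
FFMOD_DIMS = {0: 40, 1: 23, 2: 50}

ENCODER_DIMS = {"Seq": 20, "PSSM": 20, "Den": 20, "PhyChem": 21, "HyIn": 2, "K-PseAA": 30}


@dataclass
class EncoderSpec:
    """Name, output dimension and parameters of one encoder."""

    name: str
    dimension: int
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in ENCODER_DIMS:
            raise ValueError(f"unknown encoder {self.name!r}")
        if self.name == "K-PseAA":
            lam = self.parameters.get("lambda", 10)
            if self.dimension != 20 + lam:
                raise ValueError("K-PseAA dimension must be 20 + lambda")
        elif self.dimension != ENCODER_DIMS[self.name]:
            raise ValueError(f"{self.name} dimension must be {ENCODER_DIMS[self.name]}")


@dataclass
class ResidueFeatureSet:
    """Hybrid feature of one residue: targeted vector plus windowed context."""

    ffmod_index: int
    f_tr: np.ndarray
    f_ctx: np.ndarray
    pad_mask: np.ndarray
    target_position: int

    def __post_init__(self) -> None:
        if not np.array_equal(self.f_ctx[self.target_position], self.f_tr):
            raise ValueError("context row at target_position must equal f_tr")


def _check_residue(residue: str) -> None:
    if residue not in ALPHABET:
        raise ValueError(f"residue {residue!r} outside alphabet {ALPHABET!r}")


def encode_one_hot(residue: str) -> np.ndarray:
    """20-D unit indicator in alphabetical residue order; 'X' -> zeros."""
    _check_residue(residue)
    vec = np.zeros(20)
    if residue != "X":
        vec[AA_INDEX[residue]] = 1.0
    return vec


def encode_entropy_density(sequence: str) -> np.ndarray:
    """Whole-sequence entropy density: component u is -p_u log2 p_u.

    p_u is the frequency of residue u over the full sequence (zero terms
    for absent residues). The same vector is attached to every position.
    """
    if not sequence:
        raise ValueError("empty sequence")
    counts = np.zeros(20)
    for ch in sequence:
        _check_residue(ch)
        if ch != "X":
            counts[AA_INDEX[ch]] += 1
    p = counts / len(sequence)
    out = np.zeros(20)
    nz = p > 0
    out[nz] = -p[nz] * np.log2(p[nz])
    return out


def encode_phychem(residue: str) -> np.ndarray:
    """21-D physicochemical property lookup (standardized columns)."""
    _check_residue(residue)
    if residue == "X":
        return np.zeros(21)
    return phychem_table()[AA_INDEX[residue]].copy()


def encode_hyin(residue: str) -> np.ndarray:
    """2-D hydrophilicity / hydropathy lookup (standardized columns)."""
    _check_residue(residue)
    if residue == "X":
        return np.zeros(2)
    return hyin_table()[AA_INDEX[residue]].copy()


def encode_pssm_row(pssm: np.ndarray, i: int) -> np.ndarray:
    """Row ``i`` of the PSSM squashed elementwise by the logistic function."""
    pssm = np.asarray(pssm, dtype=float)
    if not 0 <= i < pssm.shape[0]:
        raise IndexError(f"row {i} out of range for PSSM with {pssm.shape[0]} rows")
    return 1.0 / (1.0 + np.exp(-pssm[i]))


def encode_kpseaa(
    sequence: str,
    i: int,
    K: int = 10,
    lam: int = 10,
    w: float = 0.05,
) -> np.ndarray:
    """Pseudo amino acid composition of the subsequence centred on residue i.

    The subsequence spans ``sequence[max(0, i-K) .. min(end, i+K)]`` (length
    at most 2K+1). Components 1..20 are ``f_u / (sum f + w * sum theta)``;
    components 20+j are ``w * theta_j / (sum f + w * sum theta)``, where
    ``theta_j`` averages the squared property differences
    :math:`\\Theta(R_t, R_{t+j})` of the three standardized scales
    (hydrophobicity, hydrophilicity, side-chain mass) over all pairs j
    apart. ``theta_j`` is clamped to 0 when the subsequence is shorter than
    j+1. 'X' residues are dropped from the subsequence before computing.
    """
    if K < 1 or lam < 1 or w <= 0:
        raise ValueError("require K >= 1, lambda >= 1, w > 0")
    if not 0 <= i < len(sequence):
        raise IndexError(f"position {i} out of range")
    sub = sequence[max(0, i - K) : min(len(sequence), i + K + 1)]
    idx = np.array([AA_INDEX[ch] for ch in sub if ch != "X"], dtype=int)
    out = np.zeros(20 + lam)
    if idx.size == 0:
        return out  # all-unknown subsequence: zeros by the 'X' policy
    props = pseaa_property_table()[idx]  # (L_s, 3)
    L_s = idx.size
    freqs = np.bincount(idx, minlength=20) / L_s
    thetas = np.zeros(lam)
    for j in range(1, lam + 1):
        if j < L_s:
            diffs = props[j:] - props[:-j]
            thetas[j - 1] = np.mean(np.sum(diffs**2, axis=1) / 3.0)
    denom = 1.0 + w * thetas.sum()
    out[:20] = freqs / denom
    out[20:] = w * thetas / denom
    return out


def _residue_features(record: ProteinRecord, ffmod: int, kpseaa_params: dict) -> np.ndarray:
    """Per-residue feature matrix [L x dim(f_tr)] for one ffmod."""
    if ffmod not in FFMOD_ENCODERS:
        raise ValueError(f"ffmod must be 0, 1 or 2, got {ffmod}")
    L = len(record)
    seq = record.sequence
    if ffmod == 0:
        den = encode_entropy_density(seq)
        left = np.stack([encode_one_hot(ch) for ch in seq])
        right = np.tile(den, (L, 1))
    elif ffmod == 1:
        left = np.stack([encode_phychem(ch) for ch in seq])
        right = np.stack([encode_hyin(ch) for ch in seq])
    else:
        if record.pssm is None:
            raise ValueError(
                f"record {record.id!r}: ffmod 2 requires a PSSM (missing feature)"
            )
        left = 1.0 / (1.0 + np.exp(-record.pssm))
        right = np.stack([encode_kpseaa(seq, i, **kpseaa_params) for i in range(L)])
    return np.concatenate([left, right], axis=1)


def build_targeted_feature(
    record: ProteinRecord,
    i: int,
    ffmod: int,
    kpseaa_params: dict | None = None,
) -> np.ndarray:
    """Concatenated pair feature of residue ``i`` for the given ffmod."""
    if not 0 <= i < len(record):
        raise IndexError(f"position {i} out of range for record {record.id!r}")
    params = kpseaa_params or {}
    seq, ch = record.sequence, record.sequence[i]
    if ffmod == 0:
        return np.concatenate([encode_one_hot(ch), encode_entropy_density(seq)])
    if ffmod == 1:
        return np.concatenate([encode_phychem(ch), encode_hyin(ch)])
    if ffmod == 2:
        if record.pssm is None:
            raise ValueError(f"record {record.id!r}: ffmod 2 requires a PSSM")
        return np.concatenate([encode_pssm_row(record.pssm, i), encode_kpseaa(seq, i, **params)])
    raise ValueError(f"ffmod must be 0, 1 or 2, got {ffmod}")


def build_context_matrix(
    record: ProteinRecord,
    i: int,
    W: int,
    ffmod: int,
    kpseaa_params: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Window of targeted features for residues ``i-W .. i+W``.

    Returns ``(f_ctx, pad_mask)`` where positions beyond either sequence end
    are zero rows with ``pad_mask`` True.
    """
    if W < 1:
        raise ValueError("window half-width W must be >= 1")
    if not 0 <= i < len(record):
        raise IndexError(f"position {i} out of range for record {record.id!r}")
    F = _residue_features(record, ffmod, kpseaa_params or {})
    L, d = F.shape
    ctx = np.zeros((2 * W + 1, d))
    mask = np.ones(2 * W + 1, dtype=bool)
    lo, hi = max(0, i - W), min(L, i + W + 1)
    ctx[lo - (i - W) : hi - (i - W)] = F[lo:hi]
    mask[lo - (i - W) : hi - (i - W)] = False
    return ctx, mask


def featurize_record(
    record: ProteinRecord,
    W: int,
    ffmod: int,
    kpseaa_params: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized featurization of every residue of one record.

    Returns ``(f_tr [L x d], f_ctx [L x (2W+1) x d], pad_mask [L x (2W+1)])``.
    """
    F = _residue_features(record, ffmod, kpseaa_params or {})
    L, d = F.shape
    padded = np.zeros((L + 2 * W, d))
    padded[W : W + L] = F
    windows = np.lib.stride_tricks.sliding_window_view(padded, (2 * W + 1,), axis=0)
    ctx = np.ascontiguousarray(windows.transpose(0, 2, 1))  # (L, 2W+1, d)
    pos = np.arange(L)[:, None] + np.arange(-W, W + 1)[None, :]
    mask = (pos < 0) | (pos >= L)
    return F, ctx, mask


def featurize_dataset(
    records: list[ProteinRecord],
    W: int,
    ffmod: int,
    kpseaa_params: dict | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[tuple[str, int]]]:
    """Stack per-residue features of many records into flat sample arrays.

    Returns ``(f_tr, f_ctx, pad_mask, labels, index)`` where ``index`` maps
    each flat sample to ``(record_id, position)``.
    """
    trs, ctxs, masks, ys, index = [], [], [], [], []
    for rec in records:
        tr, ctx, mask = featurize_record(rec, W, ffmod, kpseaa_params)
        trs.append(tr)
        ctxs.append(ctx)
        masks.append(mask)
        ys.append(rec.labels)
        index.extend((rec.id, i) for i in range(len(rec)))
    return (
        np.concatenate(trs),
        np.concatenate(ctxs),
        np.concatenate(masks),
        np.concatenate(ys).astype(np.int8),
        index,
    )
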