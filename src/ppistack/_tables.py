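"""Residue alphabet and bundled property tables.

The tables are configuration, not logic: they are loaded once, validated
structurally (shape, finiteness) and cached. Property values are standard
published scales; see the header of each TSV for sources.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np

#: The 20 standard amino acids in fixed alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Letters accepted in input sequences. 'X' (unknown residue) is retained
#: and encoded as all-zeros by every encoder.
ALPHABET = AMINO_ACIDS + "X"


class TableError(RuntimeError):
    """A bundled property table is missing or malformed."""


def _load_table(name: str, n_cols: int) -> np.ndarray:
    try:
        text = resources.files("ppistack.data").joinpath(name).read_text()
    except FileNotFoundError as exc:  # pragma: no cover - packaging error
        raise TableError(f"bundled table {name!r} not found") from exc
    rows = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        parts = line.split("\t")
        rows[parts[0]] = [float(v) for v in parts[1:]]
    arr = np.full((20, n_cols), np.nan)
    for aa, values in rows.items():
        if aa not in AA_INDEX:
            raise TableError(f"unknown residue {aa!r} in {name}")
        if len(values) != n_cols:
            raise TableError(
                f"row {aa!r} of {name} has {len(values)} columns, expected {n_cols}"
            )
        arr[AA_INDEX[aa]] = values
    if not np.isfinite(arr).all():
        raise TableError(f"table {name} has missing or non-finite entries")
    return arr


@functools.lru_cache(maxsize=None)
def phychem_table(standardized: bool = True) -> np.ndarray:
    """20x21 physicochemical property table; columns z-scored by default."""
    arr = _load_table("phychem21.tsv", 21)
    if standardized:
        arr = (arr - arr.mean(axis=0)) / arr.std(axis=0)
    return arr


@functools.lru_cache(maxsize=None)
def hyin_table(standardized: bool = True) -> np.ndarray:
    """20x2 hydrophilicity / hydropathy table; columns z-scored by default."""
    arr = _load_table("hyin.tsv", 2)
    if standardized:
        arr = (arr - arr.mean(axis=0)) / arr.std(axis=0)
    return arr


@functools.lru_cache(maxsize=None)
def pseaa_property_table() -> np.ndarray:
    """20x3 (hydrophobicity, hydrophilicity, side-chain mass), each scale
    standardized to zero mean and unit population variance over the 20
    residues, as in the classical pseudo amino acid composition."""
    arr = _load_table("pseaa_props.tsv", 3)
    return (arr - arr.mean(axis=0)) / arr.std(axis=0)
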