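"""The 22-symbol column alphabet shared by every conservation measure.

Columns of the master alignment are treated as distributions over exactly 22
symbols: the 20 standard amino acids, ``X`` (unknown residue) and ``-`` (gap).
This fixes the maximum attainable column entropy at ``ln(22) ≈ 3.09`` nats.
Non-standard one-letter codes are remapped on input: ambiguity codes and rare
amino acids (``B Z J U O``) and the stop symbol ``*`` become ``X``, while the
alternative gap character ``.`` becomes ``-``.  Any other unexpected character
also falls back to ``X`` so that downstream code never sees an out-of-alphabet
symbol.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
UNKNOWN = "X"
GAP = "-"
ALPHABET: str = AMINO_ACIDS + UNKNOWN + GAP
N_SYMBOLS = len(ALPHABET)  # 22

SYMBOL_INDEX: dict[str, int] = {s: i for i, s in enumerate(ALPHABET)}
X_INDEX = SYMBOL_INDEX[UNKNOWN]
GAP_INDEX = SYMBOL_INDEX[GAP]

#: explicit remap policy for characters outside the 22-symbol alphabet
REMAP: dict[str, str] = {
    "B": UNKNOWN,
    "Z": UNKNOWN,
    "J": UNKNOWN,
    "U": UNKNOWN,
    "O": UNKNOWN,
    "*": UNKNOWN,
    ".": GAP,
}

MAX_ENTROPY = float(np.log(N_SYMBOLS))


def sanitize(row: str) -> tuple[str, int]:
    """Uppercase ``row`` and remap out-of-alphabet characters.

    Returns the sanitized row and the number of characters that were remapped.
    """
    row = row.upper()
    if all(c in SYMBOL_INDEX for c in row):
        return row, 0
    out = []
    n_remapped = 0
    for c in row:
        if c in SYMBOL_INDEX:
            out.append(c)
        else:
            out.append(REMAP.get(c, UNKNOWN))
            n_remapped += 1
    return "".join(out), n_remapped


def encode(row: str) -> np.ndarray:
    """Encode one sanitized row as an int8 vector of symbol indices."""
    try:
        return np.fromiter((SYMBOL_INDEX[c] for c in row), dtype=np.int8, count=len(row))
    except KeyError as exc:  # pragma: no cover - guarded by sanitize()
        raise ValueError(f"symbol {exc} outside the 22-symbol alphabet") from exc


def encode_rows(rows: Iterable[str]) -> np.ndarray:
    """Encode equal-length sanitized rows into an (n_seqs, n_cols) int8 matrix."""
    return np.vstack([encode(r) for r in rows])


def decode(indices: np.ndarray) -> str:
    return "".join(ALPHABET[i] for i in np.asarray(indices).ravel())


def symbol_bitmask(symbols: Iterable[str]) -> int:
    """Bitmask over symbol indices; bit ``i`` set iff ``ALPHABET[i]`` present."""
    mask = 0
    for s in symbols:
        try:
            mask |= 1 << SYMBOL_INDEX[s]
        except KeyError as exc:
            raise ValueError(f"symbol {s!r} outside the 22-symbol alphabet") from exc
    return mask
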