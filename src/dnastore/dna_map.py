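"""Quaternary digits <-> DNA bases via a rotating (differential) code.

The first base of a stretch is an absolute map over the order T, C, G, A
(digits 0, 1, 2, 3).  Every subsequent base is offset from its predecessor:
``next_index = (prev_index + digit + 1) mod 4``.  Starting from T, digit 2
therefore yields A.  This is the simplest invertible rotation consistent
with that anchor example; note digit 3 repeats the previous base (offset 0
mod 4), so the code does not avoid homopolymers.

Each 8-mer oligo core restarts the rotation at its first (address) base, so
cores decode independently of one another.
"""

from __future__ import annotations

import numpy as np

__all__ = ["BASES", "digits_to_dna", "dna_to_digits", "dna_matrix_to_digits"]

#: Base order defining the digit alphabet: index 0..3 = T, C, G, A.
BASES = "TCGA"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def digits_to_dna(digits: str) -> str:
    """Convert a quaternary digit string to DNA with a fresh rotation start."""
    if not digits:
        raise ValueError("empty digit string")
    out = []
    prev = None
    for pos, d in enumerate(digits):
        if d not in "0123":
            raise ValueError(f"digit {d!r} at position {pos} is not in 0..3")
        v = int(d)
        idx = v if prev is None else (prev + v + 1) % 4
        out.append(BASES[idx])
        prev = idx
    return "".join(out)


def dna_to_digits(seq: str) -> str:
    """Inverse of :func:`digits_to_dna`."""
    out = []
    prev = None
    for pos, b in enumerate(seq):
        try:
            idx = _BASE_INDEX[b]
        except KeyError:
            raise ValueError(f"non-TCGA base {b!r} at position {pos}") from None
        d = idx if prev is None else (idx - prev - 1) % 4
        out.append(str(d))
        prev = idx
    return "".join(out)


# uint8 lookup from ASCII code to base index; 255 flags an invalid byte
_ASCII_TO_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ASCII_TO_INDEX[ord(_b)] = _i


def dna_matrix_to_digits(seqs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`dna_to_digits` over an ``(n, L)`` byte matrix.

    Returns ``(digits, valid)`` where ``digits`` is an ``(n, L)`` uint8 array
    of quaternary digits and ``valid`` a boolean row mask (rows containing a
    non-TCGA byte are flagged invalid and their digits are meaningless).
    """
    idx = _ASCII_TO_INDEX[seqs]
    valid = (idx != 255).all(axis=1)
    idx16 = idx.astype(np.int16)
    digits = np.empty_like(idx)
    digits[:, 0] = idx[:, 0] & 3
    digits[:, 1:] = ((idx16[:, 1:] - idx16[:, :-1] - 1) % 4).astype(np.uint8)
    return digits, valid
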