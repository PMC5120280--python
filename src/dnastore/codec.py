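"""Text <-> bits <-> quaternary digits.

The archive's source coder is a classical binary Huffman code built from the
case-folded symbol frequencies of the message itself.  The resulting bit
stream is regrouped into base-4 digits (two bits per digit, MSB first) and
zero-padded so that its length is a multiple of four — the size of one
data block on an oligonucleotide core.

Everything here is deterministic: Huffman ties are broken by the
lexicographically smallest symbol contained in each subtree, so the same
symbol table always yields the same code table.  The total encoded length
is invariant to tie-breaking in any case.
"""

from __future__ import annotations

import heapq
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "HuffmanKey",
    "QuaternaryString",
    "count_symbols",
    "build_huffman",
    "encode_text",
    "decode_bits",
    "bits_to_digits",
    "digits_to_bits",
    "shannon_information",
    "shannon_information_bits",
    "base4_digits_per_symbol",
]

#: DNA bases consumed per byte by the scheme as realized on the instrument
#: it was designed for; a documented operating constant of the capacity
#: model, not a quantity this package derives.
BASES_PER_BYTE = 2.85


def count_symbols(text: str) -> dict[str, int]:
    """Case-folded symbol frequencies of ``text``.

    Uppercase letters are mapped to lowercase before counting, so a message
    mixing cases shares codewords between the two forms (the decoder then
    reproduces the lowercase form).
    """
    return dict(Counter(text.lower()))


@dataclass(frozen=True)
class HuffmanKey:
    """A shared decode key: prefix-free code table plus message metadata.

    Attributes
    ----------
    code:
        Map from symbol to its binary codeword (string over ``{'0','1'}``).
    char_count:
        Number of characters in the source message.
    raw_bit_length:
        Total length in bits of the encoded message (sum of codeword
        lengths), before digit padding.
    """

    code: Mapping[str, str]
    char_count: int
    raw_bit_length: int

    @property
    def alphabet_size(self) -> int:
        return len(self.code)

    def kraft_sum(self) -> float:
        return sum(2.0 ** -len(w) for w in self.code.values())


@dataclass(frozen=True)
class QuaternaryString:
    """A base-4 digit stream, padded to a multiple of four digits.

    ``digits`` is a string over ``'0123'``; ``pad_count`` records how many
    trailing ``'0'`` digits were appended (0-3) so the decoder can strip
    them again.
    """

    digits: str
    pad_count: int

    def __post_init__(self) -> None:
        if len(self.digits) % 4 != 0:
            raise ValueError("digit count must be a multiple of 4 after padding")
        if not 0 <= self.pad_count <= 3:
            raise ValueError("pad_count must be in 0..3")


def _validate_counts(counts: Mapping[str, int]) -> None:
    if len(counts) < 2:
        raise ValueError(
            f"degenerate alphabet: need at least 2 symbols, got {len(counts)}"
        )
    for sym, n in counts.items():
        if len(sym) != 1:
            raise ValueError(f"symbols must be single characters, got {sym!r}")
        if n < 1:
            raise ValueError(f"count for {sym!r} must be >= 1, got {n}")


def build_huffman(counts: Mapping[str, int]) -> HuffmanKey:
    """Build an optimal binary prefix code from symbol frequencies.

    The two lowest-weight subtrees are merged repeatedly; ties are broken by
    the lexicographically smallest symbol contained in a subtree, and the
    first subtree popped (the lighter one) becomes the ``0`` branch.  With a
    single symbol a prefix code is degenerate, hence the >= 2 symbol
    requirement.
    """
    _validate_counts(counts)
    # heap entries: (weight, min contained symbol, {symbol: depth-so-far bits})
    heap: list[tuple[int, str, dict[str, str]]] = [
        (n, s, {s: ""}) for s, n in counts.items()
    ]
    heapq.heapify(heap)
    while len(heap) > 1:
        w0, s0, c0 = heapq.heappop(heap)
        w1, s1, c1 = heapq.heappop(heap)
        merged = {s: "0" + w for s, w in c0.items()}
        merged.update({s: "1" + w for s, w in c1.items()})
        heapq.heappush(heap, (w0 + w1, min(s0, s1), merged))
    code = heap[0][2]
    char_count = sum(counts.values())
    raw_bits = sum(counts[s] * len(code[s]) for s in counts)
    return HuffmanKey(code=code, char_count=char_count, raw_bit_length=raw_bits)


def encode_text(text: str, key: HuffmanKey) -> str:
    """Encode ``text`` (case-folded) to a bit string using ``key``."""
    out: list[str] = []
    for pos, ch in enumerate(text.lower()):
        try:
            out.append(key.code[ch])
        except KeyError:
            raise ValueError(
                f"character {ch!r} at position {pos} is not in the code table"
            ) from None
    return "".join(out)


def decode_bits(bits: str, key: HuffmanKey, char_count: int | None = None) -> str:
    """Decode ``char_count`` characters from a bit string.

    Bits beyond the last complete codeword are ignored: padding appended on
    the digit side never corrupts the message.  Defaults to the key's own
    ``char_count``.
    """
    n_chars = key.char_count if char_count is None else char_count
    inverse = {w: s for s, w in key.code.items()}
    out: list[str] = []
    word = ""
    i = 0
    while len(out) < n_chars:
        if i >= len(bits):
            raise ValueError(
                f"truncated message: decoded {len(out)} of {n_chars} characters"
            )
        word += bits[i]
        i += 1
        if word in inverse:
            out.append(inverse[word])
            word = ""
    return "".join(out)


_PAIR_TO_DIGIT = {"00": "0", "01": "1", "10": "2", "11": "3"}
_DIGIT_TO_PAIR = {d: p for p, d in _PAIR_TO_DIGIT.items()}


def bits_to_digits(bits: str) -> QuaternaryString:
    """Regroup a bit string into base-4 digits padded to blocks of four.

    Bit pairs map MSB-first (``00/01/10/11 -> 0/1/2/3``); an odd-length
    input gets one ``0`` bit appended first.  Trailing ``0`` digits are then
    appended until the digit count is a multiple of 4, and their number is
    recorded in ``pad_count``.
    """
    if any(b not in "01" for b in bits):
        raise ValueError("bit string may contain only '0' and '1'")
    if len(bits) % 2:
        bits = bits + "0"
    digits = "".join(_PAIR_TO_DIGIT[bits[i : i + 2]] for i in range(0, len(bits), 2))
    pad = (-len(digits)) % 4
    return QuaternaryString(digits=digits + "0" * pad, pad_count=pad)


def digits_to_bits(digits: QuaternaryString | str, raw_bit_length: int) -> str:
    """Inverse of :func:`bits_to_digits`, truncated to ``raw_bit_length`` bits."""
    digit_str = digits.digits if isinstance(digits, QuaternaryString) else digits
    if raw_bit_length > 2 * len(digit_str):
        raise ValueError(
            f"raw_bit_length {raw_bit_length} exceeds the {2 * len(digit_str)} "
            "bits available"
        )
    bits = "".join(_DIGIT_TO_PAIR[d] for d in digit_str)
    return bits[:raw_bit_length]


def shannon_information(counts: Mapping[str, int]) -> float:
    """Shannon information content of a message, in bits.

    For empirical symbol counts ``n_i`` out of ``N`` characters this is
    ``sum n_i * log2(N / n_i)`` — the entropy lower bound on the total
    length of any prefix encoding of the message.
    """
    total = sum(counts.values())
    if total == 0:
        return 0.0
    return sum(n * math.log2(total / n) for n in counts.values() if n > 0)


def shannon_information_bits(counts: Mapping[str, int]) -> int:
    """Shannon information rounded up to whole bits."""
    return math.ceil(shannon_information(counts))


def base4_digits_per_symbol(alphabet_size: int) -> float:
    """Quaternary digits needed per symbol of a uniform ``alphabet_size``-ary
    source: ``log(alphabet_size) / log(4)``."""
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be positive")
    return math.log(alphabet_size) / math.log(4)
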