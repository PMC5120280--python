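"""Huffman coding, bit/digit conversion and padding."""

import itertools
import math

import pytest
from hypothesis import given, strategies as st

from dnastore.codec import (
    QuaternaryString,
    base4_digits_per_symbol,
    bits_to_digits,
    build_huffman,
    count_symbols,
    decode_bits,
    digits_to_bits,
    encode_text,
    shannon_information,
    shannon_information_bits,
)


def optimal_total_bits(counts: dict) -> int:
    """Brute-force minimum total prefix-code length over all merge orders.

    Exhaustively explores every sequence of pairwise merges (every full
    binary tree shape/assignment), summing merged weights — an independent
    oracle for Huffman optimality on small alphabets.
    """
    weights = tuple(sorted(counts.values()))
    best = math.inf

    def rec(ws, acc):
        nonlocal best
        if acc >= best:
            return
        if len(ws) == 1:
            best = min(best, acc)
            return
        for i, j in itertools.combinations(range(len(ws)), 2):
            merged = ws[i] + ws[j]
            rest = tuple(w for k, w in enumerate(ws) if k not in (i, j))
            rec(rest + (merged,), acc + merged)

    rec(weights, 0)
    return best


class TestBuildHuffman:
    def test_two_symbol_code_is_forced(self):
        key = build_huffman({"a": 1, "b": 1})
        assert {len(w) for w in key.code.values()} == {1}
        assert key.raw_bit_length == 2

    def test_three_symbol_total_matches_brute_force(self):
        counts = {"a": 2, "b": 1, "c": 1}
        key = build_huffman(counts)
        total = sum(counts[s] * len(key.code[s]) for s in counts)
        assert total == optimal_total_bits(counts) == 6

    @given(
        st.dictionaries(
            st.characters(min_codepoint=97, max_codepoint=122),
            st.integers(min_value=1, max_value=8),
            min_size=2,
            max_size=6,
        )
    )
    def test_optimal_on_small_alphabets(self, counts):
        key = build_huffman(counts)
        total = sum(counts[s] * len(key.code[s]) for s in counts)
        assert total == optimal_total_bits(counts)

    @given(
        st.dictionaries(
            st.characters(min_codepoint=97, max_codepoint=122),
            st.integers(min_value=1, max_value=50),
            min_size=2,
            max_size=12,
        )
    )
    def test_prefix_free_and_kraft_equality(self, counts):
        key = build_huffman(counts)
        words = sorted(key.code.values())
        for a, b in zip(words, words[1:]):
            assert not b.startswith(a)
        # a Huffman tree is full, so Kraft holds with equality
        assert key.kraft_sum() == pytest.approx(1.0)

    def test_total_length_invariant_to_tie_breaking(self):
        # reversing symbol identities permutes every tie decision
        counts = {"a": 2, "b": 2, "c": 2, "d": 2, "e": 1, "f": 1}
        relabel = {s: chr(ord("z") - i) for i, s in enumerate(sorted(counts))}
        k1 = build_huffman(counts)
        k2 = build_huffman({relabel[s]: n for s, n in counts.items()})
        t1 = sum(counts[s] * len(k1.code[s]) for s in counts)
        t2 = sum(counts[s] * len(k2.code[relabel[s]]) for s in counts)
        assert t1 == t2

    def test_degenerate_alphabet_rejected(self):
        with pytest.raises(ValueError, match="degenerate alphabet"):
            build_huffman({"a": 5})

    def test_deterministic(self):
        counts = {"a": 3, "b": 3, "c": 2, "d": 2}
        assert build_huffman(counts) == build_huffman(counts)


class TestDemoMessage:
    def test_case_folded_alphabet_is_27_symbols(self, demo_text):
        counts = count_symbols(demo_text)
        assert len(demo_text) == 377
        assert len(counts) == 27
        assert set(counts) <= set("abcdefghijklmnopqrstuvwxyz ,.")

    def test_shannon_information_is_1569_bits(self, demo_text):
        counts = count_symbols(demo_text)
        assert shannon_information_bits(counts) == 1569

    def test_huffman_encoding_meets_entropy_bound(self, demo_text, demo_key):
        counts = count_symbols(demo_text)
        bits = encode_text(demo_text, demo_key)
        assert len(bits) == demo_key.raw_bit_length
        assert len(bits) >= shannon_information(counts)
        # optimal code overhead on this message is below 1%
        assert len(bits) <= 1.01 * shannon_information(counts)


class TestEncodeDecode:
    def test_empty_text(self, demo_key):
        assert encode_text("", demo_key) == ""

    def test_two_symbol_encode(self):
        key = build_huffman({"a": 1, "b": 1})
        bits = encode_text("ab", key)
        assert len(bits) == 2 and bits[0] != bits[1]
        assert decode_bits(bits, key, char_count=2) == "ab"

    def test_trailing_bits_ignored(self):
        key = build_huffman({"a": 1, "b": 1})
        bits = encode_text("ab", key)
        assert decode_bits(bits + "0", key, char_count=2) == "ab"

    def test_unknown_character_names_position(self, demo_key):
        with pytest.raises(ValueError, match=r"'#' at position 2"):
            encode_text("th#", demo_key)

    def test_truncated_message(self):
        key = build_huffman({"a": 1, "b": 1})
        with pytest.raises(ValueError, match="truncated"):
            decode_bits("0", key, char_count=2)

    @given(st.text(alphabet="abcde ,.", min_size=0, max_size=200))
    def test_roundtrip_identity(self, text):
        counts = count_symbols(text + "abcde ,.")  # ensure full alphabet
        key = build_huffman(counts)
        bits = encode_text(text, key)
        assert decode_bits(bits, key, char_count=len(text)) == text


class TestBitDigitConversion:
    def test_pair_convention(self):
        q = bits_to_digits("00011011")
        assert q.digits == "0123" and q.pad_count == 0

    def test_27_digits_pad_to_28(self):
        # 53 bits -> one appended 0 bit -> 27 digits -> one pad digit -> 28
        q = bits_to_digits("01" * 26 + "1")
        assert len(q.digits) == 28 and q.pad_count == 1
        assert q.digits.endswith("0")

    def test_1581_bits_pad_to_792_digits(self, demo_key, demo_text):
        bits = encode_text(demo_text, demo_key)
        q = bits_to_digits(bits)
        assert len(q.digits) == 4 * math.ceil(math.ceil(len(bits) / 2) / 4)
        assert (len(q.digits) - q.pad_count) == math.ceil(len(bits) / 2)

    def test_inverse_examples(self):
        assert digits_to_bits("0123", 8) == "00011011"
        assert digits_to_bits("20", 3) == "100"

    def test_raw_bit_length_overflow(self):
        with pytest.raises(ValueError, match="exceeds"):
            digits_to_bits("01", 5)

    @given(st.text(alphabet="01", min_size=0, max_size=300))
    def test_bits_digits_roundtrip(self, bits):
        q = bits_to_digits(bits)
        assert len(q.digits) % 4 == 0
        assert digits_to_bits(q, len(bits)) == bits

    def test_pad_digits_are_zero(self):
        q = bits_to_digits("11")
        assert q.digits == "3000" and q.pad_count == 3

    def test_invalid_pad_count_rejected(self):
        with pytest.raises(ValueError):
            QuaternaryString(digits="0123", pad_count=4)


def test_base4_digits_per_symbol_for_27_symbol_alphabet():
    assert round(base4_digits_per_symbol(27), 2) == 2.38
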