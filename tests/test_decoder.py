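"""Trimming, pair merging, demultiplex/parse filtering and consensus."""

import pytest

from dnastore.codec import bits_to_digits, build_huffman, encode_text
from dnastore.decoder import (
    ConsensusGapError,
    ConsensusTable,
    ParsedRead,
    consensus,
    demux_and_parse,
    merge_pairs,
    quality_trim,
    recover_text,
)
from dnastore.dna_map import digits_to_dna
from dnastore.layout import TubePlan, make_tube_plans
from dnastore.retrieval import SimRead, _revcomp


def Q(n, q=40):
    return chr(q + 33) * n


class TestQualityTrim:
    def test_high_quality_unchanged(self):
        reads = [SimRead("r1", "ACGTACGT", Q(8))]
        assert quality_trim(reads, q_threshold=20, min_len=4) == reads

    def test_low_quality_read_dropped(self):
        reads = [SimRead("r1", "ACGTACGT", Q(8, q=2))]
        assert quality_trim(reads, q_threshold=20, min_len=4) == []

    def test_low_quality_tail_trimmed(self):
        reads = [SimRead("r1", "ACGTACGTAC", Q(5) + Q(5, q=2))]
        (out,) = quality_trim(reads, q_threshold=20, min_len=3)
        assert out.sequence == "ACGTA" and len(out.qualities) == 5


class TestMergePairs:
    FRAG = "ACGGTTACGATCCGTAGGCTTATCGCACTGGATTCAAGCT"  # 40 nt, aperiodic

    def test_designed_overlap_merges_to_expected_length(self):
        frag = self.FRAG
        fwd = [SimRead("p/1", frag[:30], Q(30))]
        rev = [SimRead("p/2", _revcomp(frag[10:]), Q(30))]
        (m,) = merge_pairs(fwd, rev, min_overlap=20)
        assert m.sequence == frag
        assert len(m.sequence) == 30 + 30 - 20

    def test_no_overlap_candidates_dropped(self):
        fwd = [SimRead("p/1", "A" * 30, Q(30))]
        rev = [SimRead("p/2", "C" * 30, Q(30))]
        assert merge_pairs(fwd, rev, min_overlap=20) == []

    def test_disagreement_resolved_by_quality(self):
        frag = self.FRAG[:30]
        fwd_seq = frag[:25]
        rev_frag = frag[5:]
        # corrupt one overlap base on the low-quality forward read
        fwd_bad = fwd_seq[:10] + ("G" if fwd_seq[10] != "G" else "A") + fwd_seq[11:]
        fwd = [SimRead("p/1", fwd_bad, Q(10) + chr(2 + 33) + Q(14))]
        rev = [SimRead("p/2", _revcomp(rev_frag), Q(25))]
        (m,) = merge_pairs(fwd, rev, min_overlap=15)
        assert m.sequence == frag


def _mini_archive():
    """One tube per tile, 2 tiles, 3 blocks, short adaptors."""
    tubes = make_tube_plans(n_tiles=2)
    left, right = "GG", "CC"
    blocks = ["0123", "3210", "1111"]
    reads = []
    for t in tubes:
        for i, data in enumerate(blocks):
            addr = f"{(i + t.tile_id) % 256:>04d}"  # works for idx < 4
            core = digits_to_dna(addr + data)
            seq = t.index_sequence + left + core + right
            reads.append(SimRead(f"t{t.tube_id}b{i}", seq, Q(len(seq))))
    expected_length = 6 + 2 + 8 + 2
    return tubes, reads, expected_length, blocks


class TestDemuxAndParse:
    def test_error_free_reads_all_parse(self):
        tubes, reads, L, blocks = _mini_archive()
        parsed, discards = demux_and_parse(
            reads, tubes, expected_length=L, core_offset=8,
            blocks_per_segment=[3],
        )
        assert len(parsed) == len(reads)
        assert not discards
        for p in parsed:
            assert p.data_digits == blocks[p.position]

    def test_one_substitution_in_index_discards(self):
        tubes, reads, L, _ = _mini_archive()
        bad = "A" + reads[0].sequence[1:]
        if bad[:6] == reads[0].sequence[:6]:
            bad = "C" + reads[0].sequence[1:]
        reads = [SimRead(reads[0].read_id, bad, reads[0].qualities)]
        parsed, discards = demux_and_parse(
            reads, tubes, expected_length=L, core_offset=8,
            blocks_per_segment=[3],
        )
        assert parsed == [] and discards["index"] == 1

    def test_wrong_length_discarded_first(self):
        tubes, reads, L, _ = _mini_archive()
        short = SimRead("s", reads[0].sequence[:-1], Q(L - 1))
        _, discards = demux_and_parse(
            [short], tubes, expected_length=L, core_offset=8,
            blocks_per_segment=[3],
        )
        assert discards == {"length": 1}

    def test_out_of_range_address_discarded(self):
        tubes, _, L, _ = _mini_archive()
        core = digits_to_dna("3333" + "0000")  # address 255, M=3
        seq = tubes[0].index_sequence + "GG" + core + "CC"
        _, discards = demux_and_parse(
            [SimRead("r", seq, Q(L))], tubes, expected_length=L, core_offset=8,
            blocks_per_segment=[3],
        )
        assert discards == {"address": 1}

    def test_parsed_fraction_never_rises_with_error_rate(self):
        """Raising the substitution rate only removes reads from the
        perfect-filter output."""
        from dnastore.pipeline import PipelineConfig, cmd_roundtrip

        fractions = []
        for eps in (0.0, 0.02, 0.08):
            cfg = PipelineConfig(
                message="the human genome",
                seed=5,
                sub_error_rate=eps,
                library_molecules=200_000,
            )
            rep = cmd_roundtrip(cfg)
            fractions.append(rep["n_parsed"] / rep["n_reads_in"])
        assert fractions[0] >= fractions[1] >= fractions[2]


class TestConsensus:
    def test_unanimous_support(self):
        parsed = [ParsedRead(0, 0, "0123", f"r{i}") for i in range(3)]
        table = consensus(parsed, M=1)
        assert table.values[0] == "0123" and table.support[0] == 3

    def test_majority_wins(self):
        parsed = [
            ParsedRead(0, 0, "0123", "a"),
            ParsedRead(0, 0, "0123", "b"),
            ParsedRead(0, 0, "3210", "c"),
        ]
        assert consensus(parsed, M=1).values[0] == "0123"

    def test_single_tube_position_recovered(self):
        parsed = [ParsedRead(5, 0, "2222", "only")]
        table = consensus(parsed, M=1)
        assert table.values[0] == "2222" and table.n_tubes[0] == 1

    def test_count_tie_broken_by_tube_count(self):
        # 2-2 read tie; "1111" is seen in two tubes, "0000" in one
        parsed = [
            ParsedRead(0, 0, "0000", "a"),
            ParsedRead(0, 0, "0000", "b"),
            ParsedRead(1, 0, "1111", "c"),
            ParsedRead(2, 0, "1111", "d"),
        ]
        table = consensus(parsed, M=1)
        assert table.values[0] == "1111"

    def test_empty_position_is_gap(self):
        parsed = [ParsedRead(0, 0, "0123", "a")]
        with pytest.raises(ConsensusGapError) as exc:
            consensus(parsed, M=3)
        assert exc.value.gaps == [1, 2]

    def test_unresolvable_tie_is_gap(self):
        parsed = [
            ParsedRead(0, 0, "0000", "a"),
            ParsedRead(1, 0, "1111", "b"),
        ]
        with pytest.raises(ConsensusGapError):
            consensus(parsed, M=1)


class TestRecoverText:
    def test_single_block_roundtrip(self):
        key = build_huffman({"a": 1, "b": 1})
        bits = encode_text("ab", key)
        q = bits_to_digits(bits)
        table = ConsensusTable(
            M=1, values={0: q.digits}, support={0: 1}, n_tubes={0: 1}
        )
        assert recover_text(table, key, q.pad_count) == "ab"

    def test_empty_message(self):
        from dataclasses import replace

        key = build_huffman({"a": 1, "b": 1})
        key0 = replace(key, char_count=0, raw_bit_length=0)
        table = ConsensusTable(M=0, values={}, support={}, n_tubes={})
        assert recover_text(table, key0, 0) == ""
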