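"""Recover the message from per-tube reads.

The decode path mirrors the encode path in reverse: trim low-quality
tails (and optionally merge overlapping read pairs), demultiplex on an
exact tube-index match, keep only reads of the expected length whose core
parses to a valid in-range address, pool the surviving reads across all
tubes, call a majority-vote consensus per data-block position, and feed
the reassembled digit stream back through the base-4 and Huffman layers.

Filtering is deliberately strict — a single substitution in the index or
an address outside the message range discards the read — because the
tiling redundancy supplies many independent observations of every block;
discarded reads are counted by reason rather than rescued.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import numpy as np

from .codec import HuffmanKey, decode_bits, digits_to_bits
from .dna_map import dna_matrix_to_digits
from .layout import ADDRESS_SPACE, TubePlan
from .retrieval import SimRead, _revcomp

__all__ = [
    "ParsedRead",
    "ConsensusTable",
    "ConsensusGapError",
    "quality_trim",
    "merge_pairs",
    "demux_and_parse",
    "consensus",
    "recover_text",
]


@dataclass(frozen=True)
class ParsedRead:
    """A read that survived filtering, reduced to its digit payload.

    ``position`` is the data-block index after unshifting the address by
    the tube's tile offset (plus the segment offset for multi-segment
    archives).
    """

    tube_id: int
    position: int
    data_digits: str
    read_id: str


class ConsensusGapError(ValueError):
    """Raised when some block positions have no (or no unambiguous) winner."""

    def __init__(self, gaps: list[int]):
        self.gaps = gaps
        super().__init__(
            f"consensus has {len(gaps)} unresolved position(s): {gaps[:20]}"
            + ("..." if len(gaps) > 20 else "")
        )


def quality_trim(
    reads: list[SimRead], q_threshold: int = 20, min_len: int = 30
) -> list[SimRead]:
    """Trim trailing bases below ``q_threshold``; drop reads shorter than
    ``min_len`` afterwards."""
    out = []
    for r in reads:
        end = len(r.qualities)
        while end > 0 and ord(r.qualities[end - 1]) - 33 < q_threshold:
            end -= 1
        if end >= min_len:
            out.append(SimRead(r.read_id, r.sequence[:end], r.qualities[:end]))
    return out


def _pair_key(read_id: str) -> str:
    return read_id[:-2] if read_id.endswith(("/1", "/2")) else read_id


def merge_pairs(
    fwd: list[SimRead],
    rev: list[SimRead],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> list[SimRead]:
    """Merge overlapping mates into single fragments.

    The reverse mate is reverse-complemented, the overlap length maximizing
    (matches - mismatches) with at least ``min_overlap`` bases and at most
    ``max_mismatch_frac`` disagreement is chosen, disagreeing bases resolve
    toward the higher quality, and unmergeable pairs are dropped.
    """
    rev_by = {_pair_key(r.read_id): r for r in rev}
    merged = []
    for f in fwd:
        key = _pair_key(f.read_id)
        r = rev_by.get(key)
        if r is None:
            continue
        rseq = _revcomp(r.sequence)
        rqual = r.qualities[::-1]
        best = None
        max_l = min(len(f.sequence), len(rseq))
        for L in range(max_l, min_overlap - 1, -1):
            a = f.sequence[-L:]
            b = rseq[:L]
            mm = sum(x != y for x, y in zip(a, b))
            if mm / L > max_mismatch_frac:
                continue
            score = L - 2 * mm
            if best is None or score > best[0]:
                best = (score, L, mm)
        if best is None:
            continue
        _, L, _ = best
        head = f.sequence[:-L] if L < len(f.sequence) else ""
        headq = f.qualities[:-L] if L < len(f.sequence) else ""
        ov_seq = []
        ov_q = []
        for i in range(L):
            fq = f.qualities[len(f.qualities) - L + i]
            rq = rqual[i]
            if f.sequence[len(f.sequence) - L + i] == rseq[i]:
                ov_seq.append(rseq[i])
                ov_q.append(max(fq, rq))
            elif fq >= rq:
                ov_seq.append(f.sequence[len(f.sequence) - L + i])
                ov_q.append(fq)
            else:
                ov_seq.append(rseq[i])
                ov_q.append(rq)
        tail = rseq[L:]
        tailq = rqual[L:]
        merged.append(
            SimRead(key, head + "".join(ov_seq) + tail, headq + "".join(ov_q) + tailq)
        )
    return merged


def demux_and_parse(
    reads: list[SimRead],
    tubes: list[TubePlan],
    expected_length: int,
    core_offset: int,
    blocks_per_segment: list[int],
    segment_starts: list[int] | None = None,
) -> tuple[list[ParsedRead], Counter]:
    """Demultiplex reads on exact index match and parse their cores.

    A read survives only if its length equals ``expected_length``, its
    leading bases exactly match one tube's index sequence, its 8-mer core
    (at ``core_offset``, after the index) parses to valid DNA, and the
    unshifted address falls inside its segment's block range.  Returns the
    surviving reads plus discard counts keyed by reason
    (``length`` / ``index`` / ``core`` / ``address``).

    Filter order is length, then index, then core/address, and each read is
    attributed to exactly one tile — its tube's — never guessed from
    sequence content.
    """
    if not tubes:
        raise ValueError("no tubes configured")
    index_len = len(tubes[0].index_sequence)
    if any(len(t.index_sequence) != index_len for t in tubes):
        raise ValueError("tube index sequences must share one length")
    tube_by_index = {t.index_sequence: t for t in tubes}
    if len(tube_by_index) != len(tubes):
        raise ValueError("tube index sequences must be distinct")
    n_seg = max(t.segment for t in tubes) + 1
    if len(blocks_per_segment) != n_seg:
        raise ValueError("blocks_per_segment must cover every tube segment")
    if segment_starts is None:
        segment_starts = list(
            np.concatenate([[0], np.cumsum(blocks_per_segment)[:-1]]).astype(int)
        )

    discards: Counter = Counter()
    kept_reads: list[SimRead] = []
    kept_tubes: list[TubePlan] = []
    for r in reads:
        if len(r.sequence) != expected_length:
            discards["length"] += 1
            continue
        tube = tube_by_index.get(r.sequence[:index_len])
        if tube is None:
            discards["index"] += 1
            continue
        kept_reads.append(r)
        kept_tubes.append(tube)

    parsed: list[ParsedRead] = []
    if kept_reads:
        mat = np.frombuffer(
            "".join(r.sequence[core_offset : core_offset + 8] for r in kept_reads).encode(),
            dtype=np.uint8,
        ).reshape(len(kept_reads), 8)
        digits, valid = dna_matrix_to_digits(mat)
        addr = digits[:, :4].astype(np.int64) @ np.array([64, 16, 4, 1])
        for k, (r, tube) in enumerate(zip(kept_reads, kept_tubes)):
            if not valid[k]:
                discards["core"] += 1
                continue
            block = (int(addr[k]) - tube.tile_id) % ADDRESS_SPACE
            if block >= blocks_per_segment[tube.segment]:
                discards["address"] += 1
                continue
            parsed.append(
                ParsedRead(
                    tube_id=tube.tube_id,
                    position=segment_starts[tube.segment] + block,
                    data_digits="".join(str(d) for d in digits[k, 4:]),
                    read_id=r.read_id,
                )
            )
    return parsed, discards


@dataclass
class ConsensusTable:
    """Per-position consensus: winning digits with their support."""

    M: int
    values: dict[int, str]
    support: dict[int, int]
    n_tubes: dict[int, int]

    def digit_stream(self) -> str:
        return "".join(self.values[i] for i in range(self.M))


def consensus(parsed: list[ParsedRead], M: int) -> ConsensusTable:
    """Majority vote per block position over reads pooled from all tubes.

    Pooling across tubes is what supplements a position missing from one
    tube with observations from another.  A top-count tie is broken by the
    number of distinct tubes supporting each candidate; an unresolved tie
    or an empty position is a gap, and any gap fails the decode with the
    full gap list.
    """
    votes: dict[int, Counter] = defaultdict(Counter)
    tube_support: dict[int, dict[str, set]] = defaultdict(lambda: defaultdict(set))
    for p in parsed:
        if 0 <= p.position < M:
            votes[p.position][p.data_digits] += 1
            tube_support[p.position][p.data_digits].add(p.tube_id)

    values: dict[int, str] = {}
    support: dict[int, int] = {}
    n_tubes: dict[int, int] = {}
    gaps: list[int] = []
    for pos in range(M):
        if pos not in votes:
            gaps.append(pos)
            continue
        counts = votes[pos]
        top = max(counts.values())
        leaders = [v for v, c in counts.items() if c == top]
        if len(leaders) > 1:
            by_tubes = {v: len(tube_support[pos][v]) for v in leaders}
            best = max(by_tubes.values())
            leaders = [v for v in leaders if by_tubes[v] == best]
        if len(leaders) != 1:
            gaps.append(pos)
            continue
        values[pos] = leaders[0]
        support[pos] = top
        n_tubes[pos] = len(tube_support[pos][leaders[0]])
    if gaps:
        raise ConsensusGapError(gaps)
    return ConsensusTable(M=M, values=values, support=support, n_tubes=n_tubes)


def recover_text(table: ConsensusTable, key: HuffmanKey, pad_count: int) -> str:
    """Digit stream -> strip padding -> bits -> Huffman decode."""
    digits = table.digit_stream()
    if pad_count:
        digits = digits[: len(digits) - pad_count]
    if key.char_count == 0:
        return ""
    bits = digits_to_bits(digits, key.raw_bit_length)
    return decode_bits(bits, key)
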