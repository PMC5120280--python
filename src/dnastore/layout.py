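"""Oligo layout: data blocks, base-4 addresses, sliding-tile redundancy.

The padded digit stream is cut into 4-digit data blocks.  Each block is
prefixed with a 4-digit address (its position as a width-4 base-4 numeral;
the address space is 4^4 = 256) and the 8 digits are converted to an 8-mer
DNA core.  Redundancy comes from tiling: tile ``j`` pairs block ``i`` with
address ``(i + j) mod 256``, so with the default 8 tiles every block is
carried by 8 distinct (address, data) cores, each collected into its own
tube.  A block whose core is missing from the sequenced library under one
address may still be retrievable under another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codec import QuaternaryString
from .dna_map import digits_to_dna

__all__ = [
    "ADDRESS_SPACE",
    "LEFT_ADAPTOR",
    "RIGHT_ADAPTOR",
    "AddressBlock",
    "DataBlock",
    "Tile",
    "OligoRecord",
    "TubePlan",
    "make_addresses",
    "split_blocks",
    "build_tiles",
    "assemble_oligos",
    "make_tube_plans",
    "write_oligos_fasta",
    "oligos_to_frame",
]

#: Width-4 base-4 numerals: 4^4 distinct addresses.
ADDRESS_SPACE = 256

# Flanking sequences sized so the default full oligo is 138 nt
# (100 + 8-mer core + 30).  The right adaptor is the reverse complement of
# the 30-nt reverse extension primer; the left adaptor content is an
# arbitrary fixed sequence standing in for the platform adaptor.
LEFT_ADAPTOR = (
    "GTCTAGCCTTGCAAGACGTGTATCGGATTCACGGCTAAGTCCATGCGATA"
    "CCTTGAGTCAGGTAACGCATTGGCTACCAGTTCGTAGACCATGGTCTAGA"
)
RIGHT_ADAPTOR = "CTGAGACTGCCAAGGCACACAGGGGATAGG"


@dataclass(frozen=True)
class AddressBlock:
    """A location index: 4 quaternary digits encoding ``index`` in base 4."""

    index: int
    digits: str = field(init=False)

    def __post_init__(self) -> None:
        if not 0 <= self.index < ADDRESS_SPACE:
            raise ValueError(f"address index {self.index} outside 0..255")
        d = ""
        v = self.index
        for _ in range(4):
            d = str(v % 4) + d
            v //= 4
        object.__setattr__(self, "digits", d)


@dataclass(frozen=True)
class DataBlock:
    """One 4-digit payload block at 0-based stream position ``position``."""

    position: int
    digits: str

    def __post_init__(self) -> None:
        if len(self.digits) != 4 or any(d not in "0123" for d in self.digits):
            raise ValueError("data block must be exactly 4 quaternary digits")


@dataclass(frozen=True)
class Tile:
    """One redundancy copy: every block paired with its shifted address."""

    tile_id: int
    assignments: tuple[tuple[AddressBlock, DataBlock], ...]


@dataclass(frozen=True)
class OligoRecord:
    """A designed molecule: adaptors flanking an 8-mer address+data core."""

    tile_id: int
    block_index: int
    core: str
    left_adaptor: str = LEFT_ADAPTOR
    right_adaptor: str = RIGHT_ADAPTOR
    segment: int = 0

    def __post_init__(self) -> None:
        if len(self.core) != 8:
            raise ValueError("oligo core must be exactly 8 bases")

    @property
    def name(self) -> str:
        base = f"tile{self.tile_id}_blk{self.block_index}"
        return base if self.segment == 0 else f"seg{self.segment}_{base}"

    @property
    def full_sequence(self) -> str:
        return self.left_adaptor + self.core + self.right_adaptor


@dataclass(frozen=True)
class TubePlan:
    """Collection tube for one tile, with its demultiplexing index tag."""

    tube_id: int
    tile_id: int
    index_sequence: str
    segment: int = 0


def make_addresses(count: int) -> list[AddressBlock]:
    """Enumerate the first ``count`` addresses: 0000, 0001, 0002, 0003, 0010, ..."""
    if count < 1:
        raise ValueError("need at least one address")
    if count > ADDRESS_SPACE:
        raise ValueError(f"address space exhausted (4^4 = {ADDRESS_SPACE})")
    return [AddressBlock(i) for i in range(count)]


def split_blocks(digits: QuaternaryString | str) -> list[DataBlock]:
    """Cut a padded digit stream into consecutive 4-digit data blocks."""
    digit_str = digits.digits if isinstance(digits, QuaternaryString) else digits
    if len(digit_str) % 4 != 0:
        raise ValueError(
            f"digit count {len(digit_str)} is not a multiple of 4; pad first"
        )
    return [
        DataBlock(position=i, digits=digit_str[4 * i : 4 * i + 4])
        for i in range(len(digit_str) // 4)
    ]


def build_tiles(blocks: list[DataBlock], n_tiles: int = 8) -> list[Tile]:
    """Tile ``j`` assigns block ``i`` the address ``(i + j) mod 256``."""
    if n_tiles < 1:
        raise ValueError("need at least one tile")
    if len(blocks) > ADDRESS_SPACE:
        raise ValueError(
            f"{len(blocks)} blocks exceed the address space "
            f"(4^4 = {ADDRESS_SPACE}); split the message into segments"
        )
    tiles = []
    for j in range(n_tiles):
        assignments = tuple(
            (AddressBlock((b.position + j) % ADDRESS_SPACE), b) for b in blocks
        )
        tiles.append(Tile(tile_id=j, assignments=assignments))
    return tiles


def assemble_oligos(
    tiles: list[Tile],
    left_adaptor: str = LEFT_ADAPTOR,
    right_adaptor: str = RIGHT_ADAPTOR,
    segment: int = 0,
) -> list[OligoRecord]:
    """One oligo per (tile, block): core = fresh-start conversion of the
    8 concatenated address+data digits, flanked by the adaptors."""
    oligos = []
    for tile in tiles:
        for addr, blk in tile.assignments:
            core = digits_to_dna(addr.digits + blk.digits)
            oligos.append(
                OligoRecord(
                    tile_id=tile.tile_id,
                    block_index=blk.position,
                    core=core,
                    left_adaptor=left_adaptor,
                    right_adaptor=right_adaptor,
                    segment=segment,
                )
            )
    return oligos


# Distinct 6-nt tube indices (TruSeq-style set for the first eight tubes).
_DEFAULT_INDICES = [
    "ATCACG", "CGATGT", "TTAGGC", "TGACCA",
    "ACAGTG", "GCCAAT", "CAGATC", "ACTTGA",
]


def _index_stream():
    """Deterministic stream of distinct 6-mers for arbitrarily many tubes."""
    yield from _DEFAULT_INDICES
    alphabet = "ACGT"
    k = 0
    while True:
        idx = "".join(alphabet[(k >> (2 * p)) & 3] for p in range(6))
        k += 1
        if idx in _DEFAULT_INDICES or idx == LEFT_ADAPTOR[:6]:
            continue
        yield idx


def make_tube_plans(n_tiles: int = 8, n_segments: int = 1) -> list[TubePlan]:
    """One tube per (segment, tile), each with a distinct index sequence."""
    stream = _index_stream()
    plans = []
    tube_id = 0
    for seg in range(n_segments):
        for j in range(n_tiles):
            plans.append(
                TubePlan(
                    tube_id=tube_id,
                    tile_id=j,
                    index_sequence=next(stream),
                    segment=seg,
                )
            )
            tube_id += 1
    return plans


def write_oligos_fasta(oligos: list[OligoRecord], path) -> None:
    records = [
        SeqRecord(Seq(o.full_sequence), id=o.name, description="")
        for o in oligos
    ]
    SeqIO.write(records, path, "fasta")


def oligos_to_frame(oligos: list[OligoRecord]) -> pd.DataFrame:
    """Tabular view of a designed library (one row per oligo)."""
    from .dna_map import dna_to_digits

    rows = []
    for o in oligos:
        digits = dna_to_digits(o.core)
        rows.append(
            {
                "name": o.name,
                "segment": o.segment,
                "tile_id": o.tile_id,
                "block_index": o.block_index,
                "address": digits[:4],
                "data": digits[4:],
                "core": o.core,
                "full_sequence": o.full_sequence,
            }
        )
    return pd.DataFrame(rows)
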