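"""End-to-end orchestration: encode, simulate, retrieve, decode.

The archive travels with a JSON *key file* containing everything the
decoder needs and nothing it can infer: the Huffman code table and message
metadata, the digit padding, the tiling geometry (number of tiles, shift
direction, per-segment block counts), the adaptor sequences and the
tube-index plan.  Re-running any stage with the same configuration and
master seed reproduces its output exactly; per-stage seeds are derived by
hashing the master seed with the stage name so stages are independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import codec, decoder, layout, retrieval
from .codec import HuffmanKey
from .layout import ADDRESS_SPACE, OligoRecord, Tile, TubePlan
from .retrieval import ReadSimConfig, SimRead
from .storage_sim import LibrarySpec, sample_library

__all__ = [
    "ArchiveKey",
    "PipelineConfig",
    "encode_message",
    "decode_tubes",
    "cmd_encode",
    "cmd_roundtrip",
    "stage_seed",
]

KEY_VERSION = 1


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class ArchiveKey:
    """The shared decode key for one archived message."""

    huffman: HuffmanKey
    pad_count: int
    n_tiles: int
    blocks_per_segment: list[int]
    tile_shift: int  # address index of block i in tile j is (i + j*shift) % 256
    left_adaptor: str
    right_adaptor: str
    tubes: list[TubePlan]
    version: int = KEY_VERSION

    @property
    def total_blocks(self) -> int:
        return sum(self.blocks_per_segment)

    @property
    def expected_read_length(self) -> int:
        return (
            len(self.tubes[0].index_sequence)
            + len(self.left_adaptor)
            + 8
            + len(self.right_adaptor)
        )

    @property
    def core_offset(self) -> int:
        return len(self.tubes[0].index_sequence) + len(self.left_adaptor)

    def to_json(self) -> str:
        obj = {
            "version": self.version,
            "alphabet": sorted(self.huffman.code),
            "codewords": dict(sorted(self.huffman.code.items())),
            "char_count": self.huffman.char_count,
            "raw_bit_length": self.huffman.raw_bit_length,
            "pad_count": self.pad_count,
            "n_tiles": self.n_tiles,
            "blocks_per_segment": list(self.blocks_per_segment),
            "tile_shift": self.tile_shift,
            "left_adaptor": self.left_adaptor,
            "right_adaptor": self.right_adaptor,
            "tubes": [asdict(t) for t in self.tubes],
        }
        return json.dumps(obj, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "ArchiveKey":
        obj = json.loads(text)
        huff = HuffmanKey(
            code=obj["codewords"],
            char_count=obj["char_count"],
            raw_bit_length=obj["raw_bit_length"],
        )
        return cls(
            huffman=huff,
            pad_count=obj["pad_count"],
            n_tiles=obj["n_tiles"],
            blocks_per_segment=list(obj["blocks_per_segment"]),
            tile_shift=obj["tile_shift"],
            left_adaptor=obj["left_adaptor"],
            right_adaptor=obj["right_adaptor"],
            tubes=[TubePlan(**t) for t in obj["tubes"]],
            version=obj["version"],
        )

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "ArchiveKey":
        return cls.from_json(Path(path).read_text())


@dataclass
class PipelineConfig:
    """Everything needed to run the full write/read cycle reproducibly."""

    message: str | None = None
    message_path: str | None = None
    n_tiles: int = 8
    left_adaptor: str = layout.LEFT_ADAPTOR
    right_adaptor: str = layout.RIGHT_ADAPTOR
    library_N: int = 8
    library_molecules: int = 1_000_000
    library_base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    per_oligo_coverage: float = 30.0
    sub_error_rate: float = 0.0
    seed: int = 0
    outdir: str | None = None

    def text(self) -> str:
        if self.message is not None:
            return self.message
        if self.message_path is not None:
            return Path(self.message_path).read_text()
        raise ValueError("config needs either message or message_path")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            obj = yaml.safe_load(path.read_text())
        else:
            obj = json.loads(path.read_text())
        if "library_base_probs" in obj:
            obj["library_base_probs"] = tuple(obj["library_base_probs"])
        return cls(**obj)


def _segment_blocks(blocks: list[layout.DataBlock]) -> list[list[layout.DataBlock]]:
    """Split the block list into address-space-sized segments, reindexing
    block positions within each segment."""
    segments = []
    for start in range(0, len(blocks), ADDRESS_SPACE):
        chunk = blocks[start : start + ADDRESS_SPACE]
        segments.append(
            [layout.DataBlock(position=i, digits=b.digits) for i, b in enumerate(chunk)]
        )
    return segments or [[]]


def encode_message(
    text: str,
    n_tiles: int = 8,
    left_adaptor: str = layout.LEFT_ADAPTOR,
    right_adaptor: str = layout.RIGHT_ADAPTOR,
) -> tuple[ArchiveKey, list[list[Tile]], list[OligoRecord]]:
    """Text -> key + tiles (per segment) + designed oligos.

    Messages longer than 256 data blocks are split into independent
    segments, each with its own address space and tube set.
    """
    counts = codec.count_symbols(text)
    key = codec.build_huffman(counts)
    bits = codec.encode_text(text, key)
    quat = codec.bits_to_digits(bits)
    blocks = layout.split_blocks(quat)
    segments = _segment_blocks(blocks)
    tubes = layout.make_tube_plans(n_tiles=n_tiles, n_segments=len(segments))

    all_tiles: list[list[Tile]] = []
    oligos: list[OligoRecord] = []
    for seg, seg_blocks in enumerate(segments):
        tiles = layout.build_tiles(seg_blocks, n_tiles=n_tiles)
        all_tiles.append(tiles)
        oligos.extend(
            layout.assemble_oligos(tiles, left_adaptor, right_adaptor, segment=seg)
        )

    archive = ArchiveKey(
        huffman=key,
        pad_count=quat.pad_count,
        n_tiles=n_tiles,
        blocks_per_segment=[len(s) for s in segments],
        tile_shift=1,
        left_adaptor=left_adaptor,
        right_adaptor=right_adaptor,
        tubes=tubes,
    )
    return archive, all_tiles, oligos


def decode_tubes(
    reads_by_tube: dict[int, list[SimRead]], key: ArchiveKey
) -> tuple[str, dict]:
    """Run the full decode path; returns (text, report).

    The report carries discard counts, per-tube parsed-read yields and
    per-position support; on a consensus gap the text is None-like (empty)
    and the gap list is reported instead of raising.
    """
    all_reads = [r for reads in reads_by_tube.values() for r in reads]
    trimmed = decoder.quality_trim(all_reads, q_threshold=20, min_len=30)
    parsed, discards = decoder.demux_and_parse(
        trimmed,
        key.tubes,
        expected_length=key.expected_read_length,
        core_offset=key.core_offset,
        blocks_per_segment=key.blocks_per_segment,
    )
    per_tube_yield = pd.Series(
        [p.tube_id for p in parsed], dtype=int
    ).value_counts().to_dict()
    report = {
        "n_reads_in": len(all_reads),
        "n_reads_trimmed_out": len(all_reads) - len(trimmed),
        "n_parsed": len(parsed),
        "discards": dict(discards),
        "per_tube_parsed": per_tube_yield,
    }
    try:
        table = decoder.consensus(parsed, key.total_blocks)
    except decoder.ConsensusGapError as e:
        report["gaps"] = e.gaps
        return "", report
    report["gaps"] = []
    report["min_support"] = min(table.support.values()) if table.support else 0
    report["consensus_support"] = table.support
    text = decoder.recover_text(table, key.huffman, key.pad_count)
    return text, report


def cmd_encode(config: PipelineConfig) -> tuple[ArchiveKey, list[OligoRecord]]:
    """Encode stage: build key and oligo design, writing them to outdir
    (key.json, oligos.fasta, oligos.tsv) when one is configured."""
    text = config.text()
    key, _tiles, oligos = encode_message(
        text,
        n_tiles=config.n_tiles,
        left_adaptor=config.left_adaptor,
        right_adaptor=config.right_adaptor,
    )
    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        key.save(out / "key.json")
        layout.write_oligos_fasta(oligos, out / "oligos.fasta")
        layout.oligos_to_frame(oligos).to_csv(
            out / "oligos.tsv", sep="\t", index=False
        )
    return key, oligos


def cmd_roundtrip(config: PipelineConfig) -> dict:
    """Full write/read cycle on a simulated instrument.

    encode -> sample degenerate library -> run table -> pick lists ->
    per-tube read simulation -> decode; returns a report with the recovery
    accuracy, per-tube satisfied-target fractions and filter statistics.
    """
    text = config.text()
    key, all_tiles, oligos = encode_message(
        text,
        n_tiles=config.n_tiles,
        left_adaptor=config.left_adaptor,
        right_adaptor=config.right_adaptor,
    )

    spec = LibrarySpec(
        N=config.library_N,
        n_molecules=config.library_molecules,
        base_probs=config.library_base_probs,
        seed=stage_seed(config.seed, "library"),
    )
    library = sample_library(spec)
    run = retrieval.make_run_table(
        library, spec.N, seed=stage_seed(config.seed, "runtable")
    )

    picks_parts = []
    for seg, tiles in enumerate(all_tiles):
        seg_tubes = [t for t in key.tubes if t.segment == seg]
        picks_parts.append(retrieval.make_picklist(run, tiles, seg_tubes))
    picks = pd.concat(picks_parts, ignore_index=True)

    sim_cfg = ReadSimConfig(
        per_oligo_coverage=config.per_oligo_coverage,
        sub_error_rate=config.sub_error_rate,
        seed=stage_seed(config.seed, "reads"),
    )
    reads_by_tube = retrieval.simulate_pool_reads(picks, oligos, key.tubes, sim_cfg)

    recovered, decode_report = decode_tubes(reads_by_tube, key)
    # the codec is case-folding, so recovery is judged against the folded text
    matches = sum(a == b for a, b in zip(text.lower(), recovered))
    accuracy = matches / len(text) if text else 1.0
    exact = recovered == text.lower()

    per_tube = retrieval.picklist_summary(picks)
    report = {
        "char_count": len(text),
        "accuracy": accuracy,
        "exact": exact,
        "recovered_text": recovered,
        "per_tube_satisfied": dict(
            zip(per_tube["tube_id"], per_tube["satisfied_fraction"])
        ),
        "n_targets": int(len(picks)),
        "n_missing_picks": int((picks["read_id"] == retrieval.MISSING).sum()),
        **decode_report,
    }

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        key.save(out / "key.json")
        layout.write_oligos_fasta(oligos, out / "oligos.fasta")
        picks.to_csv(out / "picklist.tsv", sep="\t", index=False)
        for tube_id, reads in reads_by_tube.items():
            retrieval.write_fastq(reads, out / f"tube{tube_id}.fastq")
        (out / "recovered.txt").write_text(recovered)
        pd.DataFrame(
            {
                "position": list(report.get("consensus_support", {})),
                "support": list(report.get("consensus_support", {}).values()),
            }
        ).to_csv(out / "consensus_support.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(
                {k: v for k, v in report.items() if k != "consensus_support"},
                fh,
                indent=1,
                default=str,
            )
    return report
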