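"""Sequencing-run tables, pick lists and retrieved-pool read simulation.

This is the computational surface of the physical retrieval step: a
sequencing run of the degenerate library exposes every clonal molecule's
sequence together with its (x, y) position on the plate, a pick list maps
each designed core to the position of a matching clone, and the picked
clones — pooled per tube, one tube per tile — are re-amplified and
re-sequenced.  The read simulator models that second sequencing as
Poisson-distributed clonal coverage with i.i.d. substitution errors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .layout import OligoRecord, Tile, TubePlan
from .storage_sim import codes_to_seqs, seqs_to_codes

__all__ = [
    "ReadSimConfig",
    "SimRead",
    "make_run_table",
    "make_picklist",
    "picklist_summary",
    "simulate_pool_reads",
    "write_fastq",
    "read_fastq",
]


class SimRead(NamedTuple):
    """One simulated read: identifier, sequence, per-base Phred qualities."""

    read_id: str
    sequence: str
    qualities: str  # Phred+33


@dataclass(frozen=True)
class ReadSimConfig:
    """Error and depth model for re-sequencing the retrieved pools.

    ``per_oligo_coverage`` is the mean number of reads each picked clone
    yields (Poisson); ``sub_error_rate`` is the per-base probability of a
    substitution to one of the three other bases, so the observed mismatch
    rate equals the error rate.  ``read_length`` truncates single-end reads
    (None = full molecule); ``paired`` emits two ends instead.
    """

    per_oligo_coverage: float = 30.0
    sub_error_rate: float = 0.0
    read_length: int | None = None
    paired: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.sub_error_rate < 1.0:
            raise ValueError("sub_error_rate must be in [0, 1)")
        if self.per_oligo_coverage < 1:
            raise ValueError("per_oligo_coverage must be >= 1")


def make_run_table(library: np.ndarray, N: int, seed: int = 0) -> pd.DataFrame:
    """Synthesize a run table: one row per clonal molecule.

    Columns ``read_id`` (0..n-1), ``core`` (the N-mer), ``x``, ``y``
    (uniform positions on the unit square).  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    n = int(np.asarray(library).size)
    return pd.DataFrame(
        {
            "read_id": np.arange(n, dtype=np.int64),
            "core": codes_to_seqs(np.asarray(library), N),
            "x": rng.random(n),
            "y": rng.random(n),
        }
    )


MISSING = "MISSING"


def _first_match_index(run: pd.DataFrame) -> dict[int, int]:
    """Map core code -> run row of the matching read with the lowest read_id."""
    cores = run["core"].to_numpy(dtype=str)
    if not cores.size:
        return {}
    N = len(cores[0])
    codes, valid = seqs_to_codes(cores, N)
    order = np.argsort(run["read_id"].to_numpy(), kind="stable")
    order = order[valid[order]]
    uniq, first_in_order = np.unique(codes[order], return_index=True)
    return dict(zip(uniq.tolist(), order[first_in_order].tolist()))


def make_picklist_from_cores(
    run: pd.DataFrame, targets: pd.DataFrame, tubes: list[TubePlan]
) -> pd.DataFrame:
    """Pick-list a table of designed cores against a run table.

    ``targets`` needs columns ``tile_id``, ``block_index``, ``core`` and
    optionally ``segment``; each target is assigned to the tube collecting
    its (segment, tile).
    """
    first = _first_match_index(run)
    tube_by = {(t.segment, t.tile_id): t for t in tubes}
    segments = (
        targets["segment"].to_numpy()
        if "segment" in targets.columns
        else np.zeros(len(targets), dtype=int)
    )
    rows = []
    for (_, t), seg in zip(targets.iterrows(), segments):
        core = t["core"]
        tube = tube_by[(int(seg), int(t["tile_id"]))]
        code, ok = seqs_to_codes([core], len(core))
        hit = first.get(int(code[0])) if ok[0] else None
        row = {
            "target_core": core,
            "tile_id": int(t["tile_id"]),
            "tube_id": tube.tube_id,
            "block_index": int(t["block_index"]),
            "read_id": MISSING,
            "x": np.nan,
            "y": np.nan,
        }
        if hit is not None:
            r = run.iloc[hit]
            row.update(read_id=int(r["read_id"]), x=float(r["x"]), y=float(r["y"]))
        rows.append(row)
    return pd.DataFrame(rows)


def make_picklist(
    run: pd.DataFrame, tiles: list[Tile], tubes: list[TubePlan]
) -> pd.DataFrame:
    """Locate one clone per designed core, per tube.

    For every tile's (address, data) core, the matching run row with the
    lowest read_id is assigned to that tile's tube; a target with no
    matching clone is recorded with read_id ``MISSING``.  Missing targets
    are data (the tiling exists to absorb them), not errors.
    """
    from .dna_map import digits_to_dna

    seg_by_tile = {t.tile_id: t.segment for t in tubes}
    rows = []
    for tile in tiles:
        for addr, blk in tile.assignments:
            rows.append(
                {
                    "tile_id": tile.tile_id,
                    "block_index": blk.position,
                    "core": digits_to_dna(addr.digits + blk.digits),
                    "segment": seg_by_tile.get(tile.tile_id, 0),
                }
            )
    return make_picklist_from_cores(run, pd.DataFrame(rows), tubes)


def picklist_summary(picks: pd.DataFrame) -> pd.DataFrame:
    """Per-tube satisfied-target fraction plus overall block satisfiability."""
    found = picks["read_id"] != MISSING
    per_tube = (
        picks.assign(found=found)
        .groupby("tube_id")["found"]
        .agg(["mean", "sum", "count"])
        .rename(columns={"mean": "satisfied_fraction", "sum": "picked", "count": "targets"})
        .reset_index()
    )
    return per_tube


def blocks_satisfiable(picks: pd.DataFrame) -> pd.Series:
    """For each block index, whether any tile located a matching clone."""
    return (picks["read_id"] != MISSING).groupby(picks["block_index"]).any()


_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


def _mutate(mat: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with one of the 3 others at probability ``rate``."""
    if rate <= 0 or mat.size == 0:
        return mat
    lut = np.full(256, 255, dtype=np.uint8)
    alphabet = b"ACGT"
    for i, b in enumerate(alphabet):
        lut[b] = i
    idx = lut[mat]
    hits = rng.random(mat.shape) < rate
    # offset 1..3 from the current base cycles to a different base
    offsets = rng.integers(1, 4, size=mat.shape, dtype=np.uint8)
    new_idx = (idx + np.where(hits, offsets, 0)) % 4
    out = np.frombuffer(alphabet, dtype=np.uint8)[new_idx]
    return np.where(idx == 255, mat, out).astype(np.uint8)


def simulate_pool_reads(
    picks: pd.DataFrame,
    oligos: list[OligoRecord],
    tubes: list[TubePlan],
    cfg: ReadSimConfig,
) -> dict[int, list[SimRead]]:
    """Simulate the re-sequencing of each tube's retrieved pool.

    Every picked clone yields Poisson(per_oligo_coverage) reads of the full
    amplicon — tube index, left adaptor, 8-mer core, right adaptor — with
    i.i.d. substitutions.  Qualities are a constant placeholder (Q40).  In
    paired mode each fragment instead yields a forward read of the first
    ``read_length`` bases and a reverse-complemented read of the last
    ``read_length`` bases, overlapping in the middle.
    """
    rng = np.random.default_rng(cfg.seed)
    oligo_by = {(o.segment, o.tile_id, o.block_index): o for o in oligos}
    tube_by_id = {t.tube_id: t for t in tubes}
    out: dict[int, list[SimRead]] = {t.tube_id: [] for t in tubes}

    picked = picks[picks["read_id"] != MISSING]
    for tube_id, group in picked.groupby("tube_id"):
        tube = tube_by_id[tube_id]
        templates = [
            tube.index_sequence
            + oligo_by[(tube.segment, int(r.tile_id), int(r.block_index))].full_sequence
            for r in group.itertuples()
        ]
        counts = rng.poisson(cfg.per_oligo_coverage, size=len(templates))
        expanded = np.repeat(np.arange(len(templates)), counts)
        if expanded.size == 0:
            continue
        L = len(templates[0])
        tmpl_mat = np.frombuffer(
            "".join(templates).encode(), dtype=np.uint8
        ).reshape(len(templates), L)
        reads_mat = _mutate(tmpl_mat[expanded], cfg.sub_error_rate, rng)

        reads = out[tube_id]
        if cfg.paired:
            rl = cfg.read_length or L
            rl = min(rl, L)
            qual = "I" * rl
            for k in range(reads_mat.shape[0]):
                seq = reads_mat[k].tobytes().decode()
                rid = f"tube{tube_id}_read{k}"
                reads.append(SimRead(rid + "/1", seq[:rl], qual))
                reads.append(SimRead(rid + "/2", _revcomp(seq[-rl:]), qual))
        else:
            rl = min(cfg.read_length or L, L)
            qual = "I" * rl
            for k in range(reads_mat.shape[0]):
                seq = reads_mat[k, :rl].tobytes().decode()
                reads.append(SimRead(f"tube{tube_id}_read{k}", seq, qual))
    return out


def write_fastq(reads: list[SimRead], path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.sequence), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = [ord(q) - 33 for q in r.qualities]
        records.append(rec)
    SeqIO.write(records, path, "fastq")


def read_fastq(path) -> list[SimRead]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(path, "fastq"):
        quals = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(SimRead(rec.id, str(rec.seq), quals))
    return out
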