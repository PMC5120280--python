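"""Degenerate-library simulations: coverage, saturation and capacity.

A single synthesis with N fully degenerate positions yields up to 4^N
distinct molecules; sequencing R clonal molecules observes only part of
that space.  This module provides

* i.i.d. sampling of an N-mer library under a per-position base
  composition,
* Monte-Carlo coverage-ratio curves (fraction of the 4^N space seen at
  least once among R reads, with mean / s.e.m. / CV over replicates),
  against the closed-form occupancy expectation ``1 - (1 - 4^-N)^R`` for
  the uniform case,
* down-sampling saturation curves of a realized library, and
* the capacity model: storing C addressed units in N-mer cores needs
  ``B = ceil(log4 C)`` address bases, leaving ``A = N - B`` data bases, for
  a total of ``b = C * A`` DNA bases and ``I = b / 2.85`` bytes.

Libraries are represented compactly as integer codes in ``[0, 4^N)``
(base-4 value of the sequence over the alphabet ACGT); helpers convert to
and from explicit sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codec import BASES_PER_BYTE

__all__ = [
    "LibrarySpec",
    "CoverageCurve",
    "CapacityModel",
    "sample_library",
    "coverage_ratio",
    "analytic_coverage",
    "saturation_curve",
    "capacity",
    "capacity_table",
    "codes_to_seqs",
    "seqs_to_codes",
]

#: Alphabet used for integer-coding library molecules (unrelated to the
#: digit->base rotation of the archive codec).
CODE_ALPHABET = "ACGT"

#: Largest N for which the 4^N space is tracked explicitly in memory.
MAX_EXPLICIT_N = 16


@dataclass(frozen=True)
class LibrarySpec:
    """Parameters of a degenerate-N-mer sequencing library.

    ``base_probs`` is the per-position composition over A, C, G, T (the
    synthesis may be biased); ``n_molecules`` is the number of clonal
    clusters the run yields.
    """

    N: int
    n_molecules: int
    base_probs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be >= 0")
        p = np.asarray(self.base_probs, dtype=float)
        if p.shape != (4,) or (p < 0).any():
            raise ValueError("base_probs must be 4 non-negative probabilities")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"base_probs sum to {p.sum()}, not 1")

    @property
    def uniform(self) -> bool:
        return all(abs(p - 0.25) < 1e-12 for p in self.base_probs)


def _draw_codes(rng: np.random.Generator, n: int, N: int, probs) -> np.ndarray:
    """n i.i.d. N-mer codes under a per-position base composition."""
    if N > 31:
        raise ValueError("N > 31 overflows the integer code representation")
    p = np.asarray(probs, dtype=float)
    if np.allclose(p, 0.25):
        return rng.integers(0, 4 ** N, size=n, dtype=np.int64)
    draws = rng.choice(4, size=(n, N), p=p / p.sum())
    weights = 4 ** np.arange(N - 1, -1, -1, dtype=np.int64)
    return draws @ weights


def sample_library(spec: LibrarySpec) -> np.ndarray:
    """Sample the library as an array of ``n_molecules`` integer codes."""
    rng = np.random.default_rng(spec.seed)
    return _draw_codes(rng, spec.n_molecules, spec.N, spec.base_probs)


def codes_to_seqs(codes: np.ndarray, N: int) -> np.ndarray:
    """Integer codes -> array of N-character ACGT strings (vectorized)."""
    codes = np.asarray(codes, dtype=np.int64)
    mat = np.empty((codes.size, N), dtype=np.uint8)
    lut = np.frombuffer(CODE_ALPHABET.encode(), dtype=np.uint8)
    v = codes.copy()
    for pos in range(N - 1, -1, -1):
        mat[:, pos] = lut[v % 4]
        v //= 4
    return mat.reshape(codes.size, N).view(f"S{N}").ravel().astype(str)


def seqs_to_codes(seqs, N: int) -> tuple[np.ndarray, np.ndarray]:
    """ACGT strings -> integer codes plus a validity mask."""
    arr = np.asarray(seqs, dtype=f"S{N}")
    mat = arr.view(np.uint8).reshape(arr.size, N)
    lut = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(CODE_ALPHABET):
        lut[ord(b)] = i
    idx = lut[mat]
    valid = (idx != 255).all(axis=1)
    weights = 4 ** np.arange(N - 1, -1, -1, dtype=np.int64)
    codes = idx.astype(np.int64) @ weights
    return codes, valid


@dataclass
class CoverageCurve:
    """Monte-Carlo coverage summary over a grid of read counts."""

    N: int
    reads_sampled: list[int]
    mean_coverage_ratio: np.ndarray
    sem: np.ndarray
    cv: np.ndarray
    replicates: int
    per_replicate: np.ndarray = field(repr=False)  # (replicates, grid)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "N": self.N,
                "reads": self.reads_sampled,
                "mean_coverage_ratio": self.mean_coverage_ratio,
                "sem": self.sem,
                "cv": self.cv,
                "replicates": self.replicates,
            }
        )


def analytic_coverage(N: int, reads: int) -> float:
    """Expected coverage ratio of a uniform degenerate space:
    ``1 - (1 - 4^-N)^R`` (occupancy / coupon-collector expectation)."""
    return 1.0 - (1.0 - 4.0 ** (-N)) ** reads


def analytic_coverage_std(N: int, reads: int) -> float:
    """Standard deviation of the coverage ratio of one uniform replicate.

    From the exact occupancy variance for R uniform draws into m = 4^N
    cells, with q1 = (1 - 1/m)^R and q2 = (1 - 2/m)^R:
    ``Var(V) = m q1 (1 - q1) + m (m - 1) (q2 - q1^2)``.
    """
    m = 4.0 ** N
    q1 = (1.0 - 1.0 / m) ** reads
    q2 = (1.0 - 2.0 / m) ** reads
    var = m * q1 * (1.0 - q1) + m * (m - 1.0) * (q2 - q1 * q1)
    return float(np.sqrt(max(var, 0.0))) / m


def coverage_ratio(
    spec: LibrarySpec,
    reads_grid: list[int],
    replicates: int = 10,
    mode: str = "auto",
) -> CoverageCurve:
    """Coverage ratio versus sequencing depth.

    For each read count R on the grid, the fraction of the 4^N space seen
    at least once among R sampled reads, across ``replicates`` Monte-Carlo
    replicates (replicate r reseeds with ``seed + r``).  Reads accumulate
    along the grid within a replicate, mirroring cumulative subsampling of
    one run, so each replicate's curve is non-decreasing by construction.

    ``mode='analytic'`` (automatic for N > 12 with uniform composition)
    substitutes the closed-form expectation with zero spread; explicit
    tracking of spaces beyond N = 16 is refused.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    grid = sorted(int(r) for r in reads_grid)
    if any(r < 0 for r in grid):
        raise ValueError("read counts must be non-negative")

    if mode == "auto":
        mode = "analytic" if (spec.N > 12 and spec.uniform) else "simulate"
    if mode == "analytic":
        if not spec.uniform:
            raise ValueError("analytic mode requires uniform base composition")
        mean = np.array([analytic_coverage(spec.N, r) for r in grid])
        zeros = np.zeros_like(mean)
        per_rep = np.tile(mean, (replicates, 1))
        return CoverageCurve(spec.N, grid, mean, zeros, zeros, replicates, per_rep)
    if spec.N > MAX_EXPLICIT_N:
        raise ValueError(
            f"4^{spec.N} distinct sequences cannot be tracked explicitly; "
            "use mode='analytic'"
        )

    space = 4 ** spec.N
    per_rep = np.empty((replicates, len(grid)))
    for r in range(replicates):
        rng = np.random.default_rng(spec.seed + r)
        seen = np.zeros(space, dtype=bool)
        drawn = 0
        for gi, R in enumerate(grid):
            chunk = _draw_codes(rng, R - drawn, spec.N, spec.base_probs)
            seen[chunk] = True
            drawn = R
            per_rep[r, gi] = seen.sum() / space
    mean = per_rep.mean(axis=0)
    sd = per_rep.std(axis=0, ddof=1) if replicates > 1 else np.zeros_like(mean)
    sem = sd / np.sqrt(replicates)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = np.where(mean > 0, sd / mean, 0.0)
    return CoverageCurve(spec.N, grid, mean, sem, cv, replicates, per_rep)


def saturation_curve(
    library: np.ndarray, fractions: list[float], seed: int = 0
) -> list[tuple[float, int]]:
    """Distinct molecules seen in nested random subsamples of a library.

    Fractions are sorted ascending and subsamples are nested (prefixes of
    one permutation), so the distinct count is non-decreasing; a plateau
    indicates the library's diversity is saturated at that depth.
    """
    fr = sorted(float(f) for f in fractions)
    if any(not 0.0 < f <= 1.0 for f in fr):
        raise ValueError("fractions must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(np.asarray(library))
    out = []
    for f in fr:
        k = max(1, int(round(f * perm.size))) if perm.size else 0
        out.append((f, int(np.unique(perm[:k]).size)))
    return out


@dataclass(frozen=True)
class CapacityModel:
    """Base budget for storing C addressed units in N-mer cores."""

    N: int
    C: int
    B: int  # address bases = ceil(log4 C)
    A: int  # data bases = N - B
    b: int  # total DNA bases = C * A
    I: float  # information bytes = b / 2.85

    def __post_init__(self) -> None:
        assert self.A + self.B == self.N and self.b == self.C * self.A


def _ceil_log4(C: int) -> int:
    """Smallest B with 4^B >= C, in exact integer arithmetic."""
    B = 0
    while 4 ** B < C:
        B += 1
    return B


def capacity(N: int, C: int) -> CapacityModel:
    """Evaluate the capacity model ``b = C * [N - ceil(log4 C)]``."""
    if N < 1 or C < 1:
        raise ValueError("N and C must be >= 1")
    B = _ceil_log4(C)
    if B >= N:
        raise ValueError(
            f"no room for data block: ceil(log4 {C}) = {B} address bases "
            f"fill the {N}-mer core"
        )
    A = N - B
    b = C * A
    return CapacityModel(N=N, C=C, B=B, A=A, b=b, I=b / BASES_PER_BYTE)


def capacity_table(N_values, C_values) -> pd.DataFrame:
    """Capacity model over a grid, skipping infeasible (N, C) pairs."""
    rows = []
    for N in N_values:
        for C in C_values:
            try:
                m = capacity(N, C)
            except ValueError:
                continue
            rows.append(vars(m))
    return pd.DataFrame(rows)
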