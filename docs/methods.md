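# Methods

## The storage model

A message is archived as a set of 8-mer "cores" drawn from a single
degenerate-oligonucleotide synthesis. Each core carries a 4-base address
block followed by a 4-base data block. The write path is purely
computational up to the pick list: the degenerate library is sequenced, each
clonal molecule's sequence and plate position are tabulated, and the
molecules whose 8-mers equal designed cores are retrieved into tubes. The
read path re-sequences each tube's pool and reassembles the message
*in silico*.

### Source coding

The codec builds a binary Huffman code from the case-folded symbol
frequencies of the message itself, so the code table (the "key") must
travel with the archive; it is serialized into the JSON key file together
with the character count, raw bit length, digit padding and tiling geometry.
Case folding is part of the format: recovery reproduces the lowercase form
of the message, and accuracy is judged against it.

Two related quantities are exposed and deliberately kept distinct:

* `shannon_information_bits(counts)` — the information content
  ⌈Σ nᵢ log₂(N/nᵢ)⌉ of the message, the lower bound on any prefix encoding.
  For the bundled 377-character demo message (27 symbols) this is **1569
  bits**.
* `HuffmanKey.raw_bit_length` — the realized optimal prefix-code total,
  **1581 bits** for the same message (0.8 % above the bound; verified
  optimal against a brute-force merge-order search on small alphabets and an
  independent greedy merge-cost oracle at full size).

No prefix code can reach the information bound exactly here, so the two
numbers genuinely differ; conflating them would assert an impossibility.
The analytic packing rate for a 27-symbol alphabet, log 27 / log 4 ≈ 2.38
base-4 digits per symbol, is available as `base4_digits_per_symbol`. The
constant 2.85 bases/byte used by the capacity model's byte conversion is a
documented operating constant of the original instrument setting, not a
quantity derived here.

### Bit→digit and digit→base conventions

Bit pairs map MSB-first (00/01/10/11 → 0/1/2/3); an odd-length bit stream
gets one appended 0 bit, and trailing 0 *digits* (recorded as `pad_count`,
0–3) pad the stream to whole 4-digit blocks. Digits map to bases with an
absolute first base (0,1,2,3 → T,C,G,A) and the rotation
`next = (prev + digit + 1) mod 4` afterwards — the simplest invertible
rotation consistent with the anchor example T + digit 2 → A. The rotation
restarts at the first base of every core, so cores decode independently.
Neither convention is forced by the format; both are fixed choices recorded
in the key file, and any self-consistent pair round-trips.

### Tiling and segmentation

Tile j assigns block i the address `(i + j) mod 256`; the default 8 tiles
give every block 8 distinct (address, data) cores, each collected into its
own tube with a distinct 6-nt index. The shift direction (+j) is a
recorded convention — sliding backwards would be equally valid. Messages
longer than 256 blocks are split into independent segments, each with its
own address space and tube set; indices are drawn from a deterministic
stream and stay pairwise distinct and distinct from the left adaptor's
prefix. Default adaptors are 100 nt (arbitrary fixed content) and 30 nt
(reverse complement of the library's reverse extension primer), making the
default full oligo 138 nt.

## Simulators

### Degenerate library

Molecules are i.i.d. N-mers with a per-position base composition
(uniform by default; a bias vector models synthesis bias). Libraries are
stored as integer codes in [0, 4^N), which keeps a 10^6-molecule library at
8 MB and makes distinct-set operations O(n log n). The run table adds
uniform unit-square (x, y) coordinates as an abstract stand-in for plate
pixel positions.

What the generator does *not* model: cluster-density physics, pyrosequencing
flow-space artifacts, homopolymer-length errors, PCR amplification bias in
the tube pools, and indels (errors are pure substitutions). Passing tests
therefore demonstrate the coding/decoding logic and its redundancy behavior,
not robustness to every artifact of a real run.

### Retrieval and re-sequencing

Pick lists take, per target core and tube, the matching run row with the
lowest read id (a reproducible stand-in for "the first bead found");
missing targets are recorded as data, since the tiling exists precisely to
absorb them. Each picked clone then yields Poisson(coverage) reads of
index + adaptor + core + adaptor. A substituted base is replaced by one of
the other three uniformly, so the observed mismatch rate equals the
configured error rate ε. Qualities are a constant Q40 placeholder; the
trimming stage is exercised by constructed fixtures instead. Paired-end
mode emits both fragment ends with a configurable overlap to exercise the
merger; single-end full-length is the default.

## Decoding

Filters run in the order length → index → core parse → address, each
discarding to a reason-coded counter. Index matching is exact (a single
substitution discards the read) and a read is attributed only to its tube's
tile — never guessed from sequence content. Addresses are unshifted by the
tube's tile offset; out-of-range addresses (≥ M for the segment) are
discarded, which also catches most substitution-corrupted addresses.
Consensus pools all tubes per block position and takes the most frequent
data 4-gram; a top-count tie falls back to the number of distinct
supporting tubes, and an unresolved tie or empty position is a gap that
fails the decode with the full gap list. Pooling across tubes is what
supplements positions missing from individual tubes.

With the default conditions (uniform N=8 library of 10^6 molecules, 8
tubes, 30× coverage, ε = 0.01) every core is expected in the library
(P(absent) ≈ e^−15 per core) and each block collects ≈ 240 reads of which
≈ 87 % survive the perfect filters, so the majority vote is effectively
never close; exact recovery holds across seeds, consistent with a
clean-retrieval regime rather than the depth-limited regime of a small
real run (where per-tube yields near 92 % force cross-tube
supplementation).

## Numerical and testing choices

* Huffman ties: merge the two lightest subtrees, ties by lexicographically
  smallest contained symbol, lighter subtree gets bit 0. Total length is
  tie-invariant; the rule only pins down the exact table.
* Coverage curves accumulate reads along the grid within a replicate
  (cumulative subsampling), so per-replicate monotonicity is structural.
  Replicates reseed as seed + replicate index; CV = sd/mean across
  replicates.
* The Monte-Carlo mean is compared to the occupancy closed form within
  3 standard errors, flooring the empirical SEM by the exact occupancy
  standard deviation (`Var(V) = m q₁(1−q₁) + m(m−1)(q₂−q₁²)`) because at
  shallow depth all replicates can see zero collisions, collapsing the
  empirical SEM to 0.
* Explicit distinct-space tracking is limited to N ≤ 16 (a 4^16 boolean
  array); beyond N = 12 uniform runs switch automatically to the analytic
  expectation.
* `capacity` uses exact integer arithmetic for ⌈log₄ C⌉ (smallest B with
  4^B ≥ C) to avoid float-log edge cases at exact powers of 4.
* Problem sizes in the test suite (libraries of 2–10 × 10^5 molecules for
  pipeline tests, coverage grids up to 10^5 reads) are chosen to keep the
  statistical assertions well-powered at desk scale while the full-scale
  default (10^6 molecules) is exercised in the acceptance path.

## Known limitations

* The error model is substitution-only; indels would break the fixed-offset
  core extraction and are filtered only indirectly via the length check.
* The rotation code does not avoid homopolymers or constrain GC content
  (digit 3 repeats the previous base).
* Consensus operates on whole 4-digit data grams, not per base; a
  position dominated by one wrong gram decodes incorrectly without warning
  beyond its support count.
* Stand-alone `picklist` requires the oligo TSV produced by `encode`; the
  key file alone cannot regenerate targets because it carries no payload.
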