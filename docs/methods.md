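# Methods

## The transcoding model

The codec merges two equal-length bit segments into one DNA sequence,
two bits per nucleotide. A *yang* rule is a balanced base→bit map (two
bases per bit value; six exist). A *yin* rule assigns a bit to each
base conditioned on the previous base, under the constraint that the
two members of each yang pair always carry different bits (2⁸ = 256 per
yang rule). For every (yang bit, yin bit, previous base) triple exactly
one base satisfies both rules — equivalently, for a fixed previous
base the map from bit pairs to bases is a bijection — which is what
makes decoding exact and position-local. A *virtual nucleotide*
(default A, configurable per scheme) stands in for the base before
position 0.

Schemes are enumerated canonically: yang rules sorted by their bit
vector over A < C < G < T; yin rules by an 8-bit choice vector ordered
(previous base A, C, G, T) × (group 0, group 1), where each choice bit
says which pair member takes bit 0. `scheme_by_id` maps ids 1…1536 via
`id − 1 = yang_index × 256 + yin_index`. This numbering is this
package's convention; published scheme numberings that depend on
unpublished tables are not reproduced. The `REFERENCE_SCHEME`
(id 598 here) pins the documented worked-example facts: yang
{A,T}→0, {C,G}→1; yin row for previous base A: A→0, T→1, G→0, C→1. The
yin rows for previous bases T, C, G are not documented for the original
example scheme, so the reference scheme completes them with the same
split — the worked example depends only on the prev = A row.

A consequence worth noting: a scheme whose yin rows are identical for
all previous bases (the reference scheme is one) is the degenerate
worst case for homopolymers, because a constant bit-pair region then
transcodes into a constant base. The screening/pairing stage, not the
scheme, is what guarantees run limits.

## Screening

Emitted sequences must satisfy, by default:

| constraint | default | notes |
|---|---|---|
| GC content | 40–60 % inclusive | bounds inclusive so the stated range is attainable |
| max homopolymer | ≤ 4 nt | runs ≥ 5 raise synthesis/sequencing error rates |
| folding free energy | ≥ −30 kcal/mol | estimator pluggable; screen can be disabled |

The default energy estimator scores the longest substring whose
reverse complement also occurs in the sequence at −1.5 kcal/mol per
base pair with a +5 kcal/mol nucleation penalty. It is a deliberately
cheap proxy whose job is to reject pathologically self-complementary
sequences; an adapter to ViennaRNA's minimum-free-energy fold
(`vienna_energy`) is provided where thermodynamic accuracy matters.
For random-like 160 nt sequences the longest self-complementary stem
is ~8–12 nt, far above the −30 threshold, which is why screening
compliance on that criterion is effectively total; the heuristic's
−1.5 kcal/mol/bp slope is conservative relative to nearest-neighbour
stacking energies.

## Pairing and pseudobinary fillers

Segments whose bit composition exceeds 80 % of one value are pooled
apart and always take the **yin** role against a balanced partner:
under strong/weak-partitioning yang rules the yang stream alone fixes
GC content, so the biased stream must not be the yang one. Pairs
failing the screen are broken up and re-paired among themselves for up
to six rounds (re-pairing re-randomises the yin stream and hence the
run structure); persistent failures are paired with freshly *designed*
pseudobinary fillers.

A designed filler takes the yang role and is built greedily: at every
payload position the filler chooses between two distinct candidate
bases (one per yang bit consistent with the partner's yin bit), at
most one of which can extend the current homopolymer run. Runs are
therefore capped by construction, and the remaining freedom steers GC
toward the band centre (with 15 % random tie-breaking so retries
explore different designs). The filler's address and RS bits are fixed
by the framing, so the RS tail is verified after payload construction
and the design is re-drawn if the tail spoils a constraint. Random
(undesigned) fillers only pair leftover balanced segments. This makes
the 100 % screening-compliance property hold by construction for
arbitrary inputs, at the cost of one filler segment per unpairable
data segment (heavily biased files therefore store at lower net
density — an inherent cost of the pseudobinary mechanism).

Addresses are whitened before framing: the index field is XORed with a
fixed alternating 0101… mask. Sequential addresses share long runs of
identical leading bits, and because *both* segments of a pair carry
them, those prefixes would transcode into homopolymer runs that no
re-pairing can break. The mask is a fixed reversible bijection,
removed again when frames are parsed.

## Framing and redundancy

The oligo-pool frame is `index(16) ∥ payload(128) ∥ RS(16)` = 160 bits;
two frames per 160 nt sequence; 20 nt primers on both ends give 200 nt
oligos. The RS code is a byte-symbol Reed–Solomon over GF(2⁸)
(primitive polynomial 0x11d) with 2 parity bytes covering the 18 bytes
of index-plus-payload: it corrects any single corrupted byte symbol —
up to two substitution errors when they fall in one symbol — and flags
(rather than passes through) frames beyond capacity. Covering the
index means address corruption is correctable; the alternative of
covering payload-only would have made XOR parity blocks valid
codewords, but leaves addresses unprotected, and address integrity is
what the decoder's reordering step depends on.

Logical redundancy: one XOR parity segment per four consecutive data
segments (25 % added segments before fillers). Parity segments XOR the
four payload regions, then receive their own address and freshly
computed RS — the XOR of four codewords over (index ∥ payload) is not
a valid codeword for the parity segment's own index, so parity is
taken over payloads and the RS region is recomputed. Any single
missing segment per group is reconstructed by XOR; two or more losses
in one group are reported as unrecovered.

Pseudobinary fillers occupy addresses strictly above all data and
parity addresses; the manifest records the boundaries, the per-file
bit lengths and index ranges, the scheme id, primers and the seed, and
is required for decoding (no header-embedded fallback).

The double-stranded profile frames 456-bit payloads with 3 RS parity
bytes (24 bits) per strand-stream, two streams per 480 nt block; 113
blocks span (456 + 24) × 113 = 54,240 bp and carry ~12.9 kB. The
"456 bits" reading (57 bytes) is used throughout for the payload unit.

## Decoding and the recovery metric

Decode reverses each step: primer stripping (sequences whose length
differs from the designed 200 nt are treated as frameshifted and both
carried segments counted lost — no realignment is attempted), stream
extraction, RS repair, reordering by address, XOR recovery, dropping
of filler addresses, concatenation and truncation to the recorded bit
length. Missing payloads are zero-filled so partial recovery still
yields files of the right size.

The recovery rate is `100 × exactly-recovered data segments / data
segments`: a segment counts only on exact bit equality after repair,
and parity/pseudobinary segments are excluded from the denominator.
Duplicate addresses keep the first occurrence (yang-stream frames
parse first).

## Error, dropout and dilution models

`ErrorModel` supports two rate semantics. `per_sequence` (default)
corrupts each sequence with the given probability by a single random
event; `per_nucleotide` applies the rate per base independently. The
default reflects the robustness regime the codec is characterised in:
~1 % of *sequences* corrupted leaves recovery near 99 %, whereas 1 %
per-nucleotide would corrupt nearly every 160 nt sequence. Both are
available behind a flag. Dropout removes exactly `round(rate × n)`
sequences (`exact_count`) or each independently (`bernoulli`).
Dilution draws each oligo's surviving copy count from Poisson(AMC);
the lost fraction converges to e^(−AMC). Indels change sequence length
and are not re-padded, so affected sequences decode as frameshifted.

Without parity, each lost sequence costs exactly its two data
segments, so expected recovery under dropout is 100 × (1 − loss) —
the linear-retrieval property; with per-sequence substitution at rate
r and no RS repair, recovery is bounded below by 100 × (1 − 2r) since
a corrupted sequence loses at most its two segments.

## Consensus

Read pools collapse by exact match with counts (optionally filtered to
the designed length); colony-style recovery uses column-wise
single-winner plurality voting over pre-aligned equal-length rows,
with gaps voting as a fifth symbol, deterministic tie-breaking
(A < C < G < T < −, ties flagged), and gap-winning columns removed.
Alignment/assembly is accepted as input; MSA is out of scope.

Voting recovers the template exactly at every column where the
template base holds a strict plurality. The colony generator draws one
contiguous deletion block per affected colony; with heavy losses
(retention down to 40 %), long blocks cover central columns often
enough that some columns become majority-gapped — those positions are
unrecoverable by voting from any number of colonies, which the tests
state explicitly. In the moderate-loss regime (retention 60–95 %) full
template recovery is the typical outcome at 15 colonies.

## Synthetic data

The file generator draws i.i.d. bits at a specified 1-bit bias
(balanced, biased, text-like or all-zero); the mixed-file helper
concatenates sections of different biases to exercise the imbalanced
pool. It emulates the *bit composition* of real files, not their
serial correlation structure; since the codec operates on fixed-length
segments with screening decisions driven by bit composition and local
randomness, compliance and recovery results on these inputs transfer
to real files with similar segment-level bias profiles, but the
generator says nothing about, e.g., compressed-container fragility
(loss of any segment of a compressed archive can void the rest — a
property of the container, not the codec). The read-pool generator
emits each oligo a fixed number of times with per-read errors; the
colony generator is described above. All generators are
seed-deterministic.

## Problem sizes and defaults used in the shipped analyses

The headline analyses (`scripts/acceptance.py`, mirrored by the
acceptance tests) use ~1 MB inputs: 1,000,000 bytes = 62,500 data
segments, chosen so data plus fillers stay inside the 16-bit address
space for the balanced pool (a full MiB would not). Robustness runs
use 10 seeds per condition with parity disabled and RS repair off, the
regime in which the linear-retrieval and raw-error baselines are
defined. The mixed-bias compliance run uses eight equal sections with
biases (0.5, 0.9, 0.5, 0.5, 0.1, 0.5, 0.5, 0.5) — a quarter of the
content heavily biased, a stress level chosen to engage the
pseudobinary mechanism at scale while representing a realistic file
collection — framed with 24-bit addresses because data + filler
segments (~80 k) exceed 2¹⁶.

## Numerical and design notes

* Density calculators use the average nucleotide molar mass
  330.95 g/mol and the CODATA Avogadro constant 6.02214076 × 10²³ /mol;
  results agree with the standard printed design-point values to well
  under 2 %, which absorbs print rounding.
* The energy threshold is stated in kcal/mol throughout.
* GC bounds are inclusive; the homopolymer limit is "≤ 4 nt".
* Pairing, filler design and all simulations are deterministic for a
  fixed seed (numpy Generator threading throughout).
* Degenerate inputs: empty files and empty segments are rejected with
  errors; an entirely lost pool decodes to zero-filled files with a
  0 % report rather than crashing; unpairable segments (exhausted
  repair budget) raise an error naming the segment positions instead
  of being dropped silently.

## Known limitations

* The stem heuristic is not a thermodynamic model; use the ViennaRNA
  adapter when folding accuracy matters.
* No realignment of frameshifted sequences: a single indel costs both
  carried segments (consistent with treating indels as the hard error
  class).
* Bounded-distance RS decoding can miscorrect codewords corrupted
  beyond capacity (inherent to the code); the XOR parity layer and
  exact-match recovery accounting limit the impact.
* Read clustering/assembly and multiple sequence alignment are
  accepted as inputs, not computed.
* Primer design is out of scope; defaults are fixture constants.
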