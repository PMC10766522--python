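"""Bit-segment incorporation, biochemical screening and segment pairing.

Two equal-length bit segments are merged into one DNA sequence, one
nucleotide per bit pair: position ``i`` encodes bit ``i`` of the yang
segment and bit ``i`` of the yin segment, with the yin rule conditioned
on the base written at position ``i-1`` (the scheme's virtual nucleotide
before position 0).

Candidate sequences are screened for synthesis/sequencing compatibility:
GC content within bounds, homopolymer runs capped, and (optionally) a
predicted secondary-structure free energy above a threshold.  Segment
pairs that fail the screen are re-paired with different partners and, as
a last resort, with freshly generated balanced "pseudobinary" filler
segments, so that every emitted sequence satisfies the active policy by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .rules import BASES, BASE_CODE, CodingScheme

__all__ = [
    "ScreenPolicy",
    "PoolEncodeResult",
    "UnpairableSegmentError",
    "incorporate_segments",
    "extract_segments",
    "incorporate_matrix",
    "extract_matrix",
    "gc_content",
    "max_homopolymer_run",
    "screen_sequence",
    "stem_energy_estimate",
    "vienna_energy",
    "pair_and_encode_pool",
    "design_filler_bits",
    "bits_to_array",
    "array_to_bits",
    "codes_to_str",
    "str_to_codes",
]

_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)
_GC_CODES = (BASE_CODE["G"], BASE_CODE["C"])


def bits_to_array(bits: str | Sequence[int] | np.ndarray) -> np.ndarray:
    """Coerce a bit string / sequence to a uint8 array of 0s and 1s."""
    if isinstance(bits, str):
        arr = np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    else:
        arr = np.asarray(bits, dtype=np.uint8)
    if arr.size == 0:
        raise ValueError("empty bit segment")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("bit segment may contain only 0 and 1")
    return arr


def array_to_bits(arr: np.ndarray) -> str:
    return "".join("01"[b] for b in arr)


def codes_to_str(codes: np.ndarray) -> str:
    return _ASCII[codes].tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    codes = np.full(raw.shape, 255, dtype=np.uint8)
    for base, code in BASE_CODE.items():
        codes[raw == ord(base)] = code
    if (codes == 255).any():
        bad = seq[int(np.argmax(codes == 255))]
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return codes


# ---------------------------------------------------------------------------
# Incorporation / extraction
# ---------------------------------------------------------------------------

def incorporate_matrix(
    yang_bits: np.ndarray, yin_bits: np.ndarray, scheme: CodingScheme
) -> np.ndarray:
    """Vectorised incorporation of ``(n, L)`` bit matrices into base codes.

    Sequential in L (the yin rule consumes the previous written base) but
    vectorised across the n sequences.
    """
    yang_bits = np.atleast_2d(yang_bits)
    yin_bits = np.atleast_2d(yin_bits)
    if yang_bits.shape != yin_bits.shape:
        raise ValueError(
            f"segment shape mismatch: {yang_bits.shape} vs {yin_bits.shape}"
        )
    n, length = yang_bits.shape
    lut = scheme.encode_lut
    out = np.empty((n, length), dtype=np.uint8)
    prev = np.full(n, BASE_CODE[scheme.virtual_prev], dtype=np.uint8)
    for i in range(length):
        prev = lut[yang_bits[:, i], yin_bits[:, i], prev]
        out[:, i] = prev
    return out


def extract_matrix(codes: np.ndarray, scheme: CodingScheme) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`incorporate_matrix`; fully vectorised."""
    codes = np.atleast_2d(codes)
    prev = np.empty_like(codes)
    prev[:, 0] = BASE_CODE[scheme.virtual_prev]
    prev[:, 1:] = codes[:, :-1]
    return scheme.yang_lut[codes], scheme.yin_lut[prev, codes]


def incorporate_segments(
    seg_yang: str | np.ndarray, seg_yin: str | np.ndarray, scheme: CodingScheme
) -> str:
    """Merge two equal-length bit segments into one DNA sequence."""
    a = bits_to_array(seg_yang)
    b = bits_to_array(seg_yin)
    if a.shape != b.shape:
        raise ValueError(f"segment length mismatch: {a.size} vs {b.size}")
    return codes_to_str(incorporate_matrix(a, b, scheme)[0])


def extract_segments(seq: str, scheme: CodingScheme) -> tuple[str, str]:
    """Recover the (yang, yin) bit segments from an uncorrupted sequence."""
    if not seq:
        raise ValueError("empty sequence")
    codes = str_to_codes(seq)
    a, b = extract_matrix(codes, scheme)
    return array_to_bits(a[0]), array_to_bits(b[0])


# ---------------------------------------------------------------------------
# Screening metrics
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """GC content in percent."""
    if not seq:
        raise ValueError("empty sequence")
    gc = seq.count("G") + seq.count("C")
    return 100.0 * gc / len(seq)


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of a single base."""
    if not seq:
        raise ValueError("empty sequence")
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _longest_selfcomp_match(seq: str) -> int:
    """Longest substring of ``seq`` whose reverse complement also occurs in it.

    Upper bound on the stem length of any hairpin/duplex the strand can
    fold into (loop-geometry constraints ignored, so it is conservative).
    """
    rc = _revcomp(seq)
    n = len(seq)

    def has_common(k: int) -> bool:
        if k <= 0:
            return True
        if k > n:
            return False
        kmers = {seq[i : i + k] for i in range(n - k + 1)}
        return any(rc[i : i + k] in kmers for i in range(n - k + 1))

    # exponential probe then binary search on the match length
    k = 1
    while has_common(k * 2) and k * 2 <= n:
        k *= 2
    lo, hi = k, min(2 * k, n)  # has_common(lo) True, has_common(hi+1) False-ish
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if has_common(mid):
            lo = mid
        else:
            hi = mid - 1
    return lo


def stem_energy_estimate(seq: str) -> float:
    """Crude folding free-energy proxy in kcal/mol.

    Scores the longest self-complementary stem at -1.5 kcal/mol per base
    pair with a +5 kcal/mol nucleation penalty, floored at 0 for short
    stems.  A fast stand-in for thermodynamic folding: adequate for
    screening out pathologically self-complementary sequences, not for
    quantitative structure prediction.
    """
    stem = _longest_selfcomp_match(seq)
    return min(0.0, 5.0 - 1.5 * stem)


def vienna_energy(seq: str) -> float:
    """Minimum free energy (kcal/mol) from ViennaRNA's fold, if installed."""
    import RNA  # deferred: optional dependency

    return float(RNA.fold(seq)[1])


@dataclass
class ScreenPolicy:
    """Acceptance criteria for candidate DNA sequences.

    Defaults: GC in [40, 60] %, homopolymer runs of at most 4 nt, and
    estimated folding free energy of at least -30 kcal/mol.  Setting
    ``energy_estimator`` to None disables the (comparatively slow)
    free-energy screen; GC and homopolymer checks always run.
    """

    gc_min: float = 40.0
    gc_max: float = 60.0
    max_homopolymer: int = 4
    energy_threshold: float = -30.0
    energy_estimator: Callable[[str], float] | None = field(
        default=stem_energy_estimate
    )
    max_repair_attempts: int = 100

    def __post_init__(self) -> None:
        if not 0 <= self.gc_min <= self.gc_max <= 100:
            raise ValueError("require 0 <= gc_min <= gc_max <= 100")
        if self.max_homopolymer < 1:
            raise ValueError("max_homopolymer must be >= 1")


def screen_sequence(seq: str, policy: ScreenPolicy) -> tuple[bool, str | None]:
    """Check one sequence; returns (accept, reason-of-first-failure)."""
    gc = gc_content(seq)
    if not policy.gc_min <= gc <= policy.gc_max:
        return False, "gc"
    if max_homopolymer_run(seq) > policy.max_homopolymer:
        return False, "homopolymer"
    if policy.energy_estimator is not None:
        if policy.energy_estimator(seq) < policy.energy_threshold:
            return False, "energy"
    return True, None


def _screen_matrix(codes: np.ndarray, policy: ScreenPolicy) -> np.ndarray:
    """Vectorised accept mask for an (n, L) base-code matrix."""
    n, length = codes.shape
    gc = np.isin(codes, _GC_CODES).sum(axis=1) * (100.0 / length)
    ok = (gc >= policy.gc_min) & (gc <= policy.gc_max)
    run = np.ones(n, dtype=np.int32)
    max_run = np.ones(n, dtype=np.int32)
    for i in range(1, length):
        same = codes[:, i] == codes[:, i - 1]
        run = np.where(same, run + 1, 1)
        np.maximum(max_run, run, out=max_run)
    ok &= max_run <= policy.max_homopolymer
    if policy.energy_estimator is not None:
        for row in np.flatnonzero(ok):
            if policy.energy_estimator(codes_to_str(codes[row])) < policy.energy_threshold:
                ok[row] = False
    return ok


# ---------------------------------------------------------------------------
# Segment pairing
# ---------------------------------------------------------------------------

class UnpairableSegmentError(RuntimeError):
    """Raised when segments cannot be paired into screen-passing sequences."""

    def __init__(self, segment_positions: list[int]):
        self.segment_positions = segment_positions
        super().__init__(
            f"{len(segment_positions)} segment(s) unpairable after exhausting "
            f"repair attempts: positions {segment_positions[:10]}"
        )


@dataclass
class PoolEncodeResult:
    """Outcome of :func:`pair_and_encode_pool`.

    ``pairs[i] = (yang_ref, yin_ref)`` refer to positions in the input
    segment list; references >= ``n_input`` point into ``fillers``
    (pseudobinary segments generated during repair, in order).
    """

    sequences: list[str]
    pairs: list[tuple[int, int]]
    fillers: list[np.ndarray]
    n_input: int
    n_repair_rounds: int = 0


IMBALANCE_THRESHOLD = 0.8  # ones (or zeros) ratio above which a segment is pooled apart


def _is_imbalanced(seg: np.ndarray, threshold: float = IMBALANCE_THRESHOLD) -> bool:
    ones = float(seg.mean())
    return ones > threshold or ones < 1.0 - threshold


#: re-pairing rounds among data segments before falling back to designed fillers
_REPAIR_ROUNDS_BEFORE_FILLER = 6


def design_filler_bits(
    partner: np.ndarray,
    scheme: CodingScheme,
    policy: ScreenPolicy,
    rng: np.random.Generator,
    max_tries: int = 16,
) -> np.ndarray:
    """Greedy pseudobinary segment designed against a partner (yang role).

    At every position the filler chooses between two distinct bases (one
    per yang bit consistent with the partner's yin bit), at most one of
    which extends the current homopolymer run, so runs are capped by
    construction; the remaining freedom steers GC toward the centre of
    the allowed band.
    """
    partner_l = [int(x) for x in bits_to_array(partner)]
    lut = scheme.encode_lut.tolist()
    length = len(partner_l)
    gc_target = (policy.gc_min + policy.gc_max) / 200.0
    max_run = policy.max_homopolymer
    is_gc = (0, 1, 1, 0)  # base codes A, C, G, T
    lo = policy.gc_min * length / 100.0
    hi = policy.gc_max * length / 100.0
    virtual = BASE_CODE[scheme.virtual_prev]
    bits = None
    for _ in range(max_tries):
        bits = [0] * length
        jitter = (rng.random(length) < 0.15).tolist()
        coin = rng.integers(0, 2, size=length).tolist()
        prev, run, gc = virtual, 1, 0
        for i, b in enumerate(partner_l):
            base0 = lut[0][b][prev]
            base1 = lut[1][b][prev]
            full = run >= max_run
            if full and base0 == prev:
                a, base = 1, base1
            elif full and base1 == prev:
                a, base = 0, base0
            elif jitter[i]:
                a = coin[i]
                base = base1 if a else base0
            else:
                d0 = abs((gc + is_gc[base0]) / (i + 1) - gc_target)
                d1 = abs((gc + is_gc[base1]) / (i + 1) - gc_target)
                a, base = (1, base1) if d1 < d0 else (0, base0)
            bits[i] = a
            run = run + 1 if base == prev else 1
            gc += is_gc[base]
            prev = base
        if lo <= gc <= hi:
            break
    return np.array(bits, dtype=np.uint8)


def pair_and_encode_pool(
    segments: Sequence[np.ndarray | str],
    scheme: CodingScheme,
    policy: ScreenPolicy | None = None,
    rng: np.random.Generator | int | None = 0,
    filler_factory: Callable[..., np.ndarray] | None = None,
) -> PoolEncodeResult:
    """Pair bit segments and encode them into screen-passing DNA sequences.

    Heavily imbalanced segments (>80% of one bit value) are pooled apart
    and paired against randomly drawn balanced partners; balanced
    segments pair among themselves.  Pairs failing the screen are
    re-paired with different partners for a few rounds; persistent
    failures get freshly generated pseudobinary fillers from
    ``filler_factory(k, rng, partner=bits_or_None)``, which may design
    the filler against the partner (the yang role is the filler's when a
    partner is supplied).  The loop is capped at
    ``policy.max_repair_attempts`` rounds.  Deterministic for a fixed
    rng seed.
    """
    if policy is None:
        policy = ScreenPolicy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    segs = [bits_to_array(s) for s in segments]
    if not segs:
        return PoolEncodeResult([], [], [], 0)
    length = segs[0].size
    if any(s.size != length for s in segs):
        raise ValueError("all segments must have equal length")
    if filler_factory is None:
        def filler_factory(_k, r, partner=None):
            if partner is None:
                return r.integers(0, 2, size=length, dtype=np.uint8)
            return design_filler_bits(partner, scheme, policy, r)

    n = len(segs)
    balanced = [i for i in range(n) if not _is_imbalanced(segs[i])]
    imbalanced = [i for i in range(n) if _is_imbalanced(segs[i])]
    rng.shuffle(balanced)

    all_segs = list(segs)  # fillers appended as created
    fillers: list[np.ndarray] = []

    def make_filler(partner: np.ndarray | None = None) -> int:
        k = len(fillers)
        f = bits_to_array(filler_factory(k, rng, partner=partner))
        if f.size != length:
            raise ValueError("filler factory returned wrong length")
        fillers.append(f)
        all_segs.append(f)
        return n + k

    # initial pairing: each imbalanced segment takes the yin role against
    # a balanced partner; balanced leftovers pair among themselves
    pending: list[tuple[int, int]] = []
    bal = list(balanced)
    for i in imbalanced:
        if bal:
            pending.append((bal.pop(), i))
        else:
            pending.append((make_filler(partner=segs[i]), i))
    while len(bal) >= 2:
        pending.append((bal.pop(), bal.pop()))
    for i in bal:
        pending.append((make_filler(partner=segs[i]), i))

    accepted_seqs: list[str] = []
    accepted_pairs: list[tuple[int, int]] = []
    rounds = 0
    while pending:
        if rounds >= policy.max_repair_attempts:
            leftover = sorted({p for pair in pending for p in pair if p < n})
            raise UnpairableSegmentError(leftover)
        ya = np.stack([all_segs[p[0]] for p in pending])
        yi = np.stack([all_segs[p[1]] for p in pending])
        codes = incorporate_matrix(ya, yi, scheme)
        ok = _screen_matrix(codes, policy)
        for row in np.flatnonzero(ok):
            accepted_seqs.append(codes_to_str(codes[row]))
            accepted_pairs.append(pending[row])
        failed = [pending[row] for row in np.flatnonzero(~ok)]
        rounds += 1

        # break failed pairs apart and re-pair; filler partners are dropped
        loose = [p for pair in failed for p in pair if p < n]
        pending = []
        if not loose:
            continue
        loose_bal = [i for i in loose if not _is_imbalanced(all_segs[i])]
        loose_imb = [i for i in loose if _is_imbalanced(all_segs[i])]
        rng.shuffle(loose_bal)
        repair = rounds < _REPAIR_ROUNDS_BEFORE_FILLER
        for i in loose_imb:
            # an imbalanced segment rarely screens with a random partner;
            # go straight to a designed pseudobinary filler
            pending.append((make_filler(partner=all_segs[i]), i))
        while len(loose_bal) >= 2 and repair:
            pending.append((loose_bal.pop(), loose_bal.pop()))
        for i in loose_bal:
            pending.append((make_filler(partner=all_segs[i]), i))

    return PoolEncodeResult(
        sequences=accepted_seqs,
        pairs=accepted_pairs,
        fillers=fillers,
        n_input=n,
        n_repair_rounds=rounds,
    )
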