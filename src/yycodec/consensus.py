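"""Consensus building from redundant sequence observations.

Two reductions are provided: exact-match collapsing of read pools into
(sequence, count) ranks, and column-wise single-winner plurality voting
across pre-aligned equal-length sequences — the strategy used to rescue
a stored fragment from a population of cell lineages, each of which may
carry partial deletions or point mutations.  Alignment itself (MSA,
assembly) is accepted as input, not computed here.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["AlignedSet", "ConsensusResult", "collapse_reads", "plurality_consensus"]

#: symbol order used for deterministic tie-breaking (gap last)
_SYMBOLS = "ACGT-"
_SYM_INDEX = {s: i for i, s in enumerate(_SYMBOLS)}


@dataclass
class AlignedSet:
    """Equal-length sequences over {A, C, G, T, -} with optional weights."""

    sequences: list[str]
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("at least one sequence required")
        length = len(self.sequences[0])
        if any(len(s) != length for s in self.sequences):
            raise ValueError("aligned sequences must have equal length")
        for s in self.sequences:
            if any(c not in _SYM_INDEX for c in s):
                raise ValueError("sequences may contain only A, C, G, T and -")
        if self.weights is not None and len(self.weights) != len(self.sequences):
            raise ValueError("one weight per sequence required")


@dataclass
class ConsensusResult:
    sequence: str  # gap-winning columns removed
    aligned_consensus: str  # with gaps, one symbol per column
    ambiguous_columns: list[int]  # 0-based columns with vote ties


def collapse_reads(
    reads: Sequence[str], expected_length: int | None = None
) -> list[tuple[str, int]]:
    """Exact-match deduplication with counts, ranked by count (desc).

    ``expected_length`` filters reads to the designed oligo length
    first; ties rank lexicographically for determinism.
    """
    if expected_length is not None:
        reads = [r for r in reads if len(r) == expected_length]
    counts = Counter(reads)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def plurality_consensus(aligned: AlignedSet) -> ConsensusResult:
    """Column-wise single-winner plurality vote.

    Per column the (weighted) most frequent symbol wins; ties are
    flagged and broken by the fixed order A < C < G < T < -.  Columns
    won by the gap symbol are removed from the returned sequence.
    """
    n = len(aligned.sequences)
    length = len(aligned.sequences[0])
    weights = (
        np.asarray(aligned.weights, dtype=float)
        if aligned.weights is not None
        else np.ones(n)
    )
    mat = np.frombuffer(
        "".join(aligned.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(n, length)
    codes = np.zeros_like(mat)
    for sym, i in _SYM_INDEX.items():
        codes[mat == ord(sym)] = i

    votes = np.zeros((len(_SYMBOLS), length))
    for i in range(len(_SYMBOLS)):
        votes[i] = ((codes == i) * weights[:, None]).sum(axis=0)
    winners = votes.argmax(axis=0)  # argmax takes the first max: A<C<G<T<-
    top = votes.max(axis=0)
    ambiguous = [
        int(c) for c in range(length) if (votes[:, c] == top[c]).sum() > 1
    ]
    aligned_consensus = "".join(_SYMBOLS[w] for w in winners)
    sequence = aligned_consensus.replace("-", "")
    return ConsensusResult(
        sequence=sequence,
        aligned_consensus=aligned_consensus,
        ambiguous_columns=ambiguous,
    )
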