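"""Deterministic synthetic data: files, read pools and colony sets.

Every stage of the codec is testable without external data.  The file
generator emulates the binary side (balanced, bit-biased or degenerate
inputs, exercising the imbalanced-segment pool); the read-pool
generator emulates sequencing a synthesized pool at a given depth with
per-read errors; the colony-set generator emulates a population of
cell lineages each retaining the stored fragment with contiguous
deletions and sparse point mutations, gap-aligned to the template
coordinates so plurality voting can be tested against ground truth.

All generators are seed-deterministic: identical specs yield identical
bytes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .consensus import AlignedSet
from .robustness import ErrorModel, apply_error_model

__all__ = [
    "SyntheticSpec",
    "gen_file",
    "gen_mixed_file",
    "gen_read_pool",
    "gen_colony_set",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic binary file."""

    size_bytes: int
    bit_bias: float = 0.5  # fraction of 1-bits (kind="random")
    kind: str = "random"  # random | text-like | all-zero
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size_bytes < 1:
            raise ValueError("size_bytes must be >= 1")
        if not 0.0 <= self.bit_bias <= 1.0:
            raise ValueError("bit_bias must be in [0, 1]")
        if self.kind not in ("random", "text-like", "all-zero"):
            raise ValueError(f"unknown kind {self.kind!r}")


def gen_file(spec: SyntheticSpec) -> bytes:
    """Deterministic synthetic file content for a spec."""
    rng = np.random.default_rng(spec.seed)
    if spec.kind == "all-zero":
        return bytes(spec.size_bytes)
    if spec.kind == "text-like":
        # ASCII letters and spaces: structured, byte-biased input
        alphabet = np.frombuffer(
            b"abcdefghijklmnopqrstuvwxyz ETAOIN. \n", dtype=np.uint8
        )
        return rng.choice(alphabet, size=spec.size_bytes).tobytes()
    bits = (rng.random(spec.size_bytes * 8) < spec.bit_bias).astype(np.uint8)
    return np.packbits(bits).tobytes()


def gen_mixed_file(
    size_bytes: int, biases: Sequence[float] = (0.5, 0.9, 0.5, 0.1), seed: int = 0
) -> bytes:
    """Concatenation of equal-sized sections with different bit biases.

    Biased sections produce the heavily imbalanced segments that the
    pairing stage routes into the separate pool.
    """
    if size_bytes < len(biases):
        raise ValueError("size_bytes smaller than the number of sections")
    per = size_bytes // len(biases)
    parts = []
    for i, bias in enumerate(biases):
        n = per if i < len(biases) - 1 else size_bytes - per * (len(biases) - 1)
        parts.append(gen_file(SyntheticSpec(n, bit_bias=bias, seed=seed + i)))
    return b"".join(parts)


def gen_read_pool(
    pool: Sequence[str],
    depth: int,
    error_model: ErrorModel | None = None,
    seed: int = 0,
) -> list[str]:
    """Emulate sequencing: each oligo read ``depth`` times with per-read
    errors, reads shuffled."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    reads = [seq for seq in pool for _ in range(depth)]
    if error_model is not None:
        reads = apply_error_model(reads, error_model, rng)
    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def gen_colony_set(
    template: str,
    n_colonies: int,
    retention_range: tuple[float, float] = (0.4, 0.95),
    snv_rate: float = 1e-3,
    deletion_prob: float = 0.8,
    seed: int = 0,
) -> AlignedSet:
    """Colony sequences gap-aligned to the template coordinates.

    With probability ``deletion_prob`` a colony loses one contiguous
    block sized so that the retained fraction is uniform in
    ``retention_range``; surviving positions mutate independently at
    ``snv_rate``.  Gaps are written as '-' so all rows stay
    template-length.
    """
    if n_colonies < 1:
        raise ValueError("n_colonies must be >= 1")
    lo, hi = retention_range
    if not 0.0 <= lo <= hi <= 1.0:
        raise ValueError("retention_range must satisfy 0 <= lo <= hi <= 1")
    rng = np.random.default_rng(seed)
    length = len(template)
    bases = "ACGT"
    rows = []
    for _ in range(n_colonies):
        row = list(template)
        if rng.random() < deletion_prob and length > 0:
            retention = rng.uniform(lo, hi)
            del_len = int(round((1.0 - retention) * length))
            if del_len > 0:
                start = int(rng.integers(0, length - del_len + 1))
                row[start : start + del_len] = ["-"] * del_len
        if snv_rate > 0:
            for pos in np.flatnonzero(rng.random(length) < snv_rate):
                if row[pos] != "-":
                    choices = [b for b in bases if b != row[pos]]
                    row[pos] = choices[rng.integers(3)]
        rows.append("".join(row))
    return AlignedSet(sequences=rows)
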