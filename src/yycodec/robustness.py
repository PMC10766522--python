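"""In silico robustness experiments: errors, dropout and dilution.

Reproduces the simulation designs used to characterise the codec:
random substitutions and indels at rates from 0.01% to 1%, uniform
sequence loss up to total erasure, and copy-number dilution in which
each oligo survives with Poisson-distributed copy counts.  Sweep
drivers re-perturb one encoded pool across seeds and report the mean
and spread of the exact-match segment recovery rate.

Two rate semantics are supported.  ``per_sequence`` (the default)
corrupts each sequence with the given probability by a single random
event; ``per_nucleotide`` applies the rate independently per base.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .framing import FrameLayout
from .pipeline import EncodeResult, _decode_segments, encode_file, recovery_rate
from .rules import BASES, CodingScheme
from .transcode import ScreenPolicy

__all__ = [
    "ErrorModel",
    "apply_substitutions",
    "apply_indels",
    "apply_dropout",
    "simulate_dilution",
    "apply_error_model",
    "sweep_recovery",
    "SweepRow",
]


@dataclass(frozen=True)
class ErrorModel:
    """Rates and semantics for pool perturbation.

    All rates are fractions in [0, 1].  ``loss_mode='exact_count'``
    removes exactly ``round(loss_rate * n)`` sequences; ``'bernoulli'``
    removes each independently.  ``amc`` is the average molecule copy
    number for dilution (None disables it).
    """

    snv_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0
    rate_semantics: str = "per_sequence"
    loss_rate: float = 0.0
    loss_mode: str = "exact_count"
    amc: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("snv_rate", "ins_rate", "del_rate", "loss_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rate_semantics not in ("per_sequence", "per_nucleotide"):
            raise ValueError(f"unknown rate semantics {self.rate_semantics!r}")
        if self.loss_mode not in ("exact_count", "bernoulli"):
            raise ValueError(f"unknown loss mode {self.loss_mode!r}")
        if self.amc is not None and self.amc < 0:
            raise ValueError("amc must be >= 0")


def _rng(model_or_seed, rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if rng is not None:
        return np.random.default_rng(rng)
    return np.random.default_rng(model_or_seed.seed)


def _substitute(seq: str, pos: int, rng: np.random.Generator) -> str:
    old = seq[pos]
    choices = [b for b in BASES if b != old]
    return seq[:pos] + choices[rng.integers(3)] + seq[pos + 1:]


def apply_substitutions(
    pool: Sequence[str], model: ErrorModel, rng=None
) -> list[str]:
    """Random substitutions (SNVs) per the model's rate semantics."""
    r = _rng(model, rng)
    out = []
    rate = model.snv_rate
    for seq in pool:
        if rate and model.rate_semantics == "per_sequence":
            if r.random() < rate:
                seq = _substitute(seq, int(r.integers(len(seq))), r)
        elif rate:
            hits = np.flatnonzero(r.random(len(seq)) < rate)
            for pos in hits:
                seq = _substitute(seq, int(pos), r)
        out.append(seq)
    return out


def apply_indels(pool: Sequence[str], model: ErrorModel, rng=None) -> list[str]:
    """Random single-base insertions/deletions; lengths are not re-padded,
    so affected sequences decode as frameshifted (both segments lost)."""
    r = _rng(model, rng)
    out = []
    for seq in pool:
        if model.ins_rate:
            if model.rate_semantics == "per_sequence":
                if r.random() < model.ins_rate:
                    pos = int(r.integers(len(seq) + 1))
                    seq = seq[:pos] + BASES[r.integers(4)] + seq[pos:]
            else:
                for pos in np.flatnonzero(r.random(len(seq) + 1) < model.ins_rate)[::-1]:
                    seq = seq[:pos] + BASES[r.integers(4)] + seq[pos:]
        if model.del_rate and seq:
            if model.rate_semantics == "per_sequence":
                if r.random() < model.del_rate:
                    pos = int(r.integers(len(seq)))
                    seq = seq[:pos] + seq[pos + 1:]
            else:
                for pos in np.flatnonzero(r.random(len(seq)) < model.del_rate)[::-1]:
                    seq = seq[:pos] + seq[pos + 1:]
        out.append(seq)
    return out


def apply_dropout(pool: Sequence[str], model: ErrorModel, rng=None) -> list[str]:
    """Uniform loss of whole sequences."""
    r = _rng(model, rng)
    n = len(pool)
    if model.loss_rate == 0.0 or n == 0:
        return list(pool)
    if model.loss_mode == "exact_count":
        n_lose = int(round(model.loss_rate * n))
        lost = set(r.choice(n, size=n_lose, replace=False).tolist())
        return [s for i, s in enumerate(pool) if i not in lost]
    keep = r.random(n) >= model.loss_rate
    return [s for i, s in enumerate(pool) if keep[i]]


def simulate_dilution(
    pool: Sequence[str], amc: float, seed=None
) -> tuple[list[str], np.ndarray]:
    """Copy-number dilution: each oligo's surviving copy count is
    Poisson(amc); zero-copy oligos are lost.  Returns (survivors, copies).

    The fraction lost converges to the Poisson zero class exp(-amc).
    """
    if amc < 0:
        raise ValueError("amc must be >= 0")
    r = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    copies = r.poisson(amc, size=len(pool))
    survivors = [s for s, c in zip(pool, copies) if c > 0]
    return survivors, copies


def apply_error_model(pool: Sequence[str], model: ErrorModel, rng=None) -> list[str]:
    """Dropout, then dilution, then indels, then substitutions."""
    r = _rng(model, rng)
    pool = apply_dropout(pool, model, r)
    if model.amc is not None:
        pool, _ = simulate_dilution(pool, model.amc, r)
    if model.ins_rate or model.del_rate:
        pool = apply_indels(pool, model, r)
    if model.snv_rate:
        pool = apply_substitutions(pool, model, r)
    return pool


@dataclass
class SweepRow:
    condition: ErrorModel
    mean_recovery: float
    sd_recovery: float
    n_seeds: int
    recoveries: list[float]


def sweep_recovery(
    data: bytes,
    scheme: CodingScheme,
    conditions: Sequence[ErrorModel],
    n_seeds: int = 10,
    layout: FrameLayout | None = None,
    policy: ScreenPolicy | None = None,
    base_seed: int = 0,
    encoded: EncodeResult | None = None,
    rs_repair: bool = True,
) -> list[SweepRow]:
    """Encode once, perturb per (condition, seed), decode, report statistics.

    Recovery is the exact-match data-segment fraction against the
    encoder's ground-truth payloads; a pre-encoded pool may be passed to
    amortise encoding across sweeps.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    result = encoded or encode_file(
        data, scheme, layout=layout, policy=policy, seed=base_seed
    )
    sequences = [seq for _, seq in result.records]
    rows = []
    for cond_no, condition in enumerate(conditions):
        recoveries = []
        for s in range(n_seeds):
            r = np.random.default_rng((base_seed, cond_no, s))
            perturbed = apply_error_model(sequences, condition, r)
            segments = _decode_segments(perturbed, result.manifest, rs_repair=rs_repair)
            recoveries.append(recovery_rate(result.payloads, segments))
        arr = np.array(recoveries)
        rows.append(
            SweepRow(
                condition=condition,
                mean_recovery=float(arr.mean()),
                sd_recovery=float(arr.std(ddof=1)) if n_seeds > 1 else 0.0,
                n_seeds=n_seeds,
                recoveries=recoveries,
            )
        )
    return rows
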