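"""Rule space of the yin-yang codec.

The codec compresses two bits into one nucleotide by combining two
complementary mapping rules:

* a **yang rule** partitions the four bases into two pairs, one pair
  encoding bit 0 and the other bit 1 (a balanced base->bit map; six
  such partitions exist);
* a **yin rule** assigns a bit to each base *conditioned on the previous
  base*, constrained so that the two members of each yang pair always
  receive different bits.  With four possible previous bases and two
  yang pairs there are 2^8 = 256 yin rules per yang rule.

For any (yang bit, yin bit, previous base) triple exactly one base
satisfies both rules, so a scheme is a bijection between bit pairs and
bases at every position; 6 x 256 = 1,536 schemes exist in total.

Bases are ordered A < C < G < T and carry integer codes 0..3 throughout
the package; the canonical enumeration below is lexicographic in that
order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES",
    "BASE_CODE",
    "YangRule",
    "YinRule",
    "CodingScheme",
    "enumerate_yang_rules",
    "enumerate_yin_rules",
    "scheme_by_id",
    "scheme_count",
    "encode_base",
    "decode_base",
    "REFERENCE_SCHEME",
    "REFERENCE_SCHEME_ID",
    "scheme_to_text",
    "scheme_from_text",
]

BASES = "ACGT"
BASE_CODE = {b: i for i, b in enumerate(BASES)}

N_YANG = 6
N_YIN = 256
N_SCHEMES = N_YANG * N_YIN


def _require_base(symbol: str) -> int:
    code = BASE_CODE.get(symbol)
    if code is None:
        raise ValueError(f"not a DNA base: {symbol!r}")
    return code


@dataclass(frozen=True)
class YangRule:
    """Balanced base->bit map: two bases encode 0, the other two encode 1."""

    bits: tuple[int, int, int, int]  # bit of A, C, G, T

    def __post_init__(self) -> None:
        if sorted(self.bits) != [0, 0, 1, 1]:
            raise ValueError(f"yang rule must map two bases to each bit: {self.bits}")

    def bit_of(self, base: str) -> int:
        return self.bits[_require_base(base)]

    @property
    def groups(self) -> tuple[tuple[int, int], tuple[int, int]]:
        """Base codes encoding 0 and 1 respectively, each pair sorted."""
        g0 = tuple(i for i, b in enumerate(self.bits) if b == 0)
        g1 = tuple(i for i, b in enumerate(self.bits) if b == 1)
        return g0, g1  # type: ignore[return-value]


@dataclass(frozen=True)
class YinRule:
    """Previous-base-conditioned base->bit map bound to a yang partition.

    ``table[prev][base]`` is the bit of ``base`` when preceded by ``prev``
    (codes 0..3).  Validity requires that, for every previous base, the two
    members of each yang group carry different bits.
    """

    table: tuple[tuple[int, int, int, int], ...]  # [prev][base]
    yang: YangRule

    def __post_init__(self) -> None:
        if len(self.table) != 4 or any(len(r) != 4 for r in self.table):
            raise ValueError("yin table must be 4x4")
        for prev in range(4):
            for group in self.yang.groups:
                a, b = group
                if self.table[prev][a] == self.table[prev][b]:
                    raise ValueError(
                        "yin rule must split each yang group under every previous base"
                    )

    def bit_of(self, prev: str, base: str) -> int:
        return self.table[_require_base(prev)][_require_base(base)]


@dataclass(frozen=True)
class CodingScheme:
    """One of the 1,536 yang+yin rule combinations.

    ``virtual_prev`` seeds the yin rule's previous-base dependency at
    position 0 (the "virtual nucleotide", A by default).
    """

    yang: YangRule
    yin: YinRule
    virtual_prev: str = "A"
    scheme_id: int | None = None
    # cached lookup tables, built lazily (see properties below)
    _luts: dict = field(default_factory=dict, repr=False, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.yin.yang != self.yang:
            raise ValueError("yin rule is bound to a different yang partition")
        _require_base(self.virtual_prev)

    # -- numpy lookup tables used by the vectorised transcoder ------------

    @property
    def encode_lut(self) -> np.ndarray:
        """uint8 array [yang_bit, yin_bit, prev] -> base code."""
        lut = self._luts.get("enc")
        if lut is None:
            lut = np.empty((2, 2, 4), dtype=np.uint8)
            groups = self.yang.groups
            for a in (0, 1):
                for prev in range(4):
                    for b in (0, 1):
                        members = [m for m in groups[a] if self.yin.table[prev][m] == b]
                        assert len(members) == 1, "scheme violates uniqueness"
                        lut[a, b, prev] = members[0]
            self._luts["enc"] = lut
        return lut

    @property
    def yang_lut(self) -> np.ndarray:
        """uint8 array [base] -> yang bit."""
        lut = self._luts.get("yang")
        if lut is None:
            lut = np.array(self.yang.bits, dtype=np.uint8)
            self._luts["yang"] = lut
        return lut

    @property
    def yin_lut(self) -> np.ndarray:
        """uint8 array [prev, base] -> yin bit."""
        lut = self._luts.get("yin")
        if lut is None:
            lut = np.array(self.yin.table, dtype=np.uint8)
            self._luts["yin"] = lut
        return lut


def enumerate_yang_rules() -> list[YangRule]:
    """All six balanced base->bit maps, sorted by bit vector over A,C,G,T."""
    rules = []
    for zeros in itertools.combinations(range(4), 2):
        bits = tuple(0 if i in zeros else 1 for i in range(4))
        rules.append(YangRule(bits))
    rules.sort(key=lambda r: r.bits)
    return rules


def _yin_from_choices(yang: YangRule, choices: int) -> YinRule:
    """Build a yin rule from an 8-bit choice vector.

    Choice bits are ordered (prev A,C,G,T) x (group0, group1), most
    significant first.  A choice bit of 0 gives the lexicographically
    smaller group member bit 0; a choice bit of 1 swaps the pair.
    """
    table = [[0] * 4 for _ in range(4)]
    groups = yang.groups
    pos = 7
    for prev in range(4):
        for group in groups:
            swap = (choices >> pos) & 1
            lo, hi = group
            table[prev][lo] = swap
            table[prev][hi] = 1 - swap
            pos -= 1
    return YinRule(tuple(tuple(r) for r in table), yang)


def enumerate_yin_rules(yang: YangRule) -> list[YinRule]:
    """All 256 yin rules bound to ``yang``, in canonical (choice-vector) order."""
    return [_yin_from_choices(yang, c) for c in range(N_YIN)]


def scheme_count() -> int:
    return N_SCHEMES


def scheme_by_id(scheme_id: int, virtual_prev: str = "A") -> CodingScheme:
    """Deterministic bijection id -> scheme: id-1 = yang_index*256 + yin_index."""
    if not 1 <= scheme_id <= N_SCHEMES:
        raise ValueError(f"scheme id must be in 1..{N_SCHEMES}, got {scheme_id}")
    yang_index, yin_index = divmod(scheme_id - 1, N_YIN)
    yang = enumerate_yang_rules()[yang_index]
    yin = _yin_from_choices(yang, yin_index)
    return CodingScheme(yang=yang, yin=yin, virtual_prev=virtual_prev, scheme_id=scheme_id)


def scheme_id_of(scheme: CodingScheme) -> int:
    """Inverse of :func:`scheme_by_id` under the canonical enumeration."""
    yang_index = enumerate_yang_rules().index(scheme.yang)
    choices = 0
    for prev in range(4):
        for group in scheme.yang.groups:
            lo = group[0]
            choices = (choices << 1) | scheme.yin.table[prev][lo]
    return yang_index * N_YIN + choices + 1


def encode_base(yang_bit: int, yin_bit: int, prev: str, scheme: CodingScheme) -> str:
    """The unique base in yang group ``yang_bit`` whose yin bit under ``prev``
    is ``yin_bit``."""
    return BASES[scheme.encode_lut[yang_bit, yin_bit, _require_base(prev)]]


def decode_base(base: str, prev: str, scheme: CodingScheme) -> tuple[int, int]:
    """Inverse of :func:`encode_base`: (yang bit, yin bit) of ``base``."""
    return scheme.yang.bit_of(base), scheme.yin.bit_of(prev, base)


# ---------------------------------------------------------------------------
# Reference scheme
# ---------------------------------------------------------------------------

def _reference_scheme() -> CodingScheme:
    # yang: {A,T} -> 0, {C,G} -> 1
    yang = YangRule((0, 1, 1, 0))
    # yin: A->0, T->1, G->0, C->1 under every previous base
    row = (0, 1, 0, 1)  # bits of A, C, G, T
    yin = YinRule((row, row, row, row), yang)
    scheme = CodingScheme(yang=yang, yin=yin, virtual_prev="A")
    return CodingScheme(
        yang=yang, yin=yin, virtual_prev="A", scheme_id=scheme_id_of(scheme)
    )


#: Worked-example scheme used throughout the docs and tests: yang maps
#: {A,T} to 0 and {C,G} to 1; yin maps A,G to 0 and C,T to 1 regardless of
#: the previous base.  Encoding yang bit 1 with yin bit 0 after A yields G.
REFERENCE_SCHEME = _reference_scheme()
REFERENCE_SCHEME_ID = REFERENCE_SCHEME.scheme_id


# ---------------------------------------------------------------------------
# Serialization (structured key/value text)
# ---------------------------------------------------------------------------

def scheme_to_text(scheme: CodingScheme) -> str:
    lines = []
    if scheme.scheme_id is not None:
        lines.append(f"scheme_id: {scheme.scheme_id}")
    lines.append("yang: " + " ".join(f"{b}={scheme.yang.bits[i]}" for i, b in enumerate(BASES)))
    for prev in range(4):
        row = scheme.yin.table[prev]
        lines.append(
            f"yin[{BASES[prev]}]: " + " ".join(f"{b}={row[i]}" for i, b in enumerate(BASES))
        )
    lines.append(f"virtual_prev: {scheme.virtual_prev}")
    return "\n".join(lines) + "\n"


def _parse_assignments(value: str) -> tuple[int, int, int, int]:
    bits = [-1] * 4
    for token in value.split():
        base, _, bit = token.partition("=")
        bits[_require_base(base)] = int(bit)
    if -1 in bits:
        raise ValueError(f"incomplete base assignment: {value!r}")
    return tuple(bits)  # type: ignore[return-value]


def scheme_from_text(text: str) -> CodingScheme:
    fields: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition(":")
        fields[key.strip()] = value.strip()
    yang = YangRule(_parse_assignments(fields["yang"]))
    table = tuple(_parse_assignments(fields[f"yin[{BASES[p]}]"]) for p in range(4))
    yin = YinRule(table, yang)
    scheme_id = int(fields["scheme_id"]) if "scheme_id" in fields else None
    return CodingScheme(
        yang=yang,
        yin=yin,
        virtual_prev=fields.get("virtual_prev", "A"),
        scheme_id=scheme_id,
    )
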