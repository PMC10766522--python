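"""File-level framing: segmentation, addressing, RS parity and XOR redundancy.

The oligo-pool frame is ``index || payload || RS``: a 16-bit address, a
128-bit data payload and 16 bits (2 bytes) of Reed-Solomon parity
computed over the byte symbols of index-plus-payload, 160 bits in all.
Two such frames are incorporated into one 160 nt sequence, which with
two 20 nt primers gives a 200 nt oligo.

Logical redundancy is added by XORing groups of four data payloads into
a fifth parity segment (25% added segments); any single missing segment
per group is recoverable by XOR.

A second profile frames data for chromosome-scale double-stranded
storage: blocks of two 456-bit payload streams, each with 24 bits
(3 bytes) of RS parity, giving 480 nt per block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rs import RSDecodeError, rs_decode, rs_encode_matrix, rs_syndromes_matrix

__all__ = [
    "FrameLayout",
    "IN_VITRO_LAYOUT",
    "IN_VIVO_LAYOUT",
    "bytes_to_bits",
    "bits_to_bytes",
    "segment_bits",
    "build_frames",
    "parse_frames",
    "attach_rs",
    "rs_repair",
    "make_parity_group",
    "add_parity_segments",
    "recover_from_parity",
    "build_invivo_blocks",
    "decode_invivo_blocks",
]


@dataclass(frozen=True)
class FrameLayout:
    """Bit budget of one framed segment and its redundancy settings.

    ``parity_group = g`` adds one XOR parity segment per ``g`` data
    segments (0 disables logical redundancy); ``rs_bits = 0`` disables
    the inner RS code.
    """

    payload_bits: int = 128
    rs_bits: int = 16
    index_bits: int = 16
    parity_group: int = 4
    primer_len: int = 20

    def __post_init__(self) -> None:
        if self.payload_bits <= 0 or self.payload_bits % 8:
            raise ValueError("payload_bits must be a positive multiple of 8")
        if self.rs_bits % 8 or self.rs_bits < 0:
            raise ValueError("rs_bits must be a non-negative multiple of 8")
        if (self.index_bits + self.payload_bits) % 8:
            raise ValueError("index_bits + payload_bits must be a multiple of 8")
        if not 0 < self.index_bits <= 32:
            raise ValueError("index_bits must be in 1..32")
        if self.parity_group < 0:
            raise ValueError("parity_group must be >= 0")

    @property
    def frame_bits(self) -> int:
        return self.index_bits + self.payload_bits + self.rs_bits

    @property
    def rs_nsym(self) -> int:
        return self.rs_bits // 8

    @property
    def protected_bytes(self) -> int:
        return (self.index_bits + self.payload_bits) // 8

    @property
    def index_capacity(self) -> int:
        return 1 << self.index_bits

    @property
    def index_mask(self) -> int:
        """Fixed whitening mask XORed onto the address field.

        Sequential addresses share long runs of identical leading bits;
        encoded as-is those prefixes transcode into homopolymer runs
        that no re-pairing can break (both segments of a pair carry
        them).  An alternating 0101... mask makes address prefixes
        homopolymer-free while staying a trivial, reversible bijection.
        """
        pattern = ("01" * self.index_bits)[: self.index_bits]
        return int(pattern, 2)


#: 200 nt oligo profile: 16 + 128 + 16 bits per segment, two segments per
#: 160 nt sequence, 20 nt primers at both ends, 4+1 XOR redundancy.
IN_VITRO_LAYOUT = FrameLayout()

#: Chromosome-integration profile: 456-bit payload + 24-bit RS per stream,
#: two streams per 480 nt double-stranded block, no XOR groups or primers.
IN_VIVO_LAYOUT = FrameLayout(
    payload_bits=456, rs_bits=24, index_bits=16, parity_group=0, primer_len=0
)


def bytes_to_bits(data: bytes) -> np.ndarray:
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8))


def bits_to_bytes(bits: np.ndarray) -> bytes:
    return np.packbits(np.asarray(bits, dtype=np.uint8)).tobytes()


def segment_bits(
    bits: np.ndarray | bytes, layout: FrameLayout
) -> tuple[np.ndarray, int]:
    """Split a bit stream into zero-padded payload rows.

    Returns an ``(n, payload_bits)`` matrix and the original bit length
    (recorded in the manifest so decode can truncate exactly).
    """
    if isinstance(bits, (bytes, bytearray)):
        bits = bytes_to_bits(bytes(bits))
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.size == 0:
        raise ValueError("empty input")
    n_bits = bits.size
    width = layout.payload_bits
    n_seg = -(-n_bits // width)
    padded = np.zeros(n_seg * width, dtype=np.uint8)
    padded[:n_bits] = bits
    return padded.reshape(n_seg, width), n_bits


def _index_bits(indices: np.ndarray, layout: FrameLayout) -> np.ndarray:
    indices = np.asarray(indices, dtype=np.uint64)
    if (indices >= layout.index_capacity).any():
        raise ValueError(
            f"segment index exceeds the {layout.index_bits}-bit address space"
        )
    masked = indices ^ np.uint64(layout.index_mask)
    shifts = np.arange(layout.index_bits - 1, -1, -1, dtype=np.uint64)
    return ((masked[:, None] >> shifts) & np.uint64(1)).astype(np.uint8)


def _bits_to_ints(bits: np.ndarray) -> np.ndarray:
    weights = 1 << np.arange(bits.shape[1] - 1, -1, -1, dtype=np.int64)
    return bits.astype(np.int64) @ weights


def build_frames(
    payloads: np.ndarray, indices: np.ndarray, layout: FrameLayout
) -> np.ndarray:
    """Assemble ``index || payload || RS`` frames for a payload matrix."""
    payloads = np.atleast_2d(np.asarray(payloads, dtype=np.uint8))
    n = payloads.shape[0]
    if payloads.shape[1] != layout.payload_bits:
        raise ValueError(
            f"payload width {payloads.shape[1]} != layout {layout.payload_bits}"
        )
    idx_bits = _index_bits(indices, layout)
    protected = np.hstack([idx_bits, payloads])
    if layout.rs_bits == 0:
        return protected
    protected_bytes = np.packbits(protected, axis=1)
    codewords = rs_encode_matrix(protected_bytes, layout.rs_nsym)
    rs_region = np.unpackbits(codewords[:, layout.protected_bytes:], axis=1)
    return np.hstack([protected, rs_region])


def parse_frames(
    frames: np.ndarray, layout: FrameLayout, repair: bool = True
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split frames back into (indices, payloads, ok-mask), RS-repairing.

    Frames whose RS decode fails (more symbol errors than the code
    guarantees) keep their raw bits but are flagged ``ok = False``.
    """
    frames = np.atleast_2d(np.asarray(frames, dtype=np.uint8))
    if frames.shape[1] != layout.frame_bits:
        raise ValueError(f"frame width {frames.shape[1]} != {layout.frame_bits}")
    n = frames.shape[0]
    ok = np.ones(n, dtype=bool)
    body = frames[:, : layout.index_bits + layout.payload_bits].copy()
    if layout.rs_bits and repair and n:
        codewords = np.packbits(frames, axis=1)
        synd = rs_syndromes_matrix(codewords, layout.rs_nsym)
        for row in np.flatnonzero(synd.any(axis=1)):
            try:
                fixed = rs_decode(bytes(codewords[row]), layout.rs_nsym)
                body[row] = np.unpackbits(np.frombuffer(fixed, dtype=np.uint8))
            except RSDecodeError:
                ok[row] = False
    indices = _bits_to_ints(body[:, : layout.index_bits]) ^ layout.index_mask
    payloads = body[:, layout.index_bits:]
    return indices, payloads, ok


def attach_rs(
    payload: np.ndarray, layout: FrameLayout, index: int = 0
) -> np.ndarray:
    """Frame a single payload (convenience scalar wrapper)."""
    return build_frames(np.atleast_2d(payload), np.array([index]), layout)[0]


def rs_repair(frame: np.ndarray, layout: FrameLayout) -> np.ndarray:
    """Correct a single frame up to its RS capacity; raises
    :class:`RSDecodeError` if uncorrectable."""
    from .rs import rs_encode

    frames = np.atleast_2d(np.asarray(frame, dtype=np.uint8))
    codeword = np.packbits(frames, axis=1)[0]
    fixed = rs_decode(bytes(codeword), layout.rs_nsym)
    return np.unpackbits(
        np.frombuffer(rs_encode(fixed, layout.rs_nsym), dtype=np.uint8)
    )


# ---------------------------------------------------------------------------
# XOR parity groups
# ---------------------------------------------------------------------------

def make_parity_group(segments: np.ndarray) -> np.ndarray:
    """Bitwise XOR of a group of equal-length bit segments."""
    segments = np.atleast_2d(np.asarray(segments, dtype=np.uint8))
    if segments.shape[0] < 2:
        raise ValueError("parity group needs at least two segments")
    return np.bitwise_xor.reduce(segments, axis=0)


def add_parity_segments(
    payloads: np.ndarray, layout: FrameLayout
) -> np.ndarray:
    """Parity payloads for consecutive groups of ``layout.parity_group``.

    The last group may be smaller when the segment count is not a
    multiple of the group size; its parity covers what remains.
    """
    if layout.parity_group == 0:
        return np.zeros((0, payloads.shape[1]), dtype=np.uint8)
    g = layout.parity_group
    out = []
    for start in range(0, payloads.shape[0], g):
        block = payloads[start : start + g]
        out.append(
            block[0] if block.shape[0] == 1 else make_parity_group(block)
        )
    return np.array(out, dtype=np.uint8)


def recover_from_parity(
    group: dict[int, np.ndarray], expected_members: list[int], width: int
) -> tuple[dict[int, np.ndarray], list[int]]:
    """Reconstruct at most one missing member of a parity group by XOR.

    ``group`` maps member position -> payload bits for present members
    (the parity segment included); returns the completed group and the
    list of positions that stay unrecovered (two or more missing).
    """
    missing = [m for m in expected_members if m not in group]
    if not missing:
        return dict(group), []
    if len(missing) > 1:
        return dict(group), missing
    present = [group[m] for m in expected_members if m in group]
    restored = (
        np.bitwise_xor.reduce(np.array(present, dtype=np.uint8), axis=0)
        if len(present) > 1
        else np.array(present[0], dtype=np.uint8)
    )
    completed = dict(group)
    completed[missing[0]] = restored
    return completed, []


# ---------------------------------------------------------------------------
# Double-stranded fragment profile
# ---------------------------------------------------------------------------

def build_invivo_blocks(
    bits: np.ndarray | bytes, layout: FrameLayout = IN_VIVO_LAYOUT
) -> tuple[list[tuple[np.ndarray, np.ndarray]], int, int]:
    """Frame a bit stream into double-stranded storage blocks.

    Each block holds two streams of ``payload_bits + rs_bits`` bits (one
    for each codec rule), so one block spans ``payload + rs`` nucleotides
    of double-stranded DNA.  Returns (block list, total nt, original bit
    length); 113 blocks of the default 456+24 profile span 54,240 bp.
    """
    payloads, n_bits = segment_bits(bits, layout)
    if payloads.shape[0] % 2:
        payloads = np.vstack(
            [payloads, np.zeros((1, layout.payload_bits), dtype=np.uint8)]
        )
    nsym = layout.rs_nsym
    if nsym:
        byte_payloads = np.packbits(payloads, axis=1)
        coded = rs_encode_matrix(byte_payloads, nsym)
        streams = np.unpackbits(coded, axis=1)
    else:
        streams = payloads
    blocks = [
        (streams[i], streams[i + 1]) for i in range(0, streams.shape[0], 2)
    ]
    # each nucleotide carries one bit of each stream, so a block spans
    # payload_bits + rs_bits nucleotides of dsDNA
    total_nt = len(blocks) * (layout.payload_bits + layout.rs_bits)
    return blocks, total_nt, n_bits


def decode_invivo_blocks(
    blocks: list[tuple[np.ndarray, np.ndarray]],
    n_bits: int,
    layout: FrameLayout = IN_VIVO_LAYOUT,
) -> tuple[np.ndarray, int]:
    """Inverse of :func:`build_invivo_blocks`: RS-repair each stream and
    reassemble the original bit stream.  Returns (bits, n_uncorrectable)."""
    nsym = layout.rs_nsym
    payloads = []
    failures = 0
    for a, b in blocks:
        for stream in (a, b):
            stream = np.asarray(stream, dtype=np.uint8)
            if nsym:
                codeword = np.packbits(stream)
                try:
                    data = rs_decode(bytes(codeword), nsym)
                    payloads.append(np.unpackbits(np.frombuffer(data, dtype=np.uint8)))
                except RSDecodeError:
                    failures += 1
                    payloads.append(stream[: layout.payload_bits])
            else:
                payloads.append(stream[: layout.payload_bits])
    bits = np.concatenate(payloads)[:n_bits]
    return bits, failures
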