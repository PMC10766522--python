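"""End-to-end encode/decode pipeline and the recovery-rate metric.

Encoding: file bytes -> 128-bit payload segments -> XOR parity segments
-> ``index || payload || RS`` frames -> screened segment pairing -> one
160 nt sequence per frame pair -> 200 nt oligos with flanking primers.
A manifest (scheme, layout, per-file index ranges and bit lengths,
primer sequences, seed) makes the pool self-describing for decode.

Decoding reverses each step: primer stripping, base-wise extraction of
the two bit streams, RS repair, reordering by address, XOR recovery of
missing segments, dropping of pseudobinary fillers, and truncation to
the original bit length.  A segment counts as recovered only when its
payload matches the original bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from ._version import __version__ as _version
from .framing import (
    FrameLayout,
    add_parity_segments,
    bits_to_bytes,
    build_frames,
    parse_frames,
    recover_from_parity,
    segment_bits,
)
from .rules import BASE_CODE, CodingScheme, scheme_by_id
from .transcode import (
    PoolEncodeResult,
    ScreenPolicy,
    extract_matrix,
    pair_and_encode_pool,
    str_to_codes,
)

__all__ = [
    "PoolManifest",
    "FileEntry",
    "EncodeResult",
    "RecoveryReport",
    "encode_file",
    "decode_pool",
    "recovery_rate",
    "encode_invivo",
    "decode_invivo",
    "DEFAULT_FORWARD_PRIMER",
    "DEFAULT_REVERSE_PRIMER",
]

# fixture flanking sequences (user-replaceable); primer design is out of scope
DEFAULT_FORWARD_PRIMER = "AGTCGTAGGTCATGCTAGCA"
DEFAULT_REVERSE_PRIMER = "TGCAGTCATGGATCGTACGT"


@dataclass
class FileEntry:
    name: str
    n_bits: int
    first_segment: int
    n_segments: int


@dataclass
class PoolManifest:
    """Everything needed to decode a pool standalone."""

    scheme_id: int
    virtual_prev: str
    payload_bits: int
    rs_bits: int
    index_bits: int
    parity_group: int
    primer_len: int
    forward_primer: str
    reverse_primer: str
    files: list[FileEntry]
    n_data_segments: int
    n_parity_segments: int
    n_fillers: int
    seed: int | None
    version: str = _version

    @property
    def layout(self) -> FrameLayout:
        return FrameLayout(
            payload_bits=self.payload_bits,
            rs_bits=self.rs_bits,
            index_bits=self.index_bits,
            parity_group=self.parity_group,
            primer_len=self.primer_len,
        )

    @property
    def filler_start(self) -> int:
        return self.n_data_segments + self.n_parity_segments

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "PoolManifest":
        d = json.loads(text)
        d["files"] = [FileEntry(**f) for f in d["files"]]
        return cls(**d)


@dataclass
class EncodeResult:
    records: list[tuple[str, str]]  # (record id, oligo sequence)
    manifest: PoolManifest
    payloads: np.ndarray  # (n_data, payload_bits) ground-truth data payloads
    pool: PoolEncodeResult = field(repr=False)


@dataclass
class RecoveryReport:
    recovered_segments: int
    total_segments: int
    per_file: dict[str, tuple[int, int]]  # name -> (recovered, total)
    unrecovered_indices: list[int]

    @property
    def recovery_rate(self) -> float:
        if self.total_segments == 0:
            return 0.0
        return 100.0 * self.recovered_segments / self.total_segments


def _design_partner_frame(
    partner: np.ndarray,
    index: int,
    scheme: CodingScheme,
    layout: FrameLayout,
    policy: ScreenPolicy,
    rng: np.random.Generator,
    max_tries: int = 24,
) -> np.ndarray:
    """Greedily design a pseudobinary frame against a partner segment.

    The filler takes the yang role.  Its address and RS bits are fixed
    by the framing, but every payload bit is a free choice between two
    distinct bases, at most one of which can extend the current
    homopolymer run — so runs are capped by construction and the
    remaining freedom steers GC toward the centre of the allowed band.
    The RS tail is only determined once the payload is complete, so the
    design is verified and re-drawn (different tie-breaks) if the tail
    spoils it.
    """
    from .rs import rs_encode

    partner_l = [int(x) for x in np.asarray(partner, dtype=np.uint8)]
    lut = scheme.encode_lut.tolist()  # [yang][yin][prev] -> base code
    head = layout.index_bits
    pay_end = head + layout.payload_bits
    masked = index ^ layout.index_mask
    idx_l = [(masked >> (head - 1 - i)) & 1 for i in range(head)]
    gc_target = (policy.gc_min + policy.gc_max) / 200.0
    max_run = policy.max_homopolymer
    is_gc = (0, 1, 1, 0)  # codes A, C, G, T
    virtual = BASE_CODE[scheme.virtual_prev]
    length = layout.frame_bits
    lo = policy.gc_min * length / 100.0
    hi = policy.gc_max * length / 100.0
    frame = None
    for _attempt in range(max_tries):
        payload = [0] * layout.payload_bits
        jitter = (rng.random(layout.payload_bits) < 0.15).tolist()
        coin = rng.integers(0, 2, size=layout.payload_bits).tolist()
        prev, run, gc = virtual, 1, 0
        for i in range(pay_end):
            b = partner_l[i]
            if i < head:
                base = lut[idx_l[i]][b][prev]
            else:
                base0 = lut[0][b][prev]
                base1 = lut[1][b][prev]
                full = run >= max_run
                if full and base0 == prev:
                    a, base = 1, base1
                elif full and base1 == prev:
                    a, base = 0, base0
                elif jitter[i - head]:
                    a = coin[i - head]
                    base = base1 if a else base0
                else:
                    # steer GC toward the centre of the allowed band
                    d0 = abs((gc + is_gc[base0]) / (i + 1) - gc_target)
                    d1 = abs((gc + is_gc[base1]) / (i + 1) - gc_target)
                    a, base = (1, base1) if d1 < d0 else (0, base0)
                payload[i - head] = a
            run = run + 1 if base == prev else 1
            gc += is_gc[base]
            prev = base
        frame_bits = idx_l + payload
        if layout.rs_bits:
            protected = bytes(np.packbits(np.array(frame_bits, dtype=np.uint8)))
            codeword = rs_encode(protected, layout.rs_nsym)
            tail = np.unpackbits(
                np.frombuffer(codeword[layout.protected_bytes :], dtype=np.uint8)
            ).tolist()
            # the RS tail is fixed by the payload: verify it inline
            ok = True
            for i, a in enumerate(tail):
                base = lut[a][partner_l[pay_end + i]][prev]
                run = run + 1 if base == prev else 1
                if run > max_run:
                    ok = False
                    break
                gc += is_gc[base]
                prev = base
            frame_bits = frame_bits + tail
        else:
            ok = True
        frame = np.array(frame_bits, dtype=np.uint8)
        if ok and lo <= gc <= hi:
            return frame
    return frame  # let the pairing loop retry with a fresh design


def _as_file_inputs(data) -> list[tuple[str, bytes]]:
    if isinstance(data, (bytes, bytearray)):
        return [("file0", bytes(data))]
    return [(name, bytes(content)) for name, content in data]


def encode_file(
    data: bytes | list[tuple[str, bytes]],
    scheme: CodingScheme,
    layout: FrameLayout | None = None,
    policy: ScreenPolicy | None = None,
    seed: int | None = 0,
    forward_primer: str | None = None,
    reverse_primer: str | None = None,
) -> EncodeResult:
    """Encode one file (bytes) or several named files into an oligo pool.

    Every emitted oligo passes the screen policy by construction; frame
    pairs that fail are re-paired and, as a last resort, completed with
    pseudobinary fillers whose addresses lie above all data and parity
    addresses so decode can drop them.
    """
    layout = layout or FrameLayout()
    policy = policy if policy is not None else ScreenPolicy()
    files = _as_file_inputs(data)
    fwd = forward_primer if forward_primer is not None else (
        DEFAULT_FORWARD_PRIMER[: layout.primer_len] if layout.primer_len else ""
    )
    rev = reverse_primer if reverse_primer is not None else (
        DEFAULT_REVERSE_PRIMER[: layout.primer_len] if layout.primer_len else ""
    )

    entries: list[FileEntry] = []
    payload_blocks = []
    cursor = 0
    for name, content in files:
        payloads, n_bits = segment_bits(content, layout)
        entries.append(FileEntry(name, n_bits, cursor, payloads.shape[0]))
        payload_blocks.append(payloads)
        cursor += payloads.shape[0]
    data_payloads = np.vstack(payload_blocks)
    n_data = data_payloads.shape[0]

    parity_payloads = add_parity_segments(data_payloads, layout)
    n_parity = parity_payloads.shape[0]
    if n_data + n_parity > layout.index_capacity:
        raise ValueError(
            f"{n_data} data + {n_parity} parity segments exceed the "
            f"{layout.index_bits}-bit address space"
        )

    all_payloads = (
        np.vstack([data_payloads, parity_payloads]) if n_parity else data_payloads
    )
    indices = np.arange(n_data + n_parity)
    frames = build_frames(all_payloads, indices, layout)

    rng = np.random.default_rng(seed)
    filler_start = n_data + n_parity

    def filler_factory(
        k: int, r: np.random.Generator, partner: np.ndarray | None = None
    ) -> np.ndarray:
        index = filler_start + k
        if index >= layout.index_capacity:
            raise ValueError("filler segments exceed the address space")
        if partner is None:
            payload = r.integers(0, 2, size=layout.payload_bits, dtype=np.uint8)
            return build_frames(payload[None, :], np.array([index]), layout)[0]
        return _design_partner_frame(partner, index, scheme, layout, policy, r)

    pool = pair_and_encode_pool(
        list(frames), scheme, policy, rng=rng, filler_factory=filler_factory
    )

    records = [
        (f"oligo-{i:06d}|yang={a}|yin={b}", fwd + seq + rev)
        for i, (seq, (a, b)) in enumerate(zip(pool.sequences, pool.pairs))
    ]
    scheme_id = scheme.scheme_id
    if scheme_id is None:
        from .rules import scheme_id_of

        scheme_id = scheme_id_of(scheme)
    manifest = PoolManifest(
        scheme_id=scheme_id,
        virtual_prev=scheme.virtual_prev,
        payload_bits=layout.payload_bits,
        rs_bits=layout.rs_bits,
        index_bits=layout.index_bits,
        parity_group=layout.parity_group,
        primer_len=layout.primer_len,
        forward_primer=fwd,
        reverse_primer=rev,
        files=entries,
        n_data_segments=n_data,
        n_parity_segments=n_parity,
        n_fillers=len(pool.fillers),
        seed=seed,
    )
    return EncodeResult(records=records, manifest=manifest, payloads=data_payloads, pool=pool)


def _decode_segments(
    sequences: list[str], manifest: PoolManifest, rs_repair: bool = True
) -> dict[int, np.ndarray]:
    """Sequences -> {segment index: payload bits} after RS and XOR repair.

    ``rs_repair=False`` parses frames without the inner code (used to
    measure the codec's raw robustness baseline).
    """
    layout = manifest.layout
    scheme = scheme_by_id(manifest.scheme_id, virtual_prev=manifest.virtual_prev)
    frame_nt = layout.frame_bits
    expected = 2 * layout.primer_len + frame_nt

    rows = []
    for seq in sequences:
        if len(seq) != expected:
            continue  # indel frameshift: both carried segments unrecoverable
        core = seq[layout.primer_len : layout.primer_len + frame_nt]
        try:
            rows.append(str_to_codes(core))
        except ValueError:
            continue  # non-ACGT characters: corrupt sequence
    segments: dict[int, np.ndarray] = {}
    if rows:
        codes = np.stack(rows)
        yang_frames, yin_frames = extract_matrix(codes, scheme)
        frames = np.vstack([yang_frames, yin_frames])
        indices, payloads, ok = parse_frames(
            frames, layout, repair=rs_repair and layout.rs_bits > 0
        )
        order = np.argsort(indices, kind="stable")
        for row in order:
            if not ok[row]:
                continue
            idx = int(indices[row])
            if idx >= manifest.filler_start + manifest.n_fillers:
                continue  # corrupt address outside the pool's range
            if idx not in segments:
                segments[idx] = payloads[row]

    # XOR recovery of at most one missing member per parity group
    if manifest.parity_group:
        g = manifest.parity_group
        n_data = manifest.n_data_segments
        for group_no in range(manifest.n_parity_segments):
            members = list(range(group_no * g, min((group_no + 1) * g, n_data)))
            members.append(n_data + group_no)  # the parity segment
            present = {m: segments[m] for m in members if m in segments}
            completed, _ = recover_from_parity(
                present, members, manifest.payload_bits
            )
            for m, payload in completed.items():
                segments.setdefault(m, payload)
    return segments


def decode_pool(
    sequences: list[str], manifest: PoolManifest
) -> tuple[dict[str, bytes], RecoveryReport]:
    """Decode an oligo pool back into files plus a recovery report.

    Without the original data the report counts segments that were
    physically retrieved (present with a clean or repaired frame);
    missing payloads are zero-filled in the output so that partial
    recovery still yields files of the right size.
    """
    segments = _decode_segments(sequences, manifest)
    files: dict[str, bytes] = {}
    per_file: dict[str, tuple[int, int]] = {}
    unrecovered: list[int] = []
    recovered_total = 0
    for entry in manifest.files:
        width = manifest.payload_bits
        bits = np.zeros(entry.n_segments * width, dtype=np.uint8)
        got = 0
        for j in range(entry.n_segments):
            idx = entry.first_segment + j
            if idx in segments:
                bits[j * width : (j + 1) * width] = segments[idx]
                got += 1
            else:
                unrecovered.append(idx)
        files[entry.name] = bits_to_bytes(bits[: entry.n_bits])[
            : -(-entry.n_bits // 8)
        ]
        per_file[entry.name] = (got, entry.n_segments)
        recovered_total += got
    report = RecoveryReport(
        recovered_segments=recovered_total,
        total_segments=manifest.n_data_segments,
        per_file=per_file,
        unrecovered_indices=unrecovered,
    )
    return files, report


def recovery_rate(
    original_payloads: np.ndarray, recovered: dict[int, np.ndarray]
) -> float:
    """Percent of data segments recovered bit-exactly.

    Parity and pseudobinary segments are excluded from the denominator:
    only the ``n`` rows of the original data-payload matrix count.
    """
    original_payloads = np.atleast_2d(original_payloads)
    n = original_payloads.shape[0]
    if n == 0:
        return 0.0
    hits = sum(
        1
        for idx in range(n)
        if idx in recovered
        and np.array_equal(recovered[idx], original_payloads[idx])
    )
    return 100.0 * hits / n


# ---------------------------------------------------------------------------
# Double-stranded fragment profile
# ---------------------------------------------------------------------------

def encode_invivo(
    data: bytes,
    scheme: CodingScheme,
    layout: FrameLayout | None = None,
) -> tuple[str, int]:
    """Encode bytes into one long double-stranded fragment sequence.

    Returns (DNA sequence, original bit length).  Each storage block
    contributes ``payload_bits + rs_bits`` nucleotides carrying two bit
    streams (one per codec rule).
    """
    from .framing import IN_VIVO_LAYOUT, build_invivo_blocks
    from .transcode import codes_to_str, incorporate_matrix

    layout = layout or IN_VIVO_LAYOUT
    blocks, total_nt, n_bits = build_invivo_blocks(data, layout)
    a = np.stack([blk[0] for blk in blocks])
    b = np.stack([blk[1] for blk in blocks])
    codes = incorporate_matrix(a, b, scheme)
    seq = "".join(codes_to_str(row) for row in codes)
    assert len(seq) == total_nt
    return seq, n_bits


def decode_invivo(
    seq: str,
    n_bits: int,
    scheme: CodingScheme,
    layout: FrameLayout | None = None,
) -> tuple[bytes, int]:
    """Inverse of :func:`encode_invivo`; returns (bytes, RS failures)."""
    from .framing import IN_VIVO_LAYOUT, decode_invivo_blocks

    layout = layout or IN_VIVO_LAYOUT
    block_nt = layout.payload_bits + layout.rs_bits
    if len(seq) % block_nt:
        raise ValueError(f"sequence length is not a multiple of {block_nt} nt")
    codes = str_to_codes(seq).reshape(-1, block_nt)
    a, b = extract_matrix(codes, scheme)
    blocks = [(a[i], b[i]) for i in range(codes.shape[0])]
    bits, failures = decode_invivo_blocks(blocks, n_bits, layout)
    n_bytes = -(-n_bits // 8)
    return bits_to_bytes(bits)[:n_bytes], failures
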