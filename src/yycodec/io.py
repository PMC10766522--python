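"""Standard-format readers/writers: FASTA/FASTQ records and pool manifests.

FASTA handling goes through Biopython; sequences are accepted verbatim
at the IO layer (non-ACGT payloads are rejected later, at decode).
Manifests are JSON with deterministic key order.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pipeline import PoolManifest

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_fastq_sequences",
    "read_manifest",
    "write_manifest",
]


def read_fasta(path: str | Path | TextIO) -> list[tuple[str, str]]:
    """(id, sequence) pairs; wrapped and unwrapped dialects both parse."""
    return [
        (rec.description or rec.id, str(rec.seq))
        for rec in SeqIO.parse(path, "fasta")
    ]


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path | TextIO) -> int:
    """Write (id, sequence) pairs; returns the record count.

    Headers are written verbatim (single-line), sequences unwrapped, so
    output is byte-reproducible.
    """
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    return SeqIO.write(seq_records, path, "fasta-2line")


def read_fastq_sequences(path: str | Path | TextIO) -> list[str]:
    """Sequences from a FASTQ file; qualities are ignored."""
    return [str(rec.seq) for rec in SeqIO.parse(path, "fastq")]


def write_manifest(manifest: PoolManifest, path: str | Path) -> None:
    Path(path).write_text(manifest.to_json())


def read_manifest(path: str | Path) -> PoolManifest:
    return PoolManifest.from_json(Path(path).read_text())
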