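"""Sequence file reading helpers (FASTA/FASTQ, plain or gzipped)."""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterator

from Bio import SeqIO

__all__ = ["read_fasta", "read_sequences", "open_text"]


def open_text(path: str | Path):
    """Open a possibly-gzipped text file for reading."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: Path) -> str:
    name = path.name[:-3] if path.name.endswith(".gz") else path.name
    suffix = Path(name).suffix.lower()
    if suffix in {".fq", ".fastq"}:
        return "fastq"
    return "fasta"


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """All (record id, uppercase sequence) pairs of a FASTA file."""
    with open_text(path) as handle:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")]


def read_sequences(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (record id, uppercase sequence) from FASTA or FASTQ, by extension."""
    path = Path(path)
    fmt = _sniff_format(path)
    with open_text(path) as handle:
        for rec in SeqIO.parse(handle, fmt):
            yield rec.id, str(rec.seq).upper()
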