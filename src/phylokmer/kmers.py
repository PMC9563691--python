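"""2-bit k-mer encoding and canonical k-mer extraction.

Bases are encoded A=0, C=1, G=2, T=3 and packed most-significant-first
into a ``uint64``, so integer order equals lexicographic order and a
sorted key array supports binary-search lookup directly.  A canonical
k-mer is the smaller of a window and its reverse complement, which makes
database lookups strand-symmetric; k must be odd so no k-mer equals its
own reverse complement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["IndexConfig", "canonical_kmers", "encode_kmer", "decode_kmer"]

MAX_K = 31  # 2 bits/base packed into uint64

# 256-entry base -> 2-bit code table; 255 marks non-ACGT
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass(frozen=True)
class IndexConfig:
    """Database parameters shared by build and lookup.

    k defaults to 31: long enough for near-species-specific matching on
    prokaryote genomes while fitting the 64-bit packed encoding.
    """

    k: int = 31
    canonicalize: bool = True

    def __post_init__(self) -> None:
        if not 3 <= self.k <= MAX_K:
            raise ValueError(f"k must be in [3, {MAX_K}], got {self.k}")
        if self.canonicalize and self.k % 2 == 0:
            raise ValueError("k must be odd when canonicalize is enabled")


def _codes(sequence: str) -> np.ndarray:
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def canonical_kmers(sequence: str, config: IndexConfig) -> np.ndarray:
    """Encoded k-mers for every valid window of ``sequence``, in order.

    Windows containing a non-ACGT character are skipped.  Returns a
    uint64 array; use :func:`window_kmers` when per-window alignment with
    the read is needed.
    """
    encoded, valid = window_kmers(sequence, config)
    return encoded[valid]


def window_kmers(sequence: str, config: IndexConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-window encodings plus a validity mask.

    Returns ``(encoded, valid)`` of length ``max(0, len(sequence)-k+1)``;
    entries where ``valid`` is False correspond to windows containing a
    non-ACGT character and hold undefined encodings.
    """
    k = config.k
    n = len(sequence)
    if n < k:
        empty = np.empty(0, dtype=np.uint64)
        return empty, np.empty(0, dtype=bool)
    codes = _codes(sequence)
    bad = codes == 255
    codes = np.where(bad, 0, codes).astype(np.uint64)

    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    powers = (np.uint64(4) ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    fwd = windows @ powers
    if config.canonicalize:
        rc = (np.uint64(3) - windows) @ powers[::-1]
        encoded = np.minimum(fwd, rc)
    else:
        encoded = fwd
    # window is valid iff it contains no bad base
    bad_cum = np.concatenate(([0], np.cumsum(bad)))
    valid = (bad_cum[k:] - bad_cum[:-k]) == 0
    return encoded, valid


def encode_kmer(kmer: str, canonicalize: bool = True) -> int:
    """Encode a single k-mer string (reference/oracle path, not vectorized)."""
    fwd = 0
    for base in kmer.upper():
        fwd = (fwd << 2) | int(_CODE[ord(base)])
    if not canonicalize:
        return fwd
    rc = 0
    for base in reversed(kmer.upper()):
        rc = (rc << 2) | (3 - int(_CODE[ord(base)]))
    return min(fwd, rc)


def decode_kmer(encoded: int, k: int) -> str:
    bases = "ACGT"
    out = []
    value = int(encoded)
    for _ in range(k):
        out.append(bases[value & 3])
        value >>= 2
    return "".join(reversed(out))


def reverse_complement(sequence: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(sequence.upper()))
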