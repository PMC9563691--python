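"""The k-mer → tree-node database.

The database is a key-value store: keys are the sorted canonical k-mers
of the reference collection, values are tree-node IDs.  The defining
property is that the value stored for a k-mer is the lowest common
ancestor of all reference leaves whose genomes contain that k-mer, so a
k-mer unique to one genome points at its leaf while a k-mer conserved
across a clade points at the clade's root.

Builds proceed in partitions keyed by k-mer prefix that are sorted
independently and then concatenated, which bounds peak memory to a
fraction of the full key set while leaving the result byte-identical to
a single-shot sort.
"""

from __future__ import annotations

import json
import struct
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import read_fasta
from .kmers import IndexConfig, canonical_kmers
from .tree import PhyloTree

__all__ = [
    "KmerIndex",
    "IndexBuildError",
    "IndexFormatError",
    "build_index",
    "save_index",
    "load_index",
]

MAGIC = b"PHYLOKMERIDX"
FORMAT_VERSION = 1


class IndexBuildError(ValueError):
    """Inputs inconsistent with the tree (unmatched genome labels etc.)."""


class IndexFormatError(ValueError):
    """On-disk index fails a version, integrity or digest check."""


@dataclass
class KmerIndex:
    keys: np.ndarray  # uint64, strictly increasing
    values: np.ndarray  # int32 NodeIDs, parallel to keys
    config: IndexConfig
    tree_digest: str
    genome_manifest: list[tuple[str, str, int]]  # (leaf label, source path, record count)

    def __post_init__(self) -> None:
        if len(self.keys) != len(self.values):
            raise ValueError("keys and values must be parallel arrays")

    def __len__(self) -> int:
        return len(self.keys)

    def lookup(self, kmer: int) -> int | None:
        """Value for one encoded k-mer, or None on a miss."""
        pos = int(np.searchsorted(self.keys, np.uint64(kmer)))
        if pos < len(self.keys) and self.keys[pos] == np.uint64(kmer):
            return int(self.values[pos])
        return None

    def lookup_many(self, kmers: np.ndarray) -> np.ndarray:
        """Vectorized lookup; misses are returned as -1."""
        if len(kmers) == 0:
            return np.empty(0, dtype=np.int32)
        pos = np.searchsorted(self.keys, kmers)
        pos_clipped = np.minimum(pos, len(self.keys) - 1)
        hit = (len(self.keys) > 0) & (self.keys[pos_clipped] == kmers)
        out = np.where(hit, self.values[pos_clipped], -1).astype(np.int32)
        return out


def _leaf_kmers(sequences: list[str], config: IndexConfig) -> np.ndarray:
    """Distinct canonical k-mers over all records of one genome.

    Record boundaries never produce spanning k-mers: each record is
    windowed independently.
    """
    parts = [canonical_kmers(seq, config) for seq in sequences]
    if not parts:
        return np.empty(0, dtype=np.uint64)
    return np.unique(np.concatenate(parts))


def build_index(
    genomes: dict[str, "str | Path | list[str]"],
    tree: PhyloTree,
    config: IndexConfig | None = None,
    n_partitions: int = 4,
) -> KmerIndex:
    """Build the database from per-leaf genome sources.

    ``genomes`` maps leaf labels to either a FASTA path or an in-memory
    list of sequences (all records of a leaf belong to that leaf —
    contigs and plasmids of one assembly).  Tree leaves without a genome
    are warned about and excluded; genome labels absent from the tree
    are a build error.
    """
    config = config or IndexConfig()
    unmatched = sorted(set(genomes) - set(tree.leaf_name_index))
    if unmatched:
        raise IndexBuildError(f"genome labels not found among tree leaves: {unmatched}")
    missing = sorted(set(tree.leaf_name_index) - set(genomes))
    if missing:
        warnings.warn(
            f"tree leaves without genomes are excluded from the index: {missing}",
            stacklevel=2,
        )

    manifest: list[tuple[str, str, int]] = []
    leaf_kmer_sets: list[tuple[int, np.ndarray]] = []
    for label in sorted(genomes):
        source = genomes[label]
        if isinstance(source, (str, Path)):
            records = read_fasta(source)
            sequences = [seq for _, seq in records]
            manifest.append((label, str(source), len(records)))
        else:
            sequences = list(source)
            manifest.append((label, "<memory>", len(sequences)))
        leaf_kmer_sets.append((tree.leaf_name_index[label], _leaf_kmers(sequences, config)))

    # Partition by high bits of the encoding; each partition is an
    # independent sort-and-reduce whose outputs concatenate in key order.
    shift = np.uint64(2 * config.k - max(1, int(np.ceil(np.log2(max(n_partitions, 1))))))
    key_parts: list[np.ndarray] = []
    value_parts: list[np.ndarray] = []
    for part in range(max(n_partitions, 1)):
        kmer_chunks = []
        leaf_chunks = []
        for leaf_id, kmers in leaf_kmer_sets:
            if n_partitions > 1:
                sel = (kmers >> shift) == np.uint64(part)
                kmers = kmers[sel]
            elif part > 0:
                break
            kmer_chunks.append(kmers)
            leaf_chunks.append(np.full(len(kmers), leaf_id, dtype=np.int64))
        if not kmer_chunks:
            continue
        all_kmers = np.concatenate(kmer_chunks)
        all_leaves = np.concatenate(leaf_chunks)
        if len(all_kmers) == 0:
            continue
        order = np.argsort(all_kmers, kind="stable")
        all_kmers = all_kmers[order]
        all_leaves = all_leaves[order]
        uniq, starts = np.unique(all_kmers, return_index=True)
        # LCA of a leaf set reduces to LCA of its min/max preorder IDs
        min_leaf = np.minimum.reduceat(all_leaves, starts)
        max_leaf = np.maximum.reduceat(all_leaves, starts)
        pair_code = min_leaf * tree.node_count + max_leaf
        uniq_pairs, inverse = np.unique(pair_code, return_inverse=True)
        pair_lca = np.array(
            [
                tree.lca(int(code // tree.node_count), int(code % tree.node_count))
                for code in uniq_pairs
            ],
            dtype=np.int32,
        )
        key_parts.append(uniq)
        value_parts.append(pair_lca[inverse].astype(np.int32))

    if key_parts:
        keys = np.concatenate(key_parts)
        values = np.concatenate(value_parts)
    else:
        keys = np.empty(0, dtype=np.uint64)
        values = np.empty(0, dtype=np.int32)
    return KmerIndex(
        keys=keys,
        values=values,
        config=config,
        tree_digest=tree.newick_digest(),
        genome_manifest=manifest,
    )


# -- persistence -----------------------------------------------------
#
# Container layout: magic, uint32 version, uint64 header length, JSON
# header (k, canonicalize, n_keys, tree digest, manifest), key array
# (uint64 LE), value array (int32 LE). All fields little-endian; JSON
# serialized with sorted keys so identical indexes are byte-identical.


def save_index(index: KmerIndex, path: str | Path) -> None:
    header = {
        "k": index.config.k,
        "canonicalize": index.config.canonicalize,
        "n_keys": len(index.keys),
        "tree_digest": index.tree_digest,
        "genome_manifest": [list(entry) for entry in index.genome_manifest],
        "compressed": False,
    }
    payload = json.dumps(header, sort_keys=True, separators=(",", ":")).encode()
    with open(path, "wb") as handle:
        handle.write(MAGIC)
        handle.write(struct.pack("<IQ", FORMAT_VERSION, len(payload)))
        handle.write(payload)
        handle.write(np.ascontiguousarray(index.keys, dtype="<u8").tobytes())
        handle.write(np.ascontiguousarray(index.values, dtype="<i4").tobytes())


def load_index(path: str | Path, tree: PhyloTree | None = None) -> KmerIndex:
    """Load an index container, verifying format version and integrity.

    If ``tree`` is given, its digest must match the digest recorded at
    build time — classifying against the wrong tree is unrecoverable.
    """
    with open(path, "rb") as handle:
        blob = handle.read()
    if blob[: len(MAGIC)] != MAGIC:
        raise IndexFormatError(f"{path}: not a phylokmer index (bad magic)")
    offset = len(MAGIC)
    version, header_len = struct.unpack_from("<IQ", blob, offset)
    if version != FORMAT_VERSION:
        raise IndexFormatError(
            f"{path}: format version {version} unsupported (expected {FORMAT_VERSION})"
        )
    offset += struct.calcsize("<IQ")
    header = json.loads(blob[offset : offset + header_len].decode())
    offset += header_len
    n = header["n_keys"]
    expected = offset + 8 * n + 4 * n
    if len(blob) != expected:
        raise IndexFormatError(
            f"{path}: truncated or corrupt index ({len(blob)} bytes, expected {expected})"
        )
    keys = np.frombuffer(blob, dtype="<u8", count=n, offset=offset).astype(np.uint64)
    values = np.frombuffer(blob, dtype="<i4", count=n, offset=offset + 8 * n).astype(np.int32)
    index = KmerIndex(
        keys=keys,
        values=values,
        config=IndexConfig(k=header["k"], canonicalize=header["canonicalize"]),
        tree_digest=header["tree_digest"],
        genome_manifest=[tuple(entry) for entry in header["genome_manifest"]],
    )
    if tree is not None and tree.newick_digest() != index.tree_digest:
        raise IndexFormatError(
            f"{path}: tree digest mismatch — index was built against a different tree"
        )
    return index
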