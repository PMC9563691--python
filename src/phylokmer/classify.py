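"""Read classification by lineage decomposition of k-mer hit distributions.

Every k-mer of a read is looked up in the database, producing a
multiset of tree nodes (the read's *k-mer distribution*).  If the read
truly originates from a reference genome S, every hit must lie on the
root-to-leaf path ending at S, so the hit nodes of a clean read form a
single chain — a *single-lineage* (SL) read.  Hits spanning several
root-to-leaf paths mark a *split-lineage* read: either sequencing
error/chimerism, or genuine sequence from an organism whose closest
relatives sit in different database clades.  Elevated split counts
concentrated in one clade are therefore evidence of a database gap.

Assignment: decompose the hit nodes into lineages (one per deepest hit
node), drop lineages whose support falls below an ``alpha`` fraction of
all mapped k-mers, then assign the read to the lowest common node of
the surviving lineages — the deepest hit itself when one lineage
survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import zip_longest
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .index import KmerIndex
from .io import read_sequences
from .kmers import window_kmers
from .tree import PhyloTree

__all__ = [
    "ClassifierConfig",
    "HitDistribution",
    "LineageGroup",
    "ReadClassification",
    "Status",
    "map_read",
    "decompose_lineages",
    "apply_alpha_filter",
    "classify_read",
    "classify_sample",
]


class Status(str, Enum):
    SL = "SL"
    SPLIT = "SPLIT"
    UNCLASSIFIED = "UNCLASSIFIED"


class PairingError(ValueError):
    """Paired inputs whose mate counts disagree."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Classification parameters.

    ``alpha`` is the lineage-abundance filter: a lineage survives only
    if the k-mer hits supporting it amount to at least ``alpha`` of all
    mapped k-mers of the read.  The default of 0.1 tolerates up to ~10%
    stray hits from sequencing error without splitting a read, while
    still letting genuinely chimeric signal through; it is this
    package's choice and is freely tunable.  ``paired_mode`` controls
    whether mates are classified jointly (``concatenate``, the default:
    both mates come from one fragment) or independently (``separate``).
    """

    alpha: float = 0.1
    paired_mode: str = "concatenate"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ValueError(f"alpha must be in [0, 1), got {self.alpha}")
        if self.paired_mode not in {"separate", "concatenate"}:
            raise ValueError(f"unknown paired_mode {self.paired_mode!r}")


@dataclass
class HitDistribution:
    """Aggregate of one read's k-mer lookups.

    ``counts`` maps hit node → hit count; ``total_kmers`` counts every
    window examined (invalid windows and misses included),
    ``mapped_kmers`` only the hits.  ``runs`` is the run-length encoding
    of per-window outcomes in read order (node ID, or -1 for a miss /
    invalid window, or -2 for the boundary between paired mates).
    """

    counts: dict[int, int] = field(default_factory=dict)
    total_kmers: int = 0
    mapped_kmers: int = 0
    runs: list[tuple[int, int]] = field(default_factory=list)

    def merge(self, other: "HitDistribution") -> "HitDistribution":
        counts = dict(self.counts)
        for node, count in other.counts.items():
            counts[node] = counts.get(node, 0) + count
        runs = list(self.runs) + [(MATE_BOUNDARY, 0)] + list(other.runs)
        return HitDistribution(
            counts=counts,
            total_kmers=self.total_kmers + other.total_kmers,
            mapped_kmers=self.mapped_kmers + other.mapped_kmers,
            runs=runs,
        )


MISS = -1
MATE_BOUNDARY = -2


@dataclass
class LineageGroup:
    """One lineage of a hit distribution.

    ``terminal`` is the deepest hit node of the lineage (no hit strictly
    below it); ``support`` sums the hit counts of every hit node on the
    terminal's root path.  A hit node ancestral to several terminals
    contributes to each of their supports — ancestral hits are evidence
    for every lineage beneath them.
    """

    terminal: int
    support: int


@dataclass
class ReadClassification:
    read_id: str
    status: Status
    assigned_node: int | None
    lineages_surviving: int
    hits: HitDistribution
    read_lengths: tuple[int, ...] = ()


def map_read(read: str, index: KmerIndex) -> HitDistribution:
    """Look up every k-mer of a read and aggregate the results."""
    encoded, valid = window_kmers(read, index.config)
    n_windows = len(encoded)
    outcomes = np.full(n_windows, MISS, dtype=np.int32)
    if n_windows:
        outcomes[valid] = index.lookup_many(encoded[valid])
    hit_nodes = outcomes[outcomes >= 0]
    nodes, node_counts = np.unique(hit_nodes, return_counts=True)
    runs: list[tuple[int, int]] = []
    for value in outcomes:
        value = int(value)
        if runs and runs[-1][0] == value:
            runs[-1] = (value, runs[-1][1] + 1)
        else:
            runs.append((value, 1))
    return HitDistribution(
        counts={int(n): int(c) for n, c in zip(nodes, node_counts)},
        total_kmers=n_windows,
        mapped_kmers=int(len(hit_nodes)),
        runs=runs,
    )


def decompose_lineages(hits: HitDistribution, tree: PhyloTree) -> list[LineageGroup]:
    """Split the hit nodes into lineages, one per deepest hit node.

    Terminals are exactly the hit nodes with no other hit node strictly
    below them; each terminal's support sums hit counts over the hit
    nodes on its root path.  Terminals are returned in preorder.
    """
    if not hits.counts:
        return []
    hit_nodes = sorted(hits.counts)
    terminals = [
        u
        for u in hit_nodes
        if not any(v != u and tree.is_ancestor(u, v) for v in hit_nodes)
    ]
    groups = []
    for terminal in terminals:
        support = sum(
            count for node, count in hits.counts.items() if tree.is_ancestor(node, terminal)
        )
        groups.append(LineageGroup(terminal=terminal, support=support))
    return groups


def apply_alpha_filter(
    lineages: list[LineageGroup],
    hits: HitDistribution,
    config: ClassifierConfig,
) -> list[LineageGroup]:
    """Drop lineages with support below ``alpha`` of the mapped k-mers.

    If the threshold would discard everything, the single best-supported
    lineage is kept (ties broken toward the smaller preorder terminal):
    a read with hits should never become unclassified by filtering.
    """
    if not lineages:
        return []
    threshold = config.alpha * hits.mapped_kmers
    surviving = [lg for lg in lineages if lg.support >= threshold]
    if not surviving:
        best = max(lineages, key=lambda lg: (lg.support, -lg.terminal))
        surviving = [best]
    return surviving


def _classify_hits(
    read_id: str,
    hits: HitDistribution,
    tree: PhyloTree,
    config: ClassifierConfig,
    read_lengths: tuple[int, ...],
) -> ReadClassification:
    lineages = decompose_lineages(hits, tree)
    if not lineages:
        return ReadClassification(
            read_id=read_id,
            status=Status.UNCLASSIFIED,
            assigned_node=None,
            lineages_surviving=0,
            hits=hits,
            read_lengths=read_lengths,
        )
    surviving = apply_alpha_filter(lineages, hits, config)
    terminals = [lg.terminal for lg in surviving]
    assigned = tree.lca_set(terminals)
    status = Status.SL if len(surviving) == 1 else Status.SPLIT
    return ReadClassification(
        read_id=read_id,
        status=status,
        assigned_node=assigned,
        lineages_surviving=len(surviving),
        hits=hits,
        read_lengths=read_lengths,
    )


def classify_read(
    read_id: str,
    read: str,
    index: KmerIndex,
    tree: PhyloTree,
    config: ClassifierConfig | None = None,
) -> ReadClassification:
    """Classify one read: map, decompose, filter, assign."""
    config = config or ClassifierConfig()
    hits = map_read(read, index)
    return _classify_hits(read_id, hits, tree, config, (len(read),))


def classify_pair(
    read_id: str,
    read1: str,
    read2: str,
    index: KmerIndex,
    tree: PhyloTree,
    config: ClassifierConfig | None = None,
) -> ReadClassification:
    """Classify a mate pair with merged hit distributions."""
    config = config or ClassifierConfig()
    hits = map_read(read1, index).merge(map_read(read2, index))
    return _classify_hits(read_id, hits, tree, config, (len(read1), len(read2)))


def classify_sample(
    reads: "str | Path | Iterable[tuple[str, str]]",
    index: KmerIndex,
    tree: PhyloTree,
    config: ClassifierConfig | None = None,
    reads2: "str | Path | Iterable[tuple[str, str]] | None" = None,
) -> Iterator[ReadClassification]:
    """Classify every read (or pair) of a sample, preserving input order.

    ``reads`` may be a FASTA/FASTQ path (optionally gzipped) or an
    iterable of (id, sequence) pairs; ``reads2`` supplies mates.  In
    ``concatenate`` mode (default) each pair yields one classification
    from the merged hit distributions; in ``separate`` mode every mate
    is classified on its own.  Output depends only on the input reads,
    never on batching.
    """
    config = config or ClassifierConfig()
    source1 = read_sequences(reads) if isinstance(reads, (str, Path)) else iter(reads)
    if reads2 is None:
        for read_id, seq in source1:
            yield classify_read(read_id, seq, index, tree, config)
        return
    source2 = read_sequences(reads2) if isinstance(reads2, (str, Path)) else iter(reads2)
    sentinel = object()
    for i, (mate1, mate2) in enumerate(zip_longest(source1, source2, fillvalue=sentinel)):
        if mate1 is sentinel or mate2 is sentinel:
            raise PairingError(f"paired inputs differ in read count (at pair {i})")
        (id1, seq1), (_, seq2) = mate1, mate2
        if config.paired_mode == "concatenate":
            yield classify_pair(id1, seq1, seq2, index, tree, config)
        else:
            yield classify_read(id1, seq1, index, tree, config)
            yield classify_read(mate2[0], seq2, index, tree, config)
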