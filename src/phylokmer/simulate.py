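"""Synthetic trees, genomes and reads with known truth.

The generator emulates, at desk scale, the structure a reference-based
classifier faces: a rooted bifurcating tree over reference genomes,
genomes that diverge by point substitutions along branches (so sister
leaves share more k-mers than distant ones), and shotgun reads sampled
uniformly from positions and strands with i.i.d. substitution errors.
Every function is a pure function of its configuration — identical
seeds give byte-identical files.

It does not model indels, rearrangements, realistic quality-dependent
error profiles, abundance skews or host contamination, so passing tests
demonstrate algorithmic correctness on substitution-divergent genomes,
not performance on real communities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .tree import PhyloTree, parse_newick

__all__ = [
    "SimulationConfig",
    "generate_tree",
    "evolve_genomes",
    "simulate_reads",
    "write_fasta",
    "write_fastq",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a synthetic community.

    Defaults describe a small but non-trivial community: 16 reference
    genomes of 5 kb diverging at 2% substitutions per branch (within
    the span of strain-to-species divergence once accumulated over the
    tree), 150 bp reads (typical short-read length), and error-free
    sequencing unless an error rate is set.
    """

    n_leaves: int = 16
    root_genome_length: int = 5000
    branch_substitution_prob: float = 0.02
    read_length: int = 150
    n_reads: int = 1000
    read_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_leaves < 2:
            raise ValueError("n_leaves must be at least 2")
        if not 0.0 <= self.branch_substitution_prob <= 0.3:
            raise ValueError("branch_substitution_prob must be in [0, 0.3]")
        if not 0.0 <= self.read_error_rate <= 0.1:
            raise ValueError("read_error_rate must be in [0, 0.1]")
        if self.root_genome_length < 1 or self.read_length < 1 or self.n_reads < 0:
            raise ValueError("lengths and counts must be positive")


def generate_tree(config: SimulationConfig) -> tuple[PhyloTree, str]:
    """Random bifurcating rooted topology by sequential random leaf attachment.

    Starts from the cherry (G1,G2) and attaches each further leaf by
    splitting a uniformly chosen existing edge.  Returns the tree and
    its Newick text (branch lengths of 1 throughout; divergence is
    governed by the per-branch substitution probability, not lengths).
    """
    rng = np.random.default_rng(config.seed)
    # nested-list topology: a node is either a leaf label or [left, right]
    topology: list = ["G1", "G2"]
    # edges identified by (parent container, child slot)
    edges: list[tuple[list, int]] = [(topology, 0), (topology, 1)]
    for i in range(3, config.n_leaves + 1):
        container, slot = edges[int(rng.integers(len(edges)))]
        new_internal = [container[slot], f"G{i}"]
        container[slot] = new_internal
        edges.append((new_internal, 0))
        edges.append((new_internal, 1))

    def render(node) -> str:
        if isinstance(node, str):
            return f"{node}:1"
        return f"({render(node[0])},{render(node[1])}):1"

    newick = f"({render(topology[0])},{render(topology[1])});"
    return parse_newick(newick), newick


def _mutate(sequence: np.ndarray, prob: float, rng: np.random.Generator) -> np.ndarray:
    """Apply i.i.d. substitutions; a hit site changes to one of the 3 other bases."""
    out = sequence.copy()
    if prob <= 0:
        return out
    hits = np.flatnonzero(rng.random(len(sequence)) < prob)
    if len(hits):
        shift = rng.integers(1, 4, size=len(hits))
        out[hits] = (out[hits] + shift) % 4
    return out


def evolve_genomes(tree: PhyloTree, config: SimulationConfig) -> dict[str, str]:
    """Evolve genomes down the tree by per-branch point substitutions.

    The root sequence is uniform random over ACGT; each child copies
    its parent with i.i.d. substitutions at the configured per-branch
    probability (no indels).  Returns leaf label → sequence.
    """
    rng = np.random.default_rng(config.seed + 1)
    codes: dict[int, np.ndarray] = {
        tree.root: rng.integers(0, 4, size=config.root_genome_length, dtype=np.uint8)
    }
    genomes: dict[str, str] = {}
    for node in tree.nodes:  # preorder guarantees parents precede children
        if node.parent is not None:
            codes[node.id] = _mutate(
                codes[node.parent], config.branch_substitution_prob, rng
            )
        if node.is_leaf:
            genomes[node.label] = _BASES[codes[node.id]].tobytes().decode("ascii")
    return genomes


def simulate_reads(
    genomes: dict[str, str],
    config: SimulationConfig,
    weights: dict[str, float] | None = None,
) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Sample shotgun reads with known truth labels.

    Reads are drawn uniformly over source genomes (or by ``weights``),
    start positions, and strands, with i.i.d. substitution errors at
    the configured rate.  Returns (reads, truth) where reads is a list
    of (read id, sequence) and truth pairs each read id with its source
    leaf label.
    """
    labels = sorted(genomes)
    for label in labels:
        if config.read_length > len(genomes[label]):
            raise ValueError(
                f"read_length {config.read_length} exceeds genome {label!r} "
                f"of length {len(genomes[label])}"
            )
    rng = np.random.default_rng(config.seed + 2)
    if weights is not None:
        probs = np.array([weights.get(label, 0.0) for label in labels], dtype=float)
        probs /= probs.sum()
    else:
        probs = None
    reads: list[tuple[str, str]] = []
    truth: list[tuple[str, str]] = []
    code_cache = {
        label: np.frombuffer(seq.encode(), dtype=np.uint8) for label, seq in genomes.items()
    }
    base_to_code = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        base_to_code[b] = i
    for i in range(config.n_reads):
        label = labels[int(rng.choice(len(labels), p=probs))]
        seq_codes = base_to_code[code_cache[label]]
        start = int(rng.integers(0, len(seq_codes) - config.read_length + 1))
        fragment = seq_codes[start : start + config.read_length]
        if rng.random() < 0.5:  # reverse strand
            fragment = (3 - fragment)[::-1]
        fragment = _mutate(fragment, config.read_error_rate, rng)
        reads.append((f"read{i}", _BASES[fragment].tobytes().decode("ascii")))
        truth.append((f"read{i}", label))
    return reads, truth


# -- file emission ---------------------------------------------------


def write_fasta(sequences: dict[str, str] | list[tuple[str, str]], path: str | Path) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    with open(path, "w", newline="\n") as handle:
        for name, seq in items:
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                handle.write(seq[i : i + 80] + "\n")


def write_fastq(reads: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        for name, seq in reads:
            handle.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth(truth: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", newline="\n") as handle:
        handle.write("read_id\tsource\n")
        for read_id, label in truth:
            handle.write(f"{read_id}\t{label}\n")


def read_truth(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as handle:
        next(handle)  # header
        for line in handle:
            read_id, label = line.rstrip("\n").split("\t")
            out[read_id] = label
    return out
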