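"""Independent brute-force oracles used to check the package's fast paths.

Everything here works from raw parent pointers and plain Python strings,
deliberately avoiding the package's LCA, encoding and index machinery.
"""

from __future__ import annotations


def path_to_root(tree, node: int) -> list[int]:
    """Walk raw parent pointers; root first."""
    path = [node]
    while tree.nodes[path[-1]].parent is not None:
        path.append(tree.nodes[path[-1]].parent)
    return path[::-1]


def brute_lca(tree, u: int, v: int) -> int:
    """Deepest node in the intersection of the two root paths."""
    pu, pv = path_to_root(tree, u), path_to_root(tree, v)
    common = None
    for a, b in zip(pu, pv):
        if a == b:
            common = a
        else:
            break
    return common


def brute_lca_set(tree, nodes) -> int:
    nodes = list(nodes)
    acc = nodes[0]
    for n in nodes[1:]:
        acc = brute_lca(tree, acc, n)
    return acc


_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def string_canonical_kmers(seq: str, k: int) -> list[str]:
    """Canonical k-mers as strings, skipping windows with non-ACGT bases."""
    out = []
    seq = seq.upper()
    for i in range(len(seq) - k + 1):
        window = seq[i : i + k]
        if any(b not in "ACGT" for b in window):
            continue
        out.append(min(window, revcomp(window)))
    return out


def brute_kmer_to_leaves(genomes: dict[str, list[str]], k: int) -> dict[str, set[str]]:
    """Map every canonical k-mer string to the set of leaf labels containing it."""
    table: dict[str, set[str]] = {}
    for label, sequences in genomes.items():
        for seq in sequences:
            for kmer in string_canonical_kmers(seq, k):
                table.setdefault(kmer, set()).add(label)
    return table
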