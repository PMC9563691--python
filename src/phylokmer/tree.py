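"""Rooted reference trees with fast ancestor and LCA queries.

The reference tree is the coordinate system for classification: every
database k-mer points at one of its nodes, and every read is placed on
one of its nodes.  Nodes carry dense integer IDs assigned in preorder
(root = 0), which makes each subtree a contiguous ID range
``[id, id + subtree_size)`` and turns ancestor tests into two integer
comparisons.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy

__all__ = ["PhyloTree", "TreeNode", "NewickParseError", "parse_newick"]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed into a valid rooted tree."""


@dataclass
class TreeNode:
    """A single node of a :class:`PhyloTree`.

    ``id`` is the preorder index; ``label`` is the Newick label (leaves
    always have one, unlabeled internal nodes receive a synthetic
    ``n<preorder-index>`` name).
    """

    id: int
    parent: int | None
    label: str
    children: list[int] = field(default_factory=list)
    branch_length: float | None = None
    depth: int = 0
    subtree_size: int = 1

    @property
    def is_leaf(self) -> bool:
        return not self.children


class PhyloTree:
    """Rooted (possibly multifurcating) tree with preorder node IDs.

    Construct via :func:`parse_newick` or :meth:`from_parent_table`.
    """

    def __init__(self, nodes: list[TreeNode]):
        if not nodes:
            raise NewickParseError("tree has no nodes")
        self.nodes = nodes
        self.root = 0
        self.leaf_name_index: dict[str, int] = {}
        for node in nodes:
            if node.is_leaf:
                if not node.label:
                    raise NewickParseError(f"leaf node {node.id} has an empty label")
                if node.label in self.leaf_name_index:
                    raise NewickParseError(f"duplicate leaf label {node.label!r}")
                self.leaf_name_index[node.label] = node.id
        self.label_index = {n.label: n.id for n in nodes}
        self._validate()

    # -- construction ------------------------------------------------

    def _validate(self) -> None:
        roots = [n for n in self.nodes if n.parent is None]
        if len(roots) != 1 or roots[0].id != 0:
            raise NewickParseError("tree must have exactly one root with ID 0")
        for node in self.nodes:
            if node.parent is not None:
                parent = self.nodes[node.parent]
                if node.id not in parent.children:
                    raise NewickParseError(
                        f"node {node.id} missing from children of its parent {parent.id}"
                    )
                if node.depth != parent.depth + 1:
                    raise NewickParseError(f"node {node.id} has inconsistent depth")

    @property
    def node_count(self) -> int:
        return len(self.nodes)

    @property
    def leaves(self) -> list[int]:
        return [n.id for n in self.nodes if n.is_leaf]

    def node_by_label(self, label: str) -> int:
        try:
            return self.label_index[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r}") from None

    def _check(self, node: int) -> None:
        if not 0 <= node < len(self.nodes):
            raise KeyError(f"invalid node ID {node}")

    # -- queries -----------------------------------------------------

    def is_ancestor(self, a: int, b: int) -> bool:
        """True iff ``a`` is an ancestor-or-self of ``b``."""
        self._check(a)
        self._check(b)
        return a <= b < a + self.nodes[a].subtree_size

    def lca(self, u: int, v: int) -> int:
        """Lowest common ancestor of two nodes.

        Walks up from the shallower preorder ID; each ancestor test is
        O(1) via the contiguous subtree-ID-range property, so a query
        costs O(depth) and is amortized-cheap on balanced trees.
        """
        self._check(u)
        self._check(v)
        if u > v:
            u, v = v, u
        node = self.nodes[u]
        while not (u <= v < u + node.subtree_size):
            u = node.parent  # type: ignore[assignment]  # root covers all IDs
            node = self.nodes[u]
        return u

    def lca_set(self, nodes) -> int:
        """LCA of a non-empty collection of nodes.

        In preorder numbering the LCA of a set equals the LCA of its
        minimum-ID and maximum-ID members (their ID range brackets every
        other member, and subtrees are contiguous ID ranges).
        """
        nodes = list(nodes)
        if not nodes:
            raise ValueError("lca_set requires a non-empty set of nodes")
        return self.lca(min(nodes), max(nodes))

    def root_path(self, node: int) -> list[int]:
        """Node IDs from the root down to ``node``, inclusive."""
        self._check(node)
        path = []
        cur: int | None = node
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        path.reverse()
        return path

    # -- serialization -----------------------------------------------

    def to_newick(self, include_branch_lengths: bool = True) -> str:
        def fmt_label(label: str) -> str:
            if any(c in label for c in "(),:;[] '\t"):
                return "'" + label.replace("'", "''") + "'"
            return label

        def render(nid: int) -> str:
            node = self.nodes[nid]
            if node.children:
                inner = ",".join(render(c) for c in node.children)
                out = f"({inner}){fmt_label(node.label)}"
            else:
                out = fmt_label(node.label)
            if include_branch_lengths and node.branch_length is not None:
                out += f":{node.branch_length:g}"
            return out

        return render(self.root) + ";"

    def newick_digest(self) -> str:
        import hashlib

        return hashlib.sha256(self.to_newick().encode()).hexdigest()


def parse_newick(text: str) -> PhyloTree:
    """Parse a single rooted Newick statement into a :class:`PhyloTree`.

    Branch lengths and internal labels are preserved; quoted labels and
    ``[]`` comments follow standard Newick conventions.  Unlabeled
    internal nodes are named ``n<preorder-index>`` so every node has a
    stable, unique identifier in reports.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"malformed Newick: {exc}") from None

    nodes: list[TreeNode] = []
    index: dict[int, int] = {}  # id(dendropy node) -> our ID, filled in preorder
    for dnode in dtree.preorder_node_iter():
        nid = len(nodes)
        index[id(dnode)] = nid
        if dnode.parent_node is None:
            parent = None
            depth = 0
        else:
            parent = index[id(dnode.parent_node)]
            depth = nodes[parent].depth + 1
            nodes[parent].children.append(nid)
        raw = dnode.taxon.label if dnode.taxon is not None else dnode.label
        label = raw if raw else f"n{nid}"
        nodes.append(
            TreeNode(
                id=nid,
                parent=parent,
                label=label,
                branch_length=dnode.edge.length,
                depth=depth,
            )
        )
    for node in reversed(nodes):
        if node.parent is not None:
            nodes[node.parent].subtree_size += node.subtree_size
    return PhyloTree(nodes)
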