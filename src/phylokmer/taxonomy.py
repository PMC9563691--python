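"""Projection of tree-space classifications onto the NCBI taxonomy.

The reference tree is taxonomy-agnostic, but findings are communicated
taxonomically: every tree node is mapped to the taxonomic LCA of the
taxids of all reference genomes in its subtree, and per-read results
are re-expressed through that map.  The projection can only coarsen —
toward the tree root, mapped taxids get no more specific.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .classify import ReadClassification
from .tree import PhyloTree

__all__ = [
    "TaxonomyDB",
    "NodeTaxidMap",
    "TaxonomyError",
    "load_taxonomy",
    "taxid_lca",
    "build_node_taxid_map",
    "to_taxonomy",
    "load_leaf_taxids",
]

ROOT_TAXID = 1

# Kraken-convention single-letter rank codes
RANK_CODES = {
    "root": "R",
    "superkingdom": "D",
    "domain": "D",
    "kingdom": "K",
    "phylum": "P",
    "class": "C",
    "order": "O",
    "family": "F",
    "genus": "G",
    "species": "S",
}


class TaxonomyError(ValueError):
    pass


@dataclass
class TaxonomyDB:
    """NCBI taxonomy as parent pointers plus rank and name tables."""

    parent: dict[int, int]
    rank: dict[int, str]
    name: dict[int, str]
    root_taxid: int = ROOT_TAXID

    def lineage(self, taxid: int) -> list[int]:
        """Root-to-taxid chain, root first."""
        if taxid not in self.parent:
            raise TaxonomyError(f"unknown taxid {taxid}")
        chain = [taxid]
        while taxid != self.root_taxid:
            taxid = self.parent[taxid]
            chain.append(taxid)
        chain.reverse()
        return chain

    def rank_code(self, taxid: int) -> str:
        return RANK_CODES.get(self.rank.get(taxid, ""), "-")


@dataclass
class NodeTaxidMap:
    mapping: dict[int, int] = field(default_factory=dict)

    def __getitem__(self, node: int) -> int:
        try:
            return self.mapping[node]
        except KeyError:
            raise TaxonomyError(f"tree node {node} has no mapped taxid") from None


def _parse_dmp(path: str | Path) -> Iterator[tuple[int, list[str]]]:
    """Parse the NCBI dump dialect: fields '\\t|\\t'-separated, records end '\\t|'."""
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.endswith("\t|"):
                line = line[: -len("\t|")]
            fields = line.split("\t|\t")
            try:
                yield int(fields[0]), fields
            except (ValueError, IndexError):
                raise TaxonomyError(f"{path}: malformed record at line {lineno}") from None


def load_taxonomy(
    nodes_path: str | Path,
    names_path: str | Path,
    merged_path: str | Path | None = None,
) -> TaxonomyDB:
    """Load nodes.dmp / names.dmp (and optionally merged.dmp).

    Only names of class "scientific name" are retained.  Merged taxids,
    when supplied, become aliases of their targets; deleted taxids are
    not resolved.
    """
    parent: dict[int, int] = {}
    rank: dict[int, str] = {}
    for taxid, fields in _parse_dmp(nodes_path):
        parent[taxid] = int(fields[1])
        rank[taxid] = fields[2] if len(fields) > 2 else ""
    parent[ROOT_TAXID] = ROOT_TAXID
    for taxid, par in parent.items():
        if par not in parent:
            raise TaxonomyError(
                f"{nodes_path}: taxid {taxid} references undefined parent {par}"
            )
    name: dict[int, str] = {}
    for taxid, fields in _parse_dmp(names_path):
        name_class = fields[3] if len(fields) > 3 else ""
        if name_class == "scientific name":
            if taxid not in parent:
                raise TaxonomyError(f"{names_path}: name for undefined taxid {taxid}")
            name[taxid] = fields[1]
    db = TaxonomyDB(parent=parent, rank=rank, name=name)
    if merged_path is not None:
        for old, fields in _parse_dmp(merged_path):
            new = int(fields[1])
            if new not in parent:
                raise TaxonomyError(f"{merged_path}: merge target {new} undefined")
            parent[old] = parent[new]
            rank[old] = rank[new]
            name.setdefault(old, name.get(new, ""))
    return db


def taxid_lca(db: TaxonomyDB, taxids: Iterable[int]) -> int:
    """Deepest taxid ancestral-or-self to every input taxid."""
    taxids = list(taxids)
    if not taxids:
        raise TaxonomyError("taxid_lca requires a non-empty set")
    common = db.lineage(taxids[0])
    for taxid in taxids[1:]:
        other = db.lineage(taxid)
        limit = min(len(common), len(other))
        i = 0
        while i < limit and common[i] == other[i]:
            i += 1
        common = common[:i]
    return common[-1]


def build_node_taxid_map(
    tree: PhyloTree,
    leaf_taxids: dict[str, int],
    db: TaxonomyDB,
) -> NodeTaxidMap:
    """Map every tree node to the taxonomic LCA of its subtree's leaves.

    Computed bottom-up in one post-order pass: a leaf maps to its own
    taxid; an internal node maps to the taxid LCA of its children's
    mapped taxids (LCA is associative over the partition into subtrees).
    """
    missing = sorted(set(tree.leaf_name_index) - set(leaf_taxids))
    if missing:
        raise TaxonomyError(f"leaves without taxids: {missing}")
    mapping: dict[int, int] = {}
    for node in reversed(tree.nodes):  # reverse preorder = children first
        if node.is_leaf:
            taxid = leaf_taxids[node.label]
            if taxid not in db.parent:
                raise TaxonomyError(f"leaf {node.label!r}: taxid {taxid} not in taxonomy")
            mapping[node.id] = taxid
        else:
            mapping[node.id] = taxid_lca(db, [mapping[c] for c in node.children])
    return NodeTaxidMap(mapping=mapping)


def to_taxonomy(
    classifications: Iterable[ReadClassification],
    node_taxids: NodeTaxidMap,
) -> Iterator[tuple[ReadClassification, int | None]]:
    """Pair each classification with its assigned node's taxid.

    Read order and statuses are untouched; unclassified reads map to
    None.  An assigned node missing from the map is a contract error.
    """
    for rc in classifications:
        if rc.assigned_node is None:
            yield rc, None
        else:
            yield rc, node_taxids[rc.assigned_node]


def load_leaf_taxids(path: str | Path) -> dict[str, int]:
    """Read a two-column TSV (leaf label, taxid); a header line is allowed."""
    out: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise TaxonomyError(f"{path}: expected 2 columns at line {lineno}")
            if lineno == 1 and not fields[1].strip().isdigit():
                continue  # header
            out[fields[0]] = int(fields[1])
    return out
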