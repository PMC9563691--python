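"""Accumulation of per-read classifications and Kraken-compatible output.

Three artifacts are written per sample: a per-read file (one line per
read, Kraken dialect), a hierarchical report (clade-cumulative and
direct counts with percentages), and a split-count table — the
database-gap diagnostic that ranks clades by how many split-lineage
reads they absorb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Iterator

from .classify import MATE_BOUNDARY, MISS, ReadClassification, Status
from .taxonomy import NodeTaxidMap, TaxonomyDB
from .tree import PhyloTree

__all__ = [
    "SampleSummary",
    "accumulate",
    "write_per_read",
    "parse_per_read",
    "write_report",
    "parse_report",
    "write_split_table",
]


@dataclass
class SampleSummary:
    """Per-node tallies for one sample.

    ``direct_*`` count reads assigned exactly at a node, separated into
    single-lineage and split-lineage; ``cumulative`` counts reads
    assigned at or below a node (clade counts).  Conservation:
    SL + split + unclassified = total reads, and cumulative satisfies
    ``cumulative[n] = direct[n] + sum over children``.
    """

    direct_sl: dict[int, int] = field(default_factory=dict)
    direct_split: dict[int, int] = field(default_factory=dict)
    cumulative: dict[int, int] = field(default_factory=dict)
    cumulative_split: dict[int, int] = field(default_factory=dict)
    unclassified: int = 0
    total_reads: int = 0

    def direct(self, node: int) -> int:
        return self.direct_sl.get(node, 0) + self.direct_split.get(node, 0)


def accumulate(
    classifications: Iterable[ReadClassification],
    tree: PhyloTree,
) -> SampleSummary:
    """Single deterministic pass turning a classification stream into tallies."""
    summary = SampleSummary()
    for rc in classifications:
        summary.total_reads += 1
        if rc.status is Status.UNCLASSIFIED:
            summary.unclassified += 1
            continue
        bucket = summary.direct_sl if rc.status is Status.SL else summary.direct_split
        bucket[rc.assigned_node] = bucket.get(rc.assigned_node, 0) + 1
        for ancestor in tree.root_path(rc.assigned_node):
            summary.cumulative[ancestor] = summary.cumulative.get(ancestor, 0) + 1
            if rc.status is Status.SPLIT:
                summary.cumulative_split[ancestor] = (
                    summary.cumulative_split.get(ancestor, 0) + 1
                )
    return summary


# -- per-read format -------------------------------------------------
#
# One tab-separated line per read (Kraken dialect):
#   status ("C"/"U"), read id, assigned identifier, read length
#   ("len1|len2" for pairs), space-separated per-k-mer mapping RLE in
#   read order ("id:count", misses "-:count", mate boundary "|:|").


def _run_token(value: int, count: int, labeler) -> str:
    if value == MATE_BOUNDARY:
        return "|:|"
    if value == MISS:
        return f"-:{count}"
    return f"{labeler(value)}:{count}"


def write_per_read(
    classifications: Iterable[ReadClassification],
    path: str | Path,
    tree: PhyloTree,
    id_space: str = "tree",
    node_taxids: NodeTaxidMap | None = None,
) -> None:
    if id_space not in {"tree", "taxonomy"}:
        raise ValueError(f"unknown id_space {id_space!r}")
    if id_space == "taxonomy":
        if node_taxids is None:
            raise ValueError("taxonomy id_space requires a node->taxid map")
        labeler = lambda node: str(node_taxids[node])  # noqa: E731
        unassigned = "0"
    else:
        labeler = lambda node: tree.nodes[node].label  # noqa: E731
        unassigned = "0"
    with open(path, "w", newline="\n") as handle:
        for rc in classifications:
            status = "U" if rc.status is Status.UNCLASSIFIED else "C"
            ident = unassigned if rc.assigned_node is None else labeler(rc.assigned_node)
            length = "|".join(str(n) for n in rc.read_lengths) or "0"
            if rc.hits.runs:
                rle = " ".join(_run_token(v, c, labeler) for v, c in rc.hits.runs)
            else:
                rle = f"-:{rc.hits.total_kmers}"
            handle.write(f"{status}\t{rc.read_id}\t{ident}\t{length}\t{rle}\n")


def parse_per_read(path: str | Path) -> Iterator[tuple[str, str, str, str, str]]:
    """Parse a per-read file back into its five columns (round-trip reader)."""
    with open(path) as handle:
        for line in handle:
            status, read_id, ident, length, rle = line.rstrip("\n").split("\t")
            yield status, read_id, ident, length, rle


# -- hierarchical report ---------------------------------------------


def _pct(count: int, total: int) -> str:
    if total == 0:
        return "0.00"
    value = Decimal(count) / Decimal(total) * 100
    return str(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def write_report(
    summary: SampleSummary,
    tree: PhyloTree,
    path: str | Path,
    id_space: str = "tree",
    node_taxids: NodeTaxidMap | None = None,
    taxonomy: TaxonomyDB | None = None,
) -> None:
    """Write a Kraken-dialect report.

    Columns: percentage of total reads (two decimals, half-up),
    clade-cumulative count, direct count, rank code ('-' in tree
    space), identifier, name indented two spaces per depth level.  Rows
    in depth-first order, zero-cumulative rows omitted, an unclassified
    row first.
    """
    total = summary.total_reads
    lines = [
        "\t".join(
            [_pct(summary.unclassified, total), str(summary.unclassified), str(summary.unclassified), "U", "0", "unclassified"]
        )
    ]
    if id_space == "tree":
        for node in tree.nodes:  # preorder == depth-first
            clade = summary.cumulative.get(node.id, 0)
            if clade == 0:
                continue
            lines.append(
                "\t".join(
                    [
                        _pct(clade, total),
                        str(clade),
                        str(summary.direct(node.id)),
                        "-",
                        node.label,
                        "  " * node.depth + node.label,
                    ]
                )
            )
    elif id_space == "taxonomy":
        if node_taxids is None or taxonomy is None:
            raise ValueError("taxonomy id_space requires a node->taxid map and a TaxonomyDB")
        direct: dict[int, int] = {}
        for node, count in {**summary.direct_sl}.items():
            taxid = node_taxids[node]
            direct[taxid] = direct.get(taxid, 0) + count
        for node, count in summary.direct_split.items():
            taxid = node_taxids[node]
            direct[taxid] = direct.get(taxid, 0) + count
        clade: dict[int, int] = {}
        children: dict[int, list[int]] = {}
        involved: set[int] = set()
        for taxid, count in direct.items():
            for ancestor in taxonomy.lineage(taxid):
                clade[ancestor] = clade.get(ancestor, 0) + count
                involved.add(ancestor)
        for taxid in involved:
            if taxid != taxonomy.root_taxid:
                children.setdefault(taxonomy.parent[taxid], []).append(taxid)

        def emit(taxid: int, depth: int) -> None:
            name = taxonomy.name.get(taxid, str(taxid))
            lines.append(
                "\t".join(
                    [
                        _pct(clade[taxid], total),
                        str(clade[taxid]),
                        str(direct.get(taxid, 0)),
                        taxonomy.rank_code(taxid),
                        str(taxid),
                        "  " * depth + name,
                    ]
                )
            )
            for child in sorted(children.get(taxid, [])):
                emit(child, depth + 1)

        if involved:
            emit(taxonomy.root_taxid, 0)
    else:
        raise ValueError(f"unknown id_space {id_space!r}")
    with open(path, "w", newline="\n") as handle:
        handle.write("\n".join(lines) + "\n")


def parse_report(path: str | Path) -> list[tuple[str, int, int, str, str, str]]:
    """Parse a report back into (pct, clade, direct, rank, id, name) rows."""
    rows = []
    with open(path) as handle:
        for line in handle:
            pct, clade, direct, rank, ident, name = line.rstrip("\n").split("\t")
            rows.append((pct, int(clade), int(direct), rank, ident, name.lstrip(" ")))
    return rows


# -- split diagnostic ------------------------------------------------


def write_split_table(
    summary: SampleSummary,
    tree: PhyloTree,
    path: str | Path,
) -> None:
    """Write the database-gap diagnostic table.

    One row per node with any classified read in its clade: label,
    depth, direct SL and split counts, clade-cumulative split count and
    split fraction (cumulative split / cumulative total), sorted by
    descending cumulative split count.  Clades where many reads split
    are candidates for missing reference genomes.
    """
    rows = []
    for node in tree.nodes:
        clade_total = summary.cumulative.get(node.id, 0)
        if clade_total == 0:
            continue
        clade_split = summary.cumulative_split.get(node.id, 0)
        fraction = f"{clade_split / clade_total:.6f}" if clade_total else ""
        rows.append(
            (
                node.label,
                node.depth,
                summary.direct_sl.get(node.id, 0),
                summary.direct_split.get(node.id, 0),
                clade_split,
                fraction,
            )
        )
    rows.sort(key=lambda r: (-r[4], r[1], r[0]))
    with open(path, "w", newline="\n") as handle:
        handle.write("node\tdepth\tdirect_sl\tdirect_split\tcumulative_split\tsplit_fraction\n")
        for row in rows:
            handle.write("\t".join(str(x) for x in row) + "\n")
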