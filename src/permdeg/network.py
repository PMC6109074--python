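"""DEG interaction-subnetwork assembly from user-supplied edge lists.

Protein–protein interaction edges (SIF or 2/3-column TSV, possibly from
several source databases) are merged into one undirected graph; the
subnetwork induced by a selected gene list keeps those genes plus their
direct interactors that are present in the expression data, so every node
carries a defined log2 fold change.  Nodes are grouped by the first
matching pathway/process tag (sorted set name, deterministic tie-break)
for layout in external viewers; output formats are SIF, a node-attribute
TSV and GraphML.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .enrich import GeneSetCollection
from .errors import ParseError, ValidationError
from .stats import GeneStatTable

__all__ = [
    "read_edge_list",
    "merge_edge_lists",
    "induce_subnetwork",
    "group_nodes",
    "write_sif",
    "write_node_attributes",
    "write_graphml",
]


def read_edge_list(path, source: str | None = None) -> list[tuple[str, str, str]]:
    """Read SIF (nodeA <tab> interaction <tab> nodeB) or 2-column TSV.

    Returns (a, b, source_label) triples; ``source`` defaults to the file
    stem.  Malformed lines raise :class:`ParseError` with the line number.
    """
    label = source if source is not None else Path(path).stem
    edges: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = [p.strip() for p in line.split("\t")]
            if len(parts) == 2:
                a, b = parts
            elif len(parts) == 3:
                a, _, b = parts  # SIF: middle column is the interaction type
            else:
                raise ParseError(
                    f"expected 2 or 3 tab-separated fields, got {len(parts)}",
                    path=path,
                    line=i,
                )
            if not a or not b:
                raise ParseError("empty node id", path=path, line=i)
            edges.append((a, b, label))
    return edges


def merge_edge_lists(
    paths: Sequence | Mapping[str, object],
) -> list[tuple[str, str, str]]:
    """Read and concatenate several edge files ({label: path} or [paths])."""
    if isinstance(paths, Mapping):
        items = [(label, p) for label, p in paths.items()]
    else:
        items = [(None, p) for p in paths]
    merged: list[tuple[str, str, str]] = []
    for label, p in items:
        merged.extend(read_edge_list(p, source=label))
    return merged


def induce_subnetwork(
    edges: Iterable[tuple[str, str] | tuple[str, str, str]],
    selected: Sequence[str],
    stats: GeneStatTable | pd.DataFrame,
) -> nx.Graph:
    """Build the undirected subnetwork of ``selected`` genes + interactors.

    Nodes are the selected genes plus their direct neighbours present in
    the statistics table (so log2FC is defined everywhere); edges are the
    input edges with both endpoints in that node set.  Self-loops are
    dropped; duplicate edges merge with the union of their source labels.
    """
    table = stats.table if isinstance(stats, GeneStatTable) else stats
    stat_genes = set(map(str, table["gene_id"]))
    selected_set = set(map(str, selected))
    missing = sorted(selected_set - stat_genes)
    if missing:
        raise ValidationError(
            f"selected gene(s) absent from the statistics table: {missing[:10]}"
        )

    # full merged graph first, so neighbours can be looked up
    full: dict[frozenset, set[str]] = {}
    adjacency: dict[str, set[str]] = {}
    for edge in edges:
        a, b = str(edge[0]), str(edge[1])
        label = str(edge[2]) if len(edge) > 2 else "edges"
        if a == b:
            continue  # self-loops violate the network invariant
        key = frozenset((a, b))
        full.setdefault(key, set()).add(label)
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)

    nodes = set(selected_set)
    for g in selected_set:
        nodes |= adjacency.get(g, set()) & stat_genes

    G = nx.Graph()
    rows = table.set_index(table["gene_id"].astype(str))
    for node in sorted(nodes):
        attrs = {}
        if node in rows.index:
            rec = rows.loc[node]
            attrs["log2fc"] = float(rec["log2fc"])
            if "is_deg" in rec:
                attrs["is_deg"] = bool(rec["is_deg"])
        attrs["selected"] = node in selected_set
        G.add_node(node, **attrs)
    for key, sources in full.items():
        a, b = sorted(key)
        if a in nodes and b in nodes:
            G.add_edge(a, b, sources=",".join(sorted(sources)))
    return G


def group_nodes(network: nx.Graph, sets: GeneSetCollection) -> dict[str, str]:
    """Assign each node its first matching set name (sorted; deterministic).

    Unmatched nodes get "unassigned".  The mapping is also written onto the
    node attribute ``group``.
    """
    ordered = sorted(sets.sets)
    groups: dict[str, str] = {}
    for node in network.nodes:
        assigned = "unassigned"
        for name in ordered:
            if node in sets.sets[name]:
                assigned = name
                break
        groups[node] = assigned
        network.nodes[node]["group"] = assigned
    return groups


def write_sif(network: nx.Graph, path, interaction: str = "pp") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")


def write_node_attributes(network: nx.Graph, path) -> None:
    rows = []
    for node in sorted(network.nodes):
        d = network.nodes[node]
        rows.append(
            {
                "gene_id": node,
                "log2fc": d.get("log2fc", float("nan")),
                "is_deg": str(d.get("is_deg", False)).lower(),
                "selected": str(d.get("selected", False)).lower(),
                "group": d.get("group", "unassigned"),
            }
        )
    pd.DataFrame(
        rows, columns=["gene_id", "log2fc", "is_deg", "selected", "group"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_graphml(network: nx.Graph, path) -> None:
    nx.write_graphml(network, path)
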