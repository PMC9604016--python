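"""Protein-ligand interaction (PLI) networks.

Consensus target-ligand associations form a bipartite graph; projecting
it onto the targets yields a weighted network where an edge between two
targets carries the number of ligands they share.  Node size in the
paper-style figures is the degree, so it is stored as a node attribute;
targets with associated ligands but no shared ones stay in the graph as
degree-0 nodes.
"""
from __future__ import annotations

from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .consensus import ConsensusTable
from .runlog import RunLog, get_log

EXPORT_FORMATS = ("graphml", "sif", "edge_table")


def build_network(
    t: ConsensusTable, min_confidence: int = 1, log: RunLog | None = None
) -> nx.Graph:
    """Project consensus associations (confidence >= min_confidence) onto targets.

    weight(A, B) = |ligands(A) & ligands(B)|; edges exist only for
    weight >= 1.  Node attributes: ``n_ligands`` (associated ligands)
    and ``degree`` (incident edges).
    """
    log = get_log(log)
    if not 1 <= min_confidence <= 5:
        raise ValueError("min_confidence must be in [1, 5]")
    frame = t.filter(min_confidence).frame
    graph = nx.Graph()
    if frame.empty:
        log.record(f"build_network: no associations at confidence >= {min_confidence}")
        return graph
    ligands_of = {
        target: set(group["ligand_id"]) for target, group in frame.groupby("target_id")
    }
    for target in sorted(ligands_of):
        graph.add_node(target, n_ligands=len(ligands_of[target]))
    for a, b in combinations(sorted(ligands_of), 2):
        shared = len(ligands_of[a] & ligands_of[b])
        if shared:
            graph.add_edge(a, b, weight=shared)
    for node in graph.nodes:
        graph.nodes[node]["degree"] = graph.degree(node)
    return graph


def _sorted_copy(n: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    for node in sorted(n.nodes):
        out.add_node(node, **n.nodes[node])
    for a, b in sorted(tuple(sorted(e)) for e in n.edges):
        out.add_edge(a, b, **n.edges[a, b])
    return out


def export_network(n: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write the network; identical input yields a byte-identical file.

    Formats: ``graphml``, ``sif`` (Cytoscape simple-interaction lines
    ``A shared_ligands B``), or ``edge_table`` (TSV of
    target_a, target_b, weight).
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_sorted_copy(n), path)
    elif format == "sif":
        lines = [
            f"{a}\tshared_ligands\t{b}"
            for a, b in sorted(tuple(sorted(e)) for e in n.edges)
        ]
        isolated = sorted(node for node in n.nodes if n.degree(node) == 0)
        lines += [str(node) for node in isolated]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif format == "edge_table":
        rows = sorted(
            (min(a, b), max(a, b), n.edges[a, b]["weight"]) for a, b in n.edges
        )
        pd.DataFrame(rows, columns=["target_a", "target_b", "weight"]).to_csv(
            path, sep="\t", index=False
        )
    else:
        raise ValueError(f"unknown export format: {format!r} (expected one of {EXPORT_FORMATS})")
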