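"""Topology summaries of gene-interaction edge lists.

Operates on user-supplied TSV edge lists (node_a, node_b, optional
interaction type); duplicate node pairs with different types are kept as
multi-edges.  The summary statistics follow the NetworkAnalyzer
conventions: the average number of neighbors counts *distinct* adjacent
nodes (multi-edges collapse), and heterogeneity is the coefficient of
variation of that neighbor count, sqrt(population variance) / mean.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx
import numpy as np


def load_edgelist(path: str | Path, allow_self_loops: bool = False) -> nx.MultiGraph:
    """Load a TSV edge list into an undirected multigraph.

    Each row is ``node_a<TAB>node_b[<TAB>type]``.  A header row starting
    with ``node_a`` is skipped.  Malformed rows raise with their line
    number.  An empty file yields an empty graph.
    """
    g = nx.MultiGraph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[0].strip().lower() == "node_a":
                continue
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ValueError(f"{path}: malformed edge row at line {lineno}: {line!r}")
            a, b = parts[0].strip(), parts[1].strip()
            etype = parts[2].strip() if len(parts) > 2 else None
            if a == b and not allow_self_loops:
                raise ValueError(f"{path}: self-loop {a!r} at line {lineno} (not allowed)")
            g.add_edge(a, b, type=etype)
    return g


def topology_summary(g: nx.MultiGraph) -> dict:
    """Node, edge, component, multi-edge, neighbor and heterogeneity stats.

    ``avg_neighbors`` is the mean over nodes of the number of distinct
    adjacent nodes; ``heterogeneity`` is sqrt(population variance of that
    count) divided by its mean (0 for a regular graph).  An empty graph
    returns an all-zero summary flagged ``empty``.
    """
    n_nodes = g.number_of_nodes()
    if n_nodes == 0:
        return {
            "n_nodes": 0, "n_edges": 0, "n_components": 0,
            "n_multi_edge_pairs": 0, "avg_neighbors": 0.0,
            "heterogeneity": 0.0, "empty": True,
        }
    simple = nx.Graph(g)
    neighbor_counts = np.array([len(set(g.neighbors(v)) - {v}) for v in g.nodes], dtype=float)
    mean_nb = float(neighbor_counts.mean())
    var_nb = float(neighbor_counts.var())  # population variance
    heterogeneity = float(np.sqrt(var_nb) / mean_nb) if mean_nb > 0 else 0.0
    n_multi = sum(
        1 for u, v in simple.edges if u != v and g.number_of_edges(u, v) > 1
    )
    return {
        "n_nodes": n_nodes,
        "n_edges": g.number_of_edges(),
        "n_components": nx.number_connected_components(simple),
        "n_multi_edge_pairs": n_multi,
        "avg_neighbors": mean_nb,
        "heterogeneity": heterogeneity,
        "empty": False,
    }
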