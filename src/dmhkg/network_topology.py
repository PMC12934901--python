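"""Structural statistics of the knowledge graph.

Degree and weighted degree count incident edges on the directed multigraph
(in + out), matching how hub degrees are reported.  Clustering and density
are classical undirected measures, so they are computed on the undirected
simple projection in which parallel edges of different relation types
collapse to a single link.  Nodes of projected degree < 2 contribute a
local clustering of 0 (they are not excluded from the mean).
"""

from __future__ import annotations

import json
from collections import defaultdict
from pathlib import Path

import networkx as nx
import pandas as pd

from .graph_builder import KnowledgeGraph


def degree_table(graph: KnowledgeGraph) -> pd.DataFrame:
    """Per-node degree (incident edge count) and weighted degree (sum of W)."""
    degree: defaultdict[str, int] = defaultdict(int)
    weighted: defaultdict[str, float] = defaultdict(float)
    for e in graph.edges:
        for end in (e.source, e.target):
            degree[end] += 1
            weighted[end] += e.weight or 0.0
    rows = [
        {
            "label": label,
            "category": graph.node_categories[label],
            "degree": degree[label],
            "weighted_degree": weighted[label],
        }
        for label in graph.nodes
    ]
    return pd.DataFrame(rows, columns=["label", "category", "degree", "weighted_degree"])


def top_hubs(
    graph: KnowledgeGraph, k: int, measure: str = "weighted_degree"
) -> pd.DataFrame:
    """Top-k nodes by ``degree`` or ``weighted_degree``.

    Stable descending order; ties broken lexicographically by label.  If k
    exceeds the node count, all nodes are returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if measure not in ("degree", "weighted_degree"):
        raise ValueError(f"unknown hub measure {measure!r}")
    table = degree_table(graph)
    table = table.sort_values(
        by=[measure, "label"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return table.head(k)


def undirected_projection(graph: KnowledgeGraph) -> nx.Graph:
    """Simple undirected projection: parallel/antiparallel edges collapse."""
    g = nx.Graph()
    g.add_nodes_from(graph.nodes)
    for e in graph.edges:
        if e.source != e.target:
            g.add_edge(e.source, e.target)
    return g


def clustering_and_density(graph: KnowledgeGraph) -> tuple[float, float]:
    """(mean local clustering coefficient, density) on the simple projection.

    Density is E / (N(N-1)/2), the ratio of observed links to all possible
    links.  Requires at least two nodes.
    """
    g = undirected_projection(graph)
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("density undefined for graphs with fewer than 2 nodes")
    clustering = sum(nx.clustering(g).values()) / n
    density = g.number_of_edges() / (n * (n - 1) / 2)
    return clustering, density


def category_connectivity(
    graph: KnowledgeGraph, normalization: str = "max"
) -> pd.DataFrame:
    """Symmetrized, normalized edge counts between entity-category pairs.

    Cell (a, b) starts as the count of edges from category a to category b;
    off-diagonal cells are then symmetrized by summing with the transposed
    cell (the diagonal keeps its raw count).  Normalization is by the global
    maximum (default) or per row.
    """
    if normalization not in ("max", "row"):
        raise ValueError(f"unknown normalization {normalization!r}")
    categories = sorted(
        set(graph.node_categories.values())
    )
    mat = pd.DataFrame(0.0, index=categories, columns=categories)
    for e in graph.edges:
        a = graph.node_categories[e.source]
        b = graph.node_categories[e.target]
        mat.loc[a, b] += 1
    sym = mat + mat.T
    for c in categories:
        sym.loc[c, c] = mat.loc[c, c]
    if normalization == "max":
        peak = sym.to_numpy().max()
        return sym / peak if peak > 0 else sym
    row_sums = sym.sum(axis=1)
    return sym.div(row_sums.where(row_sums > 0, 1.0), axis=0)


def per_category_degree_summary(graph: KnowledgeGraph) -> pd.DataFrame:
    """min/median/mean/max degree per entity category."""
    table = degree_table(graph)
    grouped = table.groupby("category")["degree"]
    out = grouped.agg(["min", "median", "mean", "max", "count"]).reset_index()
    return out.rename(columns={"count": "n_nodes"})


def topology_report(
    graph: KnowledgeGraph,
    hub_k: int = 10,
    hub_measure: str = "weighted_degree",
    normalization: str = "max",
) -> dict:
    clustering, density = clustering_and_density(graph)
    return {
        "n_nodes": graph.n_nodes,
        "n_edges": graph.n_edges,
        "mean_clustering": clustering,
        "density": density,
        "clustering_note": (
            "unweighted undirected simple projection; degree<2 nodes "
            "contribute 0 to the mean"
        ),
        "hubs": top_hubs(graph, hub_k, hub_measure).to_dict(orient="records"),
        "hub_measure": hub_measure,
        "per_category_degrees": per_category_degree_summary(graph).to_dict(
            orient="records"
        ),
        "connectivity_normalization": normalization,
    }


def write_topology_report(
    graph: KnowledgeGraph,
    outdir: str | Path,
    hub_k: int = 10,
    hub_measure: str = "weighted_degree",
    normalization: str = "max",
    extra_metadata: dict | None = None,
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = topology_report(graph, hub_k, hub_measure, normalization)
    if extra_metadata:
        report.update(extra_metadata)
    paths = {
        "report": outdir / "topology.json",
        "degrees": outdir / "degrees.tsv",
        "connectivity": outdir / "category_connectivity.tsv",
    }
    paths["report"].write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    degree_table(graph).to_csv(paths["degrees"], sep="\t", index=False)
    category_connectivity(graph, normalization).to_csv(paths["connectivity"], sep="\t")
    return paths
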