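"""Descriptive statistics and comparison of neighbourhood graphs.

Summary indexes (density, connectivity, diameter; per-vertex degree,
betweenness, closeness), adjacency-matrix Pearson correlation between
two graphs, and the ERGM fitting/simulation/goodness-of-fit workflow
(re-exported from :mod:`nucgraph.ergm`).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

import networkx as nx
import numpy as np

from .ergm import (  # noqa: F401  (module surface)
    ErgmFit,
    ErgmTerm,
    GofReport,
    ergm_fit,
    ergm_gof,
    parse_terms,
    simulate_from_ergm,
)

__all__ = [
    "GraphSummary",
    "graph_statistics",
    "graph_correlation",
    "ergm_fit",
    "simulate_from_ergm",
    "ergm_gof",
    "ErgmFit",
    "GofReport",
]


@dataclass
class GraphSummary:
    density: float
    n_components: int
    largest_component_size: int
    diameter: int
    degree: Dict[str, int]
    betweenness: Dict[str, float]
    closeness: Dict[str, float]

    def to_dict(self) -> dict:
        return {
            "density": self.density,
            "n_components": self.n_components,
            "largest_component_size": self.largest_component_size,
            "diameter": self.diameter,
            "degree": self.degree,
            "betweenness": self.betweenness,
            "closeness": self.closeness,
        }


def _as_simple(graph) -> nx.Graph:
    if hasattr(graph, "simple_graph"):
        return graph.simple_graph()
    g = nx.Graph(graph)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g


def graph_statistics(graph) -> GraphSummary:
    """Global and local indexes on the simple undirected projection.

    Density is 2E / (V(V-1)); the diameter is taken over the largest
    connected component; betweenness and closeness follow the standard
    shortest-path definitions (closeness scaled by the reachable
    fraction, 0 for isolated vertices).
    """
    g = _as_simple(graph)
    n = g.number_of_nodes()
    if n < 1:
        raise ValueError("graph must have at least one vertex")
    density = 0.0 if n < 2 else 2.0 * g.number_of_edges() / (n * (n - 1))
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    largest = g.subgraph(components[0])
    diameter = nx.diameter(largest) if largest.number_of_nodes() > 1 else 0
    return GraphSummary(
        density=density,
        n_components=len(components),
        largest_component_size=largest.number_of_nodes(),
        diameter=diameter,
        degree={v: int(d) for v, d in g.degree()},
        betweenness=nx.betweenness_centrality(g, normalized=False),
        closeness=nx.closeness_centrality(g),
    )


def graph_correlation(g1, g2, weighted: bool = False) -> float:
    """Pearson correlation of two graphs' adjacency matrices, as a
    percentage in [-100, 100].

    The vertex universe is the union of both symbol sets; matrices are
    binary (1 iff at least one edge) unless ``weighted``, in which case
    edge multiplicities are used. The correlation is computed over the
    strict upper triangle. Identical non-degenerate graphs give 100%.
    """
    s1, s2 = _as_simple(g1), _as_simple(g2)
    if s1.number_of_nodes() == 0 or s2.number_of_nodes() == 0:
        raise ValueError("both graphs must be non-empty")
    universe = sorted(set(s1.nodes) | set(s2.nodes))
    idx = {v: i for i, v in enumerate(universe)}
    n = len(universe)

    def vec(graph, simple):
        A = np.zeros((n, n))
        if weighted and hasattr(graph, "edge_multiset"):
            for (u, v), m in graph.edge_multiset().items():
                if u != v:
                    A[idx[u], idx[v]] = A[idx[v], idx[u]] = m
        else:
            for u, v in simple.edges():
                A[idx[u], idx[v]] = A[idx[v], idx[u]] = 1
        iu, ju = np.triu_indices(n, k=1)
        return A[iu, ju]

    x, y = vec(g1, s1), vec(g2, s2)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError(
            "correlation undefined: a graph is edgeless or complete on the "
            "aligned vertex universe")
    r = np.corrcoef(x, y)[0, 1]
    return float(100.0 * r)
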