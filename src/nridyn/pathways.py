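"""Allosteric-pathway extraction over the learned interaction graph.

Strong learned edges become low-cost links (default cost -log w, so a
path's cost is the negative log of the product of its edge weights — the
most "probable" chain of interactions is the shortest path).  Shortest and
k-shortest loopless paths from source residues (the allosteric site) to
sink residues (the active site), per-residue path frequencies, and
betweenness centralities summarize which residues mediate the communication.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import islice

import networkx as nx
import numpy as np
import pandas as pd

from .graph import InteractionMatrix, symmetrize

__all__ = [
    "PathGraph",
    "Path",
    "PathSet",
    "build_path_graph",
    "shortest_paths",
    "path_residue_frequency",
    "node_centrality",
]


@dataclass
class PathGraph:
    """Directed cost graph derived from an interaction matrix."""

    graph: nx.DiGraph
    retain_threshold: float
    cost_transform: str

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class Path:
    nodes: tuple[int, ...]
    cost: float


@dataclass
class PathSet:
    """k lowest-cost loopless paths per source-sink pair."""

    paths: list[Path]
    sources: tuple[int, ...]
    sinks: tuple[int, ...]
    k: int
    by_pair: dict[tuple[int, int], list[Path]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "sources": list(self.sources),
            "sinks": list(self.sinks),
            "k": self.k,
            "paths": [{"nodes": list(p.nodes), "cost": p.cost} for p in self.paths],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_path_graph(m: InteractionMatrix, retain_threshold: float = 0.5,
                     cost_transform: str = "neg_log",
                     directed: bool = True) -> PathGraph:
    """Retain edges with weight >= threshold and assign traversal costs.

    cost_transform: ``neg_log`` (cost = -log w; default) or ``reciprocal``
    (cost = 1/w).  Stronger edges always cost less.  In undirected mode the
    matrix is symmetrized by max(w_ij, w_ji) first.
    """
    if not 0.0 < retain_threshold < 1.0:
        raise ValueError("retain_threshold must be in (0, 1)")
    if cost_transform == "neg_log":
        transform = lambda w: -np.log(w)
    elif cost_transform == "reciprocal":
        transform = lambda w: 1.0 / w
    else:
        raise ValueError(f"unknown cost transform: {cost_transform!r}")

    if not directed:
        m = symmetrize(m, "max")
    g = nx.DiGraph()
    g.add_nodes_from(range(m.n_nodes))
    kept = 0
    for i in range(m.n_nodes):
        for j in range(m.n_nodes):
            if i == j:
                continue
            w = m.w[i, j]
            if w >= retain_threshold:
                cost = float(transform(w))
                # w = 1 maps to cost 0 under neg_log; keep a tiny positive
                # floor so Dijkstra's positivity assumption holds
                g.add_edge(i, j, weight=w, cost=max(cost, 0.0))
                kept += 1
    if kept == 0:
        warnings.warn(
            f"retain_threshold={retain_threshold} filtered out every edge",
            stacklevel=2,
        )
    return PathGraph(g, retain_threshold, cost_transform)


def _path_cost(g: nx.DiGraph, nodes) -> float:
    return float(sum(g[u][v]["cost"] for u, v in zip(nodes[:-1], nodes[1:])))


def shortest_paths(g: PathGraph, sources, sinks, k: int = 1) -> PathSet:
    """k lowest-cost loopless paths for every source-sink pair.

    Pairs with no path yield an empty entry.  Equal-cost paths are ordered
    lexicographically by node sequence for reproducibility.
    """
    sources = tuple(sources)
    sinks = tuple(sinks)
    if not sources or not sinks:
        raise ValueError("sources and sinks must be non-empty")
    if set(sources) & set(sinks):
        raise ValueError("sources and sinks must be disjoint")
    for node in (*sources, *sinks):
        if node not in g.graph:
            raise ValueError(f"unknown node in sources/sinks: {node}")
    if k < 1:
        raise ValueError("k must be >= 1")

    by_pair: dict[tuple[int, int], list[Path]] = {}
    all_paths: list[Path] = []
    for s in sources:
        for t in sinks:
            try:
                candidates = list(islice(
                    nx.shortest_simple_paths(g.graph, s, t, weight="cost"), k
                ))
            except nx.NetworkXNoPath:
                by_pair[(s, t)] = []
                continue
            paths = sorted(
                (Path(tuple(nodes), _path_cost(g.graph, nodes)) for nodes in candidates),
                key=lambda p: (p.cost, p.nodes),
            )
            by_pair[(s, t)] = paths
            all_paths.extend(paths)
    return PathSet(all_paths, sources, sinks, k, by_pair)


def path_residue_frequency(ps: PathSet, n_nodes: int | None = None,
                           include_endpoints: bool = True) -> pd.Series:
    """Number of paths each node appears on (endpoints counted by default)."""
    if not ps.paths:
        raise ValueError("path set is empty")
    size = n_nodes or (max(max(p.nodes) for p in ps.paths) + 1)
    counts = np.zeros(size, dtype=int)
    for p in ps.paths:
        nodes = p.nodes if include_endpoints else p.nodes[1:-1]
        for node in set(nodes):
            counts[node] += 1
    return pd.Series(counts, name="path_frequency")


def node_centrality(g: PathGraph) -> pd.Series:
    """Betweenness centrality on the cost-weighted directed graph,
    normalized to [0, 1]: the fraction of all-pairs shortest paths passing
    through each node."""
    if g.graph.number_of_edges() == 0:
        raise ValueError("path graph has no edges")
    centrality = nx.betweenness_centrality(g.graph, weight="cost", normalized=True)
    return pd.Series([centrality[n] for n in sorted(g.graph.nodes)],
                     name="betweenness")
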