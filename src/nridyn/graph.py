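"""Residue-level and domain-level interaction maps from edge posteriors.

The learned posterior over K edge types per ordered residue pair collapses
to one scalar weight per pair.  The default rule, ``prob_any_edge``, uses
w_ij = 1 - P(nonedge): additive over the non-null types, conservation
compatible, and bounded in [0, 1].  Directionality is preserved (w_ij and
w_ji are independent); an explicit symmetrization is available for
undirected analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import EdgePosterior, pair_indices

__all__ = [
    "InteractionMatrix",
    "DomainMap",
    "BlockMatrix",
    "edge_weight_matrix",
    "aggregate_blocks",
    "node_weights",
    "symmetrize",
]


@dataclass
class InteractionMatrix:
    """Scalar learned-edge weight per ordered pair (zero diagonal)."""

    w: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("interaction matrix must be square")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("interaction matrix must have a zero diagonal")

    @property
    def n_nodes(self) -> int:
        return self.w.shape[0]

    def total(self) -> float:
        return float(self.w.sum())

    def to_edge_list(self) -> pd.DataFrame:
        i, j = np.nonzero(~np.eye(self.n_nodes, dtype=bool))
        return pd.DataFrame({"i": i, "j": j, "weight": self.w[i, j]})

    def to_tsv(self, path) -> None:
        self.to_edge_list().to_csv(path, sep="\t", index=False)


@dataclass
class DomainMap:
    """node -> block assignment (e.g. WW, catalytic loop, helices, core)."""

    assignment: dict[int, str]

    def __post_init__(self):
        if not self.assignment:
            raise ValueError("domain map must assign at least one node")

    @property
    def blocks(self) -> list[str]:
        seen: dict[str, None] = {}
        for block in self.assignment.values():
            seen.setdefault(block)
        return list(seen)

    def block_members(self) -> dict[str, list[int]]:
        members: dict[str, list[int]] = {b: [] for b in self.blocks}
        for node, block in self.assignment.items():
            members[block].append(node)
        return members

    @classmethod
    def from_tsv(cls, path) -> "DomainMap":
        table = pd.read_csv(path, sep="\t")
        return cls({int(r.node): str(r.block) for r in table.itertuples()})

    def to_tsv(self, path) -> None:
        rows = [{"node": n, "block": b} for n, b in sorted(self.assignment.items())]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


@dataclass
class BlockMatrix:
    """Aggregated weight per ordered block pair (within-block included)."""

    w: np.ndarray
    blocks: list[str]
    block_sizes: dict[str, int] = field(default_factory=dict)

    def total(self) -> float:
        return float(self.w.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.w, index=self.blocks, columns=self.blocks)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="block")


def edge_weight_matrix(q: EdgePosterior, rule: str = "prob_any_edge") -> InteractionMatrix:
    """Collapse the K-type posterior to a directed scalar weight per pair.

    Rules: ``prob_any_edge`` (1 - P(nonedge), the default), ``max_type``
    (largest non-null type probability), or ``per_type:k`` (probability of
    one specific non-null type k >= 2, 1-based as in the type numbering).
    """
    probs = q.mean().probs
    n = q.n_nodes
    senders, receivers = pair_indices(n)
    if rule == "prob_any_edge":
        values = 1.0 - probs[:, 0]
    elif rule == "max_type":
        values = probs[:, 1:].max(axis=1)
    elif rule.startswith("per_type:"):
        k = int(rule.split(":", 1)[1])
        if not 2 <= k <= probs.shape[1]:
            raise ValueError(f"per_type index must be in [2, {probs.shape[1]}]")
        values = probs[:, k - 1]
    else:
        raise ValueError(f"unknown edge-weight rule: {rule!r}")
    w = np.zeros((n, n))
    w[senders, receivers] = values
    return InteractionMatrix(w, provenance=rule)


def symmetrize(m: InteractionMatrix, how: str = "max") -> InteractionMatrix:
    """Undirected view: w_ij = max (or mean) of the two directions."""
    if how == "max":
        w = np.maximum(m.w, m.w.T)
    elif how == "mean":
        w = 0.5 * (m.w + m.w.T)
    else:
        raise ValueError(f"unknown symmetrization: {how!r}")
    return InteractionMatrix(w, provenance=f"{m.provenance}|sym:{how}")


def aggregate_blocks(m: InteractionMatrix, dm: DomainMap,
                     how: str = "sum") -> BlockMatrix:
    """Aggregate pair weights onto ordered block pairs.

    ``sum`` (default) conserves total weight; ``mean`` divides by the number
    of member ordered pairs.
    """
    missing = [n for n in range(m.n_nodes) if n not in dm.assignment]
    if missing:
        raise ValueError(f"nodes missing from domain map: {missing}")
    blocks = dm.blocks
    index = {b: i for i, b in enumerate(blocks)}
    labels = np.array([index[dm.assignment[n]] for n in range(m.n_nodes)])
    nb = len(blocks)
    w = np.zeros((nb, nb))
    counts = np.zeros((nb, nb))
    off_diag = ~np.eye(m.n_nodes, dtype=bool)
    np.add.at(w, (labels[:, None].repeat(m.n_nodes, 1)[off_diag],
                  labels[None, :].repeat(m.n_nodes, 0)[off_diag]),
              m.w[off_diag])
    np.add.at(counts, (labels[:, None].repeat(m.n_nodes, 1)[off_diag],
                       labels[None, :].repeat(m.n_nodes, 0)[off_diag]), 1.0)
    if how == "mean":
        w = np.divide(w, counts, out=np.zeros_like(w), where=counts > 0)
    elif how != "sum":
        raise ValueError(f"unknown aggregation: {how!r}")
    sizes = {b: len(v) for b, v in dm.block_members().items()}
    return BlockMatrix(w, blocks, sizes)


def to_graphml(m: InteractionMatrix, path, threshold: float = 0.0) -> None:
    """Export the directed weighted graph for external viewers."""
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(range(m.n_nodes))
    for i in range(m.n_nodes):
        for j in range(m.n_nodes):
            if i != j and m.w[i, j] > threshold:
                g.add_edge(i, j, weight=float(m.w[i, j]))
    nx.write_graphml(g, path)


def node_weights(m: InteractionMatrix, threshold: float = 0.5) -> pd.DataFrame:
    """Per-node degree (incident edges with weight >= threshold, in + out)
    and summed incident weight."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    strong = m.w >= threshold
    np.fill_diagonal(strong, False)
    degree = strong.sum(axis=0) + strong.sum(axis=1)
    weight = m.w.sum(axis=0) + m.w.sum(axis=1)
    return pd.DataFrame({"node": np.arange(m.n_nodes),
                         "degree": degree, "weight": weight})
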