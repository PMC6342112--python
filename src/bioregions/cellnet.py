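"""Spatial projection of the bipartite network into a cell-cell similarity graph.

The bipartite incidence is collapsed onto its spatial side: every unordered
pair of grid cells is weighted by the compositional similarity of their
species sets (Jaccard by default), giving a weighted undirected network whose
weights range from 0 (no species in common; pair omitted) to 1 (identical
composition).  The same container also serves the species-species similarity
graph built later from test-value profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse

from .errors import ParameterError
from .gridding import BipartiteIncidence

__all__ = [
    "SimilarityNetwork",
    "pairwise_similarity",
    "project_bipartite",
    "sparsify",
]


@dataclass
class SimilarityNetwork:
    """Weighted undirected graph stored as an (i < j) edge list.

    ``nodes`` holds node labels (grid-cell ids or species names); ``edges``
    holds index pairs into ``nodes``.  Symmetric by construction, no
    self-loops, zero-weight pairs omitted.
    """

    nodes: np.ndarray
    edges: np.ndarray  # shape (m, 2), int indices, edges[:, 0] < edges[:, 1]
    weights: np.ndarray  # shape (m,), in (0, 1]
    index_name: str = "jaccard"

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float).reshape(-1)
        if len(self.edges) != len(self.weights):
            raise ValueError("edges and weights length mismatch")
        if len(self.edges):
            lo = np.minimum(self.edges[:, 0], self.edges[:, 1])
            hi = np.maximum(self.edges[:, 0], self.edges[:, 1])
            if (lo == hi).any():
                raise ValueError("self-loops are not allowed")
            order = np.lexsort((hi, lo))
            self.edges = np.column_stack([lo, hi])[order]
            self.weights = self.weights[order]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self) -> sparse.csr_matrix:
        """Symmetric sparse weight matrix."""
        n = self.n_nodes
        i, j = self.edges[:, 0], self.edges[:, 1]
        return sparse.csr_matrix(
            (
                np.concatenate([self.weights, self.weights]),
                (np.concatenate([i, j]), np.concatenate([j, i])),
            ),
            shape=(n, n),
        )

    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(d, self.edges[:, 0], 1)
        np.add.at(d, self.edges[:, 1], 1)
        return d

    def strengths(self) -> np.ndarray:
        s = np.zeros(self.n_nodes)
        np.add.at(s, self.edges[:, 0], self.weights)
        np.add.at(s, self.edges[:, 1], self.weights)
        return s

    def node_index(self) -> dict:
        return {label: i for i, label in enumerate(self.nodes.tolist())}

    def edge_weight(self, a, b) -> float:
        """Weight between two node labels; 0.0 when the pair has no edge."""
        idx = self.node_index()
        i, j = idx[a], idx[b]
        if i > j:
            i, j = j, i
        hit = (self.edges[:, 0] == i) & (self.edges[:, 1] == j)
        return float(self.weights[hit][0]) if hit.any() else 0.0

    # -- interop -------------------------------------------------------------

    def to_igraph(self):
        import igraph

        g = igraph.Graph(
            n=self.n_nodes,
            edges=[(int(a), int(b)) for a, b in self.edges],
            edge_attrs={"weight": self.weights.tolist()},
        )
        g.vs["name"] = [str(v) for v in self.nodes.tolist()]
        return g

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        labels = self.nodes.tolist()
        g.add_nodes_from(labels)
        g.add_weighted_edges_from(
            (labels[int(a)], labels[int(b)], float(w))
            for (a, b), w in zip(self.edges, self.weights)
        )
        return g

    def write_edgelist(self, path: str | Path) -> None:
        labels = self.nodes
        pd.DataFrame(
            {
                "node_a": labels[self.edges[:, 0]],
                "node_b": labels[self.edges[:, 1]],
                "weight": self.weights,
            }
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def read_edgelist(cls, path: str | Path, index_name: str = "jaccard") -> "SimilarityNetwork":
        df = pd.read_csv(path, sep="\t")
        labels = np.unique(np.concatenate([df["node_a"].to_numpy(), df["node_b"].to_numpy()]))
        idx = {v: i for i, v in enumerate(labels.tolist())}
        edges = np.column_stack(
            [
                [idx[v] for v in df["node_a"]],
                [idx[v] for v in df["node_b"]],
            ]
        )
        return cls(nodes=labels, edges=edges, weights=df["weight"].to_numpy(), index_name=index_name)

    def write_graphml(self, path: str | Path) -> None:
        import networkx as nx

        nx.write_graphml(self.to_networkx(), path)


def pairwise_similarity(set_a: set, set_b: set, index: str = "jaccard") -> float:
    """Compositional similarity between two species sets.

    ``jaccard`` is |A∩B| / |A∪B|; ``simpson`` is |A∩B| / min(|A|, |B|), a
    turnover-oriented alternative less sensitive to richness differences.
    """
    if not set_a or not set_b:
        raise ParameterError("similarity is undefined for an empty species set")
    inter = len(set_a & set_b)
    if index == "jaccard":
        return inter / len(set_a | set_b)
    if index == "simpson":
        return inter / min(len(set_a), len(set_b))
    raise ParameterError(f"unknown similarity index {index!r}")


def _keep_mask(w: np.ndarray, min_weight: float) -> np.ndarray:
    # Inclusive lower bound, but exact zeros are always dropped so that
    # "no species in common" never yields an edge.
    return (w >= min_weight) & (w > 0)


def project_bipartite(
    incidence: BipartiteIncidence,
    index: str = "jaccard",
    min_weight: float = 0.0,
) -> SimilarityNetwork:
    """Project the incidence onto its cell side.

    Intersections are counted through one sparse product of the incidence
    with its transpose — the dense cell × cell matrix is never materialized.
    Pairs with zero shared species carry no edge; ``min_weight`` optionally
    discards weak edges (default keeps every positive one).
    """
    if incidence.n == 0:
        raise ValueError("incidence is empty")
    if min_weight < 0:
        raise ParameterError("min_weight must be >= 0")
    X = incidence.presence.astype(np.int64).tocsr()
    inter = sparse.triu(X @ X.T, k=1).tocoo()
    sizes = incidence.richness
    a, b, shared = inter.row, inter.col, inter.data.astype(float)
    if index == "jaccard":
        w = shared / (sizes[a] + sizes[b] - shared)
    elif index == "simpson":
        w = shared / np.minimum(sizes[a], sizes[b])
    else:
        raise ParameterError(f"unknown similarity index {index!r}")
    keep = _keep_mask(w, min_weight)
    return SimilarityNetwork(
        nodes=incidence.cell_ids.copy(),
        edges=np.column_stack([a[keep], b[keep]]),
        weights=w[keep],
        index_name=index,
    )


def sparsify(network: SimilarityNetwork, top_k: int) -> SimilarityNetwork:
    """Keep the union of each node's ``top_k`` strongest edges.

    Rank ties at the cut are broken in favor of the lower opposite node id,
    so the result is deterministic.  The union construction keeps the result
    symmetric and tends to preserve connectivity.
    """
    if top_k < 1:
        raise ParameterError("top_k must be >= 1")
    m = network.n_edges
    if m == 0:
        return network
    # duplicate each edge from both endpoints' perspective
    owner = np.concatenate([network.edges[:, 0], network.edges[:, 1]])
    other = np.concatenate([network.edges[:, 1], network.edges[:, 0]])
    eidx = np.concatenate([np.arange(m), np.arange(m)])
    w = np.concatenate([network.weights, network.weights])
    order = np.lexsort((other, -w, owner))  # by owner, then weight desc, then other asc
    owner_s, eidx_s = owner[order], eidx[order]
    rank = np.zeros(len(owner_s), dtype=np.int64)
    # per-owner rank via grouped cumulative count
    starts = np.flatnonzero(np.r_[True, owner_s[1:] != owner_s[:-1]])
    for s, e in zip(starts, np.r_[starts[1:], len(owner_s)]):
        rank[s:e] = np.arange(e - s)
    keep_edges = np.unique(eidx_s[rank < top_k])
    return SimilarityNetwork(
        nodes=network.nodes.copy(),
        edges=network.edges[keep_edges],
        weights=network.weights[keep_edges],
        index_name=network.index_name,
    )
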