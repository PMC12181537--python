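"""Binary network construction and nodal graph metrics.

Connectivity matrices are thresholded at a fixed sparsity (fraction of
possible edges retained, negatives discarded first) into binary undirected
networks, on which four nodal metrics are computed: betweenness centrality,
degree, nodal efficiency and the clustering coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

__all__ = [
    "BinaryNetwork",
    "NodalMetrics",
    "binarize_sparsity",
    "nodal_betweenness",
    "nodal_degree",
    "nodal_efficiency",
    "nodal_clustering",
    "compute_nodal_metrics",
]


@dataclass
class BinaryNetwork:
    """Binary undirected network obtained by sparsity thresholding."""

    adjacency: np.ndarray  # R x R 0/1 symmetric, zero diagonal
    sparsity: float
    source_kind: str  # "fc" | "sc" | "sl"

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.adjacency = a.astype(np.int8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency)


@dataclass
class NodalMetrics:
    """Per-node metric vectors (all finite and nonnegative)."""

    betweenness: np.ndarray  # normalized fraction
    degree: np.ndarray  # counts
    efficiency: np.ndarray  # in [0, 1]
    clustering: np.ndarray  # in [0, 1]

    def as_array(self) -> np.ndarray:
        """R x 4 array in (betweenness, degree, efficiency, clustering) order."""
        return np.column_stack(
            [self.betweenness, self.degree, self.efficiency, self.clustering]
        )


def binarize_sparsity(matrix: ConnectivityMatrix, sparsity: float) -> BinaryNetwork:
    """Threshold to a binary undirected network of fixed edge density.

    Negative entries are discarded, then the K = round(sparsity * R(R-1)/2)
    largest positive upper-triangle entries become edges.  Ties at the cut
    are resolved deterministically in favour of the smaller (row, column)
    lexicographic index.
    """
    if not 0 < sparsity < 1:
        raise ValueError("sparsity must lie in (0, 1)")
    v = matrix.values.copy()
    R = v.shape[0]
    m = R * (R - 1) // 2
    K = int(np.floor(sparsity * m + 0.5))
    iu, ju = np.triu_indices(R, k=1)
    w = v[iu, ju]
    w[w < 0] = 0.0
    positive = w > 0
    if positive.sum() < K:
        achievable = positive.sum() / m
        raise ValueError(
            f"only {int(positive.sum())} positive entries; "
            f"requested sparsity {sparsity} needs {K} edges "
            f"(achievable sparsity {achievable:.4f})"
        )
    # Stable sort on (-weight, row, col): lexsort keys read last-first.
    order = np.lexsort((ju, iu, -w))[:K]
    adj = np.zeros((R, R), dtype=np.int8)
    adj[iu[order], ju[order]] = 1
    adj |= adj.T
    return BinaryNetwork(adjacency=adj, sparsity=sparsity, source_kind=matrix.kind)


def nodal_betweenness(net: BinaryNetwork) -> np.ndarray:
    """Normalized betweenness centrality: the fraction of shortest paths
    between other node pairs passing through each node, scaled by
    2/((R-1)(R-2)) for undirected graphs.  Disconnected pairs contribute 0."""
    bc = nx.betweenness_centrality(net.to_networkx(), normalized=True)
    return np.array([bc[i] for i in range(net.n_nodes)])


def nodal_degree(net: BinaryNetwork) -> np.ndarray:
    """Edge counts per node (adjacency row sums)."""
    return net.adjacency.sum(axis=1).astype(float)


def nodal_efficiency(net: BinaryNetwork) -> np.ndarray:
    """Inverse harmonic mean of shortest path lengths from each node:
    eff(v) = (1/(R-1)) * sum_{u != v} 1/d(v, u), with 1/inf = 0."""
    g = net.to_networkx()
    R = net.n_nodes
    eff = np.zeros(R)
    for v in range(R):
        dists = nx.single_source_shortest_path_length(g, v)
        eff[v] = sum(1.0 / d for u, d in dists.items() if u != v) / (R - 1)
    return eff


def nodal_clustering(net: BinaryNetwork) -> np.ndarray:
    """Fraction of a node's neighbour pairs that are themselves connected;
    0 for degree < 2."""
    cc = nx.clustering(net.to_networkx())
    return np.array([cc[i] for i in range(net.n_nodes)])


def compute_nodal_metrics(net: BinaryNetwork) -> NodalMetrics:
    """All four nodal metrics of a binary network."""
    return NodalMetrics(
        betweenness=nodal_betweenness(net),
        degree=nodal_degree(net),
        efficiency=nodal_efficiency(net),
        clustering=nodal_clustering(net),
    )
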