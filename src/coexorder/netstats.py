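"""Topology statistics of thresholded module networks.

A weighted gene-gene matrix restricted to a module is thresholded into an
undirected unweighted graph (edge kept iff weight strictly above the
threshold; weights retained as edge attributes only), and the statistics a
network-analysis viewer reports are computed on that graph: node/edge
counts, mean and max degree, average number of neighbors (identical to mean
degree by definition), characteristic path length over connected pairs,
degree heterogeneity (coefficient of variation), and maximum normalized
betweenness centrality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["TopologyStats", "threshold_network", "topology_stats"]


@dataclass(frozen=True)
class TopologyStats:
    n_nodes: int
    n_edges: int
    avg_neighbors: float
    char_path_length: float
    heterogeneity: float
    mean_degree: float
    max_degree: int
    max_betweenness: float

    def as_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_neighbors": self.avg_neighbors,
            "char_path_length": self.char_path_length,
            "heterogeneity": self.heterogeneity,
            "mean_degree": self.mean_degree,
            "max_degree": self.max_degree,
            "max_betweenness": self.max_betweenness,
        }


def threshold_network(weights: pd.DataFrame, threshold: float = 0.2) -> nx.Graph:
    """Build the undirected graph of pairs with weight > threshold (strict).

    Isolated nodes are retained; self-loops never created. The input must be
    a symmetric matrix with values in [0, 1].
    """
    if not (0 <= threshold < 1):
        raise ValueError("threshold must lie in [0, 1)")
    nodes = list(weights.index)
    W = weights.to_numpy(dtype=float)
    if W.shape[0] != W.shape[1] or list(weights.columns) != nodes:
        raise ValueError("weight matrix must be square with matching ids")
    if not np.allclose(W, W.T, atol=1e-8):
        raise ValueError("weight matrix must be symmetric")
    offdiag = W[~np.eye(len(nodes), dtype=bool)]
    if len(offdiag) and (offdiag.min() < 0 or offdiag.max() > 1 + 1e-12):
        raise ValueError("weights must lie in [0, 1]")
    g = nx.Graph(threshold=threshold)
    g.add_nodes_from(nodes)
    iu, ju = np.triu_indices(len(nodes), k=1)
    keep = W[iu, ju] > threshold
    g.add_weighted_edges_from(
        (nodes[i], nodes[j], float(W[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    )
    return g


def topology_stats(g: nx.Graph) -> TopologyStats:
    """Compute the eight summary statistics of a thresholded graph.

    Characteristic path length averages unweighted shortest-path distances
    over all connected ordered pairs (disconnected pairs are ignored, keeping
    the statistic finite); heterogeneity is std(degree)/mean(degree) with
    population variance; betweenness uses the standard undirected
    normalization, and its maximum over nodes is reported.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("need at least 2 nodes")
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    mean_deg = float(degrees.mean())
    n_edges = g.number_of_edges()

    # characteristic path length over connected pairs
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            for d in dists.values():
                if d > 0:
                    total += d
                    pairs += 1
    if pairs == 0:
        logger.warning("graph has no connected pairs; path length undefined")
        cpl = float("nan")
    else:
        cpl = total / pairs

    heterogeneity = (
        float(np.sqrt(degrees.var()) / mean_deg) if mean_deg > 0 else float("nan")
    )
    btw = nx.betweenness_centrality(g, normalized=True)
    return TopologyStats(
        n_nodes=n,
        n_edges=n_edges,
        avg_neighbors=mean_deg,
        char_path_length=cpl,
        heterogeneity=heterogeneity,
        mean_degree=mean_deg,
        max_degree=int(degrees.max()),
        max_betweenness=float(max(btw.values())),
    )
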