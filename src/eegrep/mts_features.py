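"""Multivariate representations: global field power, Pearson functional
brain networks, and graph-theoretic summaries.

* GFP    — global field power: the (population) standard deviation of the
           signal across electrodes at each time point; length T (60).
* FBN    — the Pearson correlation-distance matrix d_ij = 1 - p_ij between
           channel pairs, strict upper triangle flattened; length
           C*(C-1)/2 (2016 at 64 channels).
* FBN-GT — the distance matrix is min-max normalized over its off-diagonal
           entries and thresholded at 0.1 (keeping the strongest
           correlations as edges); the binary graph is summarized by three
           global metrics (degree assortativity, average shortest path
           length, edge connectivity) and three per-vertex metrics (degree,
           betweenness, eccentricity); length 3 + 3C (195 at 64 channels).
"""

from __future__ import annotations

import logging
import warnings

import networkx as nx
import numpy as np

from .data_model import Epoch

__all__ = [
    "gfp",
    "pearson_distance",
    "fbn_vector",
    "distance_from_upper",
    "threshold_graph",
    "graph_metric_vector",
    "graph_to_edge_csv",
    "FBN_GT_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Threshold on the min-max normalized distance below which an edge is kept.
FBN_GT_THRESHOLD: float = 0.1


def _as_matrix(epoch: Epoch | np.ndarray) -> np.ndarray:
    values = epoch.values if isinstance(epoch, Epoch) else np.asarray(epoch, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"expected channels x time matrix, got shape {values.shape}")
    return values


def gfp(epoch: Epoch | np.ndarray) -> np.ndarray:
    """Global field power: per-time-point population SD across channels."""
    values = _as_matrix(epoch)
    if values.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    return np.std(values, axis=0, ddof=0)


def pearson_distance(epoch: Epoch | np.ndarray) -> np.ndarray:
    """Correlation-distance matrix d_ij = 1 - Pearson(x_i, x_j).

    Entries lie in [0, 2] with a zero diagonal.  A zero-variance channel has
    undefined correlations; these are set to 0 (distance 1) with a warning.
    """
    values = _as_matrix(epoch)
    variances = np.var(values, axis=1)
    degenerate = variances == 0.0
    if degenerate.any():
        logger.warning(
            "zero-variance channels %s: correlations set to 0 (distance 1)",
            np.flatnonzero(degenerate).tolist(),
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = np.corrcoef(values)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    return np.clip((dist + dist.T) / 2.0, 0.0, 2.0)


def fbn_vector(dist: np.ndarray) -> np.ndarray:
    """Strict upper triangle of the distance matrix, row-major."""
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {d.shape}")
    return d[np.triu_indices(d.shape[0], k=1)]


def distance_from_upper(upper: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`fbn_vector`: rebuild the symmetric zero-diagonal matrix."""
    out = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    out[iu] = upper
    out.T[iu] = upper
    return out


def threshold_graph(dist: np.ndarray, threshold: float = FBN_GT_THRESHOLD) -> nx.Graph:
    """Binary graph from a distance matrix.

    Off-diagonal distances are min-max normalized to [0, 1]; the edge (i, j)
    is present iff the normalized distance is <= ``threshold`` — small
    distance means strong correlation, so the strongest connections are
    kept.  An all-equal off-diagonal matrix is rejected (the normalization
    is undefined).
    """
    d = np.asarray(dist, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {d.shape}")
    n = d.shape[0]
    iu = np.triu_indices(n, k=1)
    values = d[iu]
    lo, hi = values.min(), values.max()
    if hi == lo:
        raise ValueError("all off-diagonal distances equal: normalization undefined")
    normalized = (values - lo) / (hi - lo)
    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    for (i, j, v) in zip(iu[0], iu[1], normalized):
        if v <= threshold:
            graph.add_edge(int(i), int(j))
    return graph


def _assortativity(graph: nx.Graph) -> float:
    # Undefined (NaN) for regular graphs or graphs with < 2 edges: use 0.
    if graph.number_of_edges() < 2:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        value = nx.degree_assortativity_coefficient(graph)
    return 0.0 if not np.isfinite(value) else float(value)


def _average_path_length(graph: nx.Graph) -> float:
    # Disconnected graphs: average the per-component averages over components
    # with at least two vertices; 0 if there is none.
    parts = [
        graph.subgraph(comp)
        for comp in nx.connected_components(graph)
        if len(comp) >= 2
    ]
    if not parts:
        return 0.0
    return float(np.mean([nx.average_shortest_path_length(g) for g in parts]))


def _eccentricities(graph: nx.Graph) -> np.ndarray:
    # Within-component eccentricity; isolated vertices get 0.
    out = np.zeros(graph.number_of_nodes())
    for comp in nx.connected_components(graph):
        sub = graph.subgraph(comp)
        for node, ecc in nx.eccentricity(sub).items():
            out[node] = ecc
    return out


def graph_metric_vector(graph: nx.Graph) -> np.ndarray:
    """Graph-theory summary: [assortativity, average path length, edge
    connectivity] followed by per-vertex [degrees, betweenness,
    eccentricities]; length 3 + 3C.

    Betweenness is the unnormalized shortest-path count.  Conventions for
    degenerate graphs: assortativity of a regular graph is 0, path length
    and eccentricity are within-component, edge connectivity of a
    disconnected graph is 0.
    """
    n = graph.number_of_nodes()
    if n < 1:
        raise ValueError("graph must have at least one vertex")
    assortativity = _assortativity(graph)
    apl = _average_path_length(graph)
    if n >= 2:
        connectivity = float(nx.edge_connectivity(graph)) if nx.is_connected(graph) else 0.0
    else:
        connectivity = 0.0
    degrees = np.array([graph.degree(v) for v in range(n)], dtype=float)
    betweenness_map = nx.betweenness_centrality(graph, normalized=False)
    betweenness = np.array([betweenness_map[v] for v in range(n)])
    eccentricity = _eccentricities(graph)
    return np.concatenate([[assortativity, apl, connectivity], degrees, betweenness, eccentricity])


def graph_to_edge_csv(graph: nx.Graph, path) -> None:
    """Serialize a binary graph as a two-column edge-list CSV."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("source,target\n")
        for i, j in sorted(graph.edges()):
            fh.write(f"{i},{j}\n")
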