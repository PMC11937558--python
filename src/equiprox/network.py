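"""Median-threshold social networks and centrality metrics.

The network for one condition is built from the mean dyadic distance matrix:
the threshold is the median of the upper-triangle entries (each dyad counted
once) and an edge exists iff the mean distance is *strictly below* it, so
entries tied at the median produce no edge and an all-equal matrix yields an
empty graph.

Centrality conventions (chosen to be internally consistent with the
published per-animal values): degree is the raw count of direct ties;
betweenness is unnormalized shortest-path betweenness on the unweighted
graph with each unordered pair counted once and fractional credit split
among equally short paths; closeness is the unnormalized reciprocal farness
1 / Σ(shortest path lengths) restricted to the reachable component — a hub
adjacent to all five others in a six-node component scores 0.2, and an
isolated animal scores 0 on all three.
"""

from __future__ import annotations

from typing import Mapping
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .cleaning import DistanceSeries


def mean_distance_matrix(
    series_by_dyad: Mapping[tuple[str, str], DistanceSeries],
    animals: list[str],
) -> pd.DataFrame:
    """Symmetric matrix of arithmetic-mean retained distance per dyad (cm).

    Raises if a rostered dyad has zero retained samples — the network is
    undefined without a complete distance matrix.
    """
    animals = sorted(animals)
    if len(animals) < 3:
        raise ValueError("need at least 3 animals for a network")
    mat = pd.DataFrame(0.0, index=animals, columns=animals)
    for i, a in enumerate(animals):
        for b in animals[i + 1 :]:
            key = (a, b)
            ds = series_by_dyad.get(key)
            if ds is None or len(ds) == 0:
                raise ValueError(f"dyad {key} has no retained samples")
            m = float(np.mean(ds.d))
            mat.loc[a, b] = mat.loc[b, a] = m
    return mat


def binarize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Binary adjacency by the median threshold (strictly below ⇒ edge)."""
    vals = matrix.to_numpy()
    if not np.allclose(vals, vals.T):
        raise ValueError("distance matrix must be symmetric")
    iu = np.triu_indices(len(matrix), k=1)
    threshold = float(np.median(vals[iu]))
    adj = (vals < threshold).astype(int)
    np.fill_diagonal(adj, 0)
    if adj.sum() == 0:
        warnings.warn("all mean distances tie at the median; graph is empty", stacklevel=2)
    return pd.DataFrame(adj, index=matrix.index, columns=matrix.columns), threshold


def centralities(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Degree, betweenness and closeness per node (conventions above)."""
    adj = adjacency.to_numpy()
    if not np.array_equal(adj, adj.T) or not set(np.unique(adj)) <= {0, 1}:
        raise ValueError("adjacency must be binary and symmetric")
    g = nx.from_numpy_array(adj)
    g = nx.relabel_nodes(g, dict(enumerate(adjacency.index)))
    degree = {n: int(d) for n, d in g.degree()}
    betweenness = nx.betweenness_centrality(g, normalized=False)
    closeness = {}
    for node in g.nodes:
        lengths = nx.single_source_shortest_path_length(g, node)
        farness = sum(v for k, v in lengths.items() if k != node)
        closeness[node] = 1.0 / farness if farness > 0 else 0.0
    return pd.DataFrame(
        {
            "degree": pd.Series(degree),
            "betweenness": pd.Series(betweenness),
            "closeness": pd.Series(closeness),
        }
    ).loc[adjacency.index]


def build_network(
    series_by_dyad: Mapping[tuple[str, str], DistanceSeries],
    animals: list[str],
) -> dict:
    """Full network stage: mean matrix → threshold/adjacency → centralities."""
    mat = mean_distance_matrix(series_by_dyad, animals)
    adj, threshold = binarize(mat)
    cent = centralities(adj)
    return {
        "mean_distance_matrix": mat,
        "adjacency": adj,
        "threshold_cm": threshold,
        "centralities": cent,
    }


def export_graph(network: dict, graphml_path, edgelist_path=None) -> None:
    """GraphML (node attrs = centralities, edge attr = mean distance) plus an
    optional edge-list CSV. The exported edge weight is the mean dyadic
    distance; round-tripping the GraphML reproduces the adjacency."""
    adj = network["adjacency"]
    mat = network["mean_distance_matrix"]
    cent = network["centralities"]
    g = nx.Graph()
    for node in adj.index:
        g.add_node(
            node,
            degree=int(cent.loc[node, "degree"]),
            betweenness=float(cent.loc[node, "betweenness"]),
            closeness=float(cent.loc[node, "closeness"]),
        )
    rows = []
    nodes = list(adj.index)
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            if adj.loc[a, b]:
                w = float(mat.loc[a, b])
                g.add_edge(a, b, mean_distance_cm=w)
                rows.append({"animal_a": a, "animal_b": b, "mean_distance_cm": w})
    nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        pd.DataFrame(rows, columns=["animal_a", "animal_b", "mean_distance_cm"]).to_csv(
            edgelist_path, index=False
        )
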