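"""Median-threshold networks and centralities, checked against a
brute-force all-shortest-paths oracle."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from equiprox import binarize, centralities, export_graph, mean_distance_matrix
from equiprox.cleaning import DistanceSeries
from .conftest import series_df


def brute_force_centralities(adj: np.ndarray) -> pd.DataFrame:
    """Independent oracle: enumerate every shortest path by breadth-first
    expansion of all simple paths; no library shortest-path code."""
    n = len(adj)
    # all-pairs shortest path lengths by hand (BFS)
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and v not in seen:
                        seen.add(v)
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt

    def count_paths(s, t):
        """Enumerate all shortest s→t paths; return list of interior nodes."""
        if not np.isfinite(dist[s, t]) or s == t:
            return []
        paths = [[s]]
        for _ in range(int(dist[s, t])):
            paths = [
                p + [v]
                for p in paths
                for v in range(n)
                if adj[p[-1], v] and dist[s, v] == len(p)
            ]
        return [p for p in paths if p[-1] == t]

    betw = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = count_paths(s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                betw[v] += 1.0 / len(paths)
    close = np.zeros(n)
    for v in range(n):
        far = dist[v][np.isfinite(dist[v])].sum()
        close[v] = 1.0 / far if far > 0 else 0.0
    return pd.DataFrame(
        {"degree": adj.sum(axis=1).astype(int), "betweenness": betw, "closeness": close}
    )


def _check_against_oracle(adj: np.ndarray):
    names = [f"n{i}" for i in range(len(adj))]
    got = centralities(pd.DataFrame(adj, index=names, columns=names))
    want = brute_force_centralities(adj)
    assert got["degree"].tolist() == want["degree"].tolist()
    np.testing.assert_allclose(got["betweenness"].to_numpy(), want["betweenness"].to_numpy(), atol=1e-9)
    np.testing.assert_allclose(got["closeness"].to_numpy(), want["closeness"].to_numpy(), atol=1e-9)


class TestCentralityConventions:
    def test_path_graph(self):
        # A–B–C–D
        adj = np.array(
            [[0, 1, 0, 0], [1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0]]
        )
        names = list("ABCD")
        out = centralities(pd.DataFrame(adj, index=names, columns=names))
        assert out["degree"].tolist() == [1, 2, 2, 1]
        assert out["betweenness"].tolist() == [0.0, 2.0, 2.0, 0.0]
        assert out.loc["A", "closeness"] == pytest.approx(1 / 6)

    def test_hub_closeness_in_six_node_component(self):
        adj = np.zeros((6, 6), int)
        adj[0, 1:] = adj[1:, 0] = 1  # hub adjacent to all five others
        names = [f"n{i}" for i in range(6)]
        out = centralities(pd.DataFrame(adj, index=names, columns=names))
        assert out.loc["n0", "degree"] == 5
        assert out.loc["n0", "closeness"] == pytest.approx(0.2)

    def test_isolated_node_all_zero(self):
        adj = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        names = list("ABC")
        out = centralities(pd.DataFrame(adj, index=names, columns=names))
        assert out.loc["C"].tolist() == [0, 0.0, 0.0]


class TestOracleEquivalence:
    def test_exhaustive_up_to_five_nodes(self):
        for n in (3, 4, 5):
            pairs = list(itertools.combinations(range(n), 2))
            for bits in range(2 ** len(pairs)):
                adj = np.zeros((n, n), int)
                for k, (i, j) in enumerate(pairs):
                    if bits >> k & 1:
                        adj[i, j] = adj[j, i] = 1
                _check_against_oracle(adj)

    def test_sampled_six_node_graphs(self):
        rng = np.random.default_rng(11)
        pairs = list(itertools.combinations(range(6), 2))
        for _ in range(200):
            adj = np.zeros((6, 6), int)
            for i, j in pairs:
                if rng.random() < rng.uniform(0.15, 0.8):
                    adj[i, j] = adj[j, i] = 1
            _check_against_oracle(adj)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        adj = (rng.random((7, 7)) < 0.4).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        names = [f"n{i}" for i in range(7)]
        base = centralities(pd.DataFrame(adj, index=names, columns=names))
        perm = rng.permutation(7)
        padj = adj[np.ix_(perm, perm)]
        pnames = [names[i] for i in perm]
        permuted = centralities(pd.DataFrame(padj, index=pnames, columns=pnames))
        pd.testing.assert_frame_equal(base.loc[pnames], permuted)


class TestBinarize:
    def test_strictly_below_median_threshold(self):
        m = pd.DataFrame(
            [[0, 200, 400], [200, 0, 600], [400, 600, 0]],
            index=list("ABC"), columns=list("ABC"), dtype=float,
        )
        adj, thr = binarize(m)
        assert thr == 400.0
        assert adj.to_numpy().sum() == 2  # single undirected edge A–B
        assert adj.loc["A", "B"] == 1 and adj.loc["A", "C"] == 0

    def test_all_equal_gives_empty_graph(self):
        m = pd.DataFrame(500.0, index=list("ABC"), columns=list("ABC"))
        np.fill_diagonal(m.values, 0)
        with pytest.warns(UserWarning):
            adj, _ = binarize(m)
        assert adj.to_numpy().sum() == 0

    def test_edge_count_equals_below_median_count(self):
        rng = np.random.default_rng(8)
        vals = rng.uniform(100, 2000, size=(8, 8))
        m = np.triu(vals, 1)
        m = m + m.T
        mat = pd.DataFrame(m, index=[f"n{i}" for i in range(8)], columns=[f"n{i}" for i in range(8)])
        adj, thr = binarize(mat)
        iu = np.triu_indices(8, 1)
        assert adj.to_numpy()[iu].sum() == int((m[iu] < thr).sum())


class TestBuildAndExport:
    def test_mean_distance_matrix_and_roundtrip(self, tmp_path):
        spec = {
            ("A", "B"): [400.0, 600.0],
            ("A", "C"): [900.0, 1100.0],
            ("B", "C"): [1500.0, 1700.0],
        }
        series = {
            k: DistanceSeries(dyad=k, samples=series_df(v)) for k, v in spec.items()
        }
        mat = mean_distance_matrix(series, ["A", "B", "C"])
        assert mat.loc["A", "B"] == 500.0 and mat.loc["B", "A"] == 500.0
        adj, thr = binarize(mat)
        net = {
            "mean_distance_matrix": mat,
            "adjacency": adj,
            "threshold_cm": thr,
            "centralities": centralities(adj),
        }
        gpath = tmp_path / "net.graphml"
        export_graph(net, gpath, tmp_path / "edges.csv")
        g = nx.read_graphml(gpath)
        assert set(g.nodes) == {"A", "B", "C"}
        assert {tuple(sorted(e)) for e in g.edges} == {("A", "B")}

    def test_missing_dyad_rejected(self):
        series = {("A", "B"): DistanceSeries(dyad=("A", "B"), samples=series_df([500.0]))}
        with pytest.raises(ValueError):
            mean_distance_matrix(series, ["A", "B", "C"])
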