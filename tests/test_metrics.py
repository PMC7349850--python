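"""Graph metrics against closed forms, brute-force enumeration and networkx."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eegconnectome.connectivity import ConnectivityMatrix
from eegconnectome.errors import ConfigError
from eegconnectome.metrics import (
    betweenness,
    clustering,
    shortest_paths,
    strength,
    summarize,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (exhaustive enumeration, no shared code)
# ---------------------------------------------------------------------------


def brute_clustering(w):
    n = len(w)
    cc = np.zeros(n)
    eligible = []
    for i in range(n):
        nb = [j for j in range(n) if w[i, j] > 0]
        k = len(nb)
        if k >= 2:
            eligible.append(i)
            total = 0.0
            for j in nb:
                for h in nb:
                    if j != h:
                        total += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
            cc[i] = total / (k * (k - 1))
    graph = float(np.mean([cc[i] for i in eligible])) if eligible else 0.0
    return cc, graph


def _all_simple_paths(w, s, t):
    """Yield (length, path) for every simple path; sequential accumulation."""
    n = len(w)
    stack = [(s, [s], 0.0)]
    while stack:
        v, path, length = stack.pop()
        if v == t:
            yield length, path
            continue
        for u in range(n):
            if w[v, u] > 0 and u not in path:
                stack.append((u, path + [u], length + 1.0 / w[v, u]))


def brute_paths_and_betweenness(w):
    n = len(w)
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    counts = np.zeros((n, n))
    passage = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s == t:
                continue
            paths = list(_all_simple_paths(w, s, t))
            if not paths:
                continue
            d = min(length for length, _ in paths)
            minimal = [p for length, p in paths if length == d]
            dist[s, t] = d
            counts[s, t] = len(minimal)
            for p in minimal:
                for v in p[1:-1]:
                    passage[v] += 1.0 / len(minimal)
    bc = passage / ((n - 1) * (n - 2))
    return dist, counts, bc, float(bc.mean())


def random_weighted_graph(rng, n, density=1.0):
    w = rng.uniform(0.05, 1.0, size=(n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        w = w * mask
    w = np.triu(w, k=1)
    w = w + w.T
    return w


# ---------------------------------------------------------------------------
# closed-form examples
# ---------------------------------------------------------------------------


class TestStrength:
    def test_uniform_complete_graphs(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0.0)
        s, graph = strength(w)
        np.testing.assert_allclose(s, 1.0)
        assert graph == pytest.approx(1.0)
        w6 = np.full((6, 6), 0.3)
        np.fill_diagonal(w6, 0.0)
        s6, _ = strength(w6)
        np.testing.assert_allclose(s6, 5 * 0.3)

    def test_zero_matrix(self):
        s, graph = strength(np.zeros((4, 4)))
        assert graph == 0.0
        assert s.max() == 0.0

    def test_asymmetric_rejected(self):
        w = np.zeros((3, 3))
        w[0, 1] = 0.5
        with pytest.raises(ConfigError, match="symmetric"):
            strength(w)


class TestClustering:
    def test_uniform_complete_graph_equals_weight(self):
        w = np.full((5, 5), 0.5)
        np.fill_diagonal(w, 0.0)
        cc, graph = clustering(w)
        np.testing.assert_allclose(cc, 0.5, atol=1e-12)
        assert graph == pytest.approx(0.5)

    def test_open_triangle_is_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 1.0
        cc, _ = clustering(w)
        assert cc[0] == 0.0

    def test_weight_above_one_rejected(self):
        w = np.full((3, 3), 1.2)
        np.fill_diagonal(w, 0.0)
        with pytest.raises(ConfigError, match=r"\[0, 1\]"):
            clustering(w)


class TestShortestPaths:
    def test_three_node_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        dist, counts = shortest_paths(w)
        assert dist[0, 2] == 2.0
        assert counts[0, 2] == 1.0
        assert np.isinf(dist[0, 2]) is not True

    def test_complete_uniform_direct_edges(self):
        w = np.full((5, 5), 0.4)
        np.fill_diagonal(w, 0.0)
        dist, counts = shortest_paths(w)
        off = ~np.eye(5, dtype=bool)
        np.testing.assert_allclose(dist[off], 1 / 0.4)
        np.testing.assert_allclose(counts[off], 1.0)

    def test_disconnected_pair(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        dist, counts = shortest_paths(w)
        assert np.isinf(dist[0, 2])
        assert counts[0, 2] == 0.0


class TestBetweenness:
    def test_three_node_path_center(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        bc, graph = betweenness(w)
        np.testing.assert_allclose(bc, [0.0, 1.0, 0.0])
        assert graph == pytest.approx(1.0 / 3.0)

    def test_star_center(self):
        w = np.zeros((4, 4))
        for leaf in (1, 2, 3):
            w[0, leaf] = w[leaf, 0] = 0.7
        bc, _ = betweenness(w)
        assert bc[0] == pytest.approx(1.0)
        np.testing.assert_allclose(bc[1:], 0.0)

    def test_complete_uniform_all_zero(self):
        w = np.full((6, 6), 0.9)
        np.fill_diagonal(w, 0.0)
        bc, graph = betweenness(w)
        np.testing.assert_allclose(bc, 0.0)
        assert graph == 0.0

    def test_tied_paths_get_fractional_credit(self):
        # square: two equal-length two-hop routes between opposite corners
        w = np.zeros((4, 4))
        for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)]:
            w[a, b] = w[b, a] = 0.5
        bc, _ = betweenness(w)
        # each corner lies on half of the 2 tied paths of one ordered pair
        # pair (0,2): via 1 or via 3 -> each contributes sigma 1 of 2
        np.testing.assert_allclose(bc, [1.0 / 6.0] * 4)

    def test_small_graph_rejected(self):
        with pytest.raises(ConfigError, match="N >= 3"):
            betweenness(np.zeros((2, 2)))


# ---------------------------------------------------------------------------
# oracle equivalence + cross-library checks
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("n,density,n_graphs", [
    (4, 1.0, 15), (5, 0.8, 15), (6, 0.7, 15), (7, 1.0, 10),
])
def test_metrics_match_bruteforce(n, density, n_graphs):
    rng = np.random.default_rng(n * 1000 + int(density * 10))
    for _ in range(n_graphs):
        w = random_weighted_graph(rng, n, density)
        cc, cg = clustering(w)
        bcc, bcg = brute_clustering(w)
        np.testing.assert_allclose(cc, bcc, atol=1e-12)
        assert abs(cg - bcg) < 1e-12

        dist, counts = shortest_paths(w)
        bdist, bcounts, bbc, bbc_g = brute_paths_and_betweenness(w)
        np.testing.assert_allclose(dist, bdist, atol=1e-12)
        np.testing.assert_allclose(counts, bcounts, atol=1e-9)

        bc, bc_g = betweenness(w)
        np.testing.assert_allclose(bc, bbc, atol=1e-12)
        assert abs(bc_g - bbc_g) < 1e-12


def test_metrics_match_networkx(rng):
    """Independent library cross-check on dense random graphs."""
    for _ in range(10):
        n = int(rng.integers(4, 9))
        w = random_weighted_graph(rng, n)
        g = nx.from_numpy_array(w)
        for u, v, d in g.edges(data=True):
            d["length"] = 1.0 / d["weight"]

        cc, _ = clustering(w)
        nx_cc = nx.clustering(g, weight="weight")
        # networkx normalizes weights by the max; rescale to raw-weight form
        scale = w.max()
        np.testing.assert_allclose(cc, [nx_cc[i] * scale for i in range(n)],
                                   atol=1e-10)

        bc, _ = betweenness(w)
        nx_bc = nx.betweenness_centrality(g, weight="length", normalized=True)
        np.testing.assert_allclose(bc, [nx_bc[i] for i in range(n)], atol=1e-10)

        s, _ = strength(w)
        nx_s = g.degree(weight="weight")
        np.testing.assert_allclose(s, [nx_s[i] for i in range(n)], atol=1e-12)

        dist, _ = shortest_paths(w)
        nx_d = dict(nx.all_pairs_dijkstra_path_length(g, weight="length"))
        for i, j in itertools.product(range(n), repeat=2):
            assert dist[i, j] == pytest.approx(nx_d[i].get(j, np.inf), abs=1e-10)


@settings(derandomize=True, max_examples=20, deadline=None)
@given(seed=st.integers(0, 10_000), n=st.integers(4, 7))
def test_permutation_equivariance(seed, n):
    rng = np.random.default_rng(seed)
    w = random_weighted_graph(rng, n)
    perm = rng.permutation(n)
    wp = w[np.ix_(perm, perm)]
    for fn in (lambda m: clustering(m), lambda m: strength(m),
               lambda m: betweenness(m)):
        node, graph = fn(w)
        node_p, graph_p = fn(wp)
        np.testing.assert_allclose(node_p, node[perm], atol=1e-12)
        assert graph_p == pytest.approx(graph, abs=1e-12)


@settings(derandomize=True, max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000), c=st.floats(0.05, 1.0))
def test_uniform_weight_scaling(seed, c):
    """Scaling weights by c scales CC and S by c; BC is unchanged."""
    rng = np.random.default_rng(seed)
    w = random_weighted_graph(rng, 6)
    cc, _ = clustering(w)
    s, _ = strength(w)
    bc, _ = betweenness(w)
    cc2, _ = clustering(c * w)
    s2, _ = strength(c * w)
    bc2, _ = betweenness(c * w)
    np.testing.assert_allclose(cc2, c * cc, rtol=1e-10)
    np.testing.assert_allclose(s2, c * s, rtol=1e-10)
    np.testing.assert_allclose(bc2, bc, atol=1e-12)


class TestSummarize:
    def test_uniform_complete_local_graph(self):
        n = 27
        w = np.full((n, n), 0.8)
        np.fill_diagonal(w, 0.0)
        m = ConnectivityMatrix(labels=tuple(f"E{i}" for i in range(n)),
                               weights=w, scope="local")
        s = summarize(m)
        assert s.cc_graph == pytest.approx(0.8)
        assert s.strength_graph == pytest.approx(26 * 0.8)
        assert s.bc_graph == pytest.approx(0.0)
        assert s.scope == "local"
        assert s.n_nodes == n

    def test_graph_values_are_node_means(self, rng):
        w = random_weighted_graph(rng, 8)
        m = ConnectivityMatrix(labels=tuple(f"E{i}" for i in range(8)),
                               weights=w)
        s = summarize(m)
        assert s.strength_graph == pytest.approx(s.strength_node.mean())
        assert s.bc_graph == pytest.approx(s.bc_node.mean())
        assert s.cc_graph == pytest.approx(s.cc_node.mean())  # all k >= 2

    def test_node_ranges(self, rng):
        w = random_weighted_graph(rng, 10, density=0.6)
        m = ConnectivityMatrix(labels=tuple(f"E{i}" for i in range(10)),
                               weights=w)
        s = summarize(m)
        assert (s.cc_node >= 0).all() and (s.cc_node <= 1).all()
        assert (s.strength_node >= 0).all() and (s.strength_node <= 9).all()
        assert (s.bc_node >= 0).all() and (s.bc_node <= 1).all()
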