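"""Weighted graph metrics on fully weighted undirected networks.

Three per-node measures and their graph averages:

* **Strength** ``S_i = sum_j w_ij`` — total connection weight of node *i*.
* **Weighted clustering coefficient** (Onnela geometric-mean form)
  ``C_i = (1 / (k_i (k_i - 1))) * sum_{j != h} (w_ij w_ih w_jh)^(1/3)``
  with ``k_i`` the number of neighbours with nonzero weight.  Raw |r|
  weights are used without max-weight normalization, so on a near-uniform
  correlation network ``C_i`` tracks the mean neighbourhood weight.
* **Betweenness centrality** — fraction of shortest paths between other node
  pairs passing through a node, with fractional credit when several paths
  tie.  Edge length is ``1/w`` (zero weight = no edge); per-node values are
  normalized by ``(N-1)(N-2)`` ordered pairs so ``BC_i`` lies in [0, 1].
  Computed by Brandes' single-source dependency accumulation over weighted
  shortest paths.

Graph-level values are the arithmetic mean of node values (for clustering,
over nodes with at least two neighbours).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectivity import ConnectivityMatrix
from .errors import ConfigError


@dataclass
class NetworkSummary:
    """Node-level and graph-averaged metrics at one scope."""

    scope: str
    n_nodes: int
    cc_node: np.ndarray
    cc_graph: float
    strength_node: np.ndarray
    strength_graph: float
    bc_node: np.ndarray
    bc_graph: float


def _validate_weights(weights: np.ndarray, max_one: bool = False) -> np.ndarray:
    w = np.asarray(weights, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ConfigError("weights must be a square matrix")
    if not np.array_equal(w, w.T):
        raise ConfigError("weights must be symmetric")
    if np.abs(np.diag(w)).max(initial=0.0) != 0.0:
        raise ConfigError("weight diagonal must be zero")
    if w.size and w.min() < 0:
        raise ConfigError("weights must be non-negative")
    if max_one and w.size and w.max(initial=0.0) > 1.0:
        raise ConfigError("weights must lie in [0, 1] (|Pearson r| convention)")
    return w


def strength(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node strengths (row sums) and their mean."""
    w = _validate_weights(weights)
    s = w.sum(axis=1)
    return s, float(s.mean())


def clustering(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Onnela weighted clustering per node; mean over nodes with k >= 2."""
    w = _validate_weights(weights, max_one=True)
    n = w.shape[0]
    w3 = np.cbrt(w)
    # diag of w3^3 counts ordered (j, h) pairs, matching k(k-1) normalizer
    triangles = np.einsum("ij,jk,ki->i", w3, w3, w3)
    k = (w > 0).sum(axis=1)
    cc = np.zeros(n)
    eligible = k >= 2
    denom = (k * (k - 1)).astype(float)
    cc[eligible] = triangles[eligible] / denom[eligible]
    graph = float(cc[eligible].mean()) if eligible.any() else 0.0
    return cc, graph


def _brandes_source(lengths: np.ndarray, s: int):
    """Array-based Dijkstra from source ``s`` on a dense length matrix.

    Returns (dist, sigma, preds, order): shortest-path distances, path
    counts, predecessor lists and the settle order.  Path-length ties use
    exact float equality, appropriate for continuous weights and for the
    structured integer-length graphs used in tests.
    """
    n = lengths.shape[0]
    dist = np.full(n, np.inf)
    sigma = np.zeros(n)
    dist[s] = 0.0
    sigma[s] = 1.0
    preds: list[list[int]] = [[] for _ in range(n)]
    visited = np.zeros(n, dtype=bool)
    order: list[int] = []
    for _ in range(n):
        cand = np.where(visited, np.inf, dist)
        v = int(np.argmin(cand))
        if not np.isfinite(cand[v]):
            break
        visited[v] = True
        order.append(v)
        alt = dist[v] + lengths[v]
        reach = np.isfinite(lengths[v]) & ~visited
        shorter = reach & (alt < dist)
        equal = reach & (alt == dist)
        for w in np.flatnonzero(shorter):
            dist[w] = alt[w]
            sigma[w] = sigma[v]
            preds[w] = [v]
        for w in np.flatnonzero(equal):
            sigma[w] += sigma[v]
            preds[w].append(v)
    return dist, sigma, preds, order


def _length_matrix(w: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(lengths, np.inf)
    return lengths


def shortest_paths(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest-path distances and minimal-path counts.

    Distance uses edge length 1/w; disconnected pairs have infinite distance
    and zero path count.
    """
    w = _validate_weights(weights)
    n = w.shape[0]
    lengths = _length_matrix(w)
    dist = np.full((n, n), np.inf)
    counts = np.zeros((n, n))
    for s in range(n):
        d, sig, _, _ = _brandes_source(lengths, s)
        dist[s] = d
        counts[s] = sig
        counts[s, s] = 0.0
        dist[s, s] = 0.0
    return dist, counts


def betweenness(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Normalized betweenness centrality per node and its mean.

    ``BC_i = (sum_{s != i != t} sigma_st(i) / sigma_st) / ((N-1)(N-2))``
    over ordered pairs; Brandes accumulation from every source visits each
    unordered pair twice, which matches the ordered-pair normalizer.
    """
    w = _validate_weights(weights)
    n = w.shape[0]
    if n < 3:
        raise ConfigError("betweenness needs N >= 3 (normalizer vanishes)")
    lengths = _length_matrix(w)
    bc = np.zeros(n)
    for s in range(n):
        _, sigma, preds, order = _brandes_source(lengths, s)
        delta = np.zeros(n)
        for v in reversed(order):
            for p in preds[v]:
                delta[p] += sigma[p] / sigma[v] * (1.0 + delta[v])
            if v != s:
                bc[v] += delta[v]
    bc /= (n - 1) * (n - 2)
    return bc, float(bc.mean())


def summarize(matrix: ConnectivityMatrix) -> NetworkSummary:
    """All three metrics on the same weights, scope propagated."""
    w = matrix.weights
    cc_node, cc_graph = clustering(w)
    s_node, s_graph = strength(w)
    bc_node, bc_graph = betweenness(w)
    return NetworkSummary(
        scope=matrix.scope,
        n_nodes=matrix.n_nodes,
        cc_node=cc_node,
        cc_graph=cc_graph,
        strength_node=s_node,
        strength_graph=s_graph,
        bc_node=bc_node,
        bc_graph=bc_graph,
    )
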