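"""Independent brute-force oracles used to validate the network and rank-sum
implementations on small inputs.

Each oracle evaluates the defining formula of its metric directly —
exhaustive path enumeration, dense power iteration, the raw modularity and
mixing-matrix sums, full permutation enumeration — without going through the
code paths under test.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def brute_betweenness(G: nx.Graph, weight: str | None = None) -> dict:
    """All-pairs shortest-path betweenness by exhaustive simple-path enumeration.

    Normalized by the number of ordered source-target pairs not involving the
    node, matching the standard convention for undirected graphs.
    """
    nodes = list(G)
    n = len(nodes)
    bc = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = list(nx.all_simple_paths(G, s, t))
        if not paths:
            continue
        lens = [
            sum(G[u][v][weight] if weight else 1 for u, v in zip(p, p[1:])) for p in paths
        ]
        dmin = min(lens)
        shortest = [p for p, L in zip(paths, lens) if L <= dmin * (1 + 1e-12)]
        sigma = len(shortest)
        for v in nodes:
            if v is s or v is t:
                continue
            bc[v] += sum(1 for p in shortest if v in p) / sigma
    if n > 2:
        scale = 2.0 / ((n - 1) * (n - 2))
        bc = {v: b * scale for v, b in bc.items()}
    return bc


def power_iteration_pagerank(G: nx.Graph, alpha: float = 0.85, weight: str | None = "weight") -> dict:
    """PageRank by dense power iteration on the explicit Google matrix."""
    nodes = list(G)
    n = len(nodes)
    A = np.zeros((n, n))
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if G.has_edge(u, v):
                A[i, j] = G[u][v].get(weight, 1.0) if weight else 1.0
    deg = A.sum(axis=1)
    x = np.full(n, 1.0 / n)
    for _ in range(100000):
        dangling = x[deg == 0].sum()
        xn = np.full(n, (1 - alpha) / n + alpha * dangling / n)
        for i in range(n):
            if deg[i] > 0:
                xn += alpha * x[i] * A[i] / deg[i]
        if np.abs(xn - x).sum() < 1e-15:
            x = xn
            break
        x = xn
    return dict(zip(nodes, x))


def definition_modularity(G: nx.Graph, labels: dict, weight: str | None = "weight") -> float:
    """Q = (1/2m) sum_ij (A_ij - k_i k_j / 2m) [c_i == c_j], summed explicitly."""
    nodes = list(G)
    n = len(nodes)
    A = np.zeros((n, n))
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if u != v and G.has_edge(u, v):
                A[i, j] = G[u][v].get(weight, 1.0) if weight else 1.0
    two_m = A.sum()
    k = A.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[nodes[i]] == labels[nodes[j]]:
                q += A[i, j] - k[i] * k[j] / two_m
    return q / two_m


def mixing_matrix_assortativity(G: nx.Graph, labels: dict, weight: str | None = "weight") -> float:
    """Categorical assortativity from an explicitly tallied mixing matrix."""
    cats = sorted(set(labels.values()))
    idx = {c: i for i, c in enumerate(cats)}
    k = len(cats)
    e = np.zeros((k, k))
    for u, v, d in G.edges(data=True):
        w = d.get(weight, 1.0) if weight else 1.0
        e[idx[labels[u]], idx[labels[v]]] += w
        e[idx[labels[v]], idx[labels[u]]] += w
    e /= e.sum()
    a = e.sum(axis=1)
    b = e.sum(axis=0)
    ab = float(a @ b)
    return (float(np.trace(e)) - ab) / (1 - ab)


def _midranks(values) -> list[float]:
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def permutation_rank_sum_p(values_a, values_b) -> float:
    """Exact two-sided rank-sum p-value by full permutation enumeration."""
    pooled = list(values_a) + list(values_b)
    ranks = _midranks(pooled)
    n_a = len(values_a)
    mean_w = sum(ranks) * n_a / len(ranks)
    w_obs = sum(ranks[:n_a])
    dev = abs(w_obs - mean_w)
    hits = total = 0
    for picks in itertools.combinations(range(len(ranks)), n_a):
        w = sum(ranks[i] for i in picks)
        if abs(w - mean_w) >= dev - 1e-12:
            hits += 1
        total += 1
    return hits / total
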