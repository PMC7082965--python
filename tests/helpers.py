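"""Independent brute-force oracles used to validate the implementation.

Everything here evaluates definitions directly (double loops over node
pairs, explicit set-partition enumeration) and deliberately shares no code
with the package.
"""

from __future__ import annotations

import networkx as nx
import numpy as np


def brute_modularity(graph: nx.Graph, labels: dict) -> float:
    """Weighted Newman modularity by direct double summation over pairs."""
    nodes = list(graph.nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    two_w = adj.sum()
    strength = adj.sum(axis=1)
    q = 0.0
    for i, u in enumerate(nodes):
        for j, v in enumerate(nodes):
            if labels[u] == labels[v]:
                q += adj[i, j] - strength[i] * strength[j] / two_w
    return q / two_w


def brute_modularity_density(graph: nx.Graph, labels: dict) -> float:
    """Weighted modularity density evaluated straight from its definition."""
    nodes = list(graph.nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    total = adj.sum() / 2.0
    comms = sorted(set(labels[u] for u in nodes), key=repr)
    members = {c: [i for i, u in enumerate(nodes) if labels[u] == c] for c in comms}

    def between(c1, c2):
        return sum(adj[i, j] for i in members[c1] for j in members[c2])

    qds = 0.0
    for c in comms:
        idx = members[c]
        n_c = len(idx)
        w_in = sum(adj[i, j] for i in idx for j in idx) / 2.0
        w_out = sum(
            adj[i, j] for i in idx for j in range(len(nodes)) if j not in idx
        )
        d_c = 2.0 * w_in / (n_c * (n_c - 1)) if n_c > 1 else 0.0
        qds += (w_in / total) * d_c - ((2 * w_in + w_out) / (2 * total) * d_c) ** 2
        for c2 in comms:
            if c2 == c:
                continue
            w_cc = between(c, c2)
            d_cc = w_cc / (n_c * len(members[c2]))
            qds -= (w_cc / (2 * total)) * d_cc
    return qds


def brute_rand_index(labels1: dict, labels2: dict) -> float:
    """Rand index by explicit enumeration of all item pairs."""
    items = sorted(labels1, key=repr)
    agree = 0
    pairs = 0
    for i, u in enumerate(items):
        for v in items[i + 1 :]:
            pairs += 1
            same1 = labels1[u] == labels1[v]
            same2 = labels2[u] == labels2[v]
            if same1 == same2:
                agree += 1
    return agree / pairs if pairs else 1.0


def all_set_partitions(items: list):
    """Every partition of ``items`` as a list of blocks."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in all_set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def random_weighted_graph(
    rng: np.random.Generator, n: int, p: float = 0.5,
    w_low: float = 0.1, w_high: float = 2.0,
) -> nx.Graph:
    """Erdős–Rényi graph with uniform edge weights; retries until it has edges."""
    while True:
        graph = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if graph.number_of_edges():
            break
    for u, v in graph.edges:
        graph[u][v]["weight"] = float(rng.uniform(w_low, w_high))
    return graph


def random_labels(rng: np.random.Generator, nodes, max_comms: int = 4) -> dict:
    return {u: int(rng.integers(1, max_comms + 1)) for u in nodes}
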