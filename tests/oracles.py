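"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive — exhaustive enumeration, dense linear
algebra, literal loops — and shares no code path with the package.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def connected_graphs(n: int):
    """All labeled connected graphs on exactly n nodes."""
    pairs = list(itertools.combinations(range(n), 2))
    for mask in range(2 ** len(pairs)):
        g = nx.Graph()
        g.add_nodes_from(range(n))
        g.add_edges_from(p for i, p in enumerate(pairs) if mask >> i & 1)
        if nx.is_connected(g):
            yield g


def _simple_paths(adj: dict, s, t):
    """All simple paths s -> t by explicit DFS (no networkx)."""
    stack = [(s, (s,))]
    while stack:
        node, path = stack.pop()
        if node == t:
            yield path
            continue
        for nxt in adj[node]:
            if nxt not in path:
                stack.append((nxt, path + (nxt,)))


def brute_degree(g: nx.Graph) -> dict:
    return {i: sum(1 for _ in g.neighbors(i)) for i in g.nodes}


def brute_betweenness(g: nx.Graph) -> dict:
    """Betweenness by enumerating every simple path of every pair.

    Sums over unordered (s, t) pairs, endpoints excluded; pairs in
    different components contribute nothing.
    """
    adj = {i: sorted(g.neighbors(i)) for i in g.nodes}
    btw = {i: 0.0 for i in g.nodes}
    for s, t in itertools.combinations(sorted(g.nodes), 2):
        paths = list(_simple_paths(adj, s, t))
        if not paths:
            continue
        shortest = min(len(p) for p in paths)
        geodesics = [p for p in paths if len(p) == shortest]
        for i in g.nodes:
            if i in (s, t):
                continue
            through = sum(1 for p in geodesics if i in p)
            btw[i] += through / len(geodesics)
    return btw


def dense_eigenvector(g: nx.Graph) -> dict:
    """Per-component principal eigenvector via dense eigendecomposition,
    each component scaled to max 1; isolated nodes 0."""
    scores = {i: 0.0 for i in g.nodes}
    for component in nx.connected_components(g):
        comp = sorted(component)
        if len(comp) == 1:
            continue
        adj = nx.to_numpy_array(g, nodelist=comp)
        eigvals, eigvecs = np.linalg.eigh(adj)
        vec = np.abs(eigvecs[:, np.argmax(eigvals)])
        vec /= vec.max()
        for node, value in zip(comp, vec):
            scores[node] = float(value)
    return scores


def triple_loop_whmb(profiles, sets, table, net, use_counts=False):
    """Literal triple loop over sets x samples x genes reading the
    normalized centrality table; out-of-network weight 1."""
    import pandas as pd

    nodes = net.nodes
    lookup = {}
    for _, row in table.iterrows():
        lookup[(row["set"], row["gene"])] = (
            row["degree_n"] + row["betweenness_n"] + row["eigenvector_n"]
        )
    out = pd.DataFrame(
        0.0, index=list(sets.names()), columns=[p.sample_id for p in profiles]
    )
    for set_name, genes in sets.items():
        for profile in profiles:
            total = 0.0
            for gene in sorted(genes):
                if gene not in profile.mutated_genes:
                    continue
                if gene in nodes:
                    w = lookup[(set_name, gene)]
                else:
                    w = 1.0
                if use_counts:
                    w *= profile.counts[gene]
                total += w
            out.at[set_name, profile.sample_id] = total / len(genes)
    return out


def dense_rwr(net, seeds, restart) -> dict:
    """Closed-form restart-walk scores: restart * (I - (1-r) W)^-1 p0,
    with W column-stochastic (dense) and dangling columns replaced by p0."""
    nodes = sorted(net.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    adj = np.zeros((n, n))
    for a, b in net.graph.edges:
        adj[index[b], index[a]] = 1.0
        adj[index[a], index[b]] = 1.0
    if net.directed is not None:
        for a, b in net.directed.edges:
            adj[index[b], index[a]] = 1.0
    p0 = np.zeros(n)
    for g in seeds:
        if g in index:
            p0[index[g]] = 1.0
    p0 /= p0.sum()
    col_sums = adj.sum(axis=0)
    W = np.where(col_sums > 0, adj / np.maximum(col_sums, 1e-300), 0.0)
    W[:, col_sums == 0] = p0[:, None]
    p = restart * np.linalg.solve(np.eye(n) - (1 - restart) * W, p0)
    return dict(zip(nodes, p))
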