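"""Network propagation and bridge-gene prioritization.

A random walk with restart (RWR) over the integrated interaction network
iterates

    p <- (1 - r) W^T p + r p0

with W the column-normalized transition matrix, p0 the (weighted) seed
distribution and r the restart probability.  Undirected interaction edges
contribute transitions both ways; directed TF -> target edges one way;
dangling nodes teleport their mass back to p0.  Bridge hub genes (BHGs)
are the intersection of the top-k rankings obtained from two seedings —
one from a progression-related gene module, one from its related immune
genes.  Hypergeometric and upper-tailed chi-square tests quantify
enrichment of gene lists, and a pluggable community-detection interface
(modularity maximization by default) partitions co-expression networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse, stats

from .io_formats import InteractionNetwork

__all__ = [
    "RwrScores",
    "BhgSet",
    "CommunityAssignment",
    "rwr",
    "top_k",
    "bhg_intersect",
    "enrich_hypergeom",
    "enrich_chisq_upper",
    "detect_communities",
]


@dataclass
class RwrScores:
    """Stationary visiting probabilities of a restart random walk."""

    scores: pd.Series  # per node, >= 0, sums to 1
    restart: float
    seeds: dict[str, float]
    iterations: int
    residual: float


@dataclass
class BhgSet:
    """Intersection of two top-k prioritized gene lists."""

    genes: list[str]  # ordered by the max of the two ranks (best first)
    k: int
    seeds_a: tuple[str, ...] = ()
    seeds_b: tuple[str, ...] = ()


@dataclass
class CommunityAssignment:
    """Node -> community id partition of a network."""

    assignment: dict[str, int]
    method: str = "modularity"

    def members(self, community: int) -> list[str]:
        return sorted(g for g, c in self.assignment.items() if c == community)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))


def _transition_matrix(net: InteractionNetwork, nodes: list[str]) -> sparse.csr_matrix:
    """Column-stochastic transition matrix (columns with outgoing edges)."""
    index = {g: i for i, g in enumerate(nodes)}
    rows, cols = [], []
    for a, b in net.graph.edges:
        rows.append(index[b]), cols.append(index[a])
        rows.append(index[a]), cols.append(index[b])
    if net.directed is not None:
        for a, b in net.directed.edges:
            rows.append(index[b]), cols.append(index[a])
    n = len(nodes)
    adj = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    )
    adj.data[:] = 1.0  # duplicate (undirected + directed) edges collapse
    adj.sum_duplicates()
    adj.data[:] = 1.0
    out_degree = np.asarray(adj.sum(axis=0)).ravel()
    scale = np.where(out_degree > 0, 1.0 / np.maximum(out_degree, 1.0), 0.0)
    return adj @ sparse.diags(scale)


def rwr(
    net: InteractionNetwork,
    seeds: Iterable[str] | Mapping[str, float],
    restart: float = 0.7,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> RwrScores:
    """Random walk with restart from the seed genes.

    ``seeds`` is a gene set (uniform weights) or a gene -> weight mapping.
    Seeds absent from the network are dropped with a warning; if none
    remain it is an error.  Stops when the L1 change per iteration falls
    below ``tol``; failure to converge within ``max_iter`` raises.
    """
    if not 0 < restart <= 1:
        raise ValueError("restart probability must be in (0, 1]")
    nodes = sorted(net.nodes)
    if not nodes:
        raise ValueError("empty network")
    if isinstance(seeds, Mapping):
        weights = {g: float(w) for g, w in seeds.items()}
    else:
        weights = {g: 1.0 for g in seeds}
    if any(w < 0 for w in weights.values()):
        raise ValueError("seed weights must be nonnegative")
    node_set = set(nodes)
    dropped = [g for g in weights if g not in node_set]
    if dropped:
        warnings.warn(
            f"{len(dropped)} seed(s) absent from the network dropped: "
            f"{sorted(dropped)[:5]}",
            stacklevel=2,
        )
    in_net = {g: w for g, w in weights.items() if g in node_set and w > 0}
    if not in_net:
        raise ValueError("no seed gene is present in the network")
    index = {g: i for i, g in enumerate(nodes)}
    p0 = np.zeros(len(nodes))
    for g, w in in_net.items():
        p0[index[g]] = w
    p0 /= p0.sum()
    if restart == 1.0:
        return RwrScores(pd.Series(p0, index=nodes), restart, in_net, 0, 0.0)
    W = _transition_matrix(net, nodes)
    dangling = np.asarray(W.sum(axis=0)).ravel() < 1e-12
    p = p0.copy()
    for iteration in range(1, max_iter + 1):
        spread = W @ p + p[dangling].sum() * p0
        p_next = (1.0 - restart) * spread + restart * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tol:
            return RwrScores(pd.Series(p, index=nodes), restart, in_net, iteration, residual)
    raise RuntimeError(
        f"RWR did not converge in {max_iter} iterations (residual {residual:.3g})"
    )


def top_k(scores: RwrScores, k: int = 500, exclude_seeds: bool = False) -> list[str]:
    """The k highest-scoring genes; ties break lexicographically."""
    if k < 1:
        raise ValueError("k must be >= 1")
    series = scores.scores
    if exclude_seeds:
        series = series.drop(labels=[g for g in scores.seeds if g in series.index])
    ranked = sorted(series.items(), key=lambda item: (-item[1], item[0]))
    if k > len(ranked):
        warnings.warn(
            f"k={k} exceeds {len(ranked)} scored genes; returning the full ranking",
            stacklevel=2,
        )
    return [gene for gene, _ in ranked[:k]]


def bhg_intersect(list_a: list[str], list_b: list[str]) -> BhgSet:
    """Genes present in both rankings, ordered by the worse of the two ranks."""
    rank_a = {g: i for i, g in enumerate(list_a)}
    rank_b = {g: i for i, g in enumerate(list_b)}
    common = set(rank_a) & set(rank_b)
    if not common:
        warnings.warn("the two prioritized lists are disjoint", stacklevel=2)
    ordered = sorted(common, key=lambda g: (max(rank_a[g], rank_b[g]), g))
    return BhgSet(genes=ordered, k=max(len(list_a), len(list_b)))


def enrich_hypergeom(
    hits: set[str], annotation: set[str], universe: set[str]
) -> tuple[float, float]:
    """Upper-tail hypergeometric enrichment of ``hits`` in ``annotation``.

    Returns (p-value, fold enrichment).  p = P(X >= overlap) drawing
    |hits| genes from a universe containing |annotation| annotated ones.
    """
    if not universe:
        raise ValueError("empty universe")
    if not hits <= universe or not annotation <= universe:
        raise ValueError("hits and annotation must be subsets of the universe")
    N, K, n = len(universe), len(annotation), len(hits)
    overlap = len(hits & annotation)
    p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
    expected = K * n / N
    fold = overlap / expected if expected > 0 else float("nan")
    return p, fold


def enrich_chisq_upper(
    hits_in: int, hits_out: int, bg_in: int, bg_out: int
) -> tuple[float, float]:
    """2x2 chi-square test (no continuity correction), upper-tailed.

    Table rows are (hits, background), columns (in annotation, out).
    Returns (statistic, upper-tail p from chi-square with 1 df).
    """
    a, b, c, d = hits_in, hits_out, bg_in, bg_out
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be nonnegative")
    margins = (a + b, c + d, a + c, b + d)
    if any(m == 0 for m in margins):
        raise ValueError("chi-square undefined: a table margin is zero")
    n = a + b + c + d
    statistic = n * (a * d - b * c) ** 2 / (margins[0] * margins[1] * margins[2] * margins[3])
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


def detect_communities(
    net: InteractionNetwork, method: str = "modularity", seed: int = 0
) -> CommunityAssignment:
    """Partition the network into communities (pluggable interface).

    ``modularity`` (default) runs greedy modularity maximization;
    ``louvain`` the Louvain method with the given seed.  Communities are
    numbered 1..m by decreasing size (ties by smallest member symbol) so
    the labeling is deterministic.
    """
    graph = net.undirected_view()
    if graph.number_of_nodes() == 0:
        raise ValueError("empty network")
    if method == "modularity":
        communities = nx.community.greedy_modularity_communities(graph)
    elif method == "louvain":
        communities = nx.community.louvain_communities(graph, seed=seed)
    else:
        raise ValueError(f"unknown community detection method {method!r}")
    ordered = sorted(communities, key=lambda c: (-len(c), min(c)))
    assignment = {
        gene: community_id
        for community_id, members in enumerate(ordered, start=1)
        for gene in members
    }
    return CommunityAssignment(assignment, method=method)
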