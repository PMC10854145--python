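"""Cohort-specific network construction and gene-set centrality features.

The scoring model weights each mutated gene by the sum of its three network
centrality features — degree, betweenness and eigenvector centrality —
computed inside the subnetwork induced by the gene set the gene belongs to,
then min-shifted and scaled by the standard deviation within that
subnetwork:

    x_n = (x - min x) / sd(x)        (sd with n-1 denominator)

Centralities follow the standard undirected conventions: degree is the
neighbour count, betweenness the sum over unordered source-target pairs
(endpoints excluded, within connected components) of the fraction of
shortest paths passing through the node, and eigenvector centrality the
principal-eigenvector score of the component adjacency, rescaled so the
maximum within the subnetwork is 1.  Isolated nodes get (0, 0, 0).
"""

from __future__ import annotations

import numpy as np
import networkx as nx
import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection, InteractionNetwork

__all__ = [
    "build_global_network",
    "cohort_specific_network",
    "geneset_subnetwork",
    "centralities",
    "normalize_centralities",
    "centrality_table",
]

CENTRALITY_FEATURES = ("degree", "betweenness", "eigenvector")


def build_global_network(edge_sources: list[InteractionNetwork]) -> InteractionNetwork:
    """Union of several edge-list networks; provenance tags concatenate."""
    if not edge_sources:
        raise ValueError("need at least one edge source")
    graph = nx.Graph()
    directed = nx.DiGraph()
    provenance: tuple[str, ...] = ()
    for source in edge_sources:
        graph.add_edges_from(source.graph.edges)
        if source.directed is not None:
            directed.add_edges_from(source.directed.edges)
        provenance = provenance + source.provenance
    if graph.number_of_nodes() == 0 and directed.number_of_nodes() == 0:
        raise ValueError("empty network: union of sources has no edges")
    return InteractionNetwork(
        graph,
        directed=directed if directed.number_of_edges() else None,
        provenance=provenance,
    )


def pearson_edge_filter(
    x: np.ndarray, y: np.ndarray, r_min: float, p_max: float
) -> bool:
    """True iff |Pearson r| > r_min and two-sided p < p_max.

    The p-value uses the exact t transform t = r sqrt((n-2)/(1-r^2)) with
    n-2 degrees of freedom.  Zero-variance profiles fail (r undefined).
    """
    n = x.size
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        return False
    r = float(np.corrcoef(x, y)[0, 1])
    if not np.isfinite(r) or abs(r) <= r_min:
        return False
    if abs(r) >= 1.0:
        return True  # t -> inf, p -> 0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(t, df=n - 2)
    return p < p_max


def cohort_specific_network(
    net: InteractionNetwork,
    expr: pd.DataFrame,
    r_min: float = 0.4,
    p_max: float = 0.05,
) -> InteractionNetwork:
    """Keep edges whose endpoints co-express in this cohort.

    An undirected edge survives iff both endpoint genes are rows of ``expr``
    and their profiles have |Pearson r| > ``r_min`` with two-sided p <
    ``p_max``.  Directed (TF -> target) edges are filtered by the same rule.
    """
    n = expr.shape[1]
    if n < 3:
        raise ValueError(f"need >= 3 samples for correlation p-values, got {n}")
    genes = set(expr.index)
    values = {g: expr.loc[g].to_numpy(dtype=float) for g in genes}

    def keep(a: str, b: str) -> bool:
        if a not in genes or b not in genes:
            return False
        return pearson_edge_filter(values[a], values[b], r_min, p_max)

    graph = nx.Graph((a, b) for a, b in net.graph.edges if keep(a, b))
    directed = None
    if net.directed is not None:
        kept = [(a, b) for a, b in net.directed.edges if keep(a, b)]
        if kept:
            directed = nx.DiGraph(kept)
    return InteractionNetwork(graph, directed=directed, provenance=net.provenance)


def geneset_subnetwork(net: InteractionNetwork, genes: list[str]) -> nx.Graph:
    """Induced undirected subgraph on (set genes ∩ network nodes).

    May be empty or disconnected; directed edges are symmetrized first.
    """
    base = net.undirected_view()
    present = [g for g in genes if g in base]
    return base.subgraph(present).copy()


def _eigenvector_power(adj: np.ndarray, tol: float = 1e-10, max_iter: int = 1000) -> np.ndarray:
    """Principal eigenvector of a connected component adjacency, power iteration.

    Nonnegative by Perron-Frobenius; returned scaled to max 1.  Iterates on
    the shifted matrix A + I so bipartite components (where the top two
    eigenvalues tie in magnitude) still converge to the Perron vector.
    """
    n = adj.shape[0]
    shifted = adj + np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        w = shifted @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            return np.zeros(n)
        w /= norm
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    return v / v.max()


def centralities(sub: nx.Graph) -> pd.DataFrame:
    """Raw degree / betweenness / eigenvector features for a subnetwork.

    Returns a DataFrame indexed by gene with columns ``degree``,
    ``betweenness`` and ``eigenvector``.
    """
    nodes = sorted(sub.nodes)
    if not nodes:
        return pd.DataFrame(columns=list(CENTRALITY_FEATURES), dtype=float)
    degree = pd.Series(dict(sub.degree), dtype=float)
    btw = pd.Series(nx.betweenness_centrality(sub, normalized=False), dtype=float)
    eig = pd.Series(0.0, index=nodes)
    for component in nx.connected_components(sub):
        comp = sorted(component)
        if len(comp) == 1:
            continue  # isolated node stays 0
        adj = nx.to_numpy_array(sub, nodelist=comp)
        eig[comp] = _eigenvector_power(adj)
    table = pd.DataFrame(
        {"degree": degree, "betweenness": btw, "eigenvector": eig}
    ).loc[nodes]
    table.index.name = "gene"
    return table


def normalize_centralities(raw: pd.DataFrame) -> pd.DataFrame:
    """Min-shift and sd-scale each feature within one subnetwork.

    x_n = (x - min x) / sd(x), sd with the n-1 denominator; a constant
    feature (sd = 0, including single-node subnetworks) normalizes to 0.
    The minimum normalized value is exactly 0.
    """
    out = {}
    for feature in CENTRALITY_FEATURES:
        x = raw[feature].to_numpy(dtype=float)
        if x.size == 0:
            out[f"{feature}_n"] = x
            continue
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0 or not np.isfinite(sd):
            out[f"{feature}_n"] = np.zeros_like(x)
        else:
            out[f"{feature}_n"] = (x - x.min()) / sd
    return pd.DataFrame(out, index=raw.index)


def centrality_table(
    net: InteractionNetwork, sets: GeneSetCollection
) -> pd.DataFrame:
    """Per (gene set, gene) raw and normalized centrality features.

    For every gene set, the induced subnetwork on the cohort network is
    extracted and the three features computed and normalized within it.
    Genes of the set absent from the network do not appear (they carry the
    out-of-network weight of 1 in the burden score instead).
    """
    frames = []
    for name, genes in sets.items():
        sub = geneset_subnetwork(net, genes)
        raw = centralities(sub)
        if raw.empty:
            continue
        table = pd.concat([raw, normalize_centralities(raw)], axis=1)
        table.insert(0, "set", name)
        frames.append(table.reset_index())
    columns = ["set", "gene", *CENTRALITY_FEATURES] + [
        f"{f}_n" for f in CENTRALITY_FEATURES
    ]
    if not frames:
        return pd.DataFrame(columns=columns)
    return pd.concat(frames, ignore_index=True)[columns]
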