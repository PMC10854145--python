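"""Pathway-mutation subtype discovery on the individualized burden matrix.

Samples (columns of the gene set x sample score matrix) are clustered with
agglomerative clustering, k-means, or consensus clustering.  Consensus
clustering repeats a base clustering on random sample subsets (fraction
``p_item`` without replacement) and records, for every sample pair, the
fraction of co-sampled runs in which the pair co-clustered; the final
partition cuts an average-linkage tree built on 1 - consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

__all__ = ["ClusterResult", "hierarchical_cluster", "kmeans_cluster", "consensus_cluster"]


@dataclass
class ClusterResult:
    """A sample partition with optional consensus evidence.

    ``labels`` maps sample -> integer cluster id in 1..k.  ``dominant_set``
    names, per cluster, the gene set with the highest mean score among the
    cluster's samples.  ``consensus`` (samples x samples, values in [0, 1],
    symmetric, unit diagonal) is present when consensus clustering produced
    the partition; ``never_cosampled`` lists sample pairs that no subsample
    ever contained together (their consensus entry is undefined and stored
    as 0).
    """

    labels: pd.Series
    k: int
    dominant_set: dict[int, str] = field(default_factory=dict)
    consensus: pd.DataFrame | None = None
    never_cosampled: list[tuple[str, str]] = field(default_factory=list)
    cdf_area: float | None = None


def _dominant_sets(matrix: pd.DataFrame, labels: pd.Series, k: int) -> dict[int, str]:
    out = {}
    for cluster in range(1, k + 1):
        members = labels.index[labels == cluster]
        if len(members):
            out[cluster] = str(matrix[members].mean(axis=1).idxmax())
    return out


def _check_k(k: int, n: int) -> None:
    if not 2 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} samples")


def hierarchical_cluster(
    matrix: pd.DataFrame, k: int, method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of sample columns on Euclidean distance."""
    n = matrix.shape[1]
    _check_k(k, n)
    distances = pdist(matrix.to_numpy(dtype=float).T, metric="euclidean")
    tree = linkage(distances, method=method)
    raw = fcluster(tree, t=k, criterion="maxclust")
    labels = pd.Series(_relabel(raw), index=matrix.columns, name="cluster")
    return ClusterResult(labels, k, _dominant_sets(matrix, labels, k))


def kmeans_cluster(matrix: pd.DataFrame, k: int, seed: int = 0) -> ClusterResult:
    """k-means over sample columns (k-means++ init, 10 restarts)."""
    n = matrix.shape[1]
    _check_k(k, n)
    model = KMeans(n_clusters=k, n_init=10, random_state=seed)
    raw = model.fit_predict(matrix.to_numpy(dtype=float).T) + 1
    labels = pd.Series(_relabel(raw), index=matrix.columns, name="cluster")
    return ClusterResult(labels, k, _dominant_sets(matrix, labels, k))


def _relabel(raw: np.ndarray) -> np.ndarray:
    """Renumber cluster ids to 1..k in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, value in enumerate(raw):
        if value not in mapping:
            mapping[value] = len(mapping) + 1
        out[i] = mapping[value]
    return out


def _base_labels(values: np.ndarray, k: int, alg: str, seed: int) -> np.ndarray:
    if alg == "km":
        return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(values)
    if alg == "hc":
        tree = linkage(pdist(values, metric="euclidean"), method="average")
        return fcluster(tree, t=k, criterion="maxclust")
    raise ValueError(f"unknown base clustering algorithm {alg!r}")


def consensus_cluster(
    matrix: pd.DataFrame,
    max_k: int,
    reps: int = 50,
    p_item: float = 0.8,
    alg: str = "km",
    seed: int = 0,
    linkage_method: str = "average",
) -> dict[int, ClusterResult]:
    """Subsampled consensus clustering for every k in 2..min(max_k, n-1).

    For each k, ``reps`` subsamples of ceil(p_item * n) sample columns are
    drawn without replacement and clustered with the base algorithm
    (default k-means); consensus(i, j) = co-clustered count / co-sampled
    count.  Final labels cut an average-linkage tree on 1 - consensus.
    The per-k area under the consensus-value CDF is reported so the usual
    delta-area heuristic can be inspected, but k is never auto-selected.
    """
    n = matrix.shape[1]
    if max_k < 2:
        raise ValueError("max_k must be >= 2")
    if reps < 2:
        raise ValueError("reps must be >= 2")
    if not 0 < p_item <= 1:
        raise ValueError("p_item must be in (0, 1]")
    ks = range(2, min(max_k, n - 1) + 1)
    values = matrix.to_numpy(dtype=float).T  # samples x features
    rng = np.random.default_rng(seed)
    results: dict[int, ClusterResult] = {}
    n_sub = int(np.ceil(p_item * n))
    for k in ks:
        together = np.zeros((n, n))
        cosampled = np.zeros((n, n))
        for rep in range(reps):
            idx = rng.choice(n, size=n_sub, replace=False)
            sub_seed = int(rng.integers(0, 2**31 - 1))
            labels = _base_labels(values[idx], k, alg, sub_seed)
            cosampled[np.ix_(idx, idx)] += 1
            for cluster in np.unique(labels):
                members = idx[labels == cluster]
                together[np.ix_(members, members)] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            consensus = np.where(cosampled > 0, together / np.maximum(cosampled, 1), 0.0)
        never = np.argwhere((cosampled == 0) & ~np.eye(n, dtype=bool))
        never_pairs = sorted(
            {
                tuple(sorted((str(matrix.columns[i]), str(matrix.columns[j]))))
                for i, j in never
            }
        )
        if never_pairs:
            warnings.warn(
                f"k={k}: {len(never_pairs)} sample pair(s) were never "
                "co-sampled; their consensus is undefined (stored as 0)",
                stacklevel=2,
            )
        consensus = (consensus + consensus.T) / 2.0
        np.fill_diagonal(consensus, 1.0)
        tree = linkage(squareform(1.0 - consensus, checks=False), method=linkage_method)
        raw = fcluster(tree, t=k, criterion="maxclust")
        labels = pd.Series(_relabel(raw), index=matrix.columns, name="cluster")
        tri = consensus[np.triu_indices(n, k=1)]
        grid = np.linspace(0, 1, 101)
        cdf_area = float(np.trapezoid([np.mean(tri <= c) for c in grid], grid))
        results[k] = ClusterResult(
            labels,
            k,
            _dominant_sets(matrix, labels, k),
            consensus=pd.DataFrame(consensus, index=matrix.columns, columns=matrix.columns),
            never_cosampled=never_pairs,
            cdf_area=cdf_area,
        )
    return results
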