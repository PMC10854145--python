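"""Pathway mutation burden scoring.

The weighted hallmark-gene-set mutation burden (WHMB) of a gene set *s* in a
sample *j* is

    WHMB(s, j) = (1 / M_size(s)) * sum over g in s ∩ mutated(j) of w(g)

where M_size(s) is the number of genes in the set, and the weight w(g) is
the sum of the gene's three normalized centrality features within the set's
subnetwork when the gene lies in the cohort-specific network, and 1
otherwise.  With mutation counts enabled each term is multiplied by the
gene's count.

The individualized score (IWHMB) z-scores WHMB across gene sets within each
sample:

    IWHMB(s, j) = (WHMB(s, j) - mean_s WHMB(., j)) / sd_s WHMB(., j)

which makes the score invariant to any per-sample positive affine rescaling
of WHMB — the mechanism by which interference from the sample's global
tumor mutational burden is removed.  IWHMB > 0 is interpreted as the
pathway's mutation status being activated in that patient.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection, InteractionNetwork, MutationProfile

__all__ = [
    "gene_weights",
    "compute_whmb",
    "compute_iwhmb",
    "dichotomize",
    "tmb",
    "cnb",
    "jaccard",
]


def gene_weights(
    table: pd.DataFrame, net: InteractionNetwork, sets: GeneSetCollection
) -> dict[str, dict[str, float]]:
    """Per (set, gene) mutation weight.

    In-network genes weigh the sum of their three normalized centrality
    features from ``table``; genes of the set outside the network weigh 1.
    """
    nodes = net.nodes
    weights: dict[str, dict[str, float]] = {}
    normalized = table.set_index(["set", "gene"])[
        ["degree_n", "betweenness_n", "eigenvector_n"]
    ].sum(axis=1)
    for name, genes in sets.items():
        per_set = {}
        for gene in genes:
            if gene in nodes and (name, gene) in normalized.index:
                per_set[gene] = float(normalized.loc[(name, gene)])
            else:
                per_set[gene] = 1.0
        weights[name] = per_set
    return weights


def compute_whmb(
    profiles: Sequence[MutationProfile],
    sets: GeneSetCollection,
    table: pd.DataFrame,
    net: InteractionNetwork,
    use_counts: bool = False,
    samples: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Weighted per-set mutation burden matrix (gene sets x samples).

    ``samples``, when given, fixes the output columns: samples without a
    mutation profile get a zero column with a warning.
    """
    for name, genes in sets.items():
        if len(genes) == 0:
            raise ValueError(f"gene set {name!r} has size 0")
    weights = gene_weights(table, net, sets)
    by_sample = {p.sample_id: p for p in profiles}
    columns = list(by_sample) if samples is None else list(samples)
    missing = [s for s in columns if s not in by_sample]
    if missing:
        warnings.warn(
            f"{len(missing)} sample(s) absent from mutation profiles, "
            f"scored as zero columns: {missing[:5]}",
            stacklevel=2,
        )
    matrix = pd.DataFrame(0.0, index=list(sets.names()), columns=columns)
    for name, genes in sets.items():
        m_size = len(genes)
        per_set = weights[name]
        gene_list = set(genes)
        for sample in columns:
            profile = by_sample.get(sample)
            if profile is None:
                continue
            total = 0.0
            # sorted so the summation order (hence fp result) is reproducible
            for gene in sorted(gene_list & profile.mutated_genes):
                term = per_set[gene]
                if use_counts:
                    term *= profile.counts[gene]
                total += term
            matrix.at[name, sample] = total / m_size
    matrix.index.name = "set"
    matrix.attrs["kind"] = "WHMB"
    return matrix


def compute_iwhmb(whmb: pd.DataFrame) -> pd.DataFrame:
    """Z-score the burden matrix across gene sets within each sample column.

    Non-degenerate columns come out with mean 0 and sd 1 (n-1 denominator);
    a constant column (sd = 0) becomes all zeros with a warning.
    """
    if whmb.shape[0] < 2:
        raise ValueError("IWHMB needs at least 2 gene sets")
    values = whmb.to_numpy(dtype=float)
    mean = values.mean(axis=0)
    sd = values.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} sample(s) have constant burden across "
            "sets; their scores are set to 0",
            stacklevel=2,
        )
    safe_sd = np.where(degenerate, 1.0, sd)
    z = (values - mean) / safe_sd
    z[:, degenerate] = 0.0
    out = pd.DataFrame(z, index=whmb.index, columns=whmb.columns)
    out.index.name = "set"
    out.attrs["kind"] = "IWHMB"
    return out


def dichotomize(iwhmb: pd.DataFrame, set_name: str) -> pd.Series:
    """Per-sample 'high' (score > 0) / 'low' (score <= 0) labels for one set."""
    if set_name not in iwhmb.index:
        raise KeyError(f"unknown gene set {set_name!r}")
    row = iwhmb.loc[set_name]
    return pd.Series(
        np.where(row.to_numpy(dtype=float) > 0, "high", "low"),
        index=iwhmb.columns,
        name=set_name,
    )


def tmb(profiles: Sequence[MutationProfile], region_mb: float = 38.0) -> pd.Series:
    """Tumor mutational burden: non-silent mutations per megabase of region.

    The default region size of 38 Mb approximates the coding exome.
    """
    if region_mb <= 0:
        raise ValueError("region_mb must be positive")
    return pd.Series(
        {p.sample_id: p.n_mutations / region_mb for p in profiles}, name="TMB"
    )


def cnb(cnv: pd.DataFrame) -> pd.Series:
    """Copy-number burden: per sample, the sum of |gene-level calls|."""
    return cnv.abs().sum(axis=0).rename("CNB")


def jaccard(a: Iterable, b: Iterable) -> float:
    """Jaccard similarity |A ∩ B| / (|A| + |B| - |A ∩ B|); 0 when both empty."""
    sa, sb = set(a), set(b)
    union = len(sa) + len(sb) - len(sa & sb)
    if union == 0:
        return 0.0
    return len(sa & sb) / union
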