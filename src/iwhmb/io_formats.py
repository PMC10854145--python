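"""Readers and writers for the plain-text formats the pipeline touches.

Mutation calls come in as MAF-like tab-separated tables, gene sets as GMT
(the MSigDB interchange dialect), interaction networks as 2-3 column edge
lists, and expression / copy-number matrices as TSV with genes in rows and a
header row of samples.  No science happens here: parsing, validation and
lossless round-tripping only.

Gene symbols are treated as case-sensitive opaque strings and are never
remapped; joins across files are by exact string match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "FormatError",
    "MutationProfile",
    "GeneSetCollection",
    "InteractionNetwork",
    "DEFAULT_SILENT_CLASSES",
    "read_maf",
    "write_maf",
    "read_gmt",
    "write_gmt",
    "read_edge_list",
    "write_edge_list",
    "read_expression",
    "read_cnv",
    "write_matrix",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


#: Variant classifications excluded by default: everything that does not
#: change the protein product or falls outside coding regions.
DEFAULT_SILENT_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA"}
)

_MAF_REQUIRED = ("Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification")


@dataclass
class MutationProfile:
    """Per-sample somatic mutation status at gene level.

    ``counts`` maps each non-silently mutated gene symbol to the number of
    retained variant rows observed for it (always >= 1).
    """

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def mutated_genes(self) -> frozenset[str]:
        return frozenset(self.counts)

    @property
    def n_mutations(self) -> int:
        """Total retained (non-silent) variant count for the sample."""
        return sum(self.counts.values())

    def __post_init__(self) -> None:
        for gene, count in self.counts.items():
            if not gene:
                raise ValueError("empty gene symbol in mutation profile")
            if count < 1:
                raise ValueError(f"mutation count for {gene!r} must be >= 1")


@dataclass
class GeneSetCollection:
    """Named, ordered gene sets (e.g. the 50 MSigDB hallmark sets)."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) < 1:
                raise ValueError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValueError(f"gene set {name!r} contains duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class InteractionNetwork:
    """Gene-symbol interaction network.

    ``graph`` holds the undirected (e.g. protein-protein) edges with the
    adjacency convention a_ij = a_ji in {0, 1} and no self loops.
    ``directed`` optionally holds one-way regulatory (TF -> target) edges,
    used by network propagation; centrality computations symmetrize them.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    directed: nx.DiGraph | None = None
    provenance: tuple[str, ...] = ()

    @property
    def nodes(self) -> set[str]:
        out = set(self.graph.nodes)
        if self.directed is not None:
            out |= set(self.directed.nodes)
        return out

    @property
    def n_edges(self) -> int:
        n = self.graph.number_of_edges()
        if self.directed is not None:
            n += self.directed.number_of_edges()
        return n

    def __contains__(self, gene: str) -> bool:
        return gene in self.nodes

    def undirected_view(self) -> nx.Graph:
        """Undirected graph over all edges (directed ones symmetrized)."""
        if self.directed is None or self.directed.number_of_edges() == 0:
            return self.graph
        g = self.graph.copy()
        g.add_edges_from(self.directed.edges)
        return g


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------

def read_maf(
    path: str | Path,
    keep_classes: Iterable[str] | None = None,
    exclude_classes: Iterable[str] = DEFAULT_SILENT_CLASSES,
) -> list[MutationProfile]:
    """Read a MAF-like table into one :class:`MutationProfile` per sample.

    Rows whose ``Variant_Classification`` is silent/non-coding are dropped;
    only non-silent mutations are retained.  If ``keep_classes`` is given it
    wins: only those classifications are kept.  Duplicate (sample, gene)
    rows collapse into a count.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty MAF, no samples read", stacklevel=2)
        return []
    for column in _MAF_REQUIRED:
        if column not in table.columns:
            raise FormatError(f"{path}: missing required MAF column {column!r}")
    if table.empty:
        warnings.warn(f"{path}: empty MAF, no samples read", stacklevel=2)
        return []
    if keep_classes is not None:
        mask = table["Variant_Classification"].isin(set(keep_classes))
    else:
        mask = ~table["Variant_Classification"].isin(set(exclude_classes))
    table = table[mask]
    profiles: dict[str, dict[str, int]] = {}
    # preserve first-appearance sample order
    for sample in pd.unique(table["Tumor_Sample_Barcode"]):
        profiles[str(sample)] = {}
    for sample, gene in zip(table["Tumor_Sample_Barcode"], table["Hugo_Symbol"]):
        counts = profiles[str(sample)]
        counts[str(gene)] = counts.get(str(gene), 0) + 1
    return [MutationProfile(sample, counts) for sample, counts in profiles.items()]


def write_maf(profiles: Iterable[MutationProfile], path: str | Path) -> None:
    """Serialize profiles back to a minimal non-silent MAF (one row per count)."""
    rows = []
    for profile in profiles:
        for gene in sorted(profile.counts):
            rows.extend(
                {
                    "Hugo_Symbol": gene,
                    "Tumor_Sample_Barcode": profile.sample_id,
                    "Variant_Classification": "Missense_Mutation",
                }
                for _ in range(profile.counts[gene])
            )
    pd.DataFrame(rows, columns=list(_MAF_REQUIRED)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read an MSigDB-dialect GMT file: name <tab> description <tab> genes..."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name, genes = fields[0], [g for g in fields[2:] if g]
            seen: list[str] = []
            for gene in genes:
                if gene in seen:
                    warnings.warn(
                        f"{path}:{lineno}: duplicate gene {gene!r} in set {name!r} dropped",
                        stacklevel=2,
                    )
                else:
                    seen.append(gene)
            sets[name] = seen
    return GeneSetCollection(sets, source=str(path))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as handle:
        for name, genes in collection.items():
            handle.write("\t".join([name, collection.source or "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Edge lists
# ---------------------------------------------------------------------------

def read_edge_list(
    path: str | Path, directed: bool = False, provenance: str | None = None
) -> InteractionNetwork:
    """Read a 2-3 column tab-separated edge list (third column ignored payload).

    Self-loops are dropped, duplicate (and for undirected graphs, reversed)
    edges merge, and the node set is exactly the symbols on retained edges.
    """
    path = Path(path)
    graph: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: edge line needs >= 2 columns")
            a, b = fields[0], fields[1]
            if not a or not b:
                raise FormatError(f"{path}:{lineno}: empty node name")
            if a == b:
                continue
            graph.add_edge(a, b)
    tag = provenance if provenance is not None else path.name
    if directed:
        return InteractionNetwork(nx.Graph(), directed=graph, provenance=(tag,))
    return InteractionNetwork(graph, provenance=(tag,))


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            handle.write(f"{a}\t{b}\n")
        if net.directed is not None:
            for a, b in sorted(net.directed.edges):
                handle.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Matrices
# ---------------------------------------------------------------------------

def _read_matrix(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        matrix = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.EmptyDataError as err:
        raise FormatError(f"{path}: empty matrix file") from err
    if matrix.shape[1] == 0:
        raise FormatError(f"{path}: no samples (no data columns)")
    if matrix.index.duplicated().any():
        dup = matrix.index[matrix.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene identifier {dup!r}")
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample identifier {dup!r}")
    for column in matrix.columns:
        bad = pd.to_numeric(matrix[column], errors="coerce").isna() & matrix[column].notna()
        if bad.any():
            gene = matrix.index[bad][0]
            raise FormatError(
                f"{path}: non-numeric value at gene {gene!r}, sample {column!r}"
            )
    matrix = matrix.astype(float)
    if matrix.isna().any().any():
        raise FormatError(f"{path}: missing values are not allowed")
    matrix.index = matrix.index.astype(str)
    matrix.columns = matrix.columns.astype(str)
    return matrix


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples expression TSV (log-scale values expected)."""
    return _read_matrix(path)


def read_cnv(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples matrix of integer gene-level copy-number calls."""
    matrix = _read_matrix(path)
    as_int = matrix.round()
    if (abs(matrix - as_int) > 1e-12).any().any():
        raise FormatError(f"{path}: copy-number calls must be integers")
    return as_int.astype(int)


def write_matrix(
    matrix: pd.DataFrame,
    path: str | Path,
    header_comments: Iterable[str] | Mapping[str, str] = (),
) -> None:
    """Write a genes x samples matrix as TSV, lossless to 10 significant digits.

    ``header_comments`` become ``# key: value`` lines before the table; the
    readers skip them.
    """
    if isinstance(header_comments, Mapping):
        lines = [f"# {k}: {v}" for k, v in header_comments.items()]
    else:
        lines = [f"# {c}" for c in header_comments]
    with open(path, "w") as handle:
        for line in lines:
            handle.write(line + "\n")
        matrix.to_csv(handle, sep="\t", float_format="%.10g")
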