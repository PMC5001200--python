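"""Genetic disease network (GDN) construction.

Diseases become nodes; two diseases are connected whenever their associated
gene sets overlap, with the edge weight given by a gene-set similarity
(cosine by default; Jaccard and overlap coefficient are alternatives).
The column-normalized adjacency matrix of this weighted, undirected graph
is the transition matrix of the random walk with restart.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .kb_io import DiseaseGeneAssociations

__all__ = [
    "SIMILARITY_METHODS",
    "GeneticDiseaseNetwork",
    "TransitionMatrix",
    "gene_set_similarity",
    "build_gdn",
    "column_normalize",
]

SIMILARITY_METHODS = ("cosine", "jaccard", "overlap")


def gene_set_similarity(a: frozenset | set, b: frozenset | set, method: str = "cosine") -> float:
    """Similarity between two nonempty gene sets, in [0, 1].

    cosine = |a∩b| / sqrt(|a|·|b|); jaccard = |a∩b| / |a∪b|;
    overlap = |a∩b| / min(|a|, |b|).  Symmetric in its arguments.
    """
    if not a or not b:
        raise ValueError("gene sets must be nonempty")
    inter = len(set(a) & set(b))
    if method == "cosine":
        return inter / math.sqrt(len(a) * len(b))
    if method == "jaccard":
        return inter / len(set(a) | set(b))
    if method == "overlap":
        return inter / min(len(a), len(b))
    raise ValueError(f"unknown similarity method {method!r}")


@dataclass(frozen=True)
class GeneticDiseaseNetwork:
    """Weighted undirected disease graph.

    ``nodes`` is the deterministic (lexicographic) node order; ``edges``
    maps index pairs (i, j) with i < j to weights in (0, 1].  Isolated
    nodes are kept so node counts match the input; they receive zero
    walk score downstream and drop out of rankings.
    """

    nodes: tuple[str, ...]
    edges: Mapping[tuple[int, int], float]
    similarity_method: str = "cosine"

    def __post_init__(self) -> None:
        for (i, j), w in self.edges.items():
            if not (0 <= i < j < len(self.nodes)):
                raise ValueError(f"bad edge index pair ({i}, {j})")
            if not (0.0 < w <= 1.0 + 1e-12):
                raise ValueError(f"edge weight {w} outside (0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def isolated_nodes(self) -> tuple[str, ...]:
        touched = {i for ij in self.edges for i in ij}
        return tuple(n for k, n in enumerate(self.nodes) if k not in touched)

    def adjacency(self) -> sp.csr_matrix:
        """Symmetric weighted adjacency matrix over the node order."""
        n = self.n_nodes
        if not self.edges:
            return sp.csr_matrix((n, n))
        ii, jj, ww = [], [], []
        for (i, j), w in self.edges.items():
            ii += [i, j]
            jj += [j, i]
            ww += [w, w]
        return sp.csr_matrix((ww, (ii, jj)), shape=(n, n))

    def edge_weight(self, a: str, b: str) -> float:
        """Weight of the edge between two named diseases (0 if absent)."""
        i, j = self.nodes.index(a), self.nodes.index(b)
        if i > j:
            i, j = j, i
        return self.edges.get((i, j), 0.0)

    def to_networkx(self):
        """Export as a networkx.Graph (for GraphML or visual inspection)."""
        import networkx as nx

        g = nx.Graph(similarity_method=self.similarity_method)
        g.add_nodes_from(self.nodes)
        for (i, j), w in self.edges.items():
            g.add_edge(self.nodes[i], self.nodes[j], weight=w)
        return g

    def write_edgelist(self, path: str | Path) -> None:
        rows = sorted(
            (self.nodes[i], self.nodes[j], w) for (i, j), w in self.edges.items()
        )
        pd.DataFrame(rows, columns=["disease_i", "disease_j", "weight"]).to_csv(
            path, sep="\t", index=False
        )


def build_gdn(
    assoc: DiseaseGeneAssociations,
    method: str = "cosine",
    min_weight: float = 0.0,
    *,
    binarize: bool = False,
) -> GeneticDiseaseNetwork:
    """Build the genetic disease network from disease-gene associations.

    One node per disease (including those that end up isolated); an edge
    for every disease pair whose gene-set similarity exceeds
    ``max(0, min_weight)``.  The default ``min_weight = 0`` connects any
    two diseases sharing at least one gene.  With ``binarize`` every
    retained edge gets weight 1 (unweighted walk variant).
    """
    if method not in SIMILARITY_METHODS:
        raise ValueError(f"unknown similarity method {method!r}")
    if not assoc.entries:
        raise ValueError("no disease-gene associations to build a network from")

    nodes = tuple(sorted(assoc.entries))
    genes = sorted(assoc.genes)
    gidx = {g: k for k, g in enumerate(genes)}

    # sparse disease x gene incidence; intersections via one spmm
    ii = [i for i, d in enumerate(nodes) for _ in assoc.entries[d]]
    jj = [gidx[g] for d in nodes for g in assoc.entries[d]]
    B = sp.csr_matrix(
        (np.ones(len(ii)), (ii, jj)), shape=(len(nodes), len(genes))
    )
    inter = sp.triu(B @ B.T, k=1).tocoo()
    sizes = np.asarray(B.sum(axis=1)).ravel()

    floor = max(0.0, float(min_weight))
    edges: dict[tuple[int, int], float] = {}
    for i, j, c in zip(inter.row, inter.col, inter.data):
        if method == "cosine":
            w = c / math.sqrt(sizes[i] * sizes[j])
        elif method == "jaccard":
            w = c / (sizes[i] + sizes[j] - c)
        else:  # overlap
            w = c / min(sizes[i], sizes[j])
        if w > floor:
            edges[(int(i), int(j))] = 1.0 if binarize else float(w)
    return GeneticDiseaseNetwork(nodes, edges, similarity_method=method)


@dataclass(frozen=True)
class TransitionMatrix:
    """Column-stochastic transition matrix of the disease network.

    Every column sums to 1 (within 1e-12) except columns of isolated
    nodes, which are entirely zero; those nodes are listed in
    ``isolated``.  Mass walking into a zero column leaks, by design:
    only the restart term reinjects probability.
    """

    matrix: sp.csr_matrix
    nodes: tuple[str, ...]
    column_sums: np.ndarray
    isolated: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.nodes)

    def index_of(self, disease: str) -> int:
        try:
            return self.nodes.index(disease)
        except ValueError:
            raise KeyError(f"disease {disease!r} not in the network") from None


def column_normalize(g: GeneticDiseaseNetwork) -> TransitionMatrix:
    """Derive the column-normalized transition matrix M of the network.

    M[i, j] = w(i, j) / sum_k w(k, j) for columns with positive sum;
    zero columns are left zero and their nodes flagged as isolated.
    """
    A = g.adjacency().tocsc()
    colsum = np.asarray(A.sum(axis=0)).ravel()
    scale = np.divide(1.0, colsum, out=np.zeros_like(colsum), where=colsum > 0)
    M = (A @ sp.diags(scale)).tocsr()
    isolated = tuple(n for n, s in zip(g.nodes, colsum) if s == 0)
    return TransitionMatrix(M, g.nodes, colsum, isolated)
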