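"""Gene graph construction and the spectral machinery of the graph convolution.

The gene--gene graph is built either from a weighted interaction table
(STRING-style protein links, restricted to the selected genes) or from
pairwise cosine similarity of gene expression profiles.  Edge weights are
row-normalized and the matrix symmetrized; the symmetric normalized Laplacian
``L = I - D^{-1/2} A D^{-1/2}`` is then rescaled to ``L~ = 2L/lambda_max - I``
so its spectrum lies in [-1, 1], the domain of the Chebyshev polynomials that
approximate the spectral convolution kernel.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

logger = logging.getLogger("cellgcn")

Edge = tuple[str, str, float]


class GraphFormatError(ValueError):
    """Raised when an interaction table does not match the expected layout."""


@dataclass
class GeneGraph:
    """Weighted, symmetric, zero-diagonal adjacency over an ordered gene set.

    ``gene_ids`` fixes the node order used by every downstream consumer
    (Laplacian, convolution, model input columns).  ``singleton_mask`` marks
    genes with no neighbors; they are kept as isolated nodes so their
    expression passes through the spectral filter unchanged.
    """

    gene_ids: list[str]
    adjacency: sp.csr_matrix
    singleton_mask: np.ndarray
    source: str = "interaction"

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if len(set(self.gene_ids)) != n:
            raise ValueError("duplicate gene_ids in GeneGraph")
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match gene_ids")

    @property
    def n_nodes(self) -> int:
        return len(self.gene_ids)

    def validate(self, tol: float = 1e-10) -> None:
        a = self.adjacency
        if a.diagonal().any():
            raise ValueError("adjacency has nonzero diagonal")
        if a.data.size and a.data.min() < 0:
            raise ValueError("adjacency has negative weights")
        if abs(a - a.T).max() > tol:
            raise ValueError("adjacency is not symmetric")


@dataclass
class ScaledLaplacian:
    """Rescaled normalized Laplacian ``2L/lambda_max - I`` with spectrum in [-1, 1]."""

    matrix: sp.csr_matrix
    lambda_max: float
    n_nodes: int = field(default=0)

    def __post_init__(self) -> None:
        if self.n_nodes == 0:
            self.n_nodes = self.matrix.shape[0]
        if self.lambda_max <= 0:
            raise ValueError("lambda_max must be positive")


# ---------------------------------------------------------------------------
# Interaction-table input
# ---------------------------------------------------------------------------

def load_interaction_table(
    path,
    id1_column: str = "protein1",
    id2_column: str = "protein2",
    score_column: str = "combined_score",
    id_mapping: Mapping[str, str] | None = None,
) -> list[Edge]:
    """Read a STRING-style edge table into a deduplicated undirected edge list.

    Each unordered pair is kept once with the maximum score seen across its
    (possibly repeated, possibly reversed) rows; self-pairs are dropped.  When
    ``id_mapping`` is given, identifiers are translated and untranslatable
    rows dropped with a logged count.
    """
    import csv as _csv
    try:
        table = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, _csv.Error):
        warnings.warn(f"interaction table {path} is empty", stacklevel=2)
        return []
    for col in (id1_column, id2_column, score_column):
        if col not in table.columns:
            raise GraphFormatError(
                f"interaction table missing column {col!r}; found {list(table.columns)}"
            )
    if table.empty:
        warnings.warn(f"interaction table {path} has no rows", stacklevel=2)
        return []

    a = table[id1_column].astype(str)
    b = table[id2_column].astype(str)
    score = pd.to_numeric(table[score_column], errors="raise").astype(float)
    if (score < 0).any():
        raise GraphFormatError("negative interaction scores")

    if id_mapping is not None:
        a_m = a.map(id_mapping)
        b_m = b.map(id_mapping)
        keep = a_m.notna() & b_m.notna()
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropped %d interaction rows with unmappable identifiers", n_drop)
        a, b, score = a_m[keep], b_m[keep], score[keep]

    best: dict[tuple[str, str], float] = {}
    for ga, gb, s in zip(a, b, score):
        if ga == gb:
            continue
        key = (ga, gb) if ga <= gb else (gb, ga)
        if s > best.get(key, -np.inf):
            best[key] = s
    return [(ga, gb, s) for (ga, gb), s in best.items()]


def write_edge_list(path, graph_or_edges) -> None:
    """Export edges as a 3-column TSV (gene_a, gene_b, weight)."""
    if isinstance(graph_or_edges, GeneGraph):
        coo = sp.triu(graph_or_edges.adjacency, k=1).tocoo()
        ids = graph_or_edges.gene_ids
        rows = [(ids[i], ids[j], w) for i, j, w in zip(coo.row, coo.col, coo.data)]
    else:
        rows = list(graph_or_edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path) -> list[Edge]:
    """Read a 3-column TSV written by :func:`write_edge_list`."""
    table = pd.read_csv(path, sep="\t")
    for col in ("gene_a", "gene_b", "weight"):
        if col not in table.columns:
            raise GraphFormatError(f"edge list missing column {col!r}")
    return [
        (str(r.gene_a), str(r.gene_b), float(r.weight))
        for r in table.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# Graph assembly
# ---------------------------------------------------------------------------

def _normalize_and_symmetrize(w: sp.csr_matrix) -> sp.csr_matrix:
    """Row-normalize weights (zero rows stay zero), then average with the
    transpose so the Laplacian factorization below has a symmetric input."""
    row_sums = np.asarray(w.sum(axis=1)).ravel()
    inv = np.divide(1.0, row_sums, out=np.zeros_like(row_sums), where=row_sums > 0)
    a_norm = sp.diags(inv) @ w
    a = (a_norm + a_norm.T) * 0.5
    a = sp.csr_matrix(a)
    a.eliminate_zeros()
    return a


def build_gene_graph(
    edges: Sequence[Edge], gene_ids: Sequence[str], source: str = "interaction"
) -> GeneGraph:
    """Restrict an edge list to ``gene_ids``, row-normalize, symmetrize.

    Edges mentioning genes outside ``gene_ids`` are ignored.  Genes with no
    surviving edges become singletons.
    """
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    if n == 0:
        raise ValueError("gene_ids is empty")
    if len(set(gene_ids)) != n:
        raise ValueError("duplicate gene_ids")
    index = {g: i for i, g in enumerate(gene_ids)}

    weight: dict[tuple[int, int], float] = {}
    for ga, gb, s in edges:
        ia, ib = index.get(ga), index.get(gb)
        if ia is None or ib is None or ia == ib:
            continue
        for key in ((ia, ib), (ib, ia)):
            if s > weight.get(key, -np.inf):
                weight[key] = s

    if weight:
        ij = np.array(list(weight.keys()), dtype=np.int64)
        w = sp.csr_matrix(
            (np.array(list(weight.values())), (ij[:, 0], ij[:, 1])), shape=(n, n)
        )
    else:
        w = sp.csr_matrix((n, n))

    adj = _normalize_and_symmetrize(w)
    singleton = np.asarray(abs(adj).sum(axis=1)).ravel() == 0
    return GeneGraph(gene_ids=gene_ids, adjacency=adj, singleton_mask=singleton, source=source)


def build_cosine_graph(
    expr: np.ndarray, gene_ids: Sequence[str], threshold: float = 0.6
) -> GeneGraph:
    """Gene graph from pairwise cosine similarity of expression profiles.

    ``expr`` is cells x genes with columns aligned to ``gene_ids``.  Pairs
    below ``threshold`` (or involving an all-zero profile) get no edge;
    surviving similarities are edge weights fed through the same
    normalization as interaction weights.
    """
    if not (-1.0 <= threshold <= 1.0):
        raise ValueError(f"cosine threshold must be in [-1, 1], got {threshold}")
    expr = np.asarray(expr, dtype=float)
    if expr.ndim != 2 or expr.shape[0] < 2:
        raise ValueError("expr must be a cells x genes matrix with at least 2 cells")
    if expr.shape[1] != len(gene_ids):
        raise ValueError("expr columns do not align with gene_ids")

    norms = np.linalg.norm(expr, axis=0)
    safe = np.where(norms > 0, norms, 1.0)
    unit = expr / safe
    sim = unit.T @ unit
    np.fill_diagonal(sim, 0.0)
    zero = norms == 0
    sim[zero, :] = 0.0
    sim[:, zero] = 0.0
    sim[sim < threshold] = 0.0

    w = sp.csr_matrix(sim)
    adj = _normalize_and_symmetrize(w)
    singleton = np.asarray(abs(adj).sum(axis=1)).ravel() == 0
    return GeneGraph(
        gene_ids=list(gene_ids), adjacency=adj, singleton_mask=singleton, source="cosine"
    )


# ---------------------------------------------------------------------------
# Laplacian and Chebyshev basis
# ---------------------------------------------------------------------------

def scaled_laplacian(graph: GeneGraph, lambda_max_mode: str = "exact") -> ScaledLaplacian:
    """Symmetric normalized Laplacian, rescaled so eigenvalues lie in [-1, 1].

    L = I - D^{-1/2} A D^{-1/2} with the 0/0 -> 0 convention for degree-zero
    nodes, which makes a singleton's Laplacian row an identity row and keeps
    L positive semidefinite.  ``lambda_max`` is the largest eigenvalue of L
    (iterative solver, tol 1e-6) or the analytic bound 2 in ``approx2`` mode.
    """
    if lambda_max_mode not in ("exact", "approx2"):
        raise ValueError(f"unknown lambda_max_mode {lambda_max_mode!r}")
    graph.validate()
    a = graph.adjacency
    n = graph.n_nodes
    deg = np.asarray(a.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        d_inv_sqrt = np.where(deg > 0, deg, 1.0) ** -0.5
    d_inv_sqrt[deg == 0] = 0.0
    lap = sp.eye(n, format="csr") - sp.diags(d_inv_sqrt) @ a @ sp.diags(d_inv_sqrt)
    lap = sp.csr_matrix((lap + lap.T) * 0.5)  # symmetrize roundoff

    if lambda_max_mode == "exact":
        try:
            if n <= 4:
                lmax = float(np.linalg.eigvalsh(lap.toarray()).max())
            else:
                lmax = float(spla.eigsh(lap, k=1, which="LA", tol=1e-6,
                                        return_eigenvectors=False)[0])
        except (spla.ArpackNoConvergence, spla.ArpackError):
            warnings.warn("eigensolver failed to converge; using lambda_max = 2",
                          stacklevel=2)
            lmax = 2.0
    else:
        lmax = 2.0
    # Edgeless graph: L = I, lmax = 1.
    lmax = max(lmax, np.finfo(float).eps)
    scaled = sp.csr_matrix(lap * (2.0 / lmax) - sp.eye(n, format="csr"))
    return ScaledLaplacian(matrix=scaled, lambda_max=lmax, n_nodes=n)


def chebyshev_basis(lap: ScaledLaplacian, x: np.ndarray, K: int) -> np.ndarray:
    """Stack ``[T_0(L~)x, ..., T_{K-1}(L~)x]`` by the three-term recursion.

    ``x`` has N rows (a vector or an N x B batch); T_k is never materialized
    as a matrix, only its action on ``x``.  Slice 0 is ``x`` itself.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    x = np.asarray(x, dtype=float)
    if x.shape[0] != lap.n_nodes:
        raise ValueError(f"x has {x.shape[0]} rows, expected {lap.n_nodes}")
    out = np.empty((K,) + x.shape, dtype=float)
    out[0] = x
    if K > 1:
        out[1] = lap.matrix @ x
    for k in range(2, K):
        out[k] = 2.0 * (lap.matrix @ out[k - 1]) - out[k - 2]
    return out
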