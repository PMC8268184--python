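"""Labeled expression matrices: I/O, filtering, normalization, gene selection,
splitting, and multi-dataset harmonization.

The pipeline order is fixed: filter cells -> filter genes -> log2(x+1) +
per-gene min-max -> top-variance gene selection -> stratified split.  The
gene order returned by :func:`select_top_variant_genes` is the canonical node
order for the graph and model modules.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from scipy.stats import gaussian_kde

logger = logging.getLogger("cellgcn")

DEFAULT_EXCLUDE_LABELS = frozenset({"unlabeled", "unlabelled", "debris", "doublet", "doublets"})


@dataclass
class LabeledExpressionMatrix:
    """Cells x genes expression with identifiers and optional cell-type labels.

    ``normalized`` records whether log + min-max has been applied; the
    transform refuses to run twice (min-max is not idempotent and a second
    application would silently rescale).
    ``source`` optionally tracks per-cell dataset provenance for
    leave-one-dataset-out experiments.
    """

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    labels: np.ndarray | None = None
    normalized: bool = False
    source: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x genes)")
        m, g = self.values.shape
        if len(self.cell_ids) != m:
            raise ValueError("cell_ids length does not match number of rows")
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match number of columns")
        if len(set(self.cell_ids)) != m:
            raise ValueError("duplicate cell_ids")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != m:
                raise ValueError("labels length does not match number of cells")
        if self.source is not None:
            self.source = np.asarray(self.source, dtype=object)
            if len(self.source) != m:
                raise ValueError("source length does not match number of cells")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def subset_cells(self, idx: np.ndarray) -> "LabeledExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            cell_ids=[self.cell_ids[i] for i in idx],
            labels=None if self.labels is None else self.labels[idx],
            source=None if self.source is None else self.source[idx],
        )

    def subset_genes(self, idx: np.ndarray) -> "LabeledExpressionMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[:, idx],
            gene_ids=[self.gene_ids[i] for i in idx],
        )


@dataclass
class SplitIndices:
    """Disjoint train/validation/test cell indices plus the seed that made them."""

    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [np.asarray(p, dtype=np.int64) for p in (self.train, self.validation, self.test)]
        self.train, self.validation, self.test = parts
        all_idx = np.concatenate(parts)
        if len(np.unique(all_idx)) != len(all_idx):
            raise ValueError("split index sets overlap")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps({
            "seed": int(self.seed),
            "train": self.train.tolist(),
            "validation": self.validation.tolist(),
            "test": self.test.tolist(),
        }))

    @classmethod
    def from_json(cls, path) -> "SplitIndices":
        d = json.loads(Path(path).read_text())
        return cls(train=np.array(d["train"]), validation=np.array(d["validation"]),
                   test=np.array(d["test"]), seed=d["seed"])


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_dense(path, label_column: str = "label",
               genes_in_rows: bool = False) -> LabeledExpressionMatrix:
    """Dense delimited text: header = gene names, first column = cell IDs,
    optional label column.  ``genes_in_rows`` transposes gene-major files."""
    table = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if genes_in_rows:
        table = table.T
    labels = None
    if label_column in table.columns:
        labels = table.pop(label_column).to_numpy(dtype=object)
    return LabeledExpressionMatrix(
        values=table.to_numpy(dtype=float),
        cell_ids=[str(c) for c in table.index],
        gene_ids=[str(g) for g in table.columns],
        labels=labels,
    )


def read_mtx_dir(directory, genes_in_rows: bool = True) -> LabeledExpressionMatrix:
    """Matrix Market directory: matrix.mtx + genes.tsv + barcodes.tsv
    [+ labels.tsv].  The conventional 10x orientation stores genes in rows."""
    directory = Path(directory)
    mat = scipy.io.mmread(directory / "matrix.mtx")
    if sp.issparse(mat):
        mat = mat.toarray()
    mat = np.asarray(mat, dtype=float)
    if genes_in_rows:
        mat = mat.T
    genes = pd.read_csv(directory / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(directory / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    labels = None
    labels_path = directory / "labels.tsv"
    if labels_path.exists():
        labels = pd.read_csv(labels_path, sep="\t", header=None)[0].astype(str).to_numpy(dtype=object)
    return LabeledExpressionMatrix(values=mat, cell_ids=cells, gene_ids=genes, labels=labels)


def read_expression(path, **kwargs) -> LabeledExpressionMatrix:
    """Dispatch on path type: directory -> Matrix Market layout, file -> dense text."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression input not found: {path}")
    if path.is_dir():
        return read_mtx_dir(path, **kwargs)
    return read_dense(path, **kwargs)


def write_mtx_dir(data: LabeledExpressionMatrix, directory) -> None:
    """Write the Matrix Market layout that :func:`read_mtx_dir` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(directory / "matrix.mtx"), sp.csr_matrix(data.values.T))
    pd.Series(data.gene_ids).to_csv(directory / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(data.cell_ids).to_csv(directory / "barcodes.tsv", sep="\t", index=False, header=False)
    if data.labels is not None:
        pd.Series(data.labels).to_csv(directory / "labels.tsv", sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Pipeline operations
# ---------------------------------------------------------------------------

def filter_cells(data: LabeledExpressionMatrix,
                 exclude_labels: Iterable[str] = DEFAULT_EXCLUDE_LABELS,
                 ) -> LabeledExpressionMatrix:
    """Drop cells with missing labels or labels in ``exclude_labels``
    (case-insensitive), preserving cell order."""
    if data.labels is None:
        raise ValueError("filter_cells requires labels")
    excluded = {str(lab).lower() for lab in exclude_labels}
    keep = np.array([
        lab is not None and not (isinstance(lab, float) and np.isnan(lab))
        and str(lab).lower() not in excluded
        for lab in data.labels
    ])
    if not keep.any():
        raise ValueError("all cells removed by label filtering")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_cells: dropped %d of %d cells", n_drop, data.n_cells)
    return data.subset_cells(np.flatnonzero(keep))


def filter_genes(data: LabeledExpressionMatrix) -> LabeledExpressionMatrix:
    """Drop genes with zero expression in every cell, preserving gene order."""
    keep = np.flatnonzero((data.values != 0).any(axis=0))
    if keep.size == 0:
        warnings.warn("all genes have zero expression", stacklevel=2)
    if keep.size < data.n_genes:
        logger.info("filter_genes: dropped %d of %d genes",
                    data.n_genes - keep.size, data.n_genes)
    return data.subset_genes(keep)


def log_and_minmax(data: LabeledExpressionMatrix) -> LabeledExpressionMatrix:
    """log2(x+1), then per-gene min-max to [0, 1]; constant genes map to 0.

    Refuses data already normalized — min-max is not idempotent.
    """
    if data.normalized:
        raise ValueError("data is already log/min-max normalized; refusing to re-apply")
    if (data.values < 0).any():
        raise ValueError("negative expression values")
    v = np.log2(data.values + 1.0)
    lo = v.min(axis=0)
    hi = v.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    v = (v - lo) / safe
    v[:, span == 0] = 0.0
    return replace(data, values=v, normalized=True)


def select_top_variant_genes(data: LabeledExpressionMatrix, n: int = 1000,
                             ) -> tuple[LabeledExpressionMatrix, list[str]]:
    """Keep the ``min(n, G)`` highest-variance genes, in descending-variance
    order (ties broken by gene id); that order is the canonical node order."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    variances = data.values.var(axis=0)
    # lexicographic tie-break: sort by (-variance, gene_id)
    order = sorted(range(data.n_genes), key=lambda i: (-variances[i], data.gene_ids[i]))
    keep = order[: min(n, data.n_genes)]
    out = data.subset_genes(np.array(keep))
    return out, list(out.gene_ids)


def split_data(data: LabeledExpressionMatrix,
               fractions: Sequence[float] = (0.8, 0.1, 0.1),
               seed: int = 0, stratified: bool = True) -> SplitIndices:
    """Stratified 80/10/10 split: each class is split independently, with at
    least one cell in validation and test for classes of >= 3 members;
    classes of < 3 members are confined to train with a warning."""
    if len(fractions) != 3 or not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must be three numbers summing to 1")
    rng = np.random.default_rng(seed)
    m = data.n_cells
    if not stratified or data.labels is None:
        perm = rng.permutation(m)
        n_val = int(round(fractions[1] * m))
        n_test = int(round(fractions[2] * m))
        return SplitIndices(train=np.sort(perm[n_val + n_test:]),
                            validation=np.sort(perm[:n_val]),
                            test=np.sort(perm[n_val:n_val + n_test]), seed=seed)
    train, val, test = [], [], []
    for cls in sorted(set(data.labels)):
        idx = np.flatnonzero(data.labels == cls)
        idx = rng.permutation(idx)
        if len(idx) < 3:
            warnings.warn(f"class {cls!r} has only {len(idx)} cells; kept in train only",
                          stacklevel=2)
            train.extend(idx)
            continue
        n_val = max(1, int(round(fractions[1] * len(idx))))
        n_test = max(1, int(round(fractions[2] * len(idx))))
        val.extend(idx[:n_val])
        test.extend(idx[n_val:n_val + n_test])
        train.extend(idx[n_val + n_test:])
    return SplitIndices(train=np.sort(np.array(train)),
                        validation=np.sort(np.array(val)),
                        test=np.sort(np.array(test)), seed=seed)


def combine_datasets(datasets: Sequence[LabeledExpressionMatrix],
                     shared_labels: Iterable[str]) -> LabeledExpressionMatrix:
    """Normalize each dataset independently, keep cells with shared labels,
    inner-join genes, and stack; per-cell provenance is retained."""
    shared = {str(lab).lower() for lab in shared_labels}
    if len(datasets) < 2:
        raise ValueError("combine_datasets needs at least 2 datasets")
    if not shared:
        raise ValueError("shared_labels is empty")

    common: set[str] | None = None
    for d in datasets:
        common = set(d.gene_ids) if common is None else common & set(d.gene_ids)
    if not common:
        raise ValueError("datasets share no genes")
    # deterministic gene order: order of appearance in the first dataset
    gene_order = [g for g in datasets[0].gene_ids if g in common]

    blocks, cells, labels, sources = [], [], [], []
    for i, d in enumerate(datasets):
        name = f"dataset{i}"
        dn = d if d.normalized else log_and_minmax(d)
        if dn.labels is None:
            raise ValueError(f"{name} has no labels")
        keep = np.flatnonzero([str(lab).lower() in shared for lab in dn.labels])
        if keep.size == 0:
            warnings.warn(f"{name} contributes no cells with the shared labels",
                          stacklevel=2)
            continue
        dn = dn.subset_cells(keep)
        col = {g: j for j, g in enumerate(dn.gene_ids)}
        dn = dn.subset_genes(np.array([col[g] for g in gene_order]))
        blocks.append(dn.values)
        cells.extend(f"{name}:{c}" for c in dn.cell_ids)
        labels.extend(dn.labels)
        sources.extend([name] * dn.n_cells)
    if not blocks:
        raise ValueError("no dataset contributed any cells")
    return LabeledExpressionMatrix(
        values=np.vstack(blocks), cell_ids=cells, gene_ids=gene_order,
        labels=np.array(labels, dtype=object), normalized=True,
        source=np.array(sources, dtype=object),
    )


def centroid_distance_density(data: LabeledExpressionMatrix, grid_size: int = 512,
                              ) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray | None]]:
    """Euclidean distances between class centroids and a Gaussian KDE curve.

    A dataset whose centroids sit close together (density mass near zero) has
    cell populations that are hard to separate.  Returns the pairwise distance
    vector and ``(grid, density)``; density is None when a KDE is undefined
    (fewer than 2 distances, or all distances equal).
    """
    if data.labels is None:
        raise ValueError("labels required")
    classes = sorted(set(data.labels))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    centroids = np.stack([data.values[data.labels == c].mean(axis=0) for c in classes])
    dists = []
    for i in range(len(classes)):
        for j in range(i + 1, len(classes)):
            dists.append(float(np.linalg.norm(centroids[i] - centroids[j])))
    dists = np.array(dists)
    grid = np.linspace(0.0, max(dists.max() * 1.1, 1e-9), grid_size)
    if len(dists) < 2 or np.ptp(dists) == 0:
        warnings.warn("too few distinct centroid distances for a density estimate",
                      stacklevel=2)
        return dists, (grid, None)
    kde = gaussian_kde(dists)  # Scott's rule bandwidth
    return dists, (grid, kde(grid))
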