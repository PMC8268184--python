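"""Synthetic labeled scRNA-seq data with a planted gene-module graph.

The generator emulates the data regime the classifier targets: class-labeled
cells whose discriminative signal is partly localized on modules of a known
gene graph (where a spectral filter can aggregate it) and partly spread over
isolated genes, with negative-binomial overdispersion and Bernoulli dropout
supplying the zero inflation and heavy right tail of droplet counts.

Genes split into ``n_modules`` connected blocks plus a reserved singleton
remainder.  Each class elevates the mean of its designated modules and a few
global (off-graph) genes by ``2**log_fold_change``.  Counts are gamma-Poisson
(NB) with variance mu + dispersion * mu^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .graph import Edge, GeneGraph, build_gene_graph, write_edge_list
from .preprocess import (LabeledExpressionMatrix, SplitIndices, filter_genes,
                         log_and_minmax, select_top_variant_genes, split_data,
                         write_mtx_dir)


@dataclass
class SyntheticSpec:
    """Generator settings; defaults give 4 moderately separable classes of
    250 cells each over 200 genes, 10 graph modules of 15 genes, ~25%
    singleton genes, and 30% dropout."""

    n_genes: int = 200
    n_cells: int = 1000
    n_classes: int = 4
    n_modules: int = 10
    module_size: int = 15
    singleton_fraction: float = 0.25
    within_module_edge_prob: float = 0.6
    signal_modules_per_class: int = 2
    global_signal_genes_per_class: int = 5
    log_fold_change: float = 1.5
    nb_dispersion: float = 0.3
    dropout_prob: float = 0.3
    base_mean: float = 5.0
    seed: int = 0
    class_proportions: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules * module_size exceeds n_genes")
        for name in ("singleton_fraction", "within_module_edge_prob", "dropout_prob"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.class_proportions is not None:
            props = tuple(self.class_proportions)
            if len(props) != self.n_classes or not np.isclose(sum(props), 1.0):
                raise ValueError("class_proportions must have n_classes entries summing to 1")
            self.class_proportions = props

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((spec.seed, stream)))


def generate_graph(spec: SyntheticSpec) -> tuple[list[Edge], np.ndarray]:
    """Planted-module gene graph.

    Genes are partitioned into modules of ``module_size``; at least
    ``singleton_fraction`` of genes are reserved with no edges at all.
    Within-module edges are Bernoulli(``within_module_edge_prob``) with
    uniform weights in [0.4, 1.0].  Returns (edge list, module index per
    gene; -1 for off-module genes).
    """
    rng = _rng(spec, 1)
    n = spec.n_genes
    n_reserved = max(int(np.ceil(spec.singleton_fraction * n)),
                     n - spec.n_modules * spec.module_size)
    n_connected = n - n_reserved
    n_modules = min(spec.n_modules, n_connected // spec.module_size)
    gene_ids = spec.gene_ids
    modules = np.full(n, -1, dtype=int)
    edges: list[Edge] = []
    for m in range(n_modules):
        lo = m * spec.module_size
        members = range(lo, lo + spec.module_size)
        for i in members:
            modules[i] = m
        for i in members:
            for j in members:
                if j <= i:
                    continue
                if rng.random() < spec.within_module_edge_prob:
                    w = rng.uniform(0.4, 1.0)
                    edges.append((gene_ids[i], gene_ids[j], float(w)))
    return edges, modules


def signal_assignment(spec: SyntheticSpec, modules: np.ndarray) -> list[np.ndarray]:
    """Per-class planted signal genes: the class's designated modules plus its
    off-module ("global") genes.  Deterministic given the spec seed, so tests
    can recover the ground truth independently of the count sampling."""
    rng = _rng(spec, 3)
    module_ids = list(range(modules.max() + 1))
    off_module = np.flatnonzero(modules == -1)
    module_perm = rng.permutation(module_ids) if module_ids else np.array([], dtype=int)
    off_perm = rng.permutation(off_module)
    signal_genes: list[np.ndarray] = []
    for c in range(spec.n_classes):
        picked = []
        if module_ids:
            start = (c * spec.signal_modules_per_class) % len(module_ids)
            picked = module_perm[start: start + spec.signal_modules_per_class]
        genes = np.flatnonzero(np.isin(modules, picked))
        globals_c = np.array([], dtype=int)
        if len(off_perm) and spec.global_signal_genes_per_class:
            g0 = (c * spec.global_signal_genes_per_class) % len(off_perm)
            globals_c = off_perm[g0: g0 + spec.global_signal_genes_per_class]
        signal_genes.append(np.concatenate([genes, globals_c]).astype(int))
    return signal_genes


def generate_expression(spec: SyntheticSpec, modules: np.ndarray,
                        ) -> LabeledExpressionMatrix:
    """Raw counts + labels with class signal planted on modules and a few
    off-module genes; downstream preprocessing applies log/min-max."""
    rng = _rng(spec, 2)
    n, m = spec.n_genes, spec.n_cells
    k = spec.n_classes

    # balanced (or specified) class assignment, shuffled
    props = spec.class_proportions or tuple([1.0 / k] * k)
    counts = np.floor(np.asarray(props) * m).astype(int)
    counts[: m - counts.sum()] += 1
    y = rng.permutation(np.repeat(np.arange(k), counts))

    signal_genes = signal_assignment(spec, modules)

    mean = np.full((m, n), spec.base_mean)
    fold = 2.0 ** spec.log_fold_change
    for c in range(k):
        rows = np.flatnonzero(y == c)
        mean[np.ix_(rows, signal_genes[c])] *= fold

    if spec.nb_dispersion > 0:
        shape = 1.0 / spec.nb_dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    values = rng.poisson(lam).astype(float)
    if spec.dropout_prob > 0:
        values *= rng.random((m, n)) >= spec.dropout_prob

    width = len(str(m - 1))
    return LabeledExpressionMatrix(
        values=values,
        cell_ids=[f"cell{i:0{width}d}" for i in range(m)],
        gene_ids=spec.gene_ids,
        labels=np.array([f"type{c}" for c in y], dtype=object),
    )


def make_fixture(spec: SyntheticSpec, top_n: int | None = None):
    """Full pipeline fixture: counts -> filters -> log/min-max -> variance-
    ranked gene selection -> stratified split, with the graph restricted and
    reordered to the selected genes.

    Returns (train, val, test, GeneGraph, SplitIndices).
    """
    edges, modules = generate_graph(spec)
    data = generate_expression(spec, modules)
    data = filter_genes(data)
    data = log_and_minmax(data)
    data, gene_order = select_top_variant_genes(data, top_n or spec.n_genes)
    split = split_data(data, seed=spec.seed)
    graph = build_gene_graph(edges, gene_order)
    return (data.subset_cells(split.train), data.subset_cells(split.validation),
            data.subset_cells(split.test), graph, split)


def write_fixture(spec: SyntheticSpec, directory) -> None:
    """Write raw counts (MTX + TSVs) and the edge list in the on-disk formats
    the preprocess/graph readers consume, for CLI round-trip tests."""
    directory = Path(directory)
    edges, modules = generate_graph(spec)
    data = generate_expression(spec, modules)
    write_mtx_dir(data, directory)
    write_edge_list(directory / "edges.tsv", edges)
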