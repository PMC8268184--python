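import numpy as np
import pytest
import scipy.sparse as sp

import cellgcn as cg


def random_gene_graph(rng: np.random.Generator, n: int, edge_prob: float = 0.3) -> cg.GeneGraph:
    """Random undirected weighted graph via the package's own builder."""
    gene_ids = [f"g{i}" for i in range(n)]
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < edge_prob:
                edges.append((gene_ids[i], gene_ids[j], float(rng.uniform(0.1, 1.0))))
    return cg.build_gene_graph(edges, gene_ids)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic dataset run through the full preprocessing
    pipeline; shared across tests that only read it."""
    return cg.make_fixture(cg.SyntheticSpec())


@pytest.fixture(scope="session")
def trained_default(default_fixture):
    """One 50-epoch training run on the default fixture (seed 0)."""
    train, val, test, graph, split = default_fixture
    lap = cg.scaled_laplacian(graph)
    config = cg.ModelConfig(n_genes=train.n_genes, n_classes=4, seed=0)
    model, history = cg.train(train, val, lap, config)
    return model, history, lap


def tiny_model_setup(seed=0, n=16, k=3, f=2, p=4, n_classes=3, batch=6):
    """Small random model + graph + batch for gradient and arithmetic checks."""
    rng = np.random.default_rng(seed)
    graph = random_gene_graph(rng, n, edge_prob=0.4)
    lap = cg.scaled_laplacian(graph)
    config = cg.ModelConfig(n_genes=n, cheb_order=k, n_filters=f, pool_size=p,
                            gcn_embed_dim=8, nn_hidden_dims=(12, 8),
                            n_classes=n_classes, seed=seed)
    model = cg.SigGCNModel(config, [f"c{i}" for i in range(n_classes)])
    x = rng.uniform(0, 1, size=(batch, n))
    y = rng.integers(0, n_classes, size=batch)
    return model, lap, x, y
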