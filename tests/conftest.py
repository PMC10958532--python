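import numpy as np
import pytest

from scfactor.genesets import (
    GLOBAL_SCOPE,
    GeneSetCollection,
    GeneVocabulary,
    WeightedGeneGraph,
    build_graph,
    restrict_to_vocabulary,
)
from scfactor.model import CountMatrix, ModelHyperparams, ModelParams


def make_vocab(p: int) -> GeneVocabulary:
    return GeneVocabulary.from_iterable([f"g{i}" for i in range(p)])


def random_params(
    rng: np.random.Generator,
    cell_types: np.ndarray,
    p: int,
    K: int = 3,
    K_c: dict | int = 1,
    type_names: tuple | None = None,
) -> ModelParams:
    """Valid random ModelParams over the given cells/genes."""
    if type_names is None:
        seen = []
        for t in cell_types:
            if t not in seen:
                seen.append(t)
        type_names = tuple(seen)
    theta = {GLOBAL_SCOPE: rng.dirichlet(np.ones(K), size=p)}
    g = {GLOBAL_SCOPE: rng.random(p)}
    B = {GLOBAL_SCOPE: rng.random((K, K))}
    kappa = {GLOBAL_SCOPE: 0.01}
    rho = {GLOBAL_SCOPE: 0.02}
    alpha = {}
    for ct in type_names:
        kc = K_c[ct] if isinstance(K_c, dict) else K_c
        n_ct = int(np.sum(cell_types == ct))
        alpha[ct] = rng.random((n_ct, K + kc)) * 2
        if kc > 0:
            theta[ct] = rng.dirichlet(np.ones(kc), size=p)
            g[ct] = rng.random(p)
            B[ct] = rng.random((kc, kc))
            kappa[ct] = 0.01
            rho[ct] = 0.02
    return ModelParams(
        theta=theta, g=g, B=B, kappa=kappa, rho=rho, alpha=alpha,
        cell_types=np.asarray(cell_types), type_names=type_names,
    )


@pytest.fixture
def small_instance():
    """5-gene, 6-cell, 2-cell-type instance with a prior graph."""
    rng = np.random.default_rng(42)
    p = 5
    vocab = make_vocab(p)
    genes = list(vocab.genes)
    coll = restrict_to_vocabulary(
        GeneSetCollection(
            {GLOBAL_SCOPE: {"s0": genes[:3]}, "T": {"sT": genes[2:5]}}
        ),
        vocab,
    )
    graphs = build_graph(coll, vocab)
    cell_types = np.array(["T", "T", "T", "B", "B", "B"])
    X = CountMatrix(
        X=rng.poisson(2.0, size=(6, p)).astype(float),
        cell_types=cell_types,
        vocab=vocab,
    )
    hyper = ModelHyperparams(K=2, K_c={"T": 2, "B": 1}, lambda_c=0.1, kappa=0.01, rho=0.02)
    params = random_params(rng, cell_types, p, K=2, K_c={"T": 2, "B": 1})
    return X, graphs, coll, hyper, params


@pytest.fixture
def single_scope_instance():
    """One cell type, global factors only — the textbook model."""
    rng = np.random.default_rng(3)
    p, n, K = 8, 10, 3
    vocab = make_vocab(p)
    genes = list(vocab.genes)
    coll = restrict_to_vocabulary(
        GeneSetCollection({GLOBAL_SCOPE: {"a": genes[:4], "b": genes[4:8]}}), vocab
    )
    graphs = build_graph(coll, vocab, weighting="uniform")
    X = CountMatrix(
        X=rng.poisson(1.5, size=(n, p)).astype(float) + 0.01,
        cell_types=np.array(["all"] * n),
        vocab=vocab,
    )
    hyper = ModelHyperparams(K=K, K_c=0, lambda_c=0.05, kappa=0.001, rho=0.01)
    params = random_params(rng, X.cell_types, p, K=K, K_c=0)
    return X, graphs, coll, hyper, params
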