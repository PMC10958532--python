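"""Objective components against independent scalar-loop oracles."""

import numpy as np
import pytest

from scfactor.genesets import GLOBAL_SCOPE
from scfactor.model import (
    CountMatrix,
    ModelHyperparams,
    ModelParams,
    edge_probability,
    edge_probability_matrix,
    expected_expression,
    expected_matrix,
    graph_objective,
    reconstruction_objective,
    total_objective,
)
from conftest import make_vocab, random_params


# ---------------------------------------------------------------------------
# independent oracles: plain Python loops, no shared code with the package


def oracle_mu(params, hyper, i):
    ct = params.cell_types[i]
    row = list(np.flatnonzero(params.cell_types == ct)).index(i)
    al = params.alpha[ct][row]
    K = params.K
    p = params.theta[GLOBAL_SCOPE].shape[0]
    mu = np.zeros(p)
    for j in range(p):
        for k in range(K):
            mu[j] += (params.g[GLOBAL_SCOPE][j] + hyper.delta) * al[k] * params.theta[GLOBAL_SCOPE][j, k]
        if params.k_specific(ct) > 0:
            for k in range(params.k_specific(ct)):
                mu[j] += (params.g[ct][j] + hyper.delta) * al[K + k] * params.theta[ct][j, k]
    return mu


def oracle_recon(X, params, hyper):
    total = 0.0
    for i in range(X.n_cells):
        lam = hyper.lambda_for(params.cell_types[i])
        mu = oracle_mu(params, hyper, i)
        for j in range(X.n_genes):
            total += lam * (X.X[i, j] * np.log(max(mu[j], 1e-12)) - mu[j])
    return total


def oracle_graph(graphs, params, hyper):
    total = 0.0
    for scope in graphs.scope_names():
        if scope not in params.theta:
            continue
        th, B = params.theta[scope], params.B[scope]
        kap, rho = params.kappa[scope], params.rho[scope]
        w = graphs.weights[scope]
        A = (w > 0).astype(float)
        p = th.shape[0]
        for i in range(p):
            for j in range(p):
                if i == j:
                    continue
                s = float(th[i] @ B @ th[j])
                p1 = (1 - kap) * (1 - rho) * s + kap * (1 - rho)
                p0 = (1 - kap) * (1 - rho) * (1 - s) + rho
                total += w[i, j] * A[i, j] * np.log(max(p1, 1e-12))
                total += (1 - A[i, j]) * np.log(max(p0, 1e-12))
    return total


class TestExpectedExpression:
    def test_zero_loadings_give_zero(self):
        params = random_params(np.random.default_rng(0), np.array(["a"] * 2), p=4, K=1, K_c=1)
        params.alpha["a"][:] = 0.0
        hyper = ModelHyperparams(K=1, K_c=1)
        assert np.allclose(expected_expression(params, hyper, 0), 0.0)

    def test_plugin_value(self):
        # theta_j = 1 (K=1), g_j = 0, delta = 1, alpha_global = 2, alpha_specific = 0
        params = random_params(np.random.default_rng(0), np.array(["a"]), p=1, K=1, K_c=1)
        params.theta[GLOBAL_SCOPE][:] = 1.0
        params.theta["a"][:] = 1.0
        params.g[GLOBAL_SCOPE][:] = 0.0
        params.alpha["a"][:] = [[2.0, 0.0]]
        hyper = ModelHyperparams(K=1, K_c=1, delta=1.0)
        assert expected_expression(params, hyper, 0)[0] == pytest.approx(2.0)

    def test_matches_loop_oracle(self, small_instance):
        X, graphs, coll, hyper, params = small_instance
        for i in range(X.n_cells):
            assert np.allclose(expected_expression(params, hyper, i), oracle_mu(params, hyper, i), atol=1e-12)

    def test_out_of_range_index(self, small_instance):
        X, graphs, coll, hyper, params = small_instance
        with pytest.raises(IndexError):
            expected_expression(params, hyper, 99)


class TestEdgeProbability:
    def test_full_support(self):
        e1 = np.array([1.0, 0.0])
        assert edge_probability(e1, e1, np.eye(2), 0.0, 0.0) == pytest.approx(1.0)

    def test_orthogonal(self):
        e1, e2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert edge_probability(e1, e2, np.eye(2), 0.0, 0.0) == pytest.approx(0.0)

    def test_background_only(self):
        e1, e2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        assert edge_probability(e1, e2, np.eye(2), 0.1, 0.2) == pytest.approx(0.08)

    def test_rates_out_of_range(self):
        e1 = np.array([1.0])
        with pytest.raises(ValueError):
            edge_probability(e1, e1, np.eye(1), 1.0, 0.0)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            K = rng.integers(1, 5)
            th = rng.dirichlet(np.ones(K), size=6)
            B = rng.random((K, K))
            kap, rho = rng.random() * 0.9, rng.random() * 0.9
            p1, p0 = edge_probability_matrix(th, B, kap, rho)
            assert np.all(np.abs(p1 + p0 - 1.0) < 1e-12)


class TestObjectives:
    def test_recon_all_zero_counts(self, small_instance):
        X, graphs, coll, hyper, params = small_instance
        X0 = CountMatrix(X=np.zeros_like(X.X), cell_types=X.cell_types, vocab=X.vocab)
        mu = expected_matrix(params, hyper)
        lam_mu = sum(
            hyper.lambda_for(ct) * mu[params.cells_of_type(ct)].sum()
            for ct in params.type_names
        )
        assert reconstruction_objective(X0, params, hyper) == pytest.approx(-lam_mu)

    def test_recon_plugin(self):
        # one cell, one gene, X = 2, mu = 2 -> 2 log 2 - 2
        params = random_params(np.random.default_rng(0), np.array(["a"]), p=1, K=1, K_c=0)
        params.theta[GLOBAL_SCOPE][:] = 1.0
        params.g[GLOBAL_SCOPE][:] = 1.0
        params.alpha["a"][:] = 2.0
        hyper = ModelHyperparams(K=1, K_c=0, lambda_c=1.0, delta=0.0)
        X = CountMatrix(X=np.array([[2.0]]), cell_types=np.array(["a"]),
                        vocab=make_vocab(1))
        assert reconstruction_objective(X, params, hyper) == pytest.approx(2 * np.log(2) - 2)

    def test_recon_matches_loop_oracle(self, small_instance):
        X, graphs, coll, hyper, params = small_instance
        assert reconstruction_objective(X, params, hyper) == pytest.approx(
            oracle_recon(X, params, hyper), abs=1e-10
        )

    def test_graph_matches_loop_oracle(self, small_instance):
        X, graphs, coll, hyper, params = small_instance
        assert graph_objective(graphs, params, hyper) == pytest.approx(
            oracle_graph(graphs, params, hyper), abs=1e-10
        )

    def test_graph_empty_zero(self):
        # empty graph, kappa = rho = 0, theta'B theta = 0 -> all log(1) = 0
        from scfactor.genesets import WeightedGeneGraph

        rng = np.random.default_rng(1)
        p, K = 4, 2
        params = random_params(rng, np.array(["a"] * 3), p=p, K=K, K_c=0)
        params.theta[GLOBAL_SCOPE] = np.tile(np.array([1.0, 0.0]), (p, 1))
        params.B[GLOBAL_SCOPE] = np.zeros((K, K))
        params.kappa[GLOBAL_SCOPE] = 0.0
        params.rho[GLOBAL_SCOPE] = 0.0
        graphs = WeightedGeneGraph(vocab=make_vocab(p), weights={GLOBAL_SCOPE: np.zeros((p, p))})
        hyper = ModelHyperparams(K=K, K_c=0)
        assert graph_objective(graphs, params, hyper) == 0.0

    def test_graph_single_edge_log_half(self):
        from scfactor.genesets import WeightedGeneGraph

        p, K = 2, 2
        params = random_params(np.random.default_rng(0), np.array(["a"]), p=p, K=K, K_c=0)
        params.theta[GLOBAL_SCOPE] = np.array([[1.0, 0.0], [1.0, 0.0]])
        params.B[GLOBAL_SCOPE] = np.diag([0.5, 0.0])
        params.kappa[GLOBAL_SCOPE] = 0.0
        params.rho[GLOBAL_SCOPE] = 0.0
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        graphs = WeightedGeneGraph(vocab=make_vocab(p), weights={GLOBAL_SCOPE: w})
        hyper = ModelHyperparams(K=K, K_c=0)
        # both ordered pairs contribute log 0.5
        assert graph_objective(graphs, params, hyper) == pytest.approx(2 * np.log(0.5))

    def test_total_is_sum_of_parts(self, small_instance):
        X, graphs, coll, hyper, params = small_instance
        assert total_objective(X, graphs, params, hyper) == pytest.approx(
            reconstruction_objective(X, params, hyper) + graph_objective(graphs, params, hyper)
        )

    def test_total_reduces_to_graph_when_lambda_zero(self, small_instance):
        X, graphs, coll, hyper, params = small_instance
        hyper0 = ModelHyperparams(K=hyper.K, K_c=hyper.K_c, lambda_c=0.0,
                                  kappa=hyper.kappa, rho=hyper.rho)
        assert total_objective(X, graphs, params, hyper0) == pytest.approx(
            graph_objective(graphs, params, hyper0)
        )


class TestInvariances:
    def test_graph_objective_permutation_invariant(self, single_scope_instance):
        X, graphs, coll, hyper, params = single_scope_instance
        base = graph_objective(graphs, params, hyper)
        perm = np.array([2, 0, 1])
        permuted = params.copy()
        permuted.theta[GLOBAL_SCOPE] = params.theta[GLOBAL_SCOPE][:, perm]
        permuted.B[GLOBAL_SCOPE] = params.B[GLOBAL_SCOPE][np.ix_(perm, perm)]
        assert graph_objective(graphs, permuted, hyper) == pytest.approx(base, rel=1e-12)

    def test_poisson_loss_scales_linearly(self, single_scope_instance):
        # scaling (X, mu) by phi multiplies objective differences by phi
        X, graphs, coll, hyper, params = single_scope_instance
        rng = np.random.default_rng(11)
        params2 = random_params(rng, X.cell_types, X.n_genes, K=hyper.K, K_c=0)
        phi = 3.0
        d_unscaled = reconstruction_objective(X, params, hyper) - reconstruction_objective(
            X, params2, hyper
        )
        Xs = CountMatrix(X=phi * X.X, cell_types=X.cell_types, vocab=X.vocab)
        scaled, scaled2 = params.copy(), params2.copy()
        for q in (scaled, scaled2):
            for ct in q.alpha:
                q.alpha[ct] = q.alpha[ct] * phi  # scales mu by phi
        d_scaled = reconstruction_objective(Xs, scaled, hyper) - reconstruction_objective(
            Xs, scaled2, hyper
        )
        # X log(phi mu) - phi mu = phi[X0 log mu - mu] + X log(phi) terms that
        # cancel in the difference of two parameter settings
        assert d_scaled == pytest.approx(phi * d_unscaled, rel=1e-9)

    def test_zeroing_expressed_gene_decreases_objective(self, single_scope_instance):
        X, graphs, coll, hyper, params = single_scope_instance
        j = int(np.argmax(X.X.sum(axis=0)))
        base = total_objective(X, graphs, params, hyper)
        degenerate = params.copy()
        degenerate.theta[GLOBAL_SCOPE][j, :] = 0.0  # leaves the simplex: bypass validate
        assert total_objective(X, graphs, degenerate, hyper) < base
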