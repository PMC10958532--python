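"""Cell/gene scores, marker lists, labeling, eta classification, aggregation."""

import numpy as np
import pytest

from scfactor.genesets import GLOBAL_SCOPE, GeneSetCollection
from scfactor.model import ModelHyperparams
from scfactor.postprocess import (
    INSUFFICIENT,
    aggregate_positive,
    cell_scores,
    classify_factors,
    cross_study_entropy,
    gene_scores,
    label_factors,
    posterior_graph,
    top_markers,
)
from conftest import random_params


@pytest.fixture
def fitted(small_instance):
    X, graphs, coll, hyper, params = small_instance
    return params, hyper


class TestCellScores:
    def test_zero_theta_column_zeroes_scores(self, fitted):
        params, hyper = fitted
        params.theta[GLOBAL_SCOPE][:, 0] = 0.0  # degenerate column for the check
        cs = cell_scores(params, hyper)
        assert np.all(cs.scores[:, 0] == 0)

    def test_uniform_theta_divides_by_K(self):
        rng = np.random.default_rng(0)
        params = random_params(rng, np.array(["a"] * 4), p=6, K=3, K_c=0)
        params.theta[GLOBAL_SCOPE][:] = 1.0 / 3.0
        hyper = ModelHyperparams(K=3, K_c=0)
        cs = cell_scores(params, hyper)
        assert np.allclose(cs.scores, params.alpha["a"] / 3.0)

    def test_matches_loop_oracle_and_mask(self, fitted):
        params, hyper = fitted
        cs = cell_scores(params, hyper)
        K = params.K
        ids = cs.factor_ids
        for i, ct in enumerate(params.cell_types):
            row = list(np.flatnonzero(params.cell_types == ct)).index(i)
            for col, fid in enumerate(ids):
                scope, k = fid.split("::")
                k = int(k)
                if scope == GLOBAL_SCOPE:
                    q = params.theta[GLOBAL_SCOPE][:, k].mean()
                    expected = q * params.alpha[ct][row, k]
                elif scope == ct:
                    q = params.theta[scope][:, k].mean()
                    expected = q * params.alpha[ct][row, K + k]
                else:
                    expected = 0.0  # structural mask
                assert cs.scores[i, col] == pytest.approx(expected, abs=1e-12)

    def test_invariant_under_joint_permutation(self, single_scope_instance):
        X, graphs, coll, hyper, params = single_scope_instance
        base = cell_scores(params, hyper).scores
        perm = np.array([1, 2, 0])
        permuted = params.copy()
        permuted.theta[GLOBAL_SCOPE] = params.theta[GLOBAL_SCOPE][:, perm]
        permuted.B[GLOBAL_SCOPE] = params.B[GLOBAL_SCOPE][np.ix_(perm, perm)]
        permuted.alpha["all"] = params.alpha["all"][:, perm]
        again = cell_scores(permuted, hyper).scores
        assert np.allclose(np.sort(base, axis=1), np.sort(again, axis=1))


class TestGeneScores:
    def test_offset_zero_returns_theta(self, fitted):
        params, hyper = fitted
        gs = gene_scores(params, hyper, offset=0.0)
        for scope in params.theta:
            assert np.allclose(gs.scores[scope], params.theta[scope])

    def test_small_g_shrinks(self, fitted):
        params, hyper = fitted
        params.g[GLOBAL_SCOPE][:] = 0.0
        gs = gene_scores(params, hyper, offset=1.0)
        factor = hyper.delta / (hyper.delta + 1.0)
        assert np.allclose(gs.scores[GLOBAL_SCOPE], factor * params.theta[GLOBAL_SCOPE])

    def test_monotone_in_g(self, fitted):
        params, hyper = fitted
        lo = params.copy()
        hi = params.copy()
        lo.g[GLOBAL_SCOPE][:] = 0.2
        hi.g[GLOBAL_SCOPE][:] = 0.8
        s_lo = gene_scores(lo, hyper, offset=1.0).scores[GLOBAL_SCOPE]
        s_hi = gene_scores(hi, hyper, offset=1.0).scores[GLOBAL_SCOPE]
        positive = params.theta[GLOBAL_SCOPE] > 0
        assert np.all(s_hi[positive] > s_lo[positive])

    def test_negative_offset_rejected(self, fitted):
        params, hyper = fitted
        with pytest.raises(ValueError):
            gene_scores(params, hyper, offset=-1.0)


class TestTopMarkers:
    def test_one_hot_column_ranks_member_first(self, fitted):
        params, hyper = fitted
        params.theta[GLOBAL_SCOPE][:, 0] = 0.0
        params.theta[GLOBAL_SCOPE][3, 0] = 1.0
        gs = gene_scores(params, hyper, offset=0.0, genes=tuple(f"g{i}" for i in range(5)))
        assert top_markers(gs, GLOBAL_SCOPE, 0, top_n=1) == ["g3"]

    def test_ties_resolve_to_vocabulary_order(self, fitted):
        params, hyper = fitted
        params.theta[GLOBAL_SCOPE][:, 0] = 0.5
        params.g[GLOBAL_SCOPE][:] = 0.5
        gs = gene_scores(params, hyper, offset=0.0, genes=tuple(f"g{i}" for i in range(5)))
        assert top_markers(gs, GLOBAL_SCOPE, 0, top_n=3) == ["g0", "g1", "g2"]

    def test_matches_full_sort(self, fitted):
        params, hyper = fitted
        gs = gene_scores(params, hyper, genes=tuple(f"g{i}" for i in range(5)))
        col = gs.scores[GLOBAL_SCOPE][:, 1]
        expected = [f"g{i}" for i in sorted(range(5), key=lambda i: (-col[i], i))]
        assert top_markers(gs, GLOBAL_SCOPE, 1, top_n=5) == expected


class TestLabelFactors:
    def make_gs(self, cols, genes=None):
        """GeneScoreMatrix with prescribed global score columns."""
        from scfactor.postprocess import GeneScoreMatrix

        cols = np.asarray(cols, dtype=float)
        genes = genes or tuple(f"g{i}" for i in range(cols.shape[0]))
        return GeneScoreMatrix(scores={GLOBAL_SCOPE: cols}, offset=0.0, genes=genes)

    def test_superset_labels(self):
        p = 30
        col = np.zeros((p, 1))
        col[:25, 0] = np.linspace(1, 0.5, 25)
        gs = self.make_gs(col)
        sets = GeneSetCollection({GLOBAL_SCOPE: {"hit": [f"g{i}" for i in range(20)]}})
        labels = label_factors(gs, sets, top_n=25)
        assert labels["global::0"] == "hit"

    def test_disjoint_markers_unlabeled(self):
        p = 30
        col = np.zeros((p, 1))
        col[20:, 0] = 1.0
        gs = self.make_gs(col)
        sets = GeneSetCollection({GLOBAL_SCOPE: {"miss": [f"g{i}" for i in range(10)]}})
        labels = label_factors(gs, sets, top_n=10)
        assert labels["global::0"] is None

    def test_unique_mode_resolves_collision(self):
        # two factors chasing one set with overlaps 0.8 vs 0.6
        p = 10
        cols = np.zeros((p, 2))
        cols[:5, 0] = [5, 4, 3, 2, 1]       # markers g0..g4, overlap 4/5 with set
        cols[[0, 1, 2, 5, 6], 1] = [5, 4, 3, 2, 1]  # overlap 3/5
        gs = self.make_gs(cols)
        sets = GeneSetCollection(
            {GLOBAL_SCOPE: {"s": ["g0", "g1", "g2", "g3", "g9"]}}
        )
        loose = label_factors(gs, sets, top_n=5, unique=False)
        assert loose["global::0"] == "s" and loose["global::1"] == "s"
        strict = label_factors(gs, sets, top_n=5, unique=True)
        assert strict["global::0"] == "s"
        assert strict["global::1"] is None

    def test_unique_mode_injective(self):
        rng = np.random.default_rng(4)
        p = 40
        cols = rng.random((p, 4))
        gs = self.make_gs(cols)
        sets = GeneSetCollection(
            {GLOBAL_SCOPE: {f"s{j}": [f"g{i}" for i in rng.choice(p, 8, replace=False)]
                            for j in range(3)}}
        )
        labels = label_factors(gs, sets, top_n=10, threshold=0.0, unique=True)
        assigned = [v for v in labels.values() if v is not None]
        assert len(assigned) == len(set(assigned))


class TestClassifyFactors:
    @pytest.mark.parametrize(
        "eta,expected",
        [(0.0, "new"), (0.2499, "new"), (0.25, "modified"), (1.0, "modified")],
    )
    def test_threshold_boundary(self, eta, expected):
        assert classify_factors(np.array([eta])) == [expected]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_factors(np.array([1.5]))


class TestPosteriorGraph:
    def test_zero_interaction_gives_zero(self, fitted):
        params, hyper = fitted
        params.B[GLOBAL_SCOPE][:] = 0.0
        assert np.all(posterior_graph(params) == 0)

    def test_identity_one_hot_gives_cliques(self):
        rng = np.random.default_rng(0)
        params = random_params(rng, np.array(["a"] * 2), p=4, K=2, K_c=0)
        params.theta[GLOBAL_SCOPE] = np.array(
            [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]
        )
        params.B[GLOBAL_SCOPE] = np.eye(2)
        pg = posterior_graph(params)
        expected = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
        )
        assert np.allclose(pg, expected)

    def test_matches_loop_oracle(self, fitted):
        params, hyper = fitted
        pg = posterior_graph(params)
        th, B = params.theta[GLOBAL_SCOPE], params.B[GLOBAL_SCOPE]
        for i in range(th.shape[0]):
            for j in range(th.shape[0]):
                assert pg[i, j] == pytest.approx(float(th[i] @ B @ th[j]), abs=1e-12)


class TestAggregation:
    def test_all_zero_scores(self):
        scores = np.zeros((4, 2))
        means, fracs = aggregate_positive(scores, ["a", "a", "b", "b"])
        assert np.all(means.values == 0)
        assert np.all(fracs.values == 0)

    def test_positive_mean_and_fraction(self):
        scores = np.array([[0.0005], [0.002], [0.004]])
        means, fracs = aggregate_positive(scores, ["g", "g", "g"])
        assert means.values[0, 0] == pytest.approx(0.003)
        assert fracs.values[0, 0] == pytest.approx(2 / 3)

    def test_matches_masked_mean_oracle(self):
        rng = np.random.default_rng(2)
        scores = rng.random((30, 3)) * 0.01
        labels = rng.choice(["a", "b"], size=30)
        means, fracs = aggregate_positive(scores, labels)
        for g in ("a", "b"):
            rows = scores[labels == g]
            for k in range(3):
                pos = rows[:, k] > 0.001
                expected = rows[pos, k].mean() if pos.any() else 0.0
                assert means.loc[g][k] == pytest.approx(expected)


class TestCrossStudyEntropy:
    def test_uniform_over_8_of_19(self):
        scores = np.concatenate([np.full(8 * 50, 1.0), np.zeros(11 * 50)])
        labels = np.concatenate(
            [np.repeat([f"s{i}" for i in range(8)], 50),
             np.repeat([f"s{i}" for i in range(8, 19)], 50)]
        )
        ent = cross_study_entropy(scores, labels)
        assert ent == pytest.approx(np.log(8), abs=5e-5)
        assert ent == pytest.approx(2.0794, abs=5e-5)

    def test_single_study_zero(self):
        scores = np.full(200, 0.5)
        labels = np.array(["only"] * 200)
        assert cross_study_entropy(scores, labels) == 0.0

    def test_boundary_positive_count_is_insufficient(self):
        scores = np.concatenate([np.full(99, 1.0), np.zeros(50)])
        labels = np.array(["a"] * 149)
        assert cross_study_entropy(scores, labels, min_positive=100) == INSUFFICIENT
        # exactly min_positive is still insufficient (strict >)
        scores = np.concatenate([np.full(100, 1.0), np.zeros(50)])
        labels = np.array(["a"] * 150)
        assert cross_study_entropy(scores, labels, min_positive=100) == INSUFFICIENT

    def test_bounded_by_log_n_studies(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n_studies = rng.integers(2, 7)
            scores = rng.random(300)
            labels = rng.choice([f"s{i}" for i in range(n_studies)], 300)
            ent = cross_study_entropy(scores, labels, min_positive=10)
            if ent != INSUFFICIENT:
                assert 0 <= ent <= np.log(n_studies) + 1e-12
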