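"""End-to-end simulation studies: generate, fit, score recovery.

These routines wire the generators in :mod:`scfactor.simulate` to the
fitting and postprocessing machinery, reproducing the package's three
benchmark designs (correlated loadings, overlapping gene sets, active-set
recovery) plus the initialization-fidelity check.  They are used by the
test suite and the reproduction script; problem sizes are the study
defaults, iteration budgets are documented in docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF

from .genesets import (
    GLOBAL_SCOPE,
    GeneSetCollection,
    GeneVocabulary,
    WeightedGeneGraph,
    build_graph,
    overlap_coefficient,
    restrict_to_vocabulary,
)
from .inference import FitConfig, fit_gradient
from .model import CountMatrix, ModelHyperparams
from .postprocess import cell_scores, gene_scores, top_markers
from . import simulate as sim

__all__ = [
    "correlated_recovery",
    "overlap_bias_run",
    "active_recovery_auc",
    "init_fidelity_overlaps",
]

# moderate-budget Adam schedule for the benchmark fits (see docs/methods.md)
BENCH_SCHEDULE = (1.0, 0.5, 0.1)
BENCH_MAX_ITER = 150
BENCH_WINDOW = 50


def _expressed(counts: np.ndarray):
    """Column filter for silent genes (the model rejects zero-sum columns)."""
    keep = counts.sum(axis=0) > 0
    return keep, counts[:, keep].astype(np.float64)


def _single_type_matrix(Xm: np.ndarray, vocab: GeneVocabulary) -> CountMatrix:
    return CountMatrix(
        X=Xm, cell_types=np.array(["all"] * Xm.shape[0]), vocab=vocab
    )


@dataclass
class CorrelatedRecovery:
    model_r: float      # mean Pearson r over the correlated factor pair
    baseline_r: float   # same, for a graph-free NMF
    per_factor_model: np.ndarray
    per_factor_baseline: np.ndarray


def correlated_recovery(
    corr: float,
    seed: int,
    n: int = 20,
    p: int = 500,
    K: int = 3,
    sigma2: float = 4.0,
    lam: float = 0.1,
    max_iter: int = BENCH_MAX_ITER,
) -> CorrelatedRecovery:
    """Fit the graph-guided model and an NMF baseline on correlated-loading
    data, returning mean Pearson r for the correlated factor pair."""
    truth = sim.sim_correlated_factors(n=n, p=p, K=K, corr=corr, sigma2=sigma2, seed=seed)
    keep, Xm = _expressed(truth.counts)
    vocab = GeneVocabulary.from_iterable([f"g{i}" for i in range(Xm.shape[1])])
    A = truth.adjacency[np.ix_(keep, keep)].astype(np.float64)
    graphs = WeightedGeneGraph(vocab=vocab, weights={GLOBAL_SCOPE: A})
    X = _single_type_matrix(Xm, vocab)
    hyper = ModelHyperparams(
        K=K, K_c=0, lambda_c=lam, delta=0.0, kappa="learn", rho="learn"
    )
    config = FitConfig(
        seed=seed, max_iter=max_iter, window=BENCH_WINDOW, lr_schedule=BENCH_SCHEDULE
    )
    res = fit_gradient(X, graphs, hyper, config)
    theta_hat = res.params.theta[GLOBAL_SCOPE].T  # K x p, per-gene simplex
    truth_norm = truth.normalized_factors[:, keep]
    perm = sim.match_factors(theta_hat, truth_norm)
    r_model = sim.recovery_correlation(theta_hat, truth_norm, perm)

    nmf = NMF(n_components=K, init="nndsvda", max_iter=500, random_state=seed, tol=1e-4)
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        nmf.fit(Xm)
    H = nmf.components_
    H_norm = H / np.maximum(H.sum(axis=0), 1e-12)
    perm_n = sim.match_factors(H_norm, truth_norm)
    r_nmf = sim.recovery_correlation(H_norm, truth_norm, perm_n)
    return CorrelatedRecovery(
        model_r=float(np.nanmean(r_model[:2])),
        baseline_r=float(np.nanmean(r_nmf[:2])),
        per_factor_model=r_model,
        per_factor_baseline=r_nmf,
    )


@dataclass
class OverlapBiasRun:
    model_accuracy: float        # mean Pearson(cell score, true loading)
    averaging_false_positive: float  # set-average score vs partner loading in
                                     # cells not expressing the factor
    model_false_positive: float


def overlap_bias_run(overlap: float, seed: int, lam: float = 0.01) -> OverlapBiasRun:
    """One overlapping-gene-sets dataset: fit with the true sets as prior and
    score both the model's cell scores and plain gene-set averaging."""
    truth = sim.sim_overlap_bias(overlap=overlap, seed=seed)
    keep, Xm = _expressed(truth.counts)
    genes = [g for g, k in zip(truth.genes, keep) if k]
    gene_index = {g: i for i, g in enumerate(genes)}
    vocab = GeneVocabulary.from_iterable(genes)
    coll = restrict_to_vocabulary(GeneSetCollection({GLOBAL_SCOPE: truth.gene_sets}), vocab)
    graphs = build_graph(coll, vocab)
    X = _single_type_matrix(Xm, vocab)
    n_sets = coll.n_sets(GLOBAL_SCOPE)
    hyper = ModelHyperparams(
        K=n_sets + 1, K_c=0, lambda_c=lam, delta=0.001, kappa="learn", rho=0.001
    )
    config = FitConfig(
        seed=seed, max_iter=BENCH_MAX_ITER, window=BENCH_WINDOW, lr_schedule=BENCH_SCHEDULE
    )
    res = fit_gradient(X, graphs, hyper, config, collection=coll)
    cs = cell_scores(res.params, hyper)
    names = list(coll.sets_in_scope(GLOBAL_SCOPE))
    set_order = list(truth.gene_sets)
    acc, fp_avg, fp_model = [], [], []
    for k, name in enumerate(set_order):
        col = names.index(name)  # factor col is seeded on set `name`
        a_true = truth.loadings[:, k]
        acc.append(np.corrcoef(cs.scores[:, col], a_true)[0, 1])
        partner = k + 1 if k % 2 == 0 else k - 1
        silent = a_true == 0
        a_partner = truth.loadings[silent, partner]
        if np.std(a_partner) == 0:
            continue
        idx = [gene_index[g] for g in truth.gene_sets[name] if g in gene_index]
        avg = sim.score_genes_baseline(Xm, idx, seed=seed)
        fp_avg.append(np.corrcoef(avg[silent], a_partner)[0, 1])
        fp_model.append(np.corrcoef(cs.scores[silent, col], a_partner)[0, 1])
    return OverlapBiasRun(
        model_accuracy=float(np.mean(acc)),
        averaging_false_positive=float(np.mean(fp_avg)),
        model_false_positive=float(np.mean(fp_model)),
    )


def active_recovery_auc(
    seed: int,
    n_active: int = 10,
    lam: float = 0.01,
    spare_factors: int = 6,
) -> float:
    """AUC of mean cell scores for separating active from control gene sets,
    fitting on the corrupted sets.  ``spare_factors`` unseeded factors absorb
    the unbiased background structure (one per background factor, plus one)."""
    truth = sim.sim_active_recovery(n_active=n_active, seed=seed)
    keep, Xm = _expressed(truth.counts)
    genes = [g for g, k in zip(truth.genes, keep) if k]
    vocab = GeneVocabulary.from_iterable(genes)
    coll = restrict_to_vocabulary(
        GeneSetCollection({GLOBAL_SCOPE: truth.corrupted_sets}), vocab
    )
    graphs = build_graph(coll, vocab)
    X = _single_type_matrix(Xm, vocab)
    n_sets = coll.n_sets(GLOBAL_SCOPE)
    hyper = ModelHyperparams(
        K=n_sets + spare_factors, K_c=0, lambda_c=lam, delta=0.001,
        kappa="learn", rho=0.001,
    )
    config = FitConfig(
        seed=seed, max_iter=BENCH_MAX_ITER, window=BENCH_WINDOW, lr_schedule=BENCH_SCHEDULE
    )
    res = fit_gradient(X, graphs, hyper, config, collection=coll)
    cs = cell_scores(res.params, hyper)
    names = list(coll.sets_in_scope(GLOBAL_SCOPE))
    mean_scores = cs.scores.mean(axis=0)[: len(names)]
    labels = np.array([1 if nm in truth.active_sets else 0 for nm in names])
    return sim.auc_active_sets(mean_scores, labels)


def init_fidelity_overlaps(
    seed: int, lam: float = 1e-4, top_n: int = 20
) -> list[float]:
    """Fit clique-structured data with gene-set initialization and a small
    reconstruction weight; return each factor's marker overlap with its
    seeding set (offset 0, so markers are the factors themselves)."""
    truth = sim.sim_overlap_bias(overlap=0.0, seed=seed)
    keep, Xm = _expressed(truth.counts)
    genes = [g for g, k in zip(truth.genes, keep) if k]
    vocab = GeneVocabulary.from_iterable(genes)
    coll = restrict_to_vocabulary(GeneSetCollection({GLOBAL_SCOPE: truth.gene_sets}), vocab)
    graphs = build_graph(coll, vocab)
    X = _single_type_matrix(Xm, vocab)
    n_sets = coll.n_sets(GLOBAL_SCOPE)
    hyper = ModelHyperparams(
        K=n_sets + 1, K_c=0, lambda_c=lam, delta=0.001, kappa="learn", rho=0.001
    )
    config = FitConfig(
        seed=seed, max_iter=BENCH_MAX_ITER, window=BENCH_WINDOW, lr_schedule=BENCH_SCHEDULE
    )
    res = fit_gradient(X, graphs, hyper, config, collection=coll)
    gs = gene_scores(res.params, hyper, offset=0.0, genes=vocab.genes)
    out = []
    for k, members in enumerate(coll.sets_in_scope(GLOBAL_SCOPE).values()):
        markers = top_markers(gs, GLOBAL_SCOPE, k, top_n=top_n)
        out.append(overlap_coefficient(markers, members))
    return out
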