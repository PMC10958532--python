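"""Expectation-maximization fitting with auxiliary count and edge variables.

Each expression entry X_ij is split across factors into latent Poisson
counts z_ijk; each graph entry A_ij is explained by a pair of latent factor
assignments (k, l) for the two genes.  The E step computes their posteriors

    phi_ijk      proportional to alpha_ik * (g+delta) * theta_jk, summing to X_ij
    phitilde_ijkl proportional to theta_ik theta_jl
                  ((1-kappa)B_kl + kappa)^(w_ij A_ij)
                  ((1-kappa)(1-rho)(1-B_kl) + rho)^(1 - A_ij), summing to 1

and the M step has closed forms for alpha, g (with projection to [0, 1])
and B (through the odds ratio Xi_kl), plus damped Newton updates for the
simplex-constrained theta rows.  Auxiliary storage is O(npK + p^2 K^2), so
this route is reserved for small problems; use the gradient optimizer
otherwise.

With unit edge weights the EM target coincides with the total objective up
to an additive constant, and cycles are monotone; the weighted case
optimizes the tilted complete-data objective, which tracks the total
objective closely but not exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genesets import GLOBAL_SCOPE, GeneSetCollection, WeightedGeneGraph
from .inference import FitConfig, FitResult, initialize_params
from .model import (
    LEARN,
    LOG_FLOOR,
    CountMatrix,
    ModelHyperparams,
    ModelParams,
    total_objective,
)

logger = logging.getLogger(__name__)

__all__ = ["EMState", "em_e_step", "em_m_step", "fit_em", "EM_SIZE_LIMIT"]

EM_SIZE_LIMIT = 2e8  # auxiliary scalars: n*p*K + sum_scopes p^2 K_s^2

# fallbacks when kappa/rho are set to "learn" (the EM updates do not cover them)
EM_KAPPA_DEFAULT = 1e-5
EM_RHO_DEFAULT = 1e-3


@dataclass
class EMState:
    """Posterior responsibilities from one E step.

    phi[ct]         : n_ct x p x (K + K_ct), sums over factors to X
    phi_tilde[scope]: p x p x K_s x K_s, sums over (k, l) to 1 per ordered
                      pair i != j (diagonal pairs are zeroed)
    """

    phi: dict[str, np.ndarray]
    phi_tilde: dict[str, np.ndarray]


def resolve_rates(hyper: ModelHyperparams, scopes) -> tuple[dict, dict]:
    kappa, rho = {}, {}
    for s in scopes:
        k = hyper.kappa_for(s)
        r = hyper.rho_for(s)
        if k == LEARN:
            logger.info("EM does not update kappa; scope %r falls back to %g", s, EM_KAPPA_DEFAULT)
            k = EM_KAPPA_DEFAULT
        if r == LEARN:
            logger.info("EM does not update rho; scope %r falls back to %g", s, EM_RHO_DEFAULT)
            r = EM_RHO_DEFAULT
        kappa[s], rho[s] = float(k), float(r)
    return kappa, rho


def em_e_step(
    X: CountMatrix,
    graphs: WeightedGeneGraph | None,
    params: ModelParams,
    hyper: ModelHyperparams,
) -> EMState:
    K = params.K
    delta = hyper.delta
    phi: dict[str, np.ndarray] = {}
    Wg = params.theta[GLOBAL_SCOPE] * (params.g[GLOBAL_SCOPE] + delta)[:, None]
    for ct in params.type_names:
        idx = params.cells_of_type(ct)
        al = params.alpha[ct]
        k_tot = al.shape[1]
        num = np.empty((idx.size, X.n_genes, k_tot))
        num[:, :, :K] = al[:, None, :K] * Wg[None, :, :]
        if params.k_specific(ct) > 0:
            Ws = params.theta[ct] * (params.g[ct] + delta)[:, None]
            num[:, :, K:] = al[:, None, K:] * Ws[None, :, :]
        mu = num.sum(axis=2)
        Xc = X.X[idx]
        bad = (mu <= 0) & (Xc > 0)
        if np.any(bad):
            raise FloatingPointError(
                "degenerate parameters: zero predicted expression where counts "
                f"are positive ({int(bad.sum())} entries, cell type {ct!r})"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(mu > 0, Xc / np.where(mu > 0, mu, 1.0), 0.0)
        phi[ct] = num * ratio[:, :, None]

    phi_tilde: dict[str, np.ndarray] = {}
    if graphs is not None:
        for scope in graphs.scope_names():
            if scope not in params.theta:
                continue
            th = params.theta[scope]
            B = params.B[scope]
            kap, rh = params.kappa[scope], params.rho[scope]
            w = graphs.weights[scope]
            A = graphs.adjacency(scope)
            L1 = np.log(np.maximum((1 - kap) * B + kap, LOG_FLOOR))  # K x K
            L0 = np.log(np.maximum((1 - kap) * (1 - rh) * (1 - B) + rh, LOG_FLOOR))
            a = w * A  # exponent of the edge factor
            b = 1.0 - A
            # log phi-tilde up to per-pair normalization
            expo = np.exp(a[:, :, None, None] * L1[None, None] + b[:, :, None, None] * L0[None, None])
            pt = th[:, None, :, None] * th[None, :, None, :] * expo
            norm = pt.sum(axis=(2, 3), keepdims=True)
            pt = np.where(norm > 0, pt / np.where(norm > 0, norm, 1.0), 0.0)
            pt[np.arange(th.shape[0]), np.arange(th.shape[0])] = 0.0  # exclude i == j
            phi_tilde[scope] = pt
    return EMState(phi=phi, phi_tilde=phi_tilde)


def _theta_stats(
    state: EMState,
    params: ModelParams,
    hyper: ModelHyperparams,
    scope: str,
) -> tuple[np.ndarray, np.ndarray]:
    """(S, b) for the per-row surrogate f_j(theta_j) = sum_l S_jl log theta_jl - b_jl theta_jl."""
    K = params.K
    delta = hyper.delta
    p = params.theta[GLOBAL_SCOPE].shape[0]
    k_s = params.theta[scope].shape[1]
    S = np.zeros((p, k_s))
    b = np.zeros((p, k_s))
    if scope == GLOBAL_SCOPE:
        for ct in params.type_names:
            lam = hyper.lambda_for(ct)
            S += lam * state.phi[ct][:, :, :K].sum(axis=0)
            b += lam * (params.g[GLOBAL_SCOPE] + delta)[:, None] * params.alpha[ct][:, :K].sum(
                axis=0
            )
    else:
        lam = hyper.lambda_for(scope)
        S += lam * state.phi[scope][:, :, K:].sum(axis=0)
        b += lam * (params.g[scope] + delta)[:, None] * params.alpha[scope][:, K:].sum(axis=0)
    if scope in state.phi_tilde:
        pt = state.phi_tilde[scope]
        S += np.einsum("ijkl->jl", pt) + np.einsum("jikl->jk", pt)
    return S, b


def _newton_theta(
    theta: np.ndarray, S: np.ndarray, b: np.ndarray, steps: int
) -> np.ndarray:
    """Damped, sum-preserving Newton ascent of f_j on each simplex row."""

    def f(th):
        return np.sum(S * np.log(np.maximum(th, LOG_FLOOR)) - b * th, axis=1)

    th = theta.copy()
    for _ in range(steps):
        S_safe = np.maximum(S, 1e-12)
        gamma = S / np.maximum(th, LOG_FLOOR) - b
        Hinv = -(th**2) / S_safe
        Delta = -np.sum(gamma * Hinv, axis=1) / np.sum(Hinv, axis=1)
        step = -Hinv * (Delta[:, None] + gamma)  # preserves each row sum
        f0 = f(th)
        scale = np.ones((th.shape[0], 1))
        proposal = th + step
        for _halving in range(21):
            ok = (proposal > 0).all(axis=1) & (f(np.maximum(proposal, LOG_FLOOR)) >= f0 - 1e-12)
            if ok.all():
                break
            scale[~ok] *= 0.5
            proposal = th + scale * step
        else:
            raise FloatingPointError(
                "theta Newton backtracking exhausted 20 halvings without a feasible ascent step"
            )
        th = np.maximum(proposal, LOG_FLOOR)
    return th / th.sum(axis=1, keepdims=True)


def em_m_step(
    state: EMState,
    X: CountMatrix,
    graphs: WeightedGeneGraph | None,
    params: ModelParams,
    hyper: ModelHyperparams,
    config: FitConfig,
) -> ModelParams:
    """One M step: theta (T Newton steps), then alpha, g and B closed forms."""
    new = params.copy()
    K = params.K
    delta = hyper.delta

    # theta per scope (uses pre-update alpha and g, as in the coordinate scheme)
    for scope in params.theta:
        S, b = _theta_stats(state, params, hyper, scope)
        new.theta[scope] = _newton_theta(params.theta[scope], S, b, config.newton_steps)

    # alpha: phi totals over genes divided by scaled-theta column sums
    Wg = new.theta[GLOBAL_SCOPE] * (new.g[GLOBAL_SCOPE] + delta)[:, None]
    for ct in params.type_names:
        phi = state.phi[ct]
        denom_g = Wg.sum(axis=0)  # K
        al = new.alpha[ct]
        al[:, :K] = phi[:, :, :K].sum(axis=1) / np.maximum(denom_g, LOG_FLOOR)
        if params.k_specific(ct) > 0:
            Ws = new.theta[ct] * (new.g[ct] + delta)[:, None]
            al[:, K:] = phi[:, :, K:].sum(axis=1) / np.maximum(Ws.sum(axis=0), LOG_FLOOR)

    # g: matched phi totals over cells/factors against predicted totals
    for scope in params.theta:
        if scope == GLOBAL_SCOPE:
            num = np.zeros(X.n_genes)
            den = np.zeros(X.n_genes)
            for ct in params.type_names:
                lam = hyper.lambda_for(ct)
                num += lam * state.phi[ct][:, :, :K].sum(axis=(0, 2))
                den += lam * (new.alpha[ct][:, :K].sum(axis=0) @ new.theta[GLOBAL_SCOPE].T)
        else:
            num = state.phi[scope][:, :, K:].sum(axis=(0, 2))
            den = new.alpha[scope][:, K:].sum(axis=0) @ new.theta[scope].T
        with np.errstate(invalid="ignore", divide="ignore"):
            cand = np.where(den > 0, num / np.where(den > 0, den, 1.0) - delta, np.nan)
        g_old = new.g[scope]
        new.g[scope] = np.where(np.isnan(cand), g_old, np.clip(cand, 0.0, 1.0))

    # B: odds ratio of expected weighted-edge vs non-edge assignments
    if graphs is not None:
        for scope in graphs.scope_names():
            if scope not in params.theta:
                continue
            pt = state.phi_tilde[scope]
            w = graphs.weights[scope]
            A = graphs.adjacency(scope)
            N1 = np.einsum("ij,ijkl->kl", w * A, pt)
            N0 = np.einsum("ij,ijkl->kl", 1.0 - A, pt)
            kap, rh = params.kappa[scope], params.rho[scope]
            with np.errstate(invalid="ignore", divide="ignore"):
                Xi = np.where(N0 > 0, N1 / np.where(N0 > 0, N0, 1.0), np.inf)
                cand = ((rh / (1 - rh) + (1 - kap)) * Xi - kap) / ((1 - kap) * (1 + Xi))
            cand = np.where(np.isinf(Xi), 1.0, cand)
            cand = np.where((N0 == 0) & (N1 == 0), params.B[scope], cand)
            new.B[scope] = np.clip(cand, 0.0, 1.0)

    new.validate()
    return new


def fit_em(
    X: CountMatrix,
    graphs: WeightedGeneGraph | None,
    hyper: ModelHyperparams,
    config: FitConfig,
    collection: GeneSetCollection | None = None,
    init_params: ModelParams | None = None,
) -> FitResult:
    """Alternate E/M steps until the relative objective change drops below tol."""
    from .inference import _check_genes_expressed

    _check_genes_expressed(X)
    p = X.n_genes
    k_tot = hyper.K + max((hyper.k_for(ct) for ct in X.type_names), default=0)
    size = X.n_cells * p * k_tot
    if graphs is not None:
        for scope in graphs.scope_names():
            k_s = hyper.K if scope == GLOBAL_SCOPE else hyper.k_for(scope)
            size += p * p * k_s * k_s
    if size > EM_SIZE_LIMIT:
        raise MemoryError(
            f"EM auxiliary storage would need ~{size:.2e} scalars (> {EM_SIZE_LIMIT:.0e}); "
            "use the gradient optimizer for problems of this size"
        )

    params = init_params.copy() if init_params is not None else initialize_params(
        collection, hyper, config, X
    )
    kappa, rho = resolve_rates(hyper, params.theta.keys())
    params.kappa.update(kappa)
    params.rho.update(rho)

    tol = config.resolved_tol()
    trajectory: list[tuple[str, int, float]] = []
    value = total_objective(X, graphs, params, hyper) if graphs is not None else None
    if value is None:
        from .model import reconstruction_objective

        value = reconstruction_objective(X, params, hyper)
    trajectory.append(("em", 0, value))
    converged = False
    for cycle in range(1, config.max_iter + 1):
        state = em_e_step(X, graphs, params, hyper)
        params = em_m_step(state, X, graphs, params, hyper, config)
        if graphs is not None:
            new_value = total_objective(X, graphs, params, hyper)
        else:
            from .model import reconstruction_objective

            new_value = reconstruction_objective(X, params, hyper)
        trajectory.append(("em", cycle, new_value))
        if new_value < value - 1e-6 * abs(value):
            logger.warning(
                "EM objective decreased at cycle %d (%.10g -> %.10g)", cycle, value, new_value
            )
        if abs(new_value - value) < tol * (abs(value) + 1e-12):
            value = new_value
            converged = True
            break
        value = new_value
    return FitResult(
        params=params,
        objective_trajectory=trajectory,
        converged={"em": converged},
        hyper=hyper,
        config=config,
    )
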