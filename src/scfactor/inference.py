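"""Initialization and gradient-based fitting of the model.

Two optimizers are provided: a momentum (Adam) ascent on the total
objective over unconstrained reparameterized variables (this module), and
an expectation-maximization routine with auxiliary count/edge variables for
small problems (:mod:`scfactor.em`).

Reparameterization: theta rows through a softmax, alpha through a softplus,
and g, B, kappa, rho through a sigmoid — constraints stay implicit and the
gene-set initialization is expressed directly on the log/logit scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.decomposition import NMF

from .genesets import GLOBAL_SCOPE, GeneSetCollection, WeightedGeneGraph
from .model import (
    LEARN,
    LOG_FLOOR,
    CountMatrix,
    ModelHyperparams,
    ModelParams,
    total_objective,
)

logger = logging.getLogger(__name__)

__all__ = ["FitConfig", "FitResult", "initialize_params", "fit_gradient", "fit"]

DEFAULT_SCHEDULE = (1.0, 0.5, 0.1, 0.01, 0.001, 0.0001)


@dataclass
class FitConfig:
    """Optimizer settings.

    t            : initialization strength on the log/logit scale
    newton_steps : damped Newton iterations per EM cycle for theta
    lr_schedule  : Adam learning rates; each stage trains to convergence
                   before the next (smaller) rate starts
    max_iter     : iteration cap per learning-rate stage (gradient) or
                   total EM cycles
    tol          : relative objective-change convergence threshold; if None,
                   1e-5 for the gradient optimizer and 1e-6 for EM
    window       : iteration span over which the gradient convergence test
                   compares objective values
    """

    optimizer: str = "gradient"
    t: float = 25.0
    newton_steps: int = 5
    lr_schedule: Sequence[float] = DEFAULT_SCHEDULE
    max_iter: int = 10000
    beta1: float = 0.9
    beta2: float = 0.999
    tol: float | None = None
    window: int = 100
    seed: int = 0
    init_noise: float = 0.1

    def __post_init__(self) -> None:
        if self.optimizer not in ("gradient", "em"):
            raise ValueError("optimizer must be 'gradient' or 'em'")
        if self.t <= 0:
            raise ValueError("t must be positive")
        if self.newton_steps < 1:
            raise ValueError("newton_steps must be >= 1")
        sched = tuple(self.lr_schedule)
        if any(b >= a for a, b in zip(sched, sched[1:])) or any(x <= 0 for x in sched):
            raise ValueError("lr_schedule must be strictly decreasing and positive")
        if self.tol is not None and self.tol <= 0:
            raise ValueError("tol must be positive")

    def resolved_tol(self) -> float:
        if self.tol is not None:
            return self.tol
        return 1e-5 if self.optimizer == "gradient" else 1e-6


@dataclass
class FitResult:
    params: ModelParams
    objective_trajectory: list[tuple[str, int, float]]
    converged: dict[str, bool]
    hyper: ModelHyperparams | None = None
    config: FitConfig | None = None

    @property
    def eta(self) -> dict[str, np.ndarray]:
        return self.params.eta()

    @property
    def final_objective(self) -> float:
        return self.objective_trajectory[-1][2]


# ---------------------------------------------------------------------------
# numerics helpers


def _sigmoid(x: np.ndarray | float) -> np.ndarray | float:
    return 0.5 * (1.0 + np.tanh(0.5 * np.asarray(x, dtype=np.float64)))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _softplus_inv(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    # inverse of log(1 + e^x); stable for y >> 0
    return y + np.log1p(-np.exp(-np.maximum(y, 1e-10)))


def _softmax_rows(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


# ---------------------------------------------------------------------------
# initialization


def _scope_plan(
    collection: GeneSetCollection | None,
    hyper: ModelHyperparams,
    X: CountMatrix,
) -> dict[str, int]:
    """Scope -> factor count.  The global scope always exists; each cell type
    contributes a scope when its specific factor count is positive."""
    plan = {GLOBAL_SCOPE: hyper.K}
    for ct in X.type_names:
        k = hyper.k_for(ct)
        if k > 0:
            plan[ct] = k
    return plan


def _nmf_theta(sub: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-simplex theta (p x k) and loadings (n x k) from an NMF of a submatrix."""
    if sub.shape[0] < 1 or np.allclose(sub, 0):
        raise ValueError("NMF initialization failed: degenerate (all-zero) submatrix")
    k_eff = min(k, *sub.shape)
    model = NMF(
        n_components=k_eff, init="nndsvda", max_iter=300, random_state=seed, tol=1e-3
    )
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(sub)
    H = model.components_  # k_eff x p
    theta = H.T + 1e-6
    if k_eff < k:  # pad with uniform columns
        theta = np.hstack([theta, np.full((sub.shape[1], k - k_eff), 1e-3)])
        W = np.hstack([W, np.full((sub.shape[0], k - k_eff), 1e-3)])
    theta = theta / theta.sum(axis=1, keepdims=True)
    return theta, W


def _init_unconstrained(
    collection: GeneSetCollection | None,
    hyper: ModelHyperparams,
    config: FitConfig,
    X: CountMatrix,
) -> dict:
    """Build the unconstrained parameter state shared by both optimizers."""
    rng = np.random.default_rng(config.seed)
    t = config.t
    p = X.n_genes
    plan = _scope_plan(collection, hyper, X)

    state: dict = {"z_theta": {}, "z_g": {}, "z_B": {}, "z_kappa": {}, "z_rho": {},
                   "raw_alpha": {}, "plan": plan, "nmf_loadings": {}}
    for scope, k in plan.items():
        sets = collection.sets_in_scope(scope) if collection is not None else {}
        n_sets = len(sets)
        if n_sets >= 1 and k >= n_sets + 1:
            z = rng.normal(0.0, config.init_noise, size=(p, k))
            for j, genes in enumerate(sets.values()):
                idx = X.vocab.indices([g for g in genes if g in X.vocab])
                z[idx, j] = t
            zB = np.zeros((k, k))
            for j in range(n_sets):
                zB[j, j] = t
            zB[-1, :] = -t
            zB[:, -1] = -t
            state["z_theta"][scope] = z
            state["z_B"][scope] = zB
        else:
            sub = X.X if scope == GLOBAL_SCOPE else X.X[X.cells_of_type(scope)]
            theta, W = _nmf_theta(sub, k, config.seed)
            state["z_theta"][scope] = np.log(np.maximum(theta, 1e-12))
            state["z_B"][scope] = np.diag(np.full(k, t))
            state["nmf_loadings"][scope] = W
        state["z_g"][scope] = np.zeros(p)  # sigmoid(0) = 0.5
        kap = hyper.kappa_for(scope)
        rho = hyper.rho_for(scope)
        state["z_kappa"][scope] = (LEARN, _logit(0.001)) if kap == LEARN else (None, float(kap))
        state["z_rho"][scope] = (LEARN, _logit(0.001)) if rho == LEARN else (None, float(rho))

    # loadings: scale so predicted row sums roughly match observed row sums
    gd = 0.5 + hyper.delta
    for ct in X.type_names:
        idx = X.cells_of_type(ct)
        k_tot = hyper.K + hyper.k_for(ct)
        base = X.X[idx].sum(axis=1) / max(gd * p, 1e-12)
        alpha = np.maximum(base[:, None] * rng.uniform(0.5, 1.5, size=(idx.size, k_tot)), 1e-4)
        gl = state["nmf_loadings"].get(GLOBAL_SCOPE)
        if gl is not None:
            alpha[:, : hyper.K] = np.maximum(gl[idx] / gd, 1e-4)
        sl = state["nmf_loadings"].get(ct)
        if sl is not None:
            alpha[:, hyper.K:] = np.maximum(sl / gd, 1e-4)
        state["raw_alpha"][ct] = _softplus_inv(alpha)
    return state


def _materialize(state: dict, hyper: ModelHyperparams, X: CountMatrix) -> ModelParams:
    theta = {s: _softmax_rows(z) for s, z in state["z_theta"].items()}
    g = {s: np.asarray(_sigmoid(z)) for s, z in state["z_g"].items()}
    B = {s: np.asarray(_sigmoid(z)) for s, z in state["z_B"].items()}
    kappa = {
        s: float(_sigmoid(v)) if mode == LEARN else v
        for s, (mode, v) in state["z_kappa"].items()
    }
    rho = {
        s: float(_sigmoid(v)) if mode == LEARN else v
        for s, (mode, v) in state["z_rho"].items()
    }
    alpha = {ct: _softplus(raw) for ct, raw in state["raw_alpha"].items()}
    return ModelParams(
        theta=theta, g=g, B=B, kappa=kappa, rho=rho, alpha=alpha,
        cell_types=X.cell_types.copy(), type_names=tuple(X.type_names),
    )


def initialize_params(
    collection: GeneSetCollection | None,
    hyper: ModelHyperparams,
    config: FitConfig,
    X: CountMatrix,
) -> ModelParams:
    """Seed factors on their gene sets (log-scale strength t) when there is
    room for a spare factor, otherwise fall back to an NMF of the scope's
    submatrix.  The final factor's interaction row/column starts detached
    (logit -t) so it is free to capture genes outside the prior graph."""
    state = _init_unconstrained(collection, hyper, config, X)
    params = _materialize(state, hyper, X)
    params.validate()
    return params


# ---------------------------------------------------------------------------
# objective + analytic gradient over the unconstrained state


def _objective_and_grad(
    state: dict,
    X: CountMatrix,
    graphs: WeightedGeneGraph | None,
    hyper: ModelHyperparams,
) -> tuple[float, dict]:
    p = X.n_genes
    K = state["z_theta"][GLOBAL_SCOPE].shape[1]
    theta = {s: _softmax_rows(z) for s, z in state["z_theta"].items()}
    g = {s: np.asarray(_sigmoid(z)) for s, z in state["z_g"].items()}
    B = {s: np.asarray(_sigmoid(z)) for s, z in state["z_B"].items()}
    kappa = {s: (float(_sigmoid(v)) if m == LEARN else v) for s, (m, v) in state["z_kappa"].items()}
    rho = {s: (float(_sigmoid(v)) if m == LEARN else v) for s, (m, v) in state["z_rho"].items()}
    alpha = {ct: _softplus(raw) for ct, raw in state["raw_alpha"].items()}

    grad_theta = {s: np.zeros_like(th) for s, th in theta.items()}
    grad_g = {s: np.zeros(p) for s in g}
    grad_B = {s: np.zeros_like(b) for s, b in B.items()}
    grad_kappa = {s: 0.0 for s in kappa}
    grad_rho = {s: 0.0 for s in rho}
    grad_alpha = {}

    delta = hyper.delta
    value = 0.0

    # --- reconstruction term
    Wg = theta[GLOBAL_SCOPE] * (g[GLOBAL_SCOPE] + delta)[:, None]  # p x K
    cells_of = {ct: np.flatnonzero(X.cell_types == ct) for ct in X.type_names}
    for ct in X.type_names:
        idx = cells_of[ct]
        if idx.size == 0:
            continue
        lam = hyper.lambda_for(ct)
        al = alpha[ct]
        a_g, a_s = al[:, :K], al[:, K:]
        mu = a_g @ Wg.T
        has_specific = ct in theta
        if has_specific:
            Ws = theta[ct] * (g[ct] + delta)[:, None]
            mu = mu + a_s @ Ws.T
        Xc = X.X[idx]
        mu_safe = np.maximum(mu, LOG_FLOOR)
        value += lam * float(np.sum(Xc * np.log(mu_safe) - mu))
        R = lam * (np.where(mu >= LOG_FLOOR, Xc / mu_safe, 0.0) - 1.0)
        ga = np.empty_like(al)
        ga[:, :K] = R @ Wg
        grad_theta[GLOBAL_SCOPE] += (g[GLOBAL_SCOPE] + delta)[:, None] * (R.T @ a_g)
        grad_g[GLOBAL_SCOPE] += np.einsum("ij,ij->j", R, a_g @ theta[GLOBAL_SCOPE].T)
        if has_specific:
            ga[:, K:] = R @ Ws
            grad_theta[ct] += (g[ct] + delta)[:, None] * (R.T @ a_s)
            grad_g[ct] += np.einsum("ij,ij->j", R, a_s @ theta[ct].T)
        elif al.shape[1] > K:
            ga[:, K:] = 0.0
        grad_alpha[ct] = ga

    for ct in X.type_names:
        if ct not in grad_alpha:  # no cells of this type
            grad_alpha[ct] = np.zeros_like(alpha[ct])

    # --- graph term
    if graphs is not None:
        for scope in graphs.scope_names():
            if scope not in theta:
                continue
            th, b = theta[scope], B[scope]
            kap, rh = kappa[scope], rho[scope]
            w = graphs.weights[scope]
            A = graphs.adjacency(scope)
            S = th @ b @ th.T
            c = (1 - kap) * (1 - rh)
            p1 = c * S + kap * (1 - rh)
            p0 = c * (1 - S) + rh
            p1_safe = np.maximum(p1, LOG_FLOOR)
            p0_safe = np.maximum(p0, LOG_FLOOR)
            term = w * A * np.log(p1_safe) + (1 - A) * np.log(p0_safe)
            np.fill_diagonal(term, 0.0)
            value += float(term.sum())
            inv1 = np.where(p1 >= LOG_FLOOR, w * A / p1_safe, 0.0)
            inv0 = np.where(p0 >= LOG_FLOOR, (1 - A) / p0_safe, 0.0)
            np.fill_diagonal(inv1, 0.0)
            np.fill_diagonal(inv0, 0.0)
            G = c * (inv1 - inv0)  # dL/dS
            grad_theta[scope] += G @ th @ b.T + G.T @ th @ b
            grad_B[scope] += th.T @ G @ th
            # dL/dkappa, dL/drho through p1 and p0
            grad_kappa[scope] += float(
                np.sum(inv1 * (1 - rh) * (1 - S) - inv0 * (1 - rh) * (1 - S))
            )
            grad_rho[scope] += float(
                np.sum(-inv1 * ((1 - kap) * S + kap) + inv0 * (1 - (1 - kap) * (1 - S)))
            )

    # --- chain rules back to unconstrained coordinates
    out: dict = {"z_theta": {}, "z_g": {}, "z_B": {}, "z_kappa": {}, "z_rho": {},
                 "raw_alpha": {}}
    for s, th in theta.items():
        gt = grad_theta[s]
        out["z_theta"][s] = th * (gt - np.sum(gt * th, axis=1, keepdims=True))
        out["z_g"][s] = grad_g[s] * g[s] * (1 - g[s])
        out["z_B"][s] = grad_B[s] * B[s] * (1 - B[s])
        m_k, v_k = state["z_kappa"][s]
        out["z_kappa"][s] = (
            grad_kappa[s] * kappa[s] * (1 - kappa[s]) if m_k == LEARN else 0.0
        )
        m_r, _ = state["z_rho"][s]
        out["z_rho"][s] = grad_rho[s] * rho[s] * (1 - rho[s]) if m_r == LEARN else 0.0
    for ct, raw in state["raw_alpha"].items():
        out["raw_alpha"][ct] = grad_alpha[ct] * np.asarray(_sigmoid(raw))
    return value, out


def _flatten_keys(state: dict):
    for s in state["z_theta"]:
        yield ("z_theta", s)
        yield ("z_g", s)
        yield ("z_B", s)
        if state["z_kappa"][s][0] == LEARN:
            yield ("z_kappa", s)
        if state["z_rho"][s][0] == LEARN:
            yield ("z_rho", s)
    for ct in state["raw_alpha"]:
        yield ("raw_alpha", ct)


def _get(state, key):
    kind, s = key
    if kind in ("z_kappa", "z_rho"):
        return state[kind][s][1]
    return state[kind][s]


def _set(state, key, val):
    kind, s = key
    if kind in ("z_kappa", "z_rho"):
        state[kind][s] = (LEARN, float(val))
    else:
        state[kind][s] = val


def fit_gradient(
    X: CountMatrix,
    graphs: WeightedGeneGraph | None,
    hyper: ModelHyperparams,
    config: FitConfig,
    collection: GeneSetCollection | None = None,
) -> FitResult:
    """Maximize the total objective with Adam over the reparameterized state.

    Each learning-rate stage trains until the relative objective change over
    a ``config.window``-iteration span drops below ``tol`` (or ``max_iter``
    iterations); the best state seen within a stage is carried into the next,
    so stage-final objectives never fall below stage-initial ones.
    """
    _check_genes_expressed(X)
    state = _init_unconstrained(collection, hyper, config, X)
    keys = list(_flatten_keys(state))
    eps = 1e-8
    trajectory: list[tuple[str, int, float]] = []
    converged: dict[str, bool] = {}

    value, _ = _objective_and_grad(state, X, graphs, hyper)
    trajectory.append(("init", 0, value))

    for stage_i, lr in enumerate(config.lr_schedule):
        stage = f"lr={lr:g}"
        m = {k: np.zeros_like(np.asarray(_get(state, k), dtype=np.float64)) for k in keys}
        v = {k: np.zeros_like(np.asarray(_get(state, k), dtype=np.float64)) for k in keys}
        history: list[float] = []
        best_val = -np.inf
        best_state = None
        converged[stage] = False
        for it in range(1, config.max_iter + 1):
            value, grad = _objective_and_grad(state, X, graphs, hyper)
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"non-finite objective at stage {stage}, iteration {it}"
                )
            history.append(value)
            trajectory.append((stage, it, value))
            if value > best_val:
                best_val = value
                best_state = {k: np.array(_get(state, k), copy=True) for k in keys}
            t_adam = it
            for k in keys:
                gk = np.asarray(grad[k[0]][k[1]] if k[0] not in ("z_kappa", "z_rho")
                                else grad[k[0]][k[1]], dtype=np.float64)
                m[k] = config.beta1 * m[k] + (1 - config.beta1) * gk
                v[k] = config.beta2 * v[k] + (1 - config.beta2) * gk * gk
                mhat = m[k] / (1 - config.beta1 ** t_adam)
                vhat = v[k] / (1 - config.beta2 ** t_adam)
                _set(state, k, np.asarray(_get(state, k)) + lr * mhat / (np.sqrt(vhat) + eps))
            if it >= config.window:
                prev = history[it - config.window]
                if abs(history[-1] - prev) < config.resolved_tol() * (abs(prev) + 1e-12):
                    converged[stage] = True
                    break
        if best_state is not None:
            for k in keys:
                _set(state, k, best_state[k])

    params = _materialize(state, hyper, X)
    params.validate()
    final, _ = _objective_and_grad(state, X, graphs, hyper)
    trajectory.append(("final", 0, final))
    return FitResult(
        params=params, objective_trajectory=trajectory, converged=converged,
        hyper=hyper, config=config,
    )


def _check_genes_expressed(X: CountMatrix) -> None:
    zero = np.flatnonzero(X.X.sum(axis=0) == 0)
    if zero.size:
        names = [X.vocab.genes[i] for i in zero[:10]]
        raise ValueError(
            f"{zero.size} genes have zero total expression (e.g. {names}); "
            "remove them before fitting — gene scalings and factor rows are "
            "unidentifiable for silent genes"
        )


def fit(
    X: CountMatrix,
    graphs: WeightedGeneGraph | None,
    hyper: ModelHyperparams,
    config: FitConfig,
    collection: GeneSetCollection | None = None,
) -> FitResult:
    """Dispatch to the configured optimizer."""
    if config.optimizer == "em":
        from .em import fit_em

        return fit_em(X, graphs, hyper, config, collection=collection)
    return fit_gradient(X, graphs, hyper, config, collection=collection)
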