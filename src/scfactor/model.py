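"""Model containers and the pseudolikelihood objective.

The generative picture: processed expression X (n cells x p genes) is
reconstructed by a low-rank product with per-gene scale factors,

    E[X_cij] = (g_j + delta) * alpha_{c,i,:K}^T theta_j
             + (g_cj + delta) * alpha_{c,i,K+1:}^T theta_cj

where theta rows live on the simplex, and the prior gene-gene graph A
(per scope, with edge weights w) is modeled through factor similarity
tempered by a factor interaction matrix B and background edge rates
kappa (spurious edges) and rho (spurious non-edges):

    P[A_ij = 1] = (1 - kappa)(1 - rho) theta_i^T B theta_j + kappa (1 - rho)

The fitted objective is  L = sum_c lambda_c * L_recon,c + L_graph,
a Poisson-form log-likelihood plus a weighted Bernoulli graph term,
and is MAXIMIZED by the optimizers in :mod:`scfactor.inference`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .genesets import GLOBAL_SCOPE, GeneVocabulary

LOG_FLOOR = 1e-12  # positivity floor for every log argument in the objectives

LEARN = "learn"  # sentinel for kappa/rho estimated alongside the other parameters

__all__ = [
    "LOG_FLOOR",
    "LEARN",
    "CountMatrix",
    "ModelHyperparams",
    "ModelParams",
    "expected_expression",
    "expected_matrix",
    "edge_probability",
    "edge_probability_matrix",
    "reconstruction_objective",
    "graph_objective",
    "total_objective",
]


@dataclass
class CountMatrix:
    """Processed (normalized, not necessarily integer) expression values.

    ``cell_types`` holds one label per cell drawn from ``type_names``;
    column order is fixed by ``vocab``.
    """

    X: np.ndarray
    cell_types: np.ndarray
    vocab: GeneVocabulary
    cell_ids: np.ndarray | None = None
    type_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional (cells x genes)")
        n, p = self.X.shape
        if n < 1:
            raise ValueError("need at least one cell")
        if p != len(self.vocab):
            raise ValueError(f"X has {p} columns but vocabulary has {len(self.vocab)} genes")
        if np.any(self.X < 0):
            raise ValueError("expression values must be nonnegative")
        self.cell_types = np.asarray(self.cell_types)
        if self.cell_types.shape != (n,):
            raise ValueError("cell_types must have one label per cell")
        if self.type_names is None:
            # order of first appearance, deterministic
            seen: list[str] = []
            for t in self.cell_types:
                if t not in seen:
                    seen.append(t)
            self.type_names = tuple(seen)
        unknown = set(self.cell_types) - set(self.type_names)
        if unknown:
            raise ValueError(f"labels not in declared cell-type list: {sorted(unknown)}")
        if self.cell_ids is not None:
            self.cell_ids = np.asarray(self.cell_ids)
            if self.cell_ids.shape != (n,):
                raise ValueError("cell_ids must have one id per cell")

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_genes(self) -> int:
        return self.X.shape[1]

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        return np.flatnonzero(self.cell_types == cell_type)


@dataclass
class ModelHyperparams:
    """Tunable weights and sizes of the model.

    lambda_c : reconstruction weight, scalar applied to every cell type or a
               per-type mapping.  Small values keep factors close to the prior.
    delta    : lower bound on gene scale factors; caps the dynamic range of
               gene scaling at ~(1 + delta)/delta.
    K        : number of global factors.
    K_c      : cell-type-specific factor counts (scalar broadcast or mapping);
               0 disables the specific block for that type.
    kappa/rho: background edge / non-edge rates per scope; a number in [0, 1)
               or the sentinel "learn".
    offset   : gene-score shrinkage offset (0 returns theta itself).
    """

    K: int = 1
    K_c: int | Mapping[str, int] = 1
    lambda_c: float | Mapping[str, float] = 0.01
    delta: float = 0.001
    kappa: float | str | Mapping[str, float | str] = LEARN
    rho: float | str | Mapping[str, float | str] = LEARN
    offset: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.offset < 0:
            raise ValueError("offset must be nonnegative")

    def k_for(self, cell_type: str) -> int:
        if isinstance(self.K_c, Mapping):
            k = int(self.K_c.get(cell_type, 0))
        else:
            k = int(self.K_c)
        if k < 0:
            raise ValueError("K_c must be >= 0")
        return k

    def lambda_for(self, cell_type: str) -> float:
        if isinstance(self.lambda_c, Mapping):
            return float(self.lambda_c[cell_type])
        return float(self.lambda_c)

    def _rate_for(self, which: str, scope: str):
        val = getattr(self, which)
        if isinstance(val, Mapping):
            val = val.get(scope, LEARN)
        if isinstance(val, str):
            if val != LEARN:
                raise ValueError(f"{which} must be a number in [0,1) or {LEARN!r}")
            return LEARN
        val = float(val)
        if not 0.0 <= val < 1.0:
            raise ValueError(f"{which} must lie in [0, 1)")
        return val

    def kappa_for(self, scope: str):
        return self._rate_for("kappa", scope)

    def rho_for(self, scope: str):
        return self._rate_for("rho", scope)


@dataclass
class ModelParams:
    """Fitted parameters, keyed by scope ("global" plus cell-type names).

    theta[scope] : p x K_scope, rows on the simplex
    g[scope]     : p-vector in [0, 1]       (gene scale factors)
    B[scope]     : K_scope x K_scope in [0, 1]  (factor interaction matrix)
    kappa, rho   : per-scope floats in [0, 1)
    alpha[ct]    : n_ct x (K + K_ct) nonnegative loadings; rows follow the
                   order of that type's cells in the data matrix
    """

    theta: dict[str, np.ndarray]
    g: dict[str, np.ndarray]
    B: dict[str, np.ndarray]
    kappa: dict[str, float]
    rho: dict[str, float]
    alpha: dict[str, np.ndarray]
    cell_types: np.ndarray  # full per-cell label vector aligned with X rows
    type_names: tuple[str, ...]

    SIMPLEX_TOL = 1e-8

    @property
    def K(self) -> int:
        return self.theta[GLOBAL_SCOPE].shape[1]

    def k_specific(self, cell_type: str) -> int:
        if cell_type in self.theta:
            return self.theta[cell_type].shape[1]
        return 0

    def cells_of_type(self, cell_type: str) -> np.ndarray:
        return np.flatnonzero(self.cell_types == cell_type)

    def scope_names(self) -> list[str]:
        return list(self.theta)

    def validate(self) -> None:
        for scope, th in self.theta.items():
            if np.any(th < -1e-15):
                raise ValueError(f"theta[{scope!r}] has negative entries")
            rows = th.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > self.SIMPLEX_TOL):
                raise ValueError(f"theta[{scope!r}] rows do not sum to 1")
        for scope, gg in self.g.items():
            if np.any((gg < 0) | (gg > 1)):
                raise ValueError(f"g[{scope!r}] outside [0, 1]")
        for scope, bb in self.B.items():
            if np.any((bb < 0) | (bb > 1)):
                raise ValueError(f"B[{scope!r}] outside [0, 1]")
        for scope in self.kappa:
            if not 0 <= self.kappa[scope] < 1 or not 0 <= self.rho[scope] < 1:
                raise ValueError(f"kappa/rho[{scope!r}] outside [0, 1)")
        for ct, al in self.alpha.items():
            if np.any(al < 0):
                raise ValueError(f"alpha[{ct!r}] has negative loadings")

    def eta(self) -> dict[str, np.ndarray]:
        """Graph-dependence of each factor: the diagonal of B per scope."""
        return {scope: np.diag(b).copy() for scope, b in self.B.items()}

    def copy(self) -> "ModelParams":
        return ModelParams(
            theta={s: v.copy() for s, v in self.theta.items()},
            g={s: v.copy() for s, v in self.g.items()},
            B={s: v.copy() for s, v in self.B.items()},
            kappa=dict(self.kappa),
            rho=dict(self.rho),
            alpha={s: v.copy() for s, v in self.alpha.items()},
            cell_types=self.cell_types.copy(),
            type_names=self.type_names,
        )


# ---------------------------------------------------------------------------
# expression model


def _scaled_theta(params: ModelParams, hyper: ModelHyperparams, scope: str) -> np.ndarray:
    """theta weighted per gene by (g + delta); the factor-to-gene map."""
    g = params.g[scope]
    return params.theta[scope] * (g + hyper.delta)[:, None]


def expected_matrix(params: ModelParams, hyper: ModelHyperparams) -> np.ndarray:
    """E[X] for every cell, assembled per cell type."""
    n = len(params.cell_types)
    p = params.theta[GLOBAL_SCOPE].shape[0]
    mu = np.zeros((n, p))
    K = params.K
    w_global = _scaled_theta(params, hyper, GLOBAL_SCOPE)  # p x K
    for ct in params.type_names:
        idx = params.cells_of_type(ct)
        if idx.size == 0:
            continue
        al = params.alpha[ct]
        block = al[:, :K] @ w_global.T
        if params.k_specific(ct) > 0:
            block = block + al[:, K:] @ _scaled_theta(params, hyper, ct).T
        mu[idx] = block
    return mu


def expected_expression(
    params: ModelParams, hyper: ModelHyperparams, cell_index: int
) -> np.ndarray:
    """Expected expression for a single cell (length-p vector)."""
    n = len(params.cell_types)
    if not 0 <= cell_index < n:
        raise IndexError(f"cell_index {cell_index} out of range [0, {n})")
    ct = params.cell_types[cell_index]
    idx = params.cells_of_type(ct)
    row = int(np.flatnonzero(idx == cell_index)[0])
    al = params.alpha[ct][row]
    K = params.K
    mu = _scaled_theta(params, hyper, GLOBAL_SCOPE) @ al[:K]
    if params.k_specific(ct) > 0:
        mu = mu + _scaled_theta(params, hyper, ct) @ al[K:]
    return mu


# ---------------------------------------------------------------------------
# graph model


def edge_probability(
    theta_i: np.ndarray,
    theta_j: np.ndarray,
    B: np.ndarray,
    kappa: float,
    rho: float,
) -> float:
    """P[A_ij = 1] for a single gene pair."""
    if not (0 <= kappa < 1 and 0 <= rho < 1):
        raise ValueError("kappa and rho must lie in [0, 1)")
    s = float(theta_i @ B @ theta_j)
    return (1 - kappa) * (1 - rho) * s + kappa * (1 - rho)


def edge_probability_matrix(
    theta: np.ndarray, B: np.ndarray, kappa: float, rho: float
) -> tuple[np.ndarray, np.ndarray]:
    """(P[A=1], P[A=0]) for all gene pairs; the two sum to 1 elementwise."""
    if not (0 <= kappa < 1 and 0 <= rho < 1):
        raise ValueError("kappa and rho must lie in [0, 1)")
    S = theta @ B @ theta.T
    p1 = (1 - kappa) * (1 - rho) * S + kappa * (1 - rho)
    p0 = (1 - kappa) * (1 - rho) * (1 - S) + rho
    return p1, p0


# ---------------------------------------------------------------------------
# objectives


def reconstruction_objective(
    X: "CountMatrix | np.ndarray", params: ModelParams, hyper: ModelHyperparams
) -> float:
    """sum_c lambda_c sum_{i in c, j} [ X log mu - mu ]  (larger is better)."""
    Xmat = X.X if isinstance(X, CountMatrix) else np.asarray(X, dtype=np.float64)
    mu = expected_matrix(params, hyper)
    log_mu = np.log(np.maximum(mu, LOG_FLOOR))
    total = 0.0
    for ct in params.type_names:
        idx = params.cells_of_type(ct)
        if idx.size == 0:
            continue
        lam = hyper.lambda_for(ct)
        total += lam * float(np.sum(Xmat[idx] * log_mu[idx] - mu[idx]))
    return total


def graph_objective(graphs, params: ModelParams, hyper: ModelHyperparams) -> float:
    """Weighted Bernoulli log-likelihood of the prior graphs, all ordered pairs i != j.

    Scopes in the model but absent from ``graphs`` contribute nothing (an
    absent graph is "no prior", not an empty one).
    """
    total = 0.0
    for scope in graphs.scope_names():
        if scope not in params.theta:
            continue
        w = graphs.weights[scope]
        A = graphs.adjacency(scope)
        p1, p0 = edge_probability_matrix(
            params.theta[scope], params.B[scope], params.kappa[scope], params.rho[scope]
        )
        term = w * A * np.log(np.maximum(p1, LOG_FLOOR)) + (1 - A) * np.log(
            np.maximum(p0, LOG_FLOOR)
        )
        np.fill_diagonal(term, 0.0)
        total += float(term.sum())
    return total


def total_objective(
    X: "CountMatrix | np.ndarray", graphs, params: ModelParams, hyper: ModelHyperparams
) -> float:
    """lambda-weighted reconstruction plus graph term; the fitter maximizes this."""
    return reconstruction_objective(X, params, hyper) + graph_objective(graphs, params, hyper)
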