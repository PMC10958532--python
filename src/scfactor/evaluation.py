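"""Factor-quality metrics: importance, information, coherence, recovery.

Importance masks one factor out of the reconstruction and reports the
relative change in the cell type's reconstruction term.  Information is an
exponentiated Mimno-style co-occurrence statistic of a factor's top M
markers inside one cell type.  Coherence averages pointwise mutual
information of marker pairs on held-out cells.  Held-out gene recovery
fits on truncated gene sets and asks how many of the removed genes come
back among the factor's top-ranked genes.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np

from .genesets import GLOBAL_SCOPE, GeneSetCollection, GeneVocabulary
from .model import CountMatrix, LOG_FLOOR, ModelHyperparams, ModelParams
from .postprocess import GeneScoreMatrix, factor_id, label_factors, top_markers

logger = logging.getLogger(__name__)

__all__ = [
    "EvalConfig",
    "importance_score",
    "information_score",
    "coherence",
    "heldout_gene_recovery",
]


@dataclass
class EvalConfig:
    M: int = 30                      # top genes entering the information score
    coherence_top_n: int = 50
    recovery_top_n: int = 200
    holdout_fraction: float = 0.4    # fraction of set genes held out for recovery
    detection_threshold: float = 0.0  # expression strictly above this counts as detected
    pmi_pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")


def _recon_term(
    X: CountMatrix,
    params: ModelParams,
    hyper: ModelHyperparams,
    cell_type: str,
    theta_override: dict[str, np.ndarray] | None = None,
) -> float:
    """lambda_c * sum_{i in c, j} [X log mu - mu] with optional masked theta."""
    idx = params.cells_of_type(cell_type)
    if idx.size == 0:
        raise ValueError(f"no cells of type {cell_type!r}")
    theta = dict(params.theta)
    if theta_override:
        theta.update(theta_override)
    K = params.K
    delta = hyper.delta
    al = params.alpha[cell_type]
    mu = al[:, :K] @ (theta[GLOBAL_SCOPE] * (params.g[GLOBAL_SCOPE] + delta)[:, None]).T
    if params.k_specific(cell_type) > 0:
        mu = mu + al[:, K:] @ (theta[cell_type] * (params.g[cell_type] + delta)[:, None]).T
    Xc = X.X[idx]
    lam = hyper.lambda_for(cell_type)
    return lam * float(np.sum(Xc * np.log(np.maximum(mu, LOG_FLOOR)) - mu))


def importance_score(
    X: CountMatrix,
    params: ModelParams,
    hyper: ModelHyperparams,
    cell_type: str,
    factor: int,
    scope: str = GLOBAL_SCOPE,
) -> float:
    """Relative change of the cell type's reconstruction term when the
    factor's theta column is zeroed: (L_masked - L) / L."""
    base = _recon_term(X, params, hyper, cell_type)
    if base == 0:
        raise ZeroDivisionError(
            f"reconstruction term for cell type {cell_type!r} is exactly zero "
            "(degenerate data); importance score undefined"
        )
    masked = params.theta[scope].copy()
    masked[:, factor] = 0.0
    loss = _recon_term(X, params, hyper, cell_type, theta_override={scope: masked})
    return (loss - base) / base


def information_score(
    X_c: np.ndarray,
    markers: list[int] | np.ndarray,
    M: int = 30,
    detection_threshold: float = 0.0,
) -> float:
    """exp of sum_{m=2..M} sum_{l<m} log[(D(g_m, g_l) + 1) / D(g_l)].

    ``X_c`` holds the cells of a single cell type; ``markers`` are column
    indices ordered by descending gene score.  D counts detecting cells.
    """
    markers = np.asarray(markers)
    if markers.shape[0] < M:
        raise ValueError(f"need at least M={M} markers, got {markers.shape[0]}")
    top = markers[:M]
    detected = X_c[:, top] > detection_threshold  # n_c x M
    joint = detected.T.astype(np.float64) @ detected  # co-occurrence counts
    single = detected.sum(axis=0).astype(np.float64)
    zero = np.flatnonzero(single[: M - 1] == 0)
    if zero.size:
        raise ZeroDivisionError(
            f"marker at rank {int(zero[0]) + 1} (column {int(top[zero[0]])}) is never "
            "detected in this cell type; the information-score denominator is undefined"
        )
    C = 0.0
    for m in range(1, M):
        for l in range(m):
            C += np.log((joint[m, l] + 1.0) / single[l])
    return float(np.exp(C))


def coherence(
    X_heldout: np.ndarray,
    markers: list[int] | np.ndarray,
    top_n: int = 50,
    detection_threshold: float = 0.0,
    pseudocount: float = 1.0,
) -> float:
    """Mean pairwise PMI of marker detection on held-out cells.

    PMI(i, j) = log p(i, j) / (p(i) p(j)) with empirical detection
    probabilities; the pseudocount (default 1) is added to joint and
    marginal counts before normalizing, guarding disjoint pairs
    (pseudocount 0 restores the raw formula).
    """
    markers = np.asarray(markers)[:top_n]
    if markers.shape[0] < 2:
        raise ValueError("need at least two markers for coherence")
    n = X_heldout.shape[0]
    detected = X_heldout[:, markers] > detection_threshold
    m = markers.shape[0]
    joint = detected.T.astype(np.float64) @ detected
    single = detected.sum(axis=0).astype(np.float64)
    denom = n + pseudocount
    vals = []
    for i in range(m):
        for j in range(i + 1, m):
            p_ij = (joint[i, j] + pseudocount) / denom
            p_i = (single[i] + pseudocount) / denom
            p_j = (single[j] + pseudocount) / denom
            vals.append(np.log(p_ij / (p_i * p_j)))
    return float(np.mean(vals))


def heldout_gene_recovery(
    fit_gene_scores: GeneScoreMatrix,
    truncated_sets: dict[str, list[str]],
    original_sets: dict[str, list[str]],
    collection: GeneSetCollection,
    top_n: int = 200,
    label_top_n: int = 50,
    threshold: float = 0.2,
) -> dict[str, float | None]:
    """Fraction of each set's held-out genes recovered in the factor's top genes.

    Factors are matched to sets by unique-mode labeling against the full
    collection; sets without a matched factor are reported as None.
    """
    labels = label_factors(
        fit_gene_scores, collection, top_n=label_top_n, threshold=threshold, unique=True
    )
    set_to_factor: dict[str, tuple[str, int]] = {}
    for fid, label in labels.items():
        if label is not None:
            scope, k = fid.split("::")
            set_to_factor[label] = (scope, int(k))
    out: dict[str, float | None] = {}
    for name, genes in original_sets.items():
        held_out = set(genes) - set(truncated_sets.get(name, []))
        if not held_out:
            continue
        match = set_to_factor.get(name)
        if match is None:
            out[name] = None
            continue
        scope, k = match
        top = set(top_markers(fit_gene_scores, scope, k, top_n))
        out[name] = len(held_out & top) / len(held_out)
    return out
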