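"""User-facing outputs derived from fitted parameters.

Cell scores rescale loadings by total factor usage (q_k, the mean of a
theta column), which removes the scale non-identifiability of factor
analysis; gene scores shrink factor weights by the gene scaling so that
very lowly expressed genes drop out of marker lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genesets import GLOBAL_SCOPE, GeneSetCollection, overlap_coefficient
from .model import ModelHyperparams, ModelParams

__all__ = [
    "CellScoreMatrix",
    "GeneScoreMatrix",
    "cell_scores",
    "gene_scores",
    "top_markers",
    "label_factors",
    "classify_factors",
    "posterior_graph",
    "aggregate_positive",
    "cross_study_entropy",
    "INSUFFICIENT",
]

INSUFFICIENT = "insufficient"  # sentinel for under-populated factors

NEW_FACTOR_THRESHOLD = 0.25


@dataclass
class CellScoreMatrix:
    """n x (K + sum_c K_c) nonnegative scores; cell-type-specific columns are
    structurally zero outside their own cell type."""

    scores: np.ndarray
    factor_ids: list[str]
    factor_scopes: list[str]

    def as_frame(self, cell_ids=None) -> pd.DataFrame:
        return pd.DataFrame(self.scores, columns=self.factor_ids, index=cell_ids)

    def column(self, factor_id: str) -> np.ndarray:
        return self.scores[:, self.factor_ids.index(factor_id)]


@dataclass
class GeneScoreMatrix:
    """Per-scope p x K_scope gene scores in [0, 1]."""

    scores: dict[str, np.ndarray]
    offset: float
    genes: tuple[str, ...]


def factor_id(scope: str, k: int) -> str:
    return f"{scope}::{k}"


def cell_scores(params: ModelParams, hyper: ModelHyperparams) -> CellScoreMatrix:
    """cell_score_ik = q_k * alpha_ik with q_k = mean_j theta_jk (per scope)."""
    n = len(params.cell_types)
    K = params.K
    scopes = [GLOBAL_SCOPE] + [s for s in params.theta if s != GLOBAL_SCOPE]
    ids: list[str] = []
    col_scopes: list[str] = []
    blocks = []
    for scope in scopes:
        k_s = params.theta[scope].shape[1]
        ids.extend(factor_id(scope, k) for k in range(k_s))
        col_scopes.extend([scope] * k_s)
        blocks.append((scope, k_s))
    total_cols = sum(k for _, k in blocks)
    out = np.zeros((n, total_cols))
    q = {scope: params.theta[scope].mean(axis=0) for scope in scopes}
    col0 = 0
    for scope, k_s in blocks:
        if scope == GLOBAL_SCOPE:
            for ct in params.type_names:
                idx = params.cells_of_type(ct)
                out[np.ix_(idx, range(col0, col0 + k_s))] = (
                    params.alpha[ct][:, :K] * q[GLOBAL_SCOPE]
                )
        else:
            idx = params.cells_of_type(scope)
            if idx.size:
                out[np.ix_(idx, range(col0, col0 + k_s))] = (
                    params.alpha[scope][:, K:] * q[scope]
                )
        col0 += k_s
    return CellScoreMatrix(scores=out, factor_ids=ids, factor_scopes=col_scopes)


def gene_scores(
    params: ModelParams,
    hyper: ModelHyperparams,
    offset: float | None = None,
    genes: tuple[str, ...] | None = None,
) -> GeneScoreMatrix:
    """((g_j + delta) / (g_j + delta + offset)) * theta_jk per scope.

    offset = 0 returns the factors theta themselves.
    """
    if offset is None:
        offset = hyper.offset
    if offset < 0:
        raise ValueError("offset must be nonnegative")
    out = {}
    for scope, th in params.theta.items():
        gd = params.g[scope] + hyper.delta
        out[scope] = (gd / (gd + offset))[:, None] * th
    if genes is None:
        genes = tuple(f"gene{i}" for i in range(next(iter(out.values())).shape[0]))
    return GeneScoreMatrix(scores=out, offset=float(offset), genes=genes)


def top_markers(
    gene_score_matrix: GeneScoreMatrix, scope: str, factor: int, top_n: int = 50
) -> list[str]:
    """Genes by descending score; ties broken by vocabulary order."""
    col = gene_score_matrix.scores[scope][:, factor]
    if top_n > col.shape[0]:
        raise ValueError(f"top_n={top_n} exceeds the number of genes ({col.shape[0]})")
    order = np.argsort(-col, kind="stable")  # stable: ties fall back to index order
    return [gene_score_matrix.genes[i] for i in order[:top_n]]


def label_factors(
    gene_score_matrix: GeneScoreMatrix,
    collection: GeneSetCollection,
    top_n: int = 50,
    threshold: float = 0.2,
    unique: bool = False,
) -> dict[str, str | None]:
    """Assign each factor the gene-set label with maximal marker overlap.

    A factor gets the label of the set maximizing the overlap coefficient of
    its top markers, provided that maximum exceeds ``threshold``.  In
    ``unique`` mode two factors cannot share a label: the higher-overlap
    factor wins and the loser falls back to its next-best set (or none).
    """
    sets = collection.all_sets()
    set_keys = list(sets)
    factors = [
        (scope, k)
        for scope, mat in gene_score_matrix.scores.items()
        for k in range(mat.shape[1])
    ]
    markers = {
        (scope, k): set(top_markers(gene_score_matrix, scope, k, top_n))
        for scope, k in factors
    }
    coeff = {
        f: {key: overlap_coefficient(markers[f], sets[key]) for key in set_keys}
        for f in factors
    }
    labels: dict[str, str | None] = {factor_id(s, k): None for s, k in factors}
    if not set_keys:
        return labels
    if not unique:
        for f in factors:
            best = max(set_keys, key=lambda key: (coeff[f][key], -set_keys.index(key)))
            if coeff[f][best] > threshold:
                labels[factor_id(*f)] = best[1]
        return labels
    # unique mode: repeatedly give the globally best (factor, set) pair its label
    remaining_f = set(factors)
    remaining_s = set(set_keys)
    while remaining_f and remaining_s:
        best_pair = None
        best_val = threshold
        for f in sorted(remaining_f, key=factors.index):
            for key in set_keys:
                if key not in remaining_s:
                    continue
                v = coeff[f][key]
                if v > best_val:
                    best_val = v
                    best_pair = (f, key)
        if best_pair is None:
            break
        f, key = best_pair
        labels[factor_id(*f)] = key[1]
        remaining_f.remove(f)
        remaining_s.remove(key)
    return labels


def classify_factors(
    eta: np.ndarray, threshold: float = NEW_FACTOR_THRESHOLD
) -> list[str]:
    """Graph dependence below the threshold marks a factor as novel ("new");
    eta >= threshold means the prior graph shaped it ("modified")."""
    eta = np.asarray(eta, dtype=np.float64)
    if np.any((eta < 0) | (eta > 1)):
        raise ValueError("eta values must lie in [0, 1]")
    return ["new" if v < threshold else "modified" for v in eta]


def posterior_graph(params: ModelParams, scope: str = GLOBAL_SCOPE) -> np.ndarray:
    """Denoised edge probabilities <theta_i, B theta_j> for every gene pair.

    The diagonal is reported for completeness but does not correspond to an
    edge of the prior graph.
    """
    th = params.theta[scope]
    return np.clip(th @ params.B[scope] @ th.T, 0.0, 1.0)


def aggregate_positive(
    scores: CellScoreMatrix | np.ndarray,
    group_labels,
    positive_threshold: float = 0.001,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean over positive cells (> threshold) per group/factor, plus the
    positive fraction; groups with no positive cell get mean 0."""
    mat = scores.scores if isinstance(scores, CellScoreMatrix) else np.asarray(scores)
    cols = scores.factor_ids if isinstance(scores, CellScoreMatrix) else list(range(mat.shape[1]))
    labels = np.asarray(group_labels)
    if labels.shape[0] != mat.shape[0]:
        raise ValueError("group_labels length must match the number of cells")
    groups = pd.unique(labels)
    means = np.zeros((len(groups), mat.shape[1]))
    fracs = np.zeros((len(groups), mat.shape[1]))
    for gi, gname in enumerate(groups):
        rows = mat[labels == gname]
        pos = rows > positive_threshold
        counts = pos.sum(axis=0)
        with np.errstate(invalid="ignore"):
            m = np.where(counts > 0, (rows * pos).sum(axis=0) / np.maximum(counts, 1), 0.0)
        means[gi] = m
        fracs[gi] = counts / rows.shape[0]
    return (
        pd.DataFrame(means, index=groups, columns=cols),
        pd.DataFrame(fracs, index=groups, columns=cols),
    )


def cross_study_entropy(
    factor_scores: np.ndarray,
    study_labels,
    min_positive: int = 100,
    positive_threshold: float = 0.001,
) -> float | str:
    """Shannon entropy (nats) of study proportions among factor-positive cells.

    Factors with at most ``min_positive`` positive cells return the
    ``INSUFFICIENT`` sentinel — too few cells to call the factor shared
    across studies.
    """
    scores = np.asarray(factor_scores, dtype=np.float64)
    labels = np.asarray(study_labels)
    if labels.shape[0] != scores.shape[0]:
        raise ValueError("study_labels length must match the number of cells")
    positive = scores > positive_threshold
    n_pos = int(positive.sum())
    if n_pos <= min_positive:
        return INSUFFICIENT
    sub = labels[positive]
    _, counts = np.unique(sub, return_counts=True)
    props = counts / n_pos
    return float(-(props * np.log(props)).sum())


def factor_summary(
    params: ModelParams,
    hyper: ModelHyperparams,
    labels: dict[str, str | None] | None = None,
) -> pd.DataFrame:
    """Per-factor table: scope, eta (graph dependence) and new/modified call."""
    rows = []
    for scope, eta in params.eta().items():
        calls = classify_factors(eta)
        for k, (e, call) in enumerate(zip(eta, calls)):
            fid = factor_id(scope, k)
            rows.append(
                {
                    "factor": fid,
                    "scope": scope,
                    "eta": float(e),
                    "classification": call,
                    "label": labels.get(fid) if labels else None,
                }
            )
    return pd.DataFrame(rows).set_index("factor")
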