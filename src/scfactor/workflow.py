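"""End-to-end pipeline: restrict sets, build graphs, fit, write reports."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import EvalConfig, importance_score, information_score
from .genesets import GLOBAL_SCOPE, build_graph, read_gene_sets_json, restrict_to_vocabulary
from .inference import FitConfig, FitResult, fit as fit_model
from .io import read_cell_types, read_count_matrix, write_fit_result, _jsonable
from .model import ModelHyperparams
from .postprocess import cell_scores, factor_summary, gene_scores, label_factors
from .selection import default_num_factors

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Paths plus the per-stage configuration of a full run."""

    matrix_path: str
    out_dir: str
    gene_sets_path: str | None = None
    labels_path: str | None = None
    matrix_format: str = "dense_tsv"
    min_set_size: int = 3
    weighting: str = "clique_size"
    hyper: ModelHyperparams = field(default_factory=ModelHyperparams)
    fit: FitConfig = field(default_factory=FitConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)
    select_k: bool = True          # K from the sets+1 rule when not set explicitly
    k_explicit: int | None = None
    top_n_labels: int = 50

    def validate_paths(self) -> None:
        for p in (self.matrix_path, self.gene_sets_path, self.labels_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _stage(name):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: RunConfig) -> FitResult:
    """Run restrict → graph → (select K) → fit → scores/labels/metrics.

    Writes, under ``config.out_dir``: model.h5 (+ JSON sidecar),
    cell_scores.tsv, gene_scores_<scope>.tsv, factors.tsv (label, eta,
    classification, importance, information) and manifest.json capturing
    the full configuration and package version.
    """
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    X = _stage("read_matrix")(read_count_matrix)(config.matrix_path, fmt=config.matrix_format)
    if config.labels_path:
        X = _stage("read_labels")(read_cell_types)(config.labels_path, X)

    collection = graphs = None
    if config.gene_sets_path:
        collection = _stage("restrict_sets")(restrict_to_vocabulary)(
            read_gene_sets_json(config.gene_sets_path), X.vocab, config.min_set_size
        )
        graphs = _stage("build_graph")(build_graph)(
            collection, X.vocab, weighting=config.weighting
        )

    hyper = config.hyper
    if config.k_explicit is not None:
        hyper = ModelHyperparams(**{**asdict(hyper), "K": config.k_explicit})
    elif config.select_k and collection is not None:
        k = default_num_factors(collection, GLOBAL_SCOPE)
        k_c = {ct: default_num_factors(collection, ct) for ct in X.type_names}
        hyper = ModelHyperparams(**{**asdict(hyper), "K": k, "K_c": k_c})
        logger.info("factor counts from the sets+1 rule: K=%d, K_c=%s", k, k_c)

    result = _stage("fit")(fit_model)(X, graphs, hyper, config.fit, collection=collection)
    write_fit_result(result, out / "model.h5")

    cs = cell_scores(result.params, hyper)
    ids = X.cell_ids if X.cell_ids is not None else [f"cell{i}" for i in range(X.n_cells)]
    cs.as_frame(cell_ids=list(ids)).to_csv(out / "cell_scores.tsv", sep="\t")

    gs = gene_scores(result.params, hyper, genes=X.vocab.genes)
    for scope, mat in gs.scores.items():
        pd.DataFrame(mat, index=list(gs.genes)).to_csv(
            out / f"gene_scores_{scope}.tsv", sep="\t"
        )

    label_top_n = min(config.top_n_labels, X.n_genes)
    labels = label_factors(gs, collection, top_n=label_top_n) if collection else None
    summary = factor_summary(result.params, hyper, labels)

    importance: dict[str, float] = {}
    information: dict[str, float | None] = {}
    for scope, mat in gs.scores.items():
        cts = X.type_names if scope == GLOBAL_SCOPE else (scope,)
        for k in range(mat.shape[1]):
            fid = f"{scope}::{k}"
            per_ct_imp, per_ct_info = [], []
            order = np.argsort(-mat[:, k], kind="stable")
            for ct in cts:
                per_ct_imp.append(importance_score(X, result.params, hyper, ct, k, scope))
                sub = X.X[X.cells_of_type(ct)]
                try:
                    per_ct_info.append(
                        information_score(sub, order, M=min(config.eval.M, X.n_genes))
                    )
                except ZeroDivisionError:
                    pass
            importance[fid] = float(np.mean(per_ct_imp))
            information[fid] = float(np.mean(per_ct_info)) if per_ct_info else None
    summary["importance"] = pd.Series(importance)
    summary["information"] = pd.Series(information)
    summary.to_csv(out / "factors.tsv", sep="\t")

    manifest = {
        "package_version": __version__,
        "config": _jsonable(asdict(config)),
        "n_cells": X.n_cells,
        "n_genes": X.n_genes,
        "final_objective": result.final_objective,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
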