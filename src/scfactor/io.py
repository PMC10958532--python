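"""Readers and writers for the package's file formats.

Expression comes in as Matrix Market triplets (with row/column name
sidecars) or a dense TSV; labels as a 2-column TSV; fitted models go to an
HDF5 container with a JSON sidecar of hyperparameters and configuration.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

from .genesets import GLOBAL_SCOPE, GeneVocabulary
from .inference import FitConfig, FitResult
from .model import CountMatrix, ModelHyperparams, ModelParams

logger = logging.getLogger(__name__)

__all__ = [
    "read_count_matrix",
    "write_count_matrix",
    "read_cell_types",
    "write_fit_result",
    "read_fit_result",
]


def read_count_matrix(
    path,
    fmt: str = "dense_tsv",
    cells_path=None,
    genes_path=None,
) -> CountMatrix:
    """Load cells x genes expression.

    ``mtx``: triplet file plus name sidecars (default <path>.rows.txt for
    cells and <path>.cols.txt for genes).  ``dense_tsv``: header row of gene
    names, first column cell ids.
    """
    path = Path(path)
    if fmt == "mtx":
        mat = spio.mmread(path)
        X = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
        cells_path = Path(cells_path) if cells_path else path.with_suffix(path.suffix + ".rows.txt")
        genes_path = Path(genes_path) if genes_path else path.with_suffix(path.suffix + ".cols.txt")
        cell_ids = np.array(cells_path.read_text().split())
        genes = genes_path.read_text().split()
        if X.shape != (len(cell_ids), len(genes)):
            raise ValueError(
                f"matrix is {X.shape} but name files declare "
                f"({len(cell_ids)}, {len(genes)})"
            )
    elif fmt == "dense_tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
        if len(set(header)) != len(header):
            raise ValueError("duplicate gene names in input")
        df = pd.read_csv(path, sep="\t", index_col=0)
        X = df.to_numpy(dtype=np.float64)
        cell_ids = df.index.to_numpy(dtype=object)
        genes = header
    else:
        raise ValueError(f"unknown format {fmt!r}")
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene names in input")
    if np.any(X < 0):
        raise ValueError("negative expression values in input")
    vocab = GeneVocabulary.from_iterable(genes)
    # placeholder labels; read_cell_types aligns the real ones
    labels = np.array(["all"] * X.shape[0])
    return CountMatrix(X=X, cell_types=labels, vocab=vocab, cell_ids=np.asarray(cell_ids))


def write_count_matrix(X: CountMatrix, path, fmt: str = "dense_tsv") -> None:
    path = Path(path)
    if fmt == "dense_tsv":
        ids = X.cell_ids if X.cell_ids is not None else [f"cell{i}" for i in range(X.n_cells)]
        pd.DataFrame(X.X, index=list(ids), columns=list(X.vocab.genes)).to_csv(path, sep="\t")
    elif fmt == "mtx":
        spio.mmwrite(path, sparse.coo_matrix(X.X))
        ids = X.cell_ids if X.cell_ids is not None else [f"cell{i}" for i in range(X.n_cells)]
        path.with_suffix(path.suffix + ".rows.txt").write_text("\n".join(map(str, ids)) + "\n")
        path.with_suffix(path.suffix + ".cols.txt").write_text("\n".join(X.vocab.genes) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def read_cell_types(path, X: CountMatrix) -> CountMatrix:
    """Align a 2-column (cell id, cell type) file with the matrix cell order."""
    df = pd.read_csv(path, sep="\t", header=None, names=["cell", "cell_type"], dtype=str)
    mapping = dict(zip(df["cell"], df["cell_type"]))
    if X.cell_ids is None:
        raise ValueError("count matrix has no cell ids to align labels against")
    ids = [str(c) for c in X.cell_ids]
    missing = [c for c in ids if c not in mapping]
    if missing:
        raise ValueError(f"cells without labels: {missing[:10]}" + ("..." if len(missing) > 10 else ""))
    extra = set(mapping) - set(ids)
    if extra:
        logger.warning("ignoring %d labeled cells absent from the matrix", len(extra))
    labels = np.array([mapping[c] for c in ids])
    return CountMatrix(
        X=X.X, cell_types=labels, vocab=X.vocab, cell_ids=X.cell_ids
    )


# ---------------------------------------------------------------------------
# fitted-model container


def write_fit_result(result: FitResult, path, sidecar_path=None) -> None:
    """HDF5 datasets per parameter plus a JSON sidecar of hyper/config."""
    path = Path(path)
    params = result.params
    with h5py.File(path, "w") as h5:
        for ct, al in params.alpha.items():
            h5.create_dataset(f"alpha/{ct}", data=al)
        for scope, th in params.theta.items():
            name = "theta_global" if scope == GLOBAL_SCOPE else f"theta_{scope}"
            h5.create_dataset(name, data=th)
        for scope, gg in params.g.items():
            name = "g" if scope == GLOBAL_SCOPE else f"g_{scope}"
            h5.create_dataset(name, data=gg)
        for scope, bb in params.B.items():
            name = "B_global" if scope == GLOBAL_SCOPE else f"B_{scope}"
            h5.create_dataset(name, data=bb)
        scopes = list(params.theta)
        h5.create_dataset("kappa", data=np.array([params.kappa[s] for s in scopes]))
        h5.create_dataset("rho", data=np.array([params.rho[s] for s in scopes]))
        h5.create_dataset("scopes", data=np.array(scopes, dtype=h5py.string_dtype()))
        h5.create_dataset(
            "cell_types", data=np.asarray(params.cell_types, dtype=h5py.string_dtype())
        )
        h5.create_dataset(
            "type_names", data=np.array(params.type_names, dtype=h5py.string_dtype())
        )
        traj = np.array([(it, val) for _, it, val in result.objective_trajectory])
        h5.create_dataset("objective_trajectory", data=traj)
        h5.create_dataset(
            "trajectory_stages",
            data=np.array([s for s, _, _ in result.objective_trajectory], dtype=h5py.string_dtype()),
        )
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(path.suffix + ".json")
    meta = {
        "hyper": _jsonable(asdict(result.hyper)) if result.hyper else None,
        "config": _jsonable(asdict(result.config)) if result.config else None,
        "converged": result.converged,
    }
    sidecar.write_text(json.dumps(meta, indent=1))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_fit_result(path, sidecar_path=None) -> FitResult:
    path = Path(path)
    with h5py.File(path, "r") as h5:
        scopes = [s.decode() for s in h5["scopes"][...]]
        theta, g, B = {}, {}, {}
        for scope in scopes:
            tname = "theta_global" if scope == GLOBAL_SCOPE else f"theta_{scope}"
            gname = "g" if scope == GLOBAL_SCOPE else f"g_{scope}"
            bname = "B_global" if scope == GLOBAL_SCOPE else f"B_{scope}"
            theta[scope] = h5[tname][...]
            g[scope] = h5[gname][...]
            B[scope] = h5[bname][...]
        kappa = dict(zip(scopes, h5["kappa"][...]))
        rho = dict(zip(scopes, h5["rho"][...]))
        alpha = {ct: h5[f"alpha/{ct}"][...] for ct in h5["alpha"]}
        cell_types = np.array([s.decode() for s in h5["cell_types"][...]])
        type_names = tuple(s.decode() for s in h5["type_names"][...])
        traj_vals = h5["objective_trajectory"][...]
        stages = [s.decode() for s in h5["trajectory_stages"][...]]
    params = ModelParams(
        theta=theta, g=g, B=B, kappa={k: float(v) for k, v in kappa.items()},
        rho={k: float(v) for k, v in rho.items()}, alpha=alpha,
        cell_types=cell_types, type_names=type_names,
    )
    trajectory = [
        (stage, int(it), float(val)) for stage, (it, val) in zip(stages, traj_vals)
    ]
    sidecar = Path(sidecar_path) if sidecar_path else path.with_suffix(path.suffix + ".json")
    hyper = config = None
    converged: dict = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        converged = meta.get("converged", {})
        if meta.get("hyper"):
            hyper = ModelHyperparams(**meta["hyper"])
        if meta.get("config"):
            config = FitConfig(**meta["config"])
    return FitResult(
        params=params, objective_trajectory=trajectory, converged=converged,
        hyper=hyper, config=config,
    )
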