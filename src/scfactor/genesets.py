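"""Gene vocabularies, scoped gene-set collections and prior gene-gene graphs.

Prior knowledge enters the model as a weighted gene-gene graph per scope
(one "global" graph plus optionally one graph per cell type).  When the
prior is given as gene sets, each set becomes a fully connected clique;
edge weights downweight large sets so that no single large community
dominates the graph term of the objective.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

GLOBAL_SCOPE = "global"

__all__ = [
    "GLOBAL_SCOPE",
    "GeneVocabulary",
    "GeneSetCollection",
    "WeightedGeneGraph",
    "RestrictionReport",
    "restrict_to_vocabulary",
    "build_graph",
    "overlap_coefficient",
    "collection_stats",
    "read_gene_sets_json",
    "write_gene_sets_json",
    "write_edge_list",
    "read_edge_list",
]


@dataclass(frozen=True)
class GeneVocabulary:
    """Ordered, unique gene identifiers fixing matrix column order."""

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) == 0:
            raise ValueError("vocabulary must contain at least one gene")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        object.__setattr__(self, "_index", {g: i for i, g in enumerate(self.genes)})

    @classmethod
    def from_iterable(cls, genes: Iterable[str]) -> "GeneVocabulary":
        return cls(tuple(genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._index  # type: ignore[attr-defined]

    def index_of(self, gene: str) -> int:
        return self._index[gene]  # type: ignore[attr-defined]

    def indices(self, genes: Iterable[str]) -> np.ndarray:
        idx = self._index  # type: ignore[attr-defined]
        return np.array([idx[g] for g in genes], dtype=np.intp)


@dataclass
class RestrictionReport:
    """Which genes / sets were lost when intersecting with a vocabulary."""

    dropped_genes: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    dropped_sets: dict[str, list[str]] = field(default_factory=dict)

    def n_dropped_sets(self) -> int:
        return sum(len(v) for v in self.dropped_sets.values())


@dataclass
class GeneSetCollection:
    """Named gene sets grouped by scope ("global" or a cell-type name)."""

    scopes: dict[str, dict[str, list[str]]]
    restriction_report: RestrictionReport | None = None

    def __post_init__(self) -> None:
        for scope, sets in self.scopes.items():
            for name, genes in sets.items():
                if len(genes) == 0:
                    raise ValueError(f"gene set {name!r} in scope {scope!r} is empty")

    def scope_names(self) -> list[str]:
        return list(self.scopes)

    def sets_in_scope(self, scope: str) -> dict[str, list[str]]:
        return self.scopes.get(scope, {})

    def n_sets(self, scope: str | None = None) -> int:
        if scope is not None:
            return len(self.scopes.get(scope, {}))
        return sum(len(s) for s in self.scopes.values())

    def all_sets(self) -> dict[tuple[str, str], list[str]]:
        """Flat view keyed by (scope, set name)."""
        return {
            (scope, name): genes
            for scope, sets in self.scopes.items()
            for name, genes in sets.items()
        }


@dataclass
class WeightedGeneGraph:
    """Per-scope symmetric weighted gene-gene adjacency over a vocabulary.

    ``weights[scope]`` is a dense p x p nonnegative symmetric matrix with
    zero diagonal; the binary adjacency is derived as ``weights > 0``.
    """

    vocab: GeneVocabulary
    weights: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        p = len(self.vocab)
        for scope, w in self.weights.items():
            if w.shape != (p, p):
                raise ValueError(f"scope {scope!r}: weight matrix shape {w.shape} != ({p}, {p})")
            if np.any(w < 0):
                raise ValueError(f"scope {scope!r}: negative edge weights")
            if not np.allclose(w, w.T):
                raise ValueError(f"scope {scope!r}: weight matrix not symmetric")
            if np.any(np.diag(w) != 0):
                raise ValueError(f"scope {scope!r}: nonzero diagonal")

    def adjacency(self, scope: str) -> np.ndarray:
        return (self.weights[scope] > 0).astype(np.float64)

    def scope_names(self) -> list[str]:
        return list(self.weights)

    def n_edges(self, scope: str) -> int:
        return int(np.count_nonzero(np.triu(self.weights[scope])))


def overlap_coefficient(set1: Iterable[str], set2: Iterable[str]) -> float:
    """Szymkiewicz-Simpson coefficient: |A ∩ B| / min(|A|, |B|)."""
    a, b = set(set1), set(set2)
    if not a or not b:
        raise ValueError("overlap coefficient is undefined for empty sets")
    return len(a & b) / min(len(a), len(b))


def restrict_to_vocabulary(
    collection: GeneSetCollection,
    vocab: GeneVocabulary,
    min_size: int = 3,
) -> GeneSetCollection:
    """Intersect every gene set with the vocabulary, dropping small leftovers.

    Sets that fall below ``min_size`` after intersection are removed (a
    2-gene set contributes a single edge and carries almost no community
    information).  The dropped genes/sets are recorded on the returned
    collection's ``restriction_report`` and logged.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    report = RestrictionReport()
    out: dict[str, dict[str, list[str]]] = {}
    for scope, sets in collection.scopes.items():
        kept: dict[str, list[str]] = {}
        for name, genes in sets.items():
            inside = [g for g in genes if g in vocab]
            lost = [g for g in genes if g not in vocab]
            if lost:
                report.dropped_genes.setdefault(scope, {})[name] = lost
            if len(inside) >= min_size:
                kept[name] = inside
            else:
                report.dropped_sets.setdefault(scope, []).append(name)
                logger.info(
                    "dropping gene set %r (scope %r): %d/%d genes in vocabulary (< min_size=%d)",
                    name, scope, len(inside), len(genes), min_size,
                )
        out[scope] = kept
    if collection.n_sets() > 0 and sum(len(s) for s in out.values()) == 0:
        raise ValueError(
            "no gene sets survive vocabulary restriction in scopes: "
            + ", ".join(sorted(collection.scopes))
        )
    return GeneSetCollection(out, restriction_report=report)


def _clique_pairs(idx: np.ndarray):
    for a in range(len(idx)):
        for b in range(a + 1, len(idx)):
            yield idx[a], idx[b]


def build_graph(
    collection: GeneSetCollection,
    vocab: GeneVocabulary,
    weighting: str = "clique_size",
    custom_weights: Mapping[str, Mapping[tuple[str, str], float]] | None = None,
) -> WeightedGeneGraph:
    """Turn each gene set into a clique and accumulate edge weights per scope.

    weighting:
      clique_size  per-set raw weight 1/C(|G|,2), rescaled so the median
                   per-set weight is 1, then accumulated additively over sets
      max_degree   w_ij = 1 / max(d(i), d(j)) on the union clique graph
      uniform      every induced edge has weight 1

    ``custom_weights`` maps scope -> {(gene_i, gene_j): weight} and overrides
    the scheme's weight on those edges verbatim; supplying a pair that no set
    induces is an error.
    """
    if weighting not in ("clique_size", "max_degree", "uniform"):
        raise ValueError(f"unknown weighting scheme {weighting!r}")
    p = len(vocab)
    weights: dict[str, np.ndarray] = {}
    for scope, sets in collection.scopes.items():
        w = np.zeros((p, p))
        members = {name: vocab.indices(genes) for name, genes in sets.items()}
        # union adjacency determines the edge support under every scheme
        support = np.zeros((p, p), dtype=bool)
        for idx in members.values():
            ij = np.ix_(idx, idx)
            support[ij] = True
        np.fill_diagonal(support, False)

        if weighting == "uniform":
            w[support] = 1.0
        elif weighting == "max_degree":
            degree = support.sum(axis=1)
            ii, jj = np.nonzero(np.triu(support))
            vals = 1.0 / np.maximum(degree[ii], degree[jj])
            w[ii, jj] = vals
            w[jj, ii] = vals
        else:  # clique_size
            raw = {
                name: 1.0 / math.comb(len(idx), 2) if len(idx) >= 2 else 0.0
                for name, idx in members.items()
            }
            positive = [v for v in raw.values() if v > 0]
            med = float(np.median(positive)) if positive else 1.0
            for name, idx in members.items():
                if len(idx) < 2:
                    continue
                scaled = raw[name] / med
                ij = np.ix_(idx, idx)
                w[ij] += scaled
                w[np.diag_indices(p)] = 0.0  # undo self pairs added by the block
        np.fill_diagonal(w, 0.0)

        if custom_weights and scope in custom_weights:
            for (gi, gj), val in custom_weights[scope].items():
                a, b = vocab.index_of(gi), vocab.index_of(gj)
                if not support[a, b]:
                    raise ValueError(
                        f"custom weight for ({gi}, {gj}) in scope {scope!r}: "
                        "edge is not induced by any gene set"
                    )
                w[a, b] = w[b, a] = float(val)
        weights[scope] = w
    return WeightedGeneGraph(vocab=vocab, weights=weights)


def collection_stats(collection: GeneSetCollection) -> dict[str, float]:
    """Summary statistics: set count, median size, median pairwise overlap.

    The median pairwise overlap coefficient is taken over all unordered pairs
    of sets in the flattened collection.
    """
    flat = list(collection.all_sets().values())
    n = len(flat)
    sizes = [len(s) for s in flat]
    overlaps: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            overlaps.append(overlap_coefficient(flat[i], flat[j]))
    return {
        "n_sets": float(n),
        "median_set_size": float(np.median(sizes)) if sizes else float("nan"),
        "median_pairwise_overlap": float(np.median(overlaps)) if overlaps else float("nan"),
    }


# ---------------------------------------------------------------------------
# file formats


def read_gene_sets_json(path) -> GeneSetCollection:
    """JSON keyed by scope; values are {set_name: [gene, ...]}."""
    with open(path) as fh:
        data = json.load(fh)
    scopes = {
        str(scope): {str(name): [str(g) for g in genes] for name, genes in sets.items()}
        for scope, sets in data.items()
    }
    return GeneSetCollection(scopes)


def write_gene_sets_json(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        json.dump(collection.scopes, fh, indent=1)


def write_edge_list(graph: WeightedGeneGraph, scope: str, path) -> None:
    """3-column TSV (gene_i, gene_j, weight), each pair once, i < j by vocab order."""
    w = graph.weights[scope]
    genes = graph.vocab.genes
    ii, jj = np.nonzero(np.triu(w))
    with open(path, "w") as fh:
        for a, b in zip(ii, jj):
            fh.write(f"{genes[a]}\t{genes[b]}\t{w[a, b]:.10g}\n")


def read_edge_list(path, vocab: GeneVocabulary, scope: str = GLOBAL_SCOPE) -> WeightedGeneGraph:
    p = len(vocab)
    w = np.zeros((p, p))
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            gi, gj, val = line.split("\t")
            a, b = vocab.index_of(gi), vocab.index_of(gj)
            w[a, b] = w[b, a] = float(val)
    return WeightedGeneGraph(vocab=vocab, weights={scope: w})
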