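"""Choosing the number of factors per scope.

Two routes: the simple rule (number of gene sets available to the scope
plus one spare factor) and bulk eigenvalue matching — calibrating a
Gaussian noise null with Gamma-distributed column variances against the
bulk of the observed covariance spectrum, then counting observed
eigenvalues that clear the null's leading-eigenvalue quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genesets import GeneSetCollection

__all__ = ["KSelectionConfig", "default_num_factors", "estimate_num_factors"]


def _default_shape_grid() -> np.ndarray:
    return np.geomspace(0.1, 10.0, 30)


@dataclass
class KSelectionConfig:
    """Monte-Carlo settings for bulk eigenvalue matching.

    shape_grid values parameterize the Gamma(s, 1/s) variance model (mean-1
    variances; small s = heavy spread across genes).
    """

    n_draws: int = 100
    shape_grid: np.ndarray = field(default_factory=_default_shape_grid)
    bulk_quantiles: tuple[float, float] = (0.25, 0.75)
    q_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.bulk_quantiles
        if not 0 < lo < hi < 1:
            raise ValueError("bulk_quantiles must satisfy 0 < lower < upper < 1")
        if not 0 < self.q_level < 0.5:
            raise ValueError("q_level must lie in (0, 0.5)")
        self.shape_grid = np.asarray(self.shape_grid, dtype=np.float64)
        if np.any(self.shape_grid <= 0):
            raise ValueError("shape_grid must be positive")


def default_num_factors(collection: GeneSetCollection, scope: str) -> int:
    """Number of gene sets available to the scope, plus one spare factor."""
    return collection.n_sets(scope) + 1


def _null_spectra(
    rng: np.random.Generator, n: int, p: int, shape: float, scale: float, n_draws: int
) -> np.ndarray:
    """Sorted (descending) eigenvalues of (1/n) Z Z^T for each draw."""
    out = np.empty((n_draws, n))
    for d in range(n_draws):
        sigma = np.sqrt(rng.gamma(shape, scale, size=p))
        Z = rng.standard_normal((n, p)) * sigma
        ev = np.linalg.eigvalsh(Z @ Z.T / n)
        out[d] = ev[::-1]
    return out


def estimate_num_factors(X_c: np.ndarray, config: KSelectionConfig | None = None) -> int:
    """Bulk eigenvalue matching estimate of the factor count.

    1. For each candidate Gamma shape s, average the sorted null spectrum of
       (1/n) Z Z^T with column variances Gamma(s, 1/s) over ``n_draws``
       matrices, regress (no intercept) the observed bulk eigenvalues on the
       null bulk, and keep the shape minimizing the residual sum of squares.
    2. Re-simulate with variances Gamma(s, beta/s), beta the fitted slope,
       recording the leading eigenvalue of each draw.
    3. K = number of observed eigenvalues above the (1 - q_level) quantile
       of the simulated leading eigenvalues.
    """
    if config is None:
        config = KSelectionConfig()
    X_c = np.asarray(X_c, dtype=np.float64)
    n, p = X_c.shape
    if n < 2 or p < 2:
        raise ValueError("need at least 2 cells and 2 genes")
    Xc = X_c - X_c.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("degenerate input: zero variance in every gene")
    observed = np.linalg.eigvalsh(Xc @ Xc.T / n)[::-1]

    lo, hi = config.bulk_quantiles
    # bulk = order statistics between the quantile positions of the sorted spectrum
    i0, i1 = int(np.floor((1 - hi) * n)), int(np.ceil((1 - lo) * n))
    bulk_idx = np.arange(max(i0, 0), min(i1, n))
    obs_bulk = observed[bulk_idx]

    rng = np.random.default_rng(config.seed)
    best = None  # (rss, shape, beta)
    for s in config.shape_grid:
        null_mean = _null_spectra(rng, n, p, s, 1.0 / s, config.n_draws).mean(axis=0)
        null_bulk = null_mean[bulk_idx]
        beta = float(null_bulk @ obs_bulk / (null_bulk @ null_bulk))
        rss = float(np.sum((obs_bulk - beta * null_bulk) ** 2))
        if best is None or rss < best[0]:
            best = (rss, float(s), beta)
    _, shape, beta = best

    leading = _null_spectra(rng, n, p, shape, beta / shape, config.n_draws)[:, 0]
    threshold = float(np.quantile(leading, 1 - config.q_level))
    return int(np.sum(observed > threshold))
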