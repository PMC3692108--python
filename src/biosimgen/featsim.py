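"""Correlated numerical feature simulation via a Gaussian copula.

Each feature's marginal law is fitted with the 1-D density engine; the
dependence structure is the matrix of Spearman rank correlations, converted
to the normal-score (Pearson) scale by the exact transform
r = 2 sin(pi * rho / 6) and factorized with a Cholesky decomposition.
Sampling colors independent standard normals with the Cholesky factor,
pushes them through the normal CDF and inverts each marginal — so the
marginals are preserved exactly in law while the target rank correlations
are induced.

Grouping modes mirror how correlated features are simulated in practice:
``independent_1D`` (no copula), ``pairwise_2D`` / ``triplet_3D`` (each
declared pair/triplet simulated jointly, independence between groups) and
``full`` (one joint copula over all features).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .densities import FittedDensity, fit_density
from .seqio import FeatureMatrix

logger = logging.getLogger(__name__)

MODES = ("independent_1D", "pairwise_2D", "triplet_3D", "full")
_EIG_FLOOR = 1e-10


def spearman_to_pearson(rho: np.ndarray) -> np.ndarray:
    """Exact Spearman-to-Pearson conversion on the normal-score scale."""
    return 2.0 * np.sin(np.pi * np.asarray(rho) / 6.0)


def nearest_positive_definite(R: np.ndarray, floor: float = _EIG_FLOOR
                              ) -> tuple[np.ndarray, float]:
    """Eigenvalue-clipped repair; returns (repaired matrix, Frobenius distance)."""
    vals, vecs = np.linalg.eigh(R)
    if vals.min() > floor:
        return R, 0.0
    clipped = np.clip(vals, floor, None)
    fixed = (vecs * clipped) @ vecs.T
    d = np.sqrt(np.outer(np.diag(fixed), np.diag(fixed)))
    fixed = fixed / d
    np.fill_diagonal(fixed, 1.0)
    fixed = 0.5 * (fixed + fixed.T)
    dist = float(np.linalg.norm(fixed - R, "fro"))
    logger.info("correlation matrix repaired (Frobenius distance %.3g)", dist)
    return fixed, dist


def _cholesky_with_repair(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    R_fixed, dist = nearest_positive_definite(R)
    try:
        C = np.linalg.cholesky(R_fixed)
    except np.linalg.LinAlgError:
        R_fixed, extra = nearest_positive_definite(R_fixed, floor=1e-8)
        dist += extra
        C = np.linalg.cholesky(R_fixed)
    return R_fixed, C, dist


@dataclass
class CorrelationModel:
    """Fitted marginals + target rank correlations + Cholesky machinery."""

    feature_names: list[str]
    marginals: dict[str, FittedDensity]
    spearman: np.ndarray          # observed rank correlations (p x p)
    target_corr: np.ndarray       # normal-score correlation matrix used by the copula
    cholesky_factor: np.ndarray
    mode: str
    groups: list[tuple[int, ...]]
    repair_distance: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if not np.allclose(self.cholesky_factor @ self.cholesky_factor.T,
                           self.target_corr, atol=1e-8):
            raise ValueError("Cholesky factor does not reproduce target correlation")


def _auto_groups(spearman: np.ndarray, size: int) -> list[tuple[int, ...]]:
    """Greedy grouping by strongest |Spearman|, each feature used once."""
    p = spearman.shape[0]
    strength = np.abs(spearman.copy())
    np.fill_diagonal(strength, 0.0)
    remaining = set(range(p))
    groups: list[tuple[int, ...]] = []
    pairs = sorted(((strength[i, j], i, j) for i in range(p) for j in range(i + 1, p)),
                   reverse=True)
    for s, i, j in pairs:
        if i not in remaining or j not in remaining:
            continue
        g = [i, j]
        if size == 3:
            cand = [(strength[i, k] + strength[j, k], k)
                    for k in remaining - {i, j}]
            if cand:
                g.append(max(cand)[1])
        if len(g) == size:
            groups.append(tuple(sorted(g)))
            remaining -= set(g)
    for k in sorted(remaining):  # leftovers simulated independently
        groups.append((k,))
    return groups


def fit_correlation_model(data: FeatureMatrix, mode: str = "full",
                          groups: list[tuple[int, ...]] | None = None
                          ) -> CorrelationModel:
    """Fit marginals and the grouped rank-correlation structure of ``data``."""
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if data.n < 10:
        raise ValueError("need at least 10 rows to fit a correlation model")
    for j, name in enumerate(data.feature_names):
        if np.ptp(data.values[:, j]) == 0:
            raise ValueError(f"feature {name!r} is constant (zero variance)")

    marginals = {name: fit_density(data.values[:, j])
                 for j, name in enumerate(data.feature_names)}
    p = data.p
    if p == 1:
        spearman = np.ones((1, 1))
    else:
        rho = stats.spearmanr(data.values).statistic
        spearman = np.atleast_2d(rho) if p > 2 else np.array(
            [[1.0, float(rho)], [float(rho), 1.0]])
    np.fill_diagonal(spearman, 1.0)

    if mode == "independent_1D":
        groups = [(j,) for j in range(p)]
    elif mode == "full":
        groups = [tuple(range(p))]
    else:
        size = 2 if mode == "pairwise_2D" else 3
        if groups is None:
            groups = _auto_groups(spearman, size)
        else:
            groups = [tuple(g) for g in groups]
            for g in groups:
                if len(g) > size:
                    raise ValueError(f"group {g} larger than mode {mode} allows")
                if data.n < len(g):
                    raise ValueError("fewer rows than group size")

    # block-diagonal target: declared groups carry their observed correlations
    target = np.eye(p)
    for g in groups:
        for a in g:
            for b in g:
                target[a, b] = spearman_to_pearson(spearman[a, b])
    np.fill_diagonal(target, 1.0)
    target, C, dist = _cholesky_with_repair(target)
    return CorrelationModel(list(data.feature_names), marginals, spearman,
                            target, C, mode, groups, dist)


def simulate_features(model: CorrelationModel, n: int,
                      rng: np.random.Generator) -> FeatureMatrix:
    """Draw ``n`` rows: color normals with the Cholesky factor, invert marginals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = len(model.feature_names)
    eps = rng.standard_normal((n, p))
    if model.mode == "independent_1D":
        z = eps
    else:
        z = eps @ model.cholesky_factor.T
    u = stats.norm.cdf(z)
    # clamp away from the exact endpoints so the inverse stays inside support
    u = np.clip(u, 1e-12, 1.0 - 1e-12)
    values = np.empty((n, p))
    for j, name in enumerate(model.feature_names):
        values[:, j] = model.marginals[name].quantile(u[:, j])
    ids = [f"sim_{i + 1:06d}" for i in range(n)]
    return FeatureMatrix(ids, list(model.feature_names), values)
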