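"""Fuzzy c-means clustering.

Minimizes the objective

    J = sum_j sum_q  u_jq^m * ||x_q - cen_j||^2

over memberships U (cl x n, columns summing to 1) and centers Cen by the
classical alternating updates: centers are membership-weighted means,
memberships follow

    u_jq = [ sum_s (||x_q - cen_j|| / ||x_q - cen_s||)^(2/(m-1)) ]^(-1)

with Euclidean distances. The fuzzification coefficient ``m`` must be
strictly greater than 1 (the update is undefined at m=1; m -> 1+ approaches
hard k-means). Iteration stops when the largest membership change falls to
``epsilon`` or below. A point coinciding with one or more centers receives
membership split equally among the coincident centers, zero elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class FcmConfig:
    cl: int = 2
    m: float = 2.0
    epsilon: float = 1e-6
    max_iter: int = 300
    n_init: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cl < 2:
            raise ValueError("cl must be >= 2")
        if not self.m > 1:
            raise ValueError("fuzzification coefficient m must be > 1")
        if not 0 < self.epsilon < 1:
            raise ValueError("epsilon must lie in (0, 1)")


@dataclass
class FuzzyPartition:
    memberships: np.ndarray  # cl x n, columns sum to 1
    centers: np.ndarray  # cl x a
    objective: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    seed: int = 0

    @property
    def cl(self) -> int:
        return self.memberships.shape[0]

    @property
    def n_points(self) -> int:
        return self.memberships.shape[1]


def _update_memberships(dist2: np.ndarray, m: float) -> np.ndarray:
    """Membership update from squared distances (cl x n)."""
    exponent = 1.0 / (m - 1.0)
    zero_mask = dist2 <= 0
    coincident = zero_mask.any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = dist2 ** (-exponent)
        u = inv / inv.sum(axis=0)
    if coincident.any():
        hard = zero_mask[:, coincident].astype(float)
        u[:, coincident] = hard / hard.sum(axis=0)
    return u


def _objective(points: np.ndarray, u: np.ndarray, centers: np.ndarray, m: float) -> float:
    dist2 = cdist(centers, points, metric="sqeuclidean")
    return float(np.sum(u**m * dist2))


def evaluate_objective(
    points: np.ndarray, u: np.ndarray, centers: np.ndarray, m: float = 2.0
) -> float:
    """Direct evaluation of J at a given (U, Cen); exposed for checks."""
    return _objective(np.asarray(points, float), np.asarray(u, float),
                      np.asarray(centers, float), m)


def _single_run(points: np.ndarray, config: FcmConfig, rng: np.random.Generator
                ) -> FuzzyPartition:
    n = points.shape[0]
    u = rng.uniform(size=(config.cl, n))
    u /= u.sum(axis=0)
    trajectory: list[float] = []
    converged = False
    n_iter = 0
    centers = np.empty((config.cl, points.shape[1]))
    for n_iter in range(1, config.max_iter + 1):
        um = u**config.m
        centers = (um @ points) / um.sum(axis=1, keepdims=True)
        dist2 = cdist(centers, points, metric="sqeuclidean")
        u_new = _update_memberships(dist2, config.m)
        trajectory.append(float(np.sum(u_new**config.m * dist2)))
        delta = np.max(np.abs(u_new - u))
        u = u_new
        if delta <= config.epsilon:
            converged = True
            break
    return FuzzyPartition(
        memberships=u,
        centers=centers,
        objective=trajectory,
        n_iter=n_iter,
        converged=converged,
        seed=config.seed,
    )


def fcm(points: np.ndarray, config: FcmConfig | None = None, **kwargs) -> FuzzyPartition:
    """Cluster points (n x a, rows are observations) by fuzzy c-means.

    Runs ``n_init`` restarts from seeded random membership initializations
    and returns the run with the smallest final objective.
    """
    if config is None:
        config = FcmConfig(**kwargs)
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be a 2-D array (n x a)")
    if not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite values")
    if config.cl > points.shape[0]:
        raise ValueError(f"cl={config.cl} exceeds n={points.shape[0]} points")
    rng = np.random.default_rng(config.seed)
    best: FuzzyPartition | None = None
    for _ in range(config.n_init):
        run = _single_run(points, config, rng)
        if best is None or run.objective[-1] < best.objective[-1]:
            best = run
    return best


def crisp_assign(u: np.ndarray) -> np.ndarray:
    """Hard labels from a membership matrix: argmax per column, ties to the
    lowest cluster index. Labels are 0-based cluster indices."""
    u = np.asarray(u, dtype=float)
    return np.argmax(u, axis=0)
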