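"""Fuzzy cluster validity indices.

Four scalar summaries of a fuzzy partition of n points into cl clusters:

* Partition entropy,  PE = -(1/n) sum_jq u_jq ln u_jq,  in [0, ln cl];
  0 for hard partitions, ln(cl) for uniform memberships; lower is better.
* Partition coefficient,  PC = (1/n) sum_jq u_jq^2,  in [1/cl, 1];
  1 for hard partitions; higher is better.
* Modified partition coefficient, MPC = 1 - cl/(cl-1) * (1 - PC), an affine
  rescaling of PC to [0, 1] removing its dependence on cl.
* Fuzzy silhouette, a membership-weighted mean of per-point crisp
  silhouette values S(x) = (beta - delta)/max(beta, delta) with weights
  u1 - u2 (gap between each point's two largest memberships); in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from mofuzz.errors import DegeneratePartitionError
from mofuzz.fcm import crisp_assign


@dataclass
class ValidityScores:
    cl: int
    FSI: float
    PE: float
    PC: float
    MPC: float

    def as_row(self) -> dict:
        return {"cl": self.cl, "FSI": self.FSI, "PE": self.PE,
                "PC": self.PC, "MPC": self.MPC}


def partition_entropy(u: np.ndarray) -> float:
    """PE with the 0*ln(0) = 0 convention; natural log."""
    u = np.asarray(u, dtype=float)
    n = u.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(u > 0, u * np.log(u), 0.0)
    return float(-terms.sum() / n)


def partition_coefficient(u: np.ndarray) -> float:
    u = np.asarray(u, dtype=float)
    return float((u**2).sum() / u.shape[1])


def modified_partition_coefficient(pc: float, cl: int) -> float:
    if cl < 2:
        raise ValueError("cl must be >= 2")
    if not (1.0 / cl - 1e-9 <= pc <= 1 + 1e-9):
        raise ValueError(f"PC={pc} outside [1/{cl}, 1]")
    return 1.0 - (cl / (cl - 1.0)) * (1.0 - pc)


def _crisp_silhouette_values(points: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Per-point silhouette of a hard labeling; singletons score 0."""
    n = points.shape[0]
    dist = cdist(points, points)
    clusters = np.unique(labels)
    s = np.zeros(n)
    for q in range(n):
        own = labels[q]
        own_mask = labels == own
        n_own = own_mask.sum()
        if n_own <= 1:
            s[q] = 0.0
            continue
        delta = dist[q, own_mask].sum() / (n_own - 1)
        beta = min(
            dist[q, labels == other].mean() for other in clusters if other != own
        )
        s[q] = (beta - delta) / max(beta, delta)
    return s


def fuzzy_silhouette(points: np.ndarray, u: np.ndarray) -> float:
    """Fuzzy silhouette index of a partition over the given feature matrix.

    Crisp clusters come from the membership argmax; points in singleton
    crisp clusters contribute silhouette 0. Raises when every point's two
    top memberships tie (no weight anywhere).
    """
    points = np.asarray(points, dtype=float)
    u = np.asarray(u, dtype=float)
    if points.shape[0] != u.shape[1]:
        raise ValueError("points and membership matrix disagree on n")
    labels = crisp_assign(u)
    top2 = np.sort(u, axis=0)[-2:, :]
    weights = top2[1] - top2[0]
    if np.all(weights <= 0):
        raise DegeneratePartitionError("all membership gaps u1-u2 are zero")
    s = _crisp_silhouette_values(points, labels)
    return float((weights * s).sum() / weights.sum())


def score_partition(points: np.ndarray, u: np.ndarray) -> ValidityScores:
    """All four indices of one fuzzy partition."""
    cl = int(np.asarray(u).shape[0])
    pc = partition_coefficient(u)
    return ValidityScores(
        cl=cl,
        FSI=fuzzy_silhouette(points, u),
        PE=partition_entropy(u),
        PC=pc,
        MPC=modified_partition_coefficient(pc, cl),
    )
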