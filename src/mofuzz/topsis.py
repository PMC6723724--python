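"""TOPSIS multi-criteria ranking of candidate clusterings.

Alternatives (rows) are scored against criteria (columns) by closeness to
an ideal solution: the decision matrix is normalized, weighted, the
per-criterion best (ideal) and worst (anti-ideal) profiles are formed, and
each alternative's relative closeness RC = d- / (d- + d+) in [0, 1] ranks
the alternatives (1 = best). Three normalizations are supported:

* ``vector``  — column root-sum-square scaling,
* ``max``     — column-maximum scaling,
* ``minmax``  — range scaling, with cost columns reversed so every
  normalized column is benefit-oriented.

Separations use the Minkowski-p distance (p=2 is the usual Euclidean).

For selecting the cluster number from the four validity indices the
package pins one configuration, chosen once by brute-force calibration of
all supported variants against a published worked example (see
``pinned_config`` and ``calibrate_configuration``): vector normalization,
p=2, and criterion weights (1/3, 0, 1/3, 1/3) for (FSI, PE, PC, MPC) —
partition entropy carries zero weight because it is the only configuration
family in which the worst alternative is the anti-ideal on every effective
criterion, as the worked example requires.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from mofuzz.errors import DegenerateColumnError

VARIANTS = ("vector", "max", "minmax")

#: Configuration pinned by calibrate_configuration against the published
#: worked example; used by the pipeline's cluster-number selection.
PINNED_VARIANT = "vector"
PINNED_P = 2
PINNED_WEIGHTS = (1.0 / 3.0, 0.0, 1.0 / 3.0, 1.0 / 3.0)  # FSI, PE, PC, MPC


@dataclass
class DecisionMatrix:
    """Alternatives x criteria values with impacts and weights."""

    values: np.ndarray
    impacts: list[str]  # "benefit" or "cost" per criterion
    weights: np.ndarray | None = None
    alternatives: list[str] = field(default_factory=list)
    criteria: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        m, n = self.values.shape
        if len(self.impacts) != n:
            raise ValueError("impacts length must equal the criterion count")
        if any(i not in ("benefit", "cost") for i in self.impacts):
            raise ValueError("impacts must be 'benefit' or 'cost'")
        if self.weights is None:
            self.weights = np.full(n, 1.0 / n)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be non-negative and sum to 1")
        if not self.alternatives:
            self.alternatives = [f"A{i + 1}" for i in range(m)]
        if not self.criteria:
            self.criteria = [f"C{j + 1}" for j in range(n)]


@dataclass
class TopsisResult:
    normalized: np.ndarray
    weighted: np.ndarray
    ideal: np.ndarray
    anti_ideal: np.ndarray
    sep_ideal: np.ndarray
    sep_anti_ideal: np.ndarray
    closeness: np.ndarray
    ranks: np.ndarray
    alternatives: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "alternative": self.alternatives,
                "closeness": self.closeness,
                "rank": self.ranks,
            }
        )


def normalize_decision_matrix(
    values: np.ndarray, variant: str, impacts: list[str] | None = None
) -> np.ndarray:
    """Normalize a decision matrix by one of the three supported schemes.

    Under ``minmax`` the cost columns are reversed, so the output is
    benefit-oriented in every column; ``vector`` and ``max`` leave impact
    handling to the ideal-solution step.
    """
    values = np.asarray(values, dtype=float)
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    if variant == "vector":
        norms = np.sqrt((values**2).sum(axis=0))
        if np.any(norms == 0):
            raise DegenerateColumnError("all-zero column under vector normalization")
        return values / norms
    if variant == "max":
        col_max = values.max(axis=0)
        if np.any(col_max == 0):
            raise DegenerateColumnError("zero column maximum under max normalization")
        return values / col_max
    if impacts is None:
        impacts = ["benefit"] * values.shape[1]
    col_min, col_max = values.min(axis=0), values.max(axis=0)
    rng = col_max - col_min
    if np.any(rng == 0):
        raise DegenerateColumnError("constant column under minmax normalization")
    benefit = np.array([i == "benefit" for i in impacts])
    return np.where(benefit, (values - col_min) / rng, (col_max - values) / rng)


def ideal_solutions(
    weighted: np.ndarray, impacts: list[str], variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Ideal (best) and anti-ideal (worst) profiles of a weighted matrix."""
    weighted = np.asarray(weighted, dtype=float)
    if variant == "minmax":  # all columns already benefit-oriented
        return weighted.max(axis=0), weighted.min(axis=0)
    benefit = np.array([i == "benefit" for i in impacts])
    ideal = np.where(benefit, weighted.max(axis=0), weighted.min(axis=0))
    anti = np.where(benefit, weighted.min(axis=0), weighted.max(axis=0))
    return ideal, anti


def separations(
    weighted: np.ndarray, ideal: np.ndarray, anti_ideal: np.ndarray, p: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Minkowski-p distances of each alternative to the two profiles."""
    if p < 1:
        raise ValueError("p must be >= 1")
    weighted = np.asarray(weighted, dtype=float)
    d_plus = (np.abs(weighted - ideal) ** p).sum(axis=1) ** (1.0 / p)
    d_minus = (np.abs(weighted - anti_ideal) ** p).sum(axis=1) ** (1.0 / p)
    return d_plus, d_minus


def relative_closeness(
    d_plus: np.ndarray, d_minus: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """RC = d- / (d- + d+) and descending-RC ranks (ties share the better
    rank). Identical alternatives (both separations zero) score 0.5."""
    d_plus = np.asarray(d_plus, dtype=float)
    d_minus = np.asarray(d_minus, dtype=float)
    total = d_plus + d_minus
    rc = np.where(total == 0, 0.5, np.divide(
        d_minus, np.where(total == 0, 1.0, total)))
    ranks = rankdata(-rc, method="min").astype(int)
    return rc, ranks


def topsis_rank(
    dm: DecisionMatrix, variant: str = PINNED_VARIANT, p: int = PINNED_P
) -> TopsisResult:
    """Full TOPSIS ranking of a decision matrix."""
    normalized = normalize_decision_matrix(dm.values, variant, dm.impacts)
    weighted = normalized * dm.weights
    ideal, anti = ideal_solutions(weighted, dm.impacts, variant)
    d_plus, d_minus = separations(weighted, ideal, anti, p)
    rc, ranks = relative_closeness(d_plus, d_minus)
    return TopsisResult(
        normalized=normalized,
        weighted=weighted,
        ideal=ideal,
        anti_ideal=anti,
        sep_ideal=d_plus,
        sep_anti_ideal=d_minus,
        closeness=rc,
        ranks=ranks,
        alternatives=list(dm.alternatives),
    )


def pinned_config() -> dict:
    """The calibrated configuration used for cluster-number selection."""
    return {
        "variant": PINNED_VARIANT,
        "p": PINNED_P,
        "weights": list(PINNED_WEIGHTS),
    }


def calibrate_configuration(
    dm: DecisionMatrix, reference_scores: np.ndarray, pe_index: int = 1
) -> dict:
    """Brute-force the configuration best matching a reference RC column.

    Evaluates every combination of normalization variant, Minkowski
    p in {1, 2}, and two treatments of the minimization criterion at
    ``pe_index`` (as a cost criterion with an equal weight share, or
    zero-weighted with equal weights on the rest), and returns the
    combination minimizing the worst-case absolute deviation from
    ``reference_scores``.
    """
    reference_scores = np.asarray(reference_scores, dtype=float)
    n_crit = dm.values.shape[1]
    best: dict | None = None
    for variant, pe_mode, p in itertools.product(VARIANTS, ("cost", "zero"), (1, 2)):
        if pe_mode == "cost":
            weights = np.full(n_crit, 1.0 / n_crit)
        else:
            weights = np.full(n_crit, 1.0 / (n_crit - 1))
            weights[pe_index] = 0.0
        trial = DecisionMatrix(
            dm.values, list(dm.impacts), weights,
            list(dm.alternatives), list(dm.criteria),
        )
        rc = topsis_rank(trial, variant=variant, p=p).closeness
        max_dev = float(np.max(np.abs(rc - reference_scores)))
        cand = {
            "variant": variant,
            "pe_mode": pe_mode,
            "p": p,
            "weights": weights.tolist(),
            "max_abs_deviation": max_dev,
        }
        if best is None or max_dev < best["max_abs_deviation"]:
            best = cand
    return best
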