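import itertools

import numpy as np
import pytest

from mofuzz.errors import DegenerateColumnError
from mofuzz.simulate import table1_fixture, table2_scores
from mofuzz.topsis import (
    PINNED_WEIGHTS,
    DecisionMatrix,
    calibrate_configuration,
    ideal_solutions,
    normalize_decision_matrix,
    relative_closeness,
    separations,
    topsis_rank,
)


def brute_force_topsis(values, impacts, weights, p=2):
    """Independent scalar-loop TOPSIS with vector normalization."""
    m, n = values.shape
    norm = [[0.0] * n for _ in range(m)]
    for j in range(n):
        denom = sum(values[i][j] ** 2 for i in range(m)) ** 0.5
        for i in range(m):
            norm[i][j] = values[i][j] / denom * weights[j]
    ideal, anti = [], []
    for j in range(n):
        col = [norm[i][j] for i in range(m)]
        if impacts[j] == "benefit":
            ideal.append(max(col)); anti.append(min(col))
        else:
            ideal.append(min(col)); anti.append(max(col))
    rc = []
    for i in range(m):
        dp = sum(abs(norm[i][j] - ideal[j]) ** p for j in range(n)) ** (1 / p)
        dn = sum(abs(norm[i][j] - anti[j]) ** p for j in range(n)) ** (1 / p)
        rc.append(0.5 if dp + dn == 0 else dn / (dp + dn))
    return np.array(rc)


class TestNormalization:
    def test_vector_on_three_four_five_triangle(self):
        out = normalize_decision_matrix(np.array([[3.0], [4.0]]), "vector")
        np.testing.assert_allclose(out.ravel(), [0.6, 0.8])

    def test_minmax_benefit_and_cost(self):
        col = np.array([[2.0], [1.0]])
        np.testing.assert_allclose(
            normalize_decision_matrix(col, "minmax", ["benefit"]).ravel(), [1.0, 0.0]
        )
        np.testing.assert_allclose(
            normalize_decision_matrix(col, "minmax", ["cost"]).ravel(), [0.0, 1.0]
        )

    def test_max_variant(self):
        out = normalize_decision_matrix(np.array([[1.0, 10.0], [2.0, 5.0]]), "max")
        np.testing.assert_allclose(out, [[0.5, 1.0], [1.0, 0.5]])

    def test_degenerate_columns_raise(self):
        with pytest.raises(DegenerateColumnError):
            normalize_decision_matrix(np.zeros((2, 1)), "vector")
        with pytest.raises(DegenerateColumnError):
            normalize_decision_matrix(np.ones((2, 1)), "minmax", ["benefit"])

    def test_table1_vector_normalization_is_columnwise(self):
        dm = table1_fixture()
        out = normalize_decision_matrix(dm.values, "vector")
        fsi = dm.values[:, 0]
        np.testing.assert_allclose(out[:, 0], fsi / np.sqrt((fsi**2).sum()))


class TestIdealSolutions:
    def test_benefit_extremes(self):
        v = np.array([[1.0, 0.0], [0.0, 1.0]])
        ideal, anti = ideal_solutions(v, ["benefit", "benefit"], "vector")
        np.testing.assert_allclose(ideal, [1, 1])
        np.testing.assert_allclose(anti, [0, 0])

    def test_dominating_row_is_ideal(self):
        v = np.array([[3.0, 5.0], [1.0, 2.0]])
        ideal, _ = ideal_solutions(v, ["benefit", "benefit"], "vector")
        np.testing.assert_allclose(ideal, v[0])

    def test_worst_row_of_table1_is_anti_ideal_on_benefit_criteria(self):
        dm = table1_fixture()
        weighted = normalize_decision_matrix(dm.values, "vector") * dm.weights
        _, anti = ideal_solutions(weighted, dm.impacts, "vector")
        # the cl=10 row is column-wise worst on FSI, PC, MPC
        np.testing.assert_allclose(anti[[0, 2, 3]], weighted[-1, [0, 2, 3]])


class TestSeparations:
    def test_zero_distance_to_matching_profile(self):
        v = np.array([[1.0, 2.0], [0.0, 0.0]])
        d_plus, d_minus = separations(v, v[0], v[1])
        assert d_plus[0] == 0.0 and d_minus[1] == 0.0

    @pytest.mark.parametrize("p", [1, 2])
    def test_matches_direct_minkowski(self, p):
        rng = np.random.default_rng(0)
        v = rng.uniform(size=(4, 3))
        ideal, anti = v.max(axis=0), v.min(axis=0)
        d_plus, d_minus = separations(v, ideal, anti, p)
        for i in range(4):
            assert d_plus[i] == pytest.approx(
                sum(abs(v[i, j] - ideal[j]) ** p for j in range(3)) ** (1 / p)
            )
            assert d_minus[i] == pytest.approx(
                sum(abs(v[i, j] - anti[j]) ** p for j in range(3)) ** (1 / p)
            )


class TestRelativeCloseness:
    def test_extremes_and_tie_convention(self):
        rc, ranks = relative_closeness(np.array([0.0, 1.0]), np.array([1.0, 0.0]))
        assert rc.tolist() == [1.0, 0.0]
        assert ranks.tolist() == [1, 2]
        rc, ranks = relative_closeness(np.zeros(3), np.zeros(3))
        assert rc.tolist() == [0.5, 0.5, 0.5]
        assert ranks.tolist() == [1, 1, 1]


class TestTopsisRank:
    def test_identical_alternatives_share_rank_one(self):
        dm = DecisionMatrix(np.ones((3, 2)), ["benefit", "benefit"])
        res = topsis_rank(dm, variant="vector", p=2)
        assert res.closeness.tolist() == [0.5, 0.5, 0.5]
        assert res.ranks.tolist() == [1, 1, 1]

    def test_dominant_alternative_scores_one(self):
        dm = DecisionMatrix(np.array([[5.0, 5.0], [1.0, 1.0]]), ["benefit", "benefit"])
        res = topsis_rank(dm)
        assert res.closeness[0] == pytest.approx(1.0)
        assert res.closeness[1] == pytest.approx(0.0)

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(1, 5, size=(5, 3))
        dm = DecisionMatrix(values, ["benefit", "cost", "benefit"])
        perm = rng.permutation(5)
        dm_perm = DecisionMatrix(values[perm], ["benefit", "cost", "benefit"])
        np.testing.assert_allclose(
            topsis_rank(dm).closeness[perm], topsis_rank(dm_perm).closeness
        )

    def test_scale_invariance_under_vector_normalization(self):
        rng = np.random.default_rng(2)
        values = rng.uniform(1, 5, size=(4, 3))
        impacts = ["benefit", "cost", "benefit"]
        scaled = values * np.array([7.0, 0.3, 1000.0])
        np.testing.assert_allclose(
            topsis_rank(DecisionMatrix(values, impacts)).closeness,
            topsis_rank(DecisionMatrix(scaled, impacts)).closeness,
        )

    def test_agrees_with_brute_force_on_all_small_integer_matrices(self):
        """Exhaustive check over every 3-alternative x 2-criterion matrix
        with entries in {1, 2, 3}, for both impact patterns."""
        weights = [0.5, 0.5]
        for entries in itertools.product([1.0, 2.0, 3.0], repeat=6):
            values = np.array(entries).reshape(3, 2)
            for impacts in (["benefit", "benefit"], ["benefit", "cost"]):
                expected = brute_force_topsis(values, impacts, weights)
                got = topsis_rank(
                    DecisionMatrix(values, impacts, np.array(weights))
                ).closeness
                np.testing.assert_allclose(got, expected, atol=1e-12)


class TestWorkedExampleRegression:
    def test_pinned_configuration_reproduces_published_ranking(self):
        dm = table1_fixture()
        pinned = DecisionMatrix(
            dm.values, dm.impacts, np.array(PINNED_WEIGHTS),
            dm.alternatives, dm.criteria,
        )
        res = topsis_rank(pinned)
        assert res.ranks.tolist() == list(range(1, 10))
        assert res.closeness[0] == pytest.approx(0.858, abs=0.02)
        assert res.closeness[-1] == 0.0

    def test_calibration_selects_the_pinned_configuration(self):
        best = calibrate_configuration(table1_fixture(), table2_scores())
        assert best["variant"] == "vector"
        assert best["pe_mode"] == "zero"
        assert best["p"] == 2
        assert best["max_abs_deviation"] < 0.05
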