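import numpy as np
import pytest
from scipy import special, stats

from mofuzz.diffexp import (
    bonferroni,
    call_markers,
    fit_variance_prior,
    log_transform,
    moderated_t_test,
)
from mofuzz.errors import GroupTooSmallError
from mofuzz.sc_io import CountMatrix
from mofuzz.simulate import generate_counts
from mofuzz.normalize import depth_scale


def oracle_moderated_t(expr, labels, cluster):
    """Step-by-step re-derivation of the moderated t for the test.

    Same model, independent numerics: scalar loops, and the trigamma
    equation solved by bisection instead of Newton.
    """
    in_grp = labels == cluster
    x1, x2 = expr[:, in_grp], expr[:, ~in_grp]
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    deltas, s2s = [], []
    for g in range(expr.shape[0]):
        m1, m2 = x1[g].mean(), x2[g].mean()
        ss = ((x1[g] - m1) ** 2).sum() + ((x2[g] - m2) ** 2).sum()
        deltas.append(m1 - m2)
        s2s.append(ss / df)
    z = np.log(s2s)
    excess = z.var(ddof=1) - special.polygamma(1, df / 2)
    base = z.mean() - special.digamma(df / 2) + np.log(df / 2)
    if excess <= 0:
        d0, s0_2 = np.inf, np.exp(base)
    else:
        lo, hi = 1e-6, 1e9
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if special.polygamma(1, mid) > excess:
                lo = mid
            else:
                hi = mid
        d0 = 2 * lo
        s0_2 = np.exp(base + special.digamma(d0 / 2) - np.log(d0 / 2))
    ts, ps = [], []
    for delta, s2 in zip(deltas, s2s):
        if np.isinf(d0):
            s2_mod, df_tot = s0_2, np.inf
        else:
            s2_mod, df_tot = (d0 * s0_2 + df * s2) / (d0 + df), d0 + df
        t = delta / np.sqrt(s2_mod * (1 / n1 + 1 / n2))
        p = (
            2 * stats.norm.sf(abs(t))
            if np.isinf(df_tot)
            else 2 * stats.t.sf(abs(t), df_tot)
        )
        ts.append(t)
        ps.append(p)
    return np.array(ts), np.array(ps)


class TestLogTransform:
    def test_small_integer_values(self):
        m = CountMatrix(np.array([[0.0, 1.0], [3.0, 7.0]]))
        np.testing.assert_allclose(log_transform(m), [[0, 1], [2, 3]])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(np.array([[-0.5]]))


class TestModeratedT:
    def test_identical_group_means_give_null_statistic(self):
        expr = np.tile(np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]]), (3, 1))
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = moderated_t_test(expr, labels, 0)
        np.testing.assert_allclose(res.table["t"], 0.0)
        np.testing.assert_allclose(res.table["p_value"], 1.0)

    def test_matches_step_by_step_oracle_on_hand_matrix(self):
        expr = np.array(
            [
                [1.0, 2.0, 1.5, 4.0, 5.0, 4.5],
                [3.0, 3.1, 2.9, 3.0, 3.2, 2.8],
                [0.0, 1.0, 0.5, 2.0, 0.5, 1.5],
            ]
        )
        labels = np.array([0, 0, 0, 1, 1, 1])
        res = moderated_t_test(expr, labels, 0)
        t_exp, p_exp = oracle_moderated_t(expr, labels, 0)
        np.testing.assert_allclose(res.table["t"], t_exp, rtol=1e-6)
        np.testing.assert_allclose(res.table["p_value"], p_exp, rtol=1e-6)

    def test_label_swap_negates_t_and_preserves_p(self):
        rng = np.random.default_rng(0)
        expr = rng.normal(size=(50, 20))
        labels = np.repeat([0, 1], 10)
        res_a = moderated_t_test(expr, labels, 0)
        res_b = moderated_t_test(expr, 1 - labels, 0)
        np.testing.assert_allclose(res_a.table["t"], -res_b.table["t"], atol=1e-12)
        np.testing.assert_allclose(
            res_a.table["p_value"], res_b.table["p_value"], atol=1e-12
        )

    def test_larger_effects_never_shrink_the_statistic(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(size=(1, 40))
        labels = np.repeat([0, 1], 20)
        background = rng.normal(size=(199, 40))
        t_values = []
        for effect in [0.0, 0.5, 1.0, 2.0]:
            expr = np.vstack([noise + effect * (labels == 0), background])
            res = moderated_t_test(expr, labels, 0)
            t_values.append(abs(res.table["t"].iloc[0]))
        assert all(b >= a for a, b in zip(t_values, t_values[1:]))

    def test_equal_variance_limit_approaches_ordinary_t(self):
        rng = np.random.default_rng(5)
        expr = rng.normal(0, 1, size=(300, 200))
        labels = np.repeat([0, 1], 100)
        res = moderated_t_test(expr, labels, 0)
        in_grp = labels == 0
        t_ord = stats.ttest_ind(
            expr[:, in_grp], expr[:, ~in_grp], axis=1, equal_var=True
        ).statistic
        assert res.d0 > 50  # near-common variance -> heavy shrinkage
        assert np.corrcoef(res.table["t"], t_ord)[0, 1] > 0.99
        ratio = res.table["t"].to_numpy() / t_ord
        ok = np.abs(t_ord) > 0.5
        assert np.median(np.abs(ratio[ok] - 1)) < 0.1

    def test_small_group_raises(self):
        expr = np.zeros((2, 4))
        with pytest.raises(GroupTooSmallError):
            moderated_t_test(expr, np.array([0, 1, 1, 1]), 0)

    def test_type_one_error_is_nominal_under_global_null(self):
        labels = np.repeat([0, 1], 20)
        fractions = []
        runs_with_bonferroni_call = 0
        for seed in range(20):
            expr = np.random.default_rng(seed).normal(size=(1000, 40))
            res = moderated_t_test(expr, labels, 0)
            fractions.append((res.table["p_value"] < 0.05).mean())
            if res.table["is_DEG"].any():
                runs_with_bonferroni_call += 1
        assert abs(np.mean(fractions) - 0.05) <= 0.02
        assert runs_with_bonferroni_call <= 2


class TestBonferroni:
    def test_multiplies_and_caps(self):
        np.testing.assert_allclose(
            bonferroni(np.array([0.01] * 10)), np.full(10, 0.1)
        )
        assert bonferroni(np.array([0.5] * 10)).tolist() == [1.0] * 10
        assert bonferroni(np.array([0.3])).tolist() == [0.3]

    def test_rejects_invalid_pvalues(self):
        with pytest.raises(ValueError):
            bonferroni(np.array([1.5]))


class TestVariancePrior:
    def test_equal_variances_give_infinite_prior_df(self):
        d0, s0 = fit_variance_prior(np.full(100, 2.0), 10)
        assert np.isinf(d0)
        # degenerate equal variances: the estimator applies the
        # log-chi-square bias correction exp(log(d/2) - digamma(d/2))
        expected = 2.0 * np.exp(np.log(5.0) - special.digamma(5.0))
        assert s0 == pytest.approx(expected)


class TestCallMarkers:
    def test_flat_gene_is_never_a_marker(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(5.0, size=(30, 40)).astype(float)
        counts[0] = 5.0  # identical in both groups
        m = CountMatrix(counts)
        labels = np.repeat([0, 1], 20)
        _, markers = call_markers(m, labels)
        for cluster_markers in markers.values():
            assert "gene_0" not in set(cluster_markers["gene_id"])

    def test_infinite_cutoff_empties_marker_lists(self):
        m, truth = generate_counts(
            n_cells_per_cluster=(30, 30), n_genes=200,
            n_markers_per_cluster=10, seed=4,
        )
        _, markers = call_markers(depth_scale(m), truth.labels, fc_cutoff=np.inf)
        assert all(len(t) == 0 for t in markers.values())

    def test_recovers_planted_markers(self):
        m, truth = generate_counts(seed=13)
        _, markers = call_markers(depth_scale(m), truth.labels)
        sensitivities = []
        for cluster, planted in truth.marker_genes.items():
            found = set(markers[cluster]["gene_id"])
            sensitivities.append(len(found & set(planted)) / len(planted))
        assert np.mean(sensitivities) >= 0.9
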