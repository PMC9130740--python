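"""Group-level statistics against hand-computed oracles."""

import numpy as np
import pytest

from nbrlifespan.group import (
    nested_regression_f,
    one_way_anova,
    pairwise_decile_difference,
    pearson_corr,
    posthoc_ttests,
    regression_slope_ci,
    residualize_on_age,
    second_level_mean_covariate,
)


class TestSecondLevel:
    def test_identical_maps_give_zero_covariate_slope(self):
        maps = [np.full((3, 3, 2), 1.7) for _ in range(5)]
        res = second_level_mean_covariate(maps, np.array([20, 30, 40, 50, 60.0]))
        assert np.allclose(res.covariate_beta, 0.0)

    def test_toy_voxel_slope_matches_hand_ols(self):
        cov = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        vals = np.array([2.0, 2.5, 3.6, 4.1, 5.2])
        maps = [np.full((1, 1, 1), v) for v in vals]
        res = second_level_mean_covariate(maps, cov)
        c = cov - cov.mean()
        slope = (c @ vals) / (c @ c)
        assert res.covariate_beta[0, 0, 0] == pytest.approx(slope, abs=1e-12)

    def test_intercept_equals_sample_mean_map(self, rng):
        maps = [rng.normal(size=(4, 4, 2)) for _ in range(8)]
        cov = rng.normal(size=8)
        res = second_level_mean_covariate(maps, cov)
        assert np.allclose(res.mean_beta, np.mean(maps, axis=0), atol=1e-12)

    def test_constant_covariate_rejected(self):
        maps = [np.zeros((2, 2, 2)) for _ in range(4)]
        with pytest.raises(ValueError, match="constant"):
            second_level_mean_covariate(maps, np.full(4, 55.0))


class TestPairwiseDecileDifference:
    def test_identical_groups_give_zero_z(self, rng):
        maps = [rng.normal(size=(3, 3, 2)) for _ in range(4)]
        z = pairwise_decile_difference(maps, maps)
        assert np.allclose(z, 0.0)

    def test_swapping_groups_negates_z(self, rng):
        a = [rng.normal(size=(3, 3, 2)) for _ in range(4)]
        b = [rng.normal(size=(3, 3, 2)) for _ in range(5)]
        assert np.allclose(
            pairwise_decile_difference(a, b), -pairwise_decile_difference(b, a),
            atol=1e-10,
        )

    def test_toy_three_plus_three_matches_pooled_t(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        z = pairwise_decile_difference(
            [np.full((1, 1, 1), v) for v in a], [np.full((1, 1, 1), v) for v in b]
        )[0, 0, 0]
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        from scipy import stats
        expected = -stats.norm.isf(stats.t.sf(-t, 4))  # t is negative here
        assert z == pytest.approx(expected, abs=1e-10)

    def test_zero_variance_voxels_flagged(self):
        a = [np.full((1, 1, 1), 1.0) for _ in range(3)]
        b = [np.full((1, 1, 1), 2.0) for _ in range(3)]
        assert np.isnan(pairwise_decile_difference(a, b)[0, 0, 0])


class TestOneWayAnova:
    def test_equal_means_give_zero_f(self):
        f, df1, df2, p = one_way_anova(
            [np.array([1.0, 2.0, 3.0]), np.array([0.0, 2.0, 4.0])]
        )
        assert f == pytest.approx(0.0, abs=1e-12)
        assert (df1, df2) == (1, 4)

    def test_matches_sum_of_squares_oracle(self):
        groups = [
            np.array([1.0, 2.0, 3.0]),
            np.array([2.0, 3.0, 5.0]),
            np.array([6.0, 7.0, 9.0]),
        ]
        f, df1, df2, p = one_way_anova(groups)
        allv = np.concatenate(groups)
        grand = allv.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / 2) / (ss_within / 6)
        assert f == pytest.approx(f_oracle, abs=1e-10)
        assert (df1, df2) == (2, 6)

    def test_within_group_permutation_invariance(self, rng):
        groups = [rng.normal(size=6) for _ in range(3)]
        f1, *_ = one_way_anova(groups)
        f2, *_ = one_way_anova([rng.permutation(g) for g in groups])
        assert f1 == pytest.approx(f2)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            one_way_anova([np.full(3, 2.0), np.full(4, 2.0)])


class TestPosthocTtests:
    def test_identical_groups_give_zero_t(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        table = posthoc_ttests([g, g.copy()])
        assert table.loc[0, "t"] == pytest.approx(0.0)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=8)
        t_ab = posthoc_ttests([a, b]).loc[0, "t"]
        t_ba = posthoc_ttests([b, a]).loc[0, "t"]
        assert t_ab == pytest.approx(-t_ba)

    def test_matches_welch_formula_by_hand(self):
        a = np.array([1.0, 2.0, 4.0])
        b = np.array([2.0, 6.0, 7.0, 9.0])
        t = posthoc_ttests([a, b]).loc[0, "t"]
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 4
        t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
        assert t == pytest.approx(t_oracle, abs=1e-10)

    def test_bonferroni_column_present_not_applied(self, rng):
        groups = [rng.normal(size=5) for _ in range(3)]
        table = posthoc_ttests(groups)
        assert len(table) == 3
        assert np.all(table["p_bonferroni"] >= table["p"] - 1e-15)


class TestPearsonAndResidualize:
    def test_perfect_linearity(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_five_point_toy_matches_formula(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0])
        r, _ = pearson_corr(x, y)
        cx, cy = x - x.mean(), y - y.mean()
        r_oracle = (cx @ cy) / np.sqrt((cx @ cx) * (cy @ cy))
        assert r == pytest.approx(r_oracle, abs=1e-12)

    def test_symmetry_and_zero_variance_error(self, rng):
        x, y = rng.normal(size=10), rng.normal(size=10)
        assert pearson_corr(x, y)[0] == pytest.approx(pearson_corr(y, x)[0])
        with pytest.raises(ValueError, match="variance"):
            pearson_corr(np.full(5, 1.0), y[:5])

    def test_residuals_orthogonal_to_age(self, rng):
        ages = rng.uniform(20, 88, 30)
        values = 0.01 * ages + rng.normal(size=30)
        resid = residualize_on_age(values, ages)
        assert abs(np.corrcoef(resid, ages)[0, 1]) < 1e-10

    def test_residuals_match_hand_ols(self):
        ages = np.array([20.0, 40.0, 60.0, 80.0])
        values = np.array([1.0, 0.8, 0.9, 0.4])
        X = np.column_stack([np.ones(4), ages])
        beta = np.linalg.solve(X.T @ X, X.T @ values)
        assert np.allclose(residualize_on_age(values, ages), values - X @ beta)

    def test_residualized_correlation_equals_partial_correlation(self, rng):
        n = 60
        age = rng.uniform(20, 88, n)
        x = 0.02 * age + rng.normal(size=n)
        y = -0.01 * age + 0.5 * rng.normal(size=n)
        rx = residualize_on_age(x, age)
        ry = residualize_on_age(y, age)
        r_resid, _ = pearson_corr(rx, ry)
        # partial correlation formula
        rxy, _ = pearson_corr(x, y)
        rxa, _ = pearson_corr(x, age)
        rya, _ = pearson_corr(y, age)
        partial = (rxy - rxa * rya) / np.sqrt((1 - rxa**2) * (1 - rya**2))
        assert r_resid == pytest.approx(partial, abs=1e-10)


class TestNestedRegressionF:
    def test_perfect_completion_reaches_r2_of_one(self, rng):
        n = 30
        base = rng.normal(size=(n, 2))
        y = base @ np.array([1.0, -0.5]) + rng.normal(size=n)
        X0 = np.column_stack([np.ones(n), base])
        resid = y - X0 @ np.linalg.lstsq(X0, y, rcond=None)[0]
        delta_r2, f, p = nested_regression_f(y, base, resid)
        tss = np.sum((y - y.mean()) ** 2)
        r2_base = 1 - resid @ resid / tss
        assert delta_r2 == pytest.approx(1 - r2_base, abs=1e-8)

    def test_orthogonal_predictor_adds_nothing(self, rng):
        n = 40
        base = rng.normal(size=n)
        y = 2 * base + rng.normal(size=n)
        X0 = np.column_stack([np.ones(n), base, y])
        added = rng.normal(size=n)
        # orthogonalize against intercept, base and y
        added -= X0 @ np.linalg.lstsq(X0, added, rcond=None)[0]
        delta_r2, f, p = nested_regression_f(y, base, added)
        assert delta_r2 == pytest.approx(0.0, abs=1e-12)
        assert p > 0.999

    def test_matches_rss_oracle(self, rng):
        n = 25
        base = rng.normal(size=(n, 2))
        added = rng.normal(size=n)
        y = base @ np.array([0.5, 1.0]) + 0.3 * added + rng.normal(size=n)
        delta_r2, f, p = nested_regression_f(y, base, added)
        X0 = np.column_stack([np.ones(n), base])
        X1 = np.column_stack([X0, added])
        rss = lambda X: float(
            np.sum((y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2)
        )
        f_oracle = (rss(X0) - rss(X1)) / (rss(X1) / (n - X1.shape[1]))
        assert f == pytest.approx(f_oracle, abs=1e-8)

    def test_collinear_added_predictor_rejected(self, rng):
        n = 20
        base = rng.normal(size=n)
        y = rng.normal(size=n)
        with pytest.raises(ValueError, match="collinear"):
            nested_regression_f(y, base, 2 * base)


class TestRegressionSlopeCi:
    def test_ci_contains_true_slope_for_clean_data(self):
        x = np.arange(10, dtype=float)
        y = 3.0 * x + 1.0
        slope, lo, hi = regression_slope_ci(x, y + np.sin(x) * 0.01)
        assert lo <= 3.0 <= hi
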