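"""Covariate battery: robust fits, Bayes factors, corrections, power."""

import numpy as np
import pytest

from gastricnet import (
    adjust_pvalues,
    bic_bf,
    jzs_bf_two_sample,
    power_sample_size,
    robust_regression,
    roi_covariate_scan,
    two_sample_t,
    voxelwise_glm,
)


class TestRobustRegression:
    def test_exact_line(self):
        x = np.linspace(0, 10, 20)
        res = robust_regression(2 * x + 1, x)
        assert res.estimate == pytest.approx(2.0, abs=1e-8)
        assert res.df == 18

    def test_matches_ols_on_clean_gaussian(self, rng):
        x = rng.standard_normal(200)
        y = 1.5 * x + rng.standard_normal(200)
        res = robust_regression(y, x)
        ols_slope = np.polyfit(x, y, 1)[0]
        assert res.estimate == pytest.approx(ols_slope, rel=0.01)

    def test_resists_gross_outlier(self, rng):
        x = np.linspace(0, 10, 30)
        y = 2 * x + 0.2 * rng.standard_normal(30)
        y_dirty = y.copy()
        y_dirty[-1] += 200.0
        robust_slope = robust_regression(y_dirty, x).estimate
        ols_clean = np.polyfit(x, y, 1)[0]
        ols_dirty = np.polyfit(x, y_dirty, 1)[0]
        assert abs(robust_slope - ols_clean) < abs(ols_dirty - ols_clean)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            robust_regression(np.arange(10.0), np.ones(10))


class TestTwoSampleT:
    def test_identical_groups(self):
        a = np.array([1.0, 2.0, 3.0])
        res = two_sample_t(a, a.copy())
        assert res.t_value == pytest.approx(0.0)
        assert res.p_uncorrected == pytest.approx(1.0)

    def test_zero_pooled_variance_error(self):
        with pytest.raises(ValueError, match="variance"):
            two_sample_t(np.array([0.0, 0.0]), np.array([1.0, 1.0]))

    def test_matches_formula_oracle(self, rng):
        a = rng.normal(1.0, 2.0, 14)
        b = rng.normal(0.0, 2.0, 19)
        res = two_sample_t(a, b)
        sp2 = ((13) * a.var(ddof=1) + (18) * b.var(ddof=1)) / 31
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 14 + 1 / 19))
        assert res.t_value == pytest.approx(t, abs=1e-12)
        assert res.df == 31


class TestJzsBayesFactor:
    def test_null_favored_at_t_zero(self):
        for n in (2, 5, 30):
            assert jzs_bf_two_sample(0.0, n, n) < 1.0

    def test_monotone_in_abs_t(self):
        bfs = [jzs_bf_two_sample(t, 20, 22) for t in (0.0, 0.5, 1.0, 2.0, 4.0, 8.0)]
        assert np.all(np.diff(bfs) > 0)
        assert bfs[-1] > 1e3

    def test_matches_fine_grid_quadrature(self):
        """Independent oracle: dense quadrature after mapping g to (0, 1).

        The substitution g = u/(1-u) folds the infinite tail into a finite
        grid, avoiding truncation bias.
        """
        for t, n1, n2 in [(0.48, 32, 31), (1.41, 29, 34), (2.5, 12, 15)]:
            r2 = 0.5
            N, v = n1 * n2 / (n1 + n2), n1 + n2 - 2
            u = np.linspace(1e-9, 1 - 1e-9, 2_000_001)
            g = u / (1 - u)
            jac = 1.0 / (1 - u) ** 2
            a = 1 + N * g * r2
            with np.errstate(over="ignore"):
                integ = (
                    a**-0.5
                    * (1 + t * t / (a * v)) ** (-(v + 1) / 2)
                    * (2 * np.pi) ** -0.5
                    * g**-1.5
                    * np.exp(-1 / (2 * g))
                    * jac
                )
            integ[~np.isfinite(integ)] = 0.0
            oracle = np.trapezoid(integ, u) / (1 + t * t / v) ** (-(v + 1) / 2)
            got = jzs_bf_two_sample(t, n1, n2)
            assert got == pytest.approx(oracle, rel=1e-3)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            jzs_bf_two_sample(1.0, 1, 10)


class TestBicBayesFactor:
    def test_null_slope_penalized(self, rng):
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        assert bic_bf(y, x) < 1.0

    def test_perfect_relation_overwhelming(self):
        x = np.linspace(0, 1, 50)
        y = 3 * x + 1e-6 * np.sin(50 * x)
        assert bic_bf(y, x) > 1e6

    def test_matches_direct_bic_formula(self, rng):
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        n = 40
        X = np.column_stack([np.ones(n), x])
        b = np.linalg.lstsq(X, y, rcond=None)[0]
        rss1 = np.sum((y - X @ b) ** 2)
        rss0 = np.sum((y - y.mean()) ** 2)
        bic1 = n * np.log(rss1 / n) + 2 * np.log(n)
        bic0 = n * np.log(rss0 / n) + 1 * np.log(n)
        assert bic_bf(y, x) == pytest.approx(np.exp((bic0 - bic1) / 2), rel=1e-9)


class TestPvalueAdjustment:
    def test_bonferroni_twelve_tests(self):
        p = np.full(12, 0.5)
        p[0] = 0.0004
        adj = adjust_pvalues(p, "bonferroni")
        assert adj[0] == pytest.approx(0.0048)

    def test_single_test_identity(self):
        for method in ("bonferroni", "benjamini_hochberg"):
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_bh_matches_brute_force_step_up(self):
        p = np.array([0.001, 0.02, 0.03, 0.04])
        adj = adjust_pvalues(p, "benjamini_hochberg")
        assert np.allclose(adj, [0.004, 0.04, 0.04, 0.04])

    def test_bh_brute_force_oracle_random(self, rng):
        p = rng.uniform(0.001, 1.0, 25)
        adj = adjust_pvalues(p, "benjamini_hochberg")
        # brute-force step-up definition
        m = p.size
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, m + 1)
        stepup = np.minimum.accumulate(ranked[::-1])[::-1]
        want = np.empty(m)
        want[order] = np.minimum(stepup, 1.0)
        assert np.allclose(adj, want)

    def test_outputs_bounded_and_not_smaller(self, rng):
        p = rng.uniform(0.001, 1.0, 30)
        for method in ("bonferroni", "benjamini_hochberg"):
            adj = adjust_pvalues(p, method)
            assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.0, 0.5], "bonferroni")


class TestPowerSampleSize:
    def test_monotonicity(self):
        n_base = power_sample_size(0.4, 0.005, 0.8)
        assert power_sample_size(0.5, 0.005, 0.8) < n_base
        assert power_sample_size(0.4, 0.05, 0.8) < n_base
        assert power_sample_size(0.4, 0.005, 0.9) > n_base

    def test_achieved_power_verified_by_simulation(self, rng):
        """Monte-Carlo one-sample t tests reproduce the noncentral-t power."""
        from scipy import stats

        d, alpha, n = 0.5, 0.05, 30
        reps = 20000
        x = rng.standard_normal((reps, n)) + d
        t = x.mean(axis=1) / (x.std(axis=1, ddof=1) / np.sqrt(n))
        tcrit = stats.t.ppf(1 - alpha, n - 1)
        emp = np.mean(t > tcrit)
        theo = stats.nct.sf(tcrit, n - 1, d * np.sqrt(n))
        se = np.sqrt(emp * (1 - emp) / reps)
        assert abs(emp - theo) < 3 * se

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            power_sample_size(-0.1, 0.05, 0.8)
        with pytest.raises(ValueError):
            power_sample_size(0.4, 0.7, 0.8)


class TestScans:
    def test_planted_roi_effect_survives_fdr(self, rng):
        import pandas as pd

        n, n_roi = 40, 15
        cov = pd.DataFrame({"bmi": rng.normal(21, 2, n)})
        coupling = pd.DataFrame(rng.normal(0.04, 0.01, (n, n_roi)), columns=[f"roi{i}" for i in range(n_roi)])
        coupling["roi3"] += 0.02 * (cov["bmi"] - 21)
        tab = roi_covariate_scan(coupling, cov)
        assert len(tab) == n_roi
        hit = tab[(tab.roi == "roi3")].iloc[0]
        assert hit.p_fdr < 0.05
        assert (tab.p_fdr < 0.05).sum() <= 3

    def test_glm_intercept_only_equals_one_sample_t(self, rng):
        from scipy import stats

        n = 15
        maps = rng.standard_normal((n, 10)) + 0.4
        t_maps, _ = voxelwise_glm(maps, np.zeros((n, 0)), n_perm=10, seed=0)
        t_direct = maps.mean(axis=0) / (maps.std(axis=0, ddof=1) / np.sqrt(n))
        assert np.allclose(t_maps[0], t_direct, rtol=1e-10)

    def test_glm_detects_planted_voxel_association(self, rng):
        n, v = 30, 40
        x = rng.standard_normal(n)
        maps = rng.standard_normal((n, v))
        maps[:, 7] += 1.5 * x
        t_maps, p_fwe = voxelwise_glm(maps, x, n_perm=300, seed=2)
        assert p_fwe[1, 7] < 0.05
        assert np.argmax(np.abs(t_maps[1])) == 7

    def test_glm_rank_deficiency_rejected(self, rng):
        x = rng.standard_normal(10)
        with pytest.raises(ValueError, match="rank"):
            voxelwise_glm(rng.standard_normal((10, 5)), np.column_stack([x, x]), n_perm=10)
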