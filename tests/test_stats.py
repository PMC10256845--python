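"""Behavioural statistics layer: tests against closed forms and oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_hyp

from hexlearn import stats as st
from hexlearn.errors import ConfigurationError, DegenerateDataError


class TestPairedT:
    def test_identical_samples(self):
        x = np.arange(10.0)
        res = st.paired_t(x, x)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_constant_shift_zero_noise_guard(self):
        x = np.arange(10.0)
        with pytest.raises(DegenerateDataError):
            st.paired_t(x + 1.0, x)

    def test_null_calibration(self):
        rng = np.random.default_rng(0)
        n_sims, n = 4000, 20
        rejections = 0
        for _ in range(n_sims):
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            rejections += st.paired_t(x, y, bayes=False).p_value < 0.05
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / n_sims)

    def test_independent_t_effect_size(self):
        rng = np.random.default_rng(1)
        x = rng.normal(1.0, 1.0, 200)
        y = rng.normal(0.0, 1.0, 200)
        res = st.independent_t(x, y)
        assert res.effect_size == pytest.approx(1.0, abs=0.3)
        assert res.p_value < 1e-10


class TestRmAnova2x2:
    def test_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(2)
        cells = rng.normal(size=(25, 4)) + np.array([0.5, 0.0, 0.2, 0.0])
        res = st.rm_anova_2x2(cells, bayes=False)
        a1b1, a1b2, a2b1, a2b2 = cells.T
        for eff, contrast in (("A", (a1b1 + a1b2 - a2b1 - a2b2) / 2),
                              ("B", (a1b1 - a1b2 + a2b1 - a2b2) / 2),
                              ("AxB", (a1b1 - a1b2 - a2b1 + a2b2) / 2)):
            t = st.paired_t(contrast, np.zeros_like(contrast), bayes=False)
            assert res[eff].statistic == pytest.approx(t.statistic ** 2, abs=1e-8)

    def test_flat_cells_give_zero_f(self):
        cells = np.tile(np.random.default_rng(3).normal(size=(10, 1)), (1, 4))
        res = st.rm_anova_2x2(cells, bayes=False)
        assert all(r.statistic == 0.0 and r.p_value == 1.0 for r in res.values())

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        cells = rng.normal(size=(12, 4)) + np.array([1.0, 0.3, 0.1, 0.0])
        res = st.rm_anova_2x2(cells, bayes=False)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "a": np.tile(["a1", "a1", "a2", "a2"], 12),
            "b": np.tile(["b1", "b2", "b1", "b2"], 12),
            "y": cells.ravel(),
        })
        oracle = pg.rm_anova(data=long, dv="y", within=["a", "b"],
                             subject="subject", detailed=True)
        for eff, label in (("A", "a"), ("B", "b"), ("AxB", "a * b")):
            f_oracle = float(oracle.loc[oracle["Source"] == label, "F"].iloc[0])
            assert res[eff].statistic == pytest.approx(f_oracle, rel=1e-6)

    def test_missing_cells_rejected(self):
        cells = np.random.default_rng(5).normal(size=(8, 4))
        cells[2, 1] = np.nan
        with pytest.raises(ConfigurationError):
            st.rm_anova_2x2(cells)


class TestJzsBayesFactor:
    @staticmethod
    def _oracle(t, n, n2=None, scale=math.sqrt(2) / 2):
        """Independent fixed-grid quadrature after u = g/(1+g) substitution."""
        if n2 is None:
            nu, big_n = n - 1.0, float(n)
        else:
            nu, big_n = n + n2 - 2.0, n * n2 / float(n + n2)
        r2 = scale ** 2
        us = np.linspace(1e-9, 1 - 1e-9, 400_001)
        g = us / (1 - us)
        integrand = ((1 + big_n * g) ** -0.5
                     * (1 + t * t / ((1 + big_n * g) * nu)) ** (-(nu + 1) / 2)
                     * (r2 / 2) ** 0.5 / math.gamma(0.5)
                     * g ** -1.5 * np.exp(-r2 / (2 * g))
                     / (1 - us) ** 2)
        num = np.trapezoid(integrand, us)
        return num / (1 + t * t / nu) ** (-(nu + 1) / 2)

    @pytest.mark.parametrize("t,n,n2", [(0.0, 50, None), (2.0, 30, None),
                                        (3.5, 100, None), (-1.2, 20, None),
                                        (2.5, 24, 30)])
    def test_matches_quadrature_oracle(self, t, n, n2):
        assert st.jzs_bf_ttest(t, n, n2) == pytest.approx(
            self._oracle(t, n, n2), rel=1e-4)

    def test_null_t_supports_null(self):
        assert st.jzs_bf_ttest(0.0, 50) < 1.0

    def test_monotone_in_t(self):
        bfs = [st.jzs_bf_ttest(t, 40) for t in np.linspace(0, 6, 25)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))
        assert bfs[-1] > 1e3  # large t -> overwhelming evidence

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        for t, n in ((1.5, 30), (2.5, 60)):
            expect = float(pg.bayesfactor_ttest(t, n))
            assert st.jzs_bf_ttest(t, n) == pytest.approx(expect, rel=1e-3)


class TestCorrelation:
    def test_perfect_correlation(self):
        x = np.arange(20.0)
        res = st.pearson_cor_test(x, x)
        assert res.extra["r"] == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        r1 = st.pearson_cor_test(x, y).extra["r"]
        r2 = st.pearson_cor_test(y, x).extra["r"]
        r3 = st.pearson_cor_test(3.0 * x + 7.0, 0.1 * y - 2.0).extra["r"]
        assert r1 == pytest.approx(r2) == pytest.approx(r3)

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(7)
        ps = [st.pearson_cor_test(rng.standard_normal(30),
                                  rng.standard_normal(30), bayes=False).p_value
              for _ in range(2000)]
        from scipy import stats as sps
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_input_rejected(self):
        with pytest.raises(DegenerateDataError):
            st.pearson_cor_test(np.ones(10), np.arange(10.0))

    def test_bf_direction(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(150)
        y = 0.5 * x + 0.8 * rng.standard_normal(150)
        assert st.pearson_cor_test(x, y).bf10 > 3
        assert st.pearson_cor_test(x, rng.standard_normal(150)).bf10 < 1


class TestFdrBh:
    def test_hand_computed_examples(self):
        assert st.fdr_bh([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert st.fdr_bh([0.005, 0.5]) == pytest.approx([0.01, 0.5])
        assert st.fdr_bh([0.2]) == pytest.approx([0.2])

    @staticmethod
    def _brute_force_rejections(p, alpha):
        """Direct step-up rule: largest k with p_(k) <= k/m * alpha."""
        p = np.asarray(p)
        order = np.argsort(p)
        m = len(p)
        k_star = 0
        for k in range(1, m + 1):
            if p[order[k - 1]] <= k / m * alpha:
                k_star = k
        rejected = np.zeros(m, dtype=bool)
        rejected[order[:k_star]] = True
        return rejected

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_step_up_rule(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(40) ** 2
        q = st.fdr_bh(p)
        assert np.array_equal(q <= 0.05, self._brute_force_rejections(p, 0.05))

    @given(st_hyp.lists(st_hyp.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=50)
    def test_q_monotone_in_sorted_p(self, p):
        q = st.fdr_bh(p)
        order = np.argsort(p)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()
        assert ((q >= np.asarray(p) - 1e-12) & (q <= 1 + 1e-12)).all()


class TestPower:
    def test_reported_sample_size_calculations(self):
        # n = 188 affords 78 % power at r = 0.2 and 98 % at r = 0.3
        # (printed values truncate the Fisher-z results 78.7 % and 98.8 %)
        assert st.correlation_power(188, 0.2, 0.05) == pytest.approx(0.787, abs=0.005)
        assert st.correlation_power(188, 0.3, 0.05) == pytest.approx(0.988, abs=0.005)

    def test_null_effect_gives_alpha(self):
        for alpha in (0.01, 0.05):
            assert st.correlation_power(100, 0.0, alpha) == pytest.approx(alpha, abs=1e-9)

    def test_monotone_in_n_and_rho(self):
        p_n = [st.correlation_power(n, 0.2) for n in (20, 50, 100, 400)]
        p_r = [st.correlation_power(100, r) for r in (0.05, 0.1, 0.3, 0.6)]
        assert p_n == sorted(p_n) and p_r == sorted(p_r)


class TestReliability:
    def test_alpha_closed_form_exchangeable_items(self):
        rng = np.random.default_rng(9)
        n, k, r = 10_000, 4, 0.5
        f = rng.standard_normal(n)
        items = np.column_stack([math.sqrt(r) * f
                                 + math.sqrt(1 - r) * rng.standard_normal(n)
                                 for _ in range(k)])
        population = k * r / (1 + (k - 1) * r)  # = 0.8
        assert st.cronbach_alpha(items) == pytest.approx(population, abs=0.02)

    def test_duplicated_items_push_alpha_to_one(self):
        x = np.random.default_rng(10).standard_normal(200)
        items = np.column_stack([x, x, x, x])
        assert st.cronbach_alpha(items) == pytest.approx(1.0, abs=1e-12)

    def test_independent_items_give_near_zero_alpha(self):
        items = np.random.default_rng(11).standard_normal((5000, 5))
        assert abs(st.cronbach_alpha(items)) < 0.1

    def test_omega_equals_alpha_under_tau_equivalence(self):
        rng = np.random.default_rng(12)
        n = 10_000
        f = rng.standard_normal(n)
        items = np.column_stack([0.7 * f + 0.6 * rng.standard_normal(n)
                                 for _ in range(4)])
        assert st.mcdonald_omega(items) == pytest.approx(
            st.cronbach_alpha(items), abs=1e-3)

    def test_omega_penalizes_zero_loading_item(self):
        rng = np.random.default_rng(13)
        n = 4000
        f = rng.standard_normal(n)
        good = [0.8 * f + 0.6 * rng.standard_normal(n) for _ in range(3)]
        noise = rng.standard_normal(n)
        w3 = st.mcdonald_omega(np.column_stack(good))
        w4 = st.mcdonald_omega(np.column_stack(good + [noise]))
        assert w4 < w3

    def test_omega_near_zero_without_common_factor(self):
        items = np.random.default_rng(14).standard_normal((4000, 4))
        assert st.mcdonald_omega(items) < 0.1


class TestPca:
    def test_identity_structure(self):
        x = np.random.default_rng(15).standard_normal((3000, 5))
        res = st.pca_scores(pd.DataFrame(x))
        assert np.allclose(res.eigenvalues, 1.0, atol=0.15)
        assert res.eigenvalues.sum() == pytest.approx(5.0, abs=1e-8)

    def test_two_block_structure_retains_two_components(self):
        rng = np.random.default_rng(16)
        n = 2000
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        cols = {}
        for i in range(4):
            cols[f"a{i}"] = math.sqrt(0.6) * f1 + math.sqrt(0.4) * rng.standard_normal(n)
            cols[f"b{i}"] = math.sqrt(0.6) * f2 + math.sqrt(0.4) * rng.standard_normal(n)
        res = st.pca_scores(pd.DataFrame(cols))
        assert res.n_retained == 2

    def test_listwise_deletion_logged(self):
        x = pd.DataFrame(np.random.default_rng(17).standard_normal((100, 3)))
        x.iloc[0, 0] = np.nan
        res = st.pca_scores(x)
        assert res.n_dropped_rows == 1
        assert len(res.scores) == 99

    def test_constant_column_named_in_error(self):
        x = pd.DataFrame({"ok": np.random.default_rng(18).standard_normal(50),
                          "flat": np.ones(50)})
        with pytest.raises(DegenerateDataError, match="flat"):
            st.pca_scores(x)


class TestDecisionRule:
    def test_dual_criterion(self):
        assert st.significant_by_both(0.01, 5.0)
        assert not st.significant_by_both(0.01, 2.0)
        assert not st.significant_by_both(0.2, 10.0)
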