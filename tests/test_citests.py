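"""Tests of the G², trend and regression backends against independent
oracles: scipy's log-likelihood-ratio contingency test, a frozen R
prop.trend.test value, and d-separation properties of simulated chains."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import chi2_contingency

from mbfish import GenotypeDataset, armitage_trend_test
from mbfish.citests import (
    DegenerateTableError,
    TableTooLargeError,
    conditional_g2,
    g2_from_table,
    marginal_screen,
    regression_ci_test,
    stratified_cell_count,
    trend_test_all,
)
from tests.conftest import make_chain_dataset


class TestG2FromTable:
    def test_independence_identity_gives_zero(self):
        # outer product of margins: O == E exactly
        t = np.outer([30, 70], [40, 60]) / 100.0 * 100
        stat, df = g2_from_table(t)
        assert stat == pytest.approx(0.0, abs=1e-10)
        assert df == 1

    def test_known_2x2_value(self):
        stat, df = g2_from_table([[10, 20], [30, 40]])
        assert stat == pytest.approx(0.8043486, abs=1e-6)
        assert df == 1

    def test_zero_cell_convention(self):
        stat, df = g2_from_table([[5, 0], [0, 5]])
        assert stat == pytest.approx(20 * np.log(2), abs=1e-9)  # 13.8629
        assert df == 1

    def test_zero_margin_row_dropped_and_df_reduced(self):
        stat3, df3 = g2_from_table([[10, 20], [0, 0], [30, 40]])
        stat2, df2 = g2_from_table([[10, 20], [30, 40]])
        assert stat3 == pytest.approx(stat2)
        assert df3 == df2 == 1

    def test_all_zero_table_is_a_distinct_no_test_signal(self):
        with pytest.raises(DegenerateTableError):
            g2_from_table([[0, 0], [0, 0]])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.lists(st.integers(min_value=1, max_value=200), min_size=3, max_size=3),
            min_size=2,
            max_size=4,
        )
    )
    def test_matches_scipy_log_likelihood_ratio(self, rows):
        table = np.array(rows)
        stat, df = g2_from_table(table)
        ref = chi2_contingency(table, correction=False, lambda_="log-likelihood")
        assert stat == pytest.approx(ref.statistic, rel=1e-9)
        assert df == ref.dof

    def test_g2_close_to_pearson_on_large_margin_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            table = rng.integers(200, 1000, size=(2, 3))
            stat, _ = g2_from_table(table)
            pearson = chi2_contingency(table, correction=False).statistic
            if pearson > 1:
                assert abs(stat - pearson) / pearson < 0.05


class TestConditionalG2:
    def test_empty_conditioning_reduces_to_marginal_table(self):
        rng = np.random.default_rng(2)
        g = rng.binomial(2, 0.3, size=(500, 2)).astype(np.int8)
        y = rng.integers(0, 2, 500).astype(np.int8)
        data = GenotypeDataset(g, y)
        res = conditional_g2(data, 0)
        table = np.array(
            [[(g[y == yy, 0] == gg).sum() for gg in (0, 1, 2)] for yy in (0, 1)]
        )
        stat, df = g2_from_table(table)
        assert res.statistic == pytest.approx(stat)
        assert res.df == df

    def test_df_product_rule_when_no_stratum_dropped(self):
        rng = np.random.default_rng(3)
        g = rng.binomial(2, 0.4, size=(20_000, 3)).astype(np.int8)
        y = rng.integers(0, 2, 20_000).astype(np.int8)
        data = GenotypeDataset(g, y)
        res = conditional_g2(data, 0, (1, 2))
        # (Cat(Y)-1)(Cat(V)-1)*Cat(C1)*Cat(C2) = 1*2*3*3
        assert res.df == 18

    def test_pathological_cell_count_formula(self):
        # binary phenotype, ternary SNP, 9 ternary conditioners
        assert stratified_cell_count(2, 3, [3] * 9) == 118_098

    def test_cell_cap_refusal(self):
        rng = np.random.default_rng(4)
        g = rng.binomial(2, 0.4, size=(200, 12)).astype(np.int8)
        y = rng.integers(0, 2, 200).astype(np.int8)
        data = GenotypeDataset(g, y)
        with pytest.raises(TableTooLargeError):
            conditional_g2(data, 0, tuple(range(1, 11)), max_cells=100_000)

    def test_conditioning_on_target_rejected(self):
        data = GenotypeDataset(
            np.zeros((10, 2), dtype=np.int8), np.zeros(10, dtype=np.int8)
        )
        with pytest.raises(ValueError):
            conditional_g2(data, 0, (0,))

    def test_sparse_stratification_flagged_unreliable(self):
        rng = np.random.default_rng(5)
        g = rng.binomial(2, 0.3, size=(60, 6)).astype(np.int8)
        y = rng.integers(0, 2, 60).astype(np.int8)
        data = GenotypeDataset(g, y)
        res = conditional_g2(data, 0, (1, 2, 3, 4))  # 486 cells, 60 samples
        assert not res.reliable

    def test_d_separation_chain_is_conditionally_independent(self):
        hits = 0
        for seed in range(30):
            data = make_chain_dataset(n=20_000, seed=seed)
            res = conditional_g2(data, 0, (1,))  # V given C
            hits += res.p_value >= 0.05
        assert hits >= 27  # >= 90% non-significant

    def test_chain_direct_member_is_dependent(self):
        data = make_chain_dataset(n=20_000, seed=99)
        res = conditional_g2(data, 1, (0,))  # C given V: still dependent
        assert res.p_value < 0.01

    def test_pvalues_uniform_under_permuted_phenotype(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.3, size=(500, 1)).astype(np.int8)
        y0 = rng.integers(0, 2, 500).astype(np.int8)
        ps = []
        for _ in range(2000):
            y = rng.permutation(y0)
            ps.append(conditional_g2(GenotypeDataset(g, y), 0).p_value)
        d = stats.kstest(ps, "uniform").statistic
        assert d < 0.06  # discrete statistic: near-uniform


class TestRegressionCITest:
    @staticmethod
    def _correlated_pair(n, rho, rng):
        x2 = rng.normal(size=n)
        x3 = rho * x2 + np.sqrt(1 - rho**2) * rng.normal(size=n)
        return x2, x3

    def test_conditional_independence_oracle_logistic(self):
        from scipy.special import expit

        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x2, x3 = self._correlated_pair(20_000, 0.5, rng)
            y = (rng.random(20_000) < expit(0.8 * x2)).astype(np.int8)
            data = GenotypeDataset(np.column_stack([x2, x3]), y)
            res = regression_ci_test(data, 1, (0,), "logistic")
            hits += res.p_value >= 0.05
        assert hits >= 18

    def test_true_direct_effect_detected(self):
        from scipy.special import expit

        rng = np.random.default_rng(21)
        x2, x3 = self._correlated_pair(20_000, 0.5, rng)
        y = (rng.random(20_000) < expit(0.8 * x2)).astype(np.int8)
        data = GenotypeDataset(np.column_stack([x2, x3]), y)
        res = regression_ci_test(data, 0, (1,), "logistic")
        assert res.p_value < 1e-6

    def test_empty_conditioning_equals_single_covariate_fit(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(22)
        x = rng.normal(size=2000)
        y = 0.3 * x + rng.normal(size=2000)
        data = GenotypeDataset(x[:, None], y)
        res = regression_ci_test(data, 0, (), "linear")
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert res.statistic == pytest.approx(fit.tvalues[1] ** 2, rel=1e-8)

    def test_collinear_conditioner_gives_no_test_signal(self):
        rng = np.random.default_rng(23)
        x = rng.normal(size=500)
        y = (x > 0).astype(float)
        data = GenotypeDataset(np.column_stack([x, x]), y)
        res = regression_ci_test(data, 0, (1,), "linear")
        assert not res.reliable


class TestArmitageTrend:
    def test_identical_distributions_give_zero(self):
        res = armitage_trend_test([10, 20, 30], [10, 20, 30])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_frozen_oracle_value(self):
        # prop.trend.test(c(10,20,30), c(40,40,40), score=0:2) -> X^2 = 20
        res = armitage_trend_test([10, 20, 30], [30, 20, 10])
        assert res.statistic == pytest.approx(20.0, abs=1e-9)
        assert res.df == 1

    def test_case_control_label_symmetry(self):
        a = armitage_trend_test([12, 25, 9], [30, 18, 6])
        b = armitage_trend_test([30, 18, 6], [12, 25, 9])
        assert a.statistic == pytest.approx(b.statistic, rel=1e-12)

    def test_zero_total_raises(self):
        with pytest.raises(DegenerateTableError):
            armitage_trend_test([0, 0, 0], [0, 0, 0])

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(30)
        g = rng.binomial(2, 0.3, size=(400, 10)).astype(np.int8)
        y = rng.integers(0, 2, 400).astype(np.int8)
        p_vec = trend_test_all(g, y)
        for j in range(10):
            cases = [(g[y == 1, j] == k).sum() for k in (0, 1, 2)]
            ctrls = [(g[y == 0, j] == k).sum() for k in (0, 1, 2)]
            assert p_vec[j] == pytest.approx(
                armitage_trend_test(cases, ctrls).p_value, rel=1e-10
            )


class TestMarginalScreen:
    def test_null_pool_size_near_alpha_fraction(self, small_null_dataset):
        pools = []
        rng = np.random.default_rng(40)
        for _ in range(30):
            y = rng.permutation(small_null_dataset.phenotype)
            d = GenotypeDataset(small_null_dataset.genotypes, y)
            pools.append(len(marginal_screen(d, 0.05)))
        assert abs(np.mean(pools) - 0.05 * 60) < 2.0

    def test_stricter_alpha_gives_nested_pool(self, small_null_dataset):
        loose = set(marginal_screen(small_null_dataset, 0.05).indices)
        tight = set(marginal_screen(small_null_dataset, 0.01).indices)
        assert tight <= loose

    def test_constant_marker_skipped(self):
        rng = np.random.default_rng(41)
        g = rng.binomial(2, 0.3, size=(200, 3)).astype(np.int8)
        g[:, 1] = 1
        d = GenotypeDataset(g, rng.integers(0, 2, 200).astype(np.int8))
        res = marginal_screen(d, 0.5)
        assert 1 in res.skipped and 1 not in res.indices

    def test_pool_ordered_by_ascending_p(self, chain_data):
        res = marginal_screen(chain_data, 0.5)
        assert np.all(np.diff(res.p_values) >= 0)

    def test_invalid_alpha(self, chain_data):
        with pytest.raises(ValueError):
            marginal_screen(chain_data, 1.5)
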