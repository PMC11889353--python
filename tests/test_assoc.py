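"""Summary-statistic checks against closed forms and an independent solver."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from phosmr.assoc import (
    SummaryStats,
    adjusted_regression,
    batch_summary,
    marginal_regression,
    pearson_test,
    spearman_test,
)


def ols_oracle(y, X):
    """Independent QR-based least squares with classical SEs."""
    fit = sm.OLS(y, X).fit()
    return fit.params, fit.bse, fit.pvalues


class TestMarginalRegression:
    def test_hand_worked_three_points(self):
        # g=[0,1,2], y=[0,1,1]: beta=1/2, se=sqrt(1/12), t=sqrt(3), p=1/3 on t(1)
        res = marginal_regression([0, 1, 2], [0, 1, 1])
        assert res.beta == pytest.approx(0.5, abs=1e-12)
        assert res.se == pytest.approx(np.sqrt(1 / 12), abs=1e-12)
        assert res.pvalue == pytest.approx(1 / 3, abs=1e-12)
        assert res.n_used == 3 and not res.degenerate

    def test_constant_response_flagged(self):
        res = marginal_regression([0, 1, 2, 0, 1, 2], [5, 5, 5, 5, 5, 5])
        assert res.beta == 0.0 and res.pvalue == 1.0 and res.degenerate

    def test_constant_genotype_flagged(self):
        res = marginal_regression([1, 1, 1, 1], [0.1, 2.0, -1.0, 0.5])
        assert np.isnan(res.beta) and res.pvalue == 1.0 and res.degenerate

    def test_too_few_complete_cases_raises(self):
        with pytest.raises(ValueError):
            marginal_regression([0, 1, np.nan], [1.0, 2.0, 3.0])

    def test_matches_oracle_on_random_data(self, rng):
        for _ in range(50):
            n = rng.integers(5, 40)
            g = rng.integers(0, 3, n).astype(float)
            if np.ptp(g) == 0:
                continue
            y = rng.normal(size=n)
            res = marginal_regression(g, y)
            coef, bse, pv = ols_oracle(y, sm.add_constant(g))
            assert res.beta == pytest.approx(coef[1], abs=1e-10)
            assert res.se == pytest.approx(bse[1], abs=1e-10)
            assert res.pvalue == pytest.approx(pv[1], abs=1e-10)

    def test_beta_equals_cov_over_var(self, rng):
        g = rng.integers(0, 3, 100).astype(float)
        y = rng.normal(size=100)
        res = marginal_regression(g, y)
        assert res.beta == pytest.approx(np.cov(g, y)[0, 1] / np.var(g, ddof=1), abs=1e-10)

    def test_pvalue_invariant_to_affine_trait_rescaling(self, rng):
        g = rng.integers(0, 3, 60).astype(float)
        y = rng.normal(size=60)
        p1 = marginal_regression(g, y).pvalue
        p2 = marginal_regression(g, 7.3 * y - 11.0).pvalue
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_complete_case_handling(self, rng):
        g = rng.integers(0, 3, 50).astype(float)
        y = rng.normal(size=50)
        g_miss, y_miss = g.copy(), y.copy()
        g_miss[:5] = np.nan
        y_miss[5:8] = np.nan
        res = marginal_regression(g_miss, y_miss)
        ref = marginal_regression(g[8:], y[8:])
        assert res.n_used == 42
        assert res.beta == pytest.approx(ref.beta, abs=1e-12)


class TestAdjustedRegression:
    def test_zero_covariates_reduces_to_marginal(self, rng):
        g = rng.integers(0, 3, 30).astype(float)
        y = rng.normal(size=30)
        res = adjusted_regression(g, y, np.empty((30, 0)))
        ref = marginal_regression(g, y)
        assert res.beta == pytest.approx(ref.beta, abs=1e-12)
        assert res.pvalue == pytest.approx(ref.pvalue, abs=1e-12)

    def test_orthogonal_covariates_leave_slope(self, rng):
        # Frisch-Waugh: covariates orthogonal to genotype and trait
        n = 40
        g = np.tile([0.0, 1.0, 2.0, 1.0], n // 4)
        y = rng.normal(size=n)
        c = rng.normal(size=n)
        # project c off span{1, g}: the genotype coefficient is then unchanged
        B = np.column_stack([np.ones(n), g])
        c -= B @ np.linalg.lstsq(B, c, rcond=None)[0]
        res = adjusted_regression(g, y, c)
        ref = marginal_regression(g, y)
        assert res.beta == pytest.approx(ref.beta, abs=1e-8)

    def test_matches_oracle_with_covariates(self, rng):
        for _ in range(20):
            n = 35
            g = rng.integers(0, 3, n).astype(float)
            C = rng.normal(size=(n, 3))
            y = rng.normal(size=n) + 0.3 * g + C @ [0.5, -0.2, 0.1]
            res = adjusted_regression(g, y, C)
            X = np.column_stack([np.ones(n), g, C])
            coef, bse, pv = ols_oracle(y, X)
            assert res.beta == pytest.approx(coef[1], abs=1e-10)
            assert res.se == pytest.approx(bse[1], abs=1e-10)
            assert res.pvalue == pytest.approx(pv[1], abs=1e-10)

    def test_rank_deficiency_names_columns(self, rng):
        g = rng.integers(0, 3, 30).astype(float)
        C = np.column_stack([g, rng.normal(size=30)])  # duplicate of genotype
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            adjusted_regression(g, rng.normal(size=30), C)

    def test_null_permutation_pvalues_uniform(self, rng):
        n = 50
        g = rng.integers(0, 3, n).astype(float)
        C = rng.normal(size=(n, 2))
        y = rng.normal(size=n)
        pvals = []
        for _ in range(400):
            pvals.append(adjusted_regression(g, rng.permutation(y), C).pvalue)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestBatchSummary:
    def test_matches_per_column_calls(self, rng):
        G = rng.integers(0, 3, size=(200, 5)).astype(float)
        y = rng.normal(size=200)
        ss = batch_summary(G, y)
        for j in range(5):
            ref = marginal_regression(G[:, j], y)
            assert ss.beta[j] == pytest.approx(ref.beta, abs=1e-10)
            assert ss.se[j] == pytest.approx(ref.se, abs=1e-10)
            assert ss.pvalue[j] == pytest.approx(ref.pvalue, abs=1e-10)

    def test_vectorized_path_matches_loop_at_scale(self, rng):
        G = rng.integers(0, 3, size=(20_000, 50))
        y = rng.normal(size=20_000)
        ss = batch_summary(G, y)
        for j in (0, 17, 49):
            ref = marginal_regression(G[:, j].astype(float), y)
            assert ss.beta[j] == pytest.approx(ref.beta, abs=1e-10)
            assert ss.se[j] == pytest.approx(ref.se, abs=1e-10)

    def test_missing_values_fall_back_to_complete_case(self, rng):
        G = rng.integers(0, 3, size=(50, 3)).astype(float)
        G[0, 0] = np.nan
        y = rng.normal(size=50)
        ss = batch_summary(G, y)
        assert ss.n_used[0] == 49 and ss.n_used[1] == 50

    def test_empty_snp_set(self, rng):
        ss = batch_summary(np.empty((10, 0)), rng.normal(size=10))
        assert len(ss) == 0

    def test_dimension_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            batch_summary(np.zeros((10, 2)), np.zeros(11))

    def test_type_i_error_calibrated_under_null(self, rng):
        # independent g and y: raw alpha=.05 rejections in [.04, .06]
        reps, hits = 10_000, 0
        G = rng.integers(0, 3, size=(30, reps))
        y = rng.normal(size=(30,))
        ss = batch_summary(G, y)
        hits = (ss.pvalue < 0.05).sum()
        assert 0.04 <= hits / reps <= 0.06

    def test_tsv_round_trip(self, tmp_path, rng):
        G = rng.integers(0, 3, size=(30, 4)).astype(float)
        ss = batch_summary(G, rng.normal(size=30), trait_id="X")
        path = tmp_path / "stats.tsv"
        ss.to_tsv(path)
        back = SummaryStats.from_tsv(path, trait_id="X")
        np.testing.assert_allclose(back.beta, ss.beta)
        np.testing.assert_allclose(back.pvalue, ss.pvalue)


class TestCorrelationTests:
    def test_identity_and_antisymmetry(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert pearson_test(x, x)[0] == pytest.approx(1.0)
        assert spearman_test(x, x)[0] == pytest.approx(1.0)
        assert pearson_test(x, -x)[0] == pytest.approx(-1.0)

    def test_spearman_matches_rank_formula(self):
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([2, 1, 4, 3, 5], dtype=float)
        # brute-force: Pearson correlation of the ranks
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman_test(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_pairwise_complete(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        x_m = x.copy()
        x_m[:3] = np.nan
        r_m, _ = pearson_test(x_m, y)
        r_ref, _ = pearson_test(x[3:], y[3:])
        assert r_m == pytest.approx(r_ref, abs=1e-12)

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError):
            spearman_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
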