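import numpy as np
import pytest
import scipy.stats

from chd.errors import InputError
from chd.stats import (
    bonferroni,
    cohens_d,
    energy_rating_correlation,
    harmonic_correlate_representation,
    indirect_multiple_correlation,
    kstest2,
    multiple_correlation,
    permutation_test,
    ttest2,
)


class TestTtest2:
    def test_identical_groups(self):
        res = ttest2([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_large_shift_significant(self):
        res = ttest2([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value < 0.01

    def test_matches_textbook_formula_three_elements(self):
        a = np.array([1.0, 4.0, 5.0])
        b = np.array([2.0, 2.5, 6.0])
        res = ttest2(a, b)
        sp2 = (2 * a.var(ddof=1) + 2 * b.var(ddof=1)) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 3 + 1 / 3))
        p = 2 * scipy.stats.t.sf(abs(t), 4)
        assert res.statistic == pytest.approx(t, rel=1e-12)
        assert res.p_value == pytest.approx(p, rel=1e-12)

    def test_degenerate_zero_variance(self):
        equal = ttest2([2.0, 2.0], [2.0, 2.0])
        assert equal.p_value == 1.0
        unequal = ttest2([2.0, 2.0], [3.0, 3.0])
        assert unequal.p_value == 0.0
        assert unequal.notes

    def test_too_small_group(self):
        with pytest.raises(InputError):
            ttest2([1.0], [1.0, 2.0])


class TestKstest2:
    def test_identical_samples(self):
        x = np.arange(10.0)
        assert kstest2(x, x).statistic == 0.0

    def test_disjoint_supports(self):
        res = kstest2(np.arange(10.0), np.arange(10.0) + 100)
        assert res.statistic == 1.0

    def test_matches_ecdf_sweep_oracle(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=40)
        b = rng.normal(0.5, 1.2, size=55)
        res = kstest2(a, b)
        grid = np.sort(np.concatenate([a, b]))
        ecdf_a = np.searchsorted(np.sort(a), grid, side="right") / len(a)
        ecdf_b = np.searchsorted(np.sort(b), grid, side="right") / len(b)
        assert res.statistic == pytest.approx(np.max(np.abs(ecdf_a - ecdf_b)), abs=1e-12)

    def test_tiny_samples_rejected(self):
        with pytest.raises(InputError):
            kstest2([1.0, 2.0], [1.0, 2.0, 3.0, 4.0, 5.0])


class TestPermutationTest:
    def test_identical_pairs_p_one(self):
        x = np.arange(8.0)
        res = permutation_test(x, x, n_perm=500, seed=0)
        assert res.p_value == 1.0

    def test_p_floor_add_one_rule(self):
        a = np.arange(12.0) + 100
        b = np.arange(12.0)
        res = permutation_test(a, b, n_perm=1000, seed=1)
        assert res.p_value >= 1.0 / 1001.0

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=10), rng.normal(size=10)
        r1 = permutation_test(a, b, n_perm=500, seed=7)
        r2 = permutation_test(a, b, n_perm=500, seed=7)
        assert r1.p_value == r2.p_value

    def test_exact_enumeration_matches_mc(self):
        # oracle: full 2^n enumeration of within-pair label swaps
        rng = np.random.default_rng(3)
        a = rng.normal(0.8, 1.0, size=10)
        b = rng.normal(0.0, 1.0, size=10)
        exact = permutation_test(a, b, exact=True)
        mc = permutation_test(a, b, n_perm=20000, seed=11)
        se = np.sqrt(exact.p_value * (1 - exact.p_value) / 20000)
        assert abs(mc.p_value - exact.p_value) < 4 * se + 2.0 / 20001

    def test_small_n_perm_rejected(self):
        with pytest.raises(InputError):
            permutation_test([1.0, 2.0], [3.0, 4.0], n_perm=10)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(InputError):
            permutation_test([1.0, 2.0], [1.0, 2.0, 3.0])


class TestBonferroni:
    def test_single_test_unchanged(self):
        adj, dec = bonferroni([0.004], k=1, alpha=0.01)
        assert adj[0] == 0.004
        assert dec[0]

    def test_fifteen_bins_example(self):
        adj, dec = bonferroni([0.004], k=15, alpha=0.01)
        assert adj[0] == pytest.approx(0.06)
        assert not dec[0]

    def test_capped_at_one(self):
        adj, _ = bonferroni([0.2, 0.9], k=10)
        np.testing.assert_array_equal(adj, [1.0, 1.0])

    def test_k_smaller_than_tests_rejected(self):
        with pytest.raises(InputError):
            bonferroni([0.1, 0.2], k=1)


class TestCohensD:
    def test_equal_means_zero(self):
        assert cohens_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]) == 0.0

    def test_one_pooled_sd_shift(self):
        a = np.array([0.0, 1.0, 2.0])
        b = a + a.std(ddof=1)
        assert cohens_d(b, a) == pytest.approx(1.0, abs=1e-12)

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(size=20), rng.normal(0.3, 2.0, size=30)
        pooled = np.sqrt(
            (19 * a.var(ddof=1) + 29 * b.var(ddof=1)) / 48
        )
        assert cohens_d(a, b) == pytest.approx((a.mean() - b.mean()) / pooled, rel=1e-12)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(InputError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestRatingCorrelation:
    def test_exact_proportionality(self):
        x = np.arange(24.0)
        res = energy_rating_correlation(x, 2.0 * x + 1.0)
        assert res.statistic == pytest.approx(1.0, abs=1e-12)

    def test_null_simulation(self):
        rng = np.random.default_rng(6)
        hits = 0
        for _ in range(200):
            r = energy_rating_correlation(
                rng.normal(size=24), rng.normal(size=24)
            ).statistic
            hits += abs(r) < 0.5
        assert hits / 200 >= 0.95

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=15), rng.normal(size=15)
        r = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert energy_rating_correlation(x, y).statistic == pytest.approx(r, rel=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(InputError):
            energy_rating_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


class TestMultipleCorrelation:
    def test_single_predictor_reduces_to_abs_pearson(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(size=20), rng.normal(size=20)
        res = multiple_correlation(x, y)
        assert res.statistic == pytest.approx(abs(scipy.stats.pearsonr(x, y)[0]), rel=1e-10)

    def test_exact_linear_combination_r_one(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(24, 3))
        y = x @ np.array([1.0, -2.0, 0.5]) + 4.0
        res = multiple_correlation(x, y)
        assert res.statistic == pytest.approx(1.0, abs=1e-8)

    def test_matches_ols_r2_oracle(self):
        # oracle: R^2 from an explicit least-squares regression with intercept
        rng = np.random.default_rng(10)
        x = rng.normal(size=(24, 3))
        y = x @ np.array([0.5, 0.2, -0.1]) + rng.normal(size=24)
        res = multiple_correlation(x, y)
        design = np.column_stack([np.ones(24), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert res.statistic == pytest.approx(np.sqrt(r2), abs=1e-10)

    def test_f_test_p_value(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        res = multiple_correlation(x, y)
        r2 = res.statistic**2
        f = (r2 / 2) / ((1 - r2) / 27)
        assert res.p_value == pytest.approx(scipy.stats.f.sf(f, 2, 27), rel=1e-10)

    def test_collinearity_rejected(self):
        x = np.column_stack([np.arange(10.0), 2 * np.arange(10.0)])
        with pytest.raises(InputError, match="singular|collinearity"):
            multiple_correlation(x, np.random.default_rng(0).normal(size=10))


class TestIndirectMultipleCorrelation:
    def test_self_representation_single_harmonic(self):
        v = np.arange(24.0)
        rep = harmonic_correlate_representation(v, v[:, None], 1)
        assert rep[0] == pytest.approx(1.0, abs=1e-12)

    def test_response_identical_to_predictor_r_one(self):
        rng = np.random.default_rng(13)
        e = rng.normal(size=(24, 40))
        x = rng.normal(size=(24, 2))
        with pytest.warns(UserWarning):
            res = indirect_multiple_correlation(
                np.column_stack([x, x[:, 0]])[:, :2], x[:, 0], e, n_harmonics=40
            )
        assert res.statistic == pytest.approx(1.0, abs=1e-8)

    def test_resolution_grows_with_harmonics(self):
        # distinct inputs map to distinct representations once n is sufficient
        rng = np.random.default_rng(14)
        e = rng.normal(size=(24, 200))
        v1, v2 = rng.normal(size=24), rng.normal(size=24)
        d30 = np.linalg.norm(
            harmonic_correlate_representation(v1, e, 30)
            - harmonic_correlate_representation(v2, e, 30)
        )
        d200 = np.linalg.norm(
            harmonic_correlate_representation(v1, e, 200)
            - harmonic_correlate_representation(v2, e, 200)
        )
        assert d30 > 0
        assert d200 >= d30

    def test_insufficient_harmonics_rejected(self):
        rng = np.random.default_rng(15)
        e = rng.normal(size=(24, 10))
        x = rng.normal(size=(24, 3))
        with pytest.raises(InputError):
            indirect_multiple_correlation(x, rng.normal(size=24), e, n_harmonics=4)

    def test_warning_always_attached(self):
        rng = np.random.default_rng(16)
        e = rng.normal(size=(24, 30))
        x = rng.normal(size=(24, 2))
        with pytest.warns(UserWarning, match="not.*independent"):
            res = indirect_multiple_correlation(x, rng.normal(size=24), e, 30)
        assert any("independent" in note for note in res.notes)


class TestTypeICalibration:
    def test_permutation_type_i_error_small(self):
        # 100 null replicates at alpha=0.05 (full calibration in acceptance)
        rng = np.random.default_rng(17)
        rejections = 0
        n_rep = 100
        for i in range(n_rep):
            a, b = rng.normal(size=(2, 10))
            res = permutation_test(a, b, n_perm=500, seed=int(rng.integers(2**32)))
            rejections += res.p_value < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= 0.05 + 3 * se
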