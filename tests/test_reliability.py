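import numpy as np
import pytest

from emometa.reliability import (
    LOA_MULTIPLIER,
    bland_altman,
    cohens_d_from_t,
    correlate,
    correlation_power_exact,
    icc3_1,
    paired_comparison,
    required_n_correlation,
    required_n_correlation_fisher,
)

# 6 x 2 fixture with unequal rater means and real subject spread
ICC_FIXTURE = np.array(
    [
        [9.0, 10.0],
        [6.5, 7.0],
        [8.0, 8.5],
        [4.0, 5.5],
        [7.0, 6.0],
        [5.5, 6.5],
    ]
)


def anova_icc_oracle(x):
    """Hand ANOVA decomposition: independent route to ICC(3,1)."""
    n, k = x.shape
    grand = x.mean()
    ms_r = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)


class TestIcc:
    def test_identical_columns_give_one(self):
        scores = np.column_stack([ICC_FIXTURE[:, 0], ICC_FIXTURE[:, 0]])
        assert icc3_1(scores).icc == pytest.approx(1.0)

    def test_constant_shift_gives_one(self):
        scores = np.column_stack([ICC_FIXTURE[:, 0], ICC_FIXTURE[:, 0] + 0.2])
        assert icc3_1(scores).icc == pytest.approx(1.0, abs=1e-12)

    def test_fixture_matches_anova_oracle(self):
        res = icc3_1(ICC_FIXTURE)
        assert res.icc == pytest.approx(anova_icc_oracle(ICC_FIXTURE), abs=1e-10)
        assert res.ci_low <= res.icc <= res.ci_high
        assert res.df1 == 5 and res.df2 == 5

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        n = ICC_FIXTURE.shape[0]
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile([1, 2], n),
                "score": ICC_FIXTURE.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, "subject", "rater", "score")
        ref3 = ref.loc[ref["Type"] == "ICC(C,1)"].iloc[0]  # consistency, single
        res = icc3_1(ICC_FIXTURE)
        assert res.icc == pytest.approx(ref3["ICC"], abs=1e-10)
        assert res.f_value == pytest.approx(ref3["F"], abs=1e-10)
        assert (res.df1, res.df2) == (ref3["df1"], ref3["df2"])
        assert res.ci_low == pytest.approx(ref3["CI95"][0], abs=5e-3)  # ref rounds to 2 dp
        assert res.ci_high == pytest.approx(ref3["CI95"][1], abs=5e-3)

    def test_equals_pearson_when_variances_equal(self):
        a = ICC_FIXTURE[:, 0]
        b = 2 * a.mean() - a + 0.3  # same variance, reversed
        r = np.corrcoef(a, b)[0, 1]
        assert icc3_1(np.column_stack([a, b])).icc == pytest.approx(r, abs=1e-10)

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            icc3_1(ICC_FIXTURE[:2])


class TestBlandAltman:
    def test_identical_vectors(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0 and res.loa_low == res.loa_high == 0

    def test_constant_offset(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a, a + 1)
        assert res.bias == pytest.approx(-1.0)
        assert res.loa_high - res.loa_low == pytest.approx(0.0)

    def test_hand_computed_differences(self):
        a = np.array([0.1, -0.1, 0.3, -0.3])
        res = bland_altman(a, np.zeros(4))
        assert res.bias == pytest.approx(0.0)
        assert res.sd_diff == pytest.approx(0.2582, abs=1e-4)
        assert res.loa_high == pytest.approx(1.96 * 0.258198, abs=1e-4)

    def test_antisymmetric_bias(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert bland_altman(a, b).bias == pytest.approx(-bland_altman(b, a).bias)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestCorrelate:
    def test_linear_relation_pearson_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = correlate(a, 2 * a + 3, method="pearson")
        assert res.statistic == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_one(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = correlate(a, a**3, method="spearman")
        assert res.statistic == pytest.approx(1.0)

    def test_spearman_matches_rank_oracle(self):
        rng = np.random.default_rng(21)
        a = rng.normal(size=10)
        b = rng.normal(size=10)
        res = correlate(a, b, method="spearman")
        ranks_a = np.argsort(np.argsort(a)).astype(float)
        ranks_b = np.argsort(np.argsort(b)).astype(float)
        oracle = np.corrcoef(ranks_a, ranks_b)[0, 1]
        assert res.statistic == pytest.approx(oracle, abs=1e-12)

    def test_auto_picks_spearman_for_skewed_margin(self):
        rng = np.random.default_rng(6)
        a = rng.lognormal(0, 2.0, 50)  # grossly non-normal
        b = rng.normal(size=50)
        assert correlate(a, b, method="auto").method == "spearman"
        c = rng.normal(size=50)
        assert correlate(b, c, method="auto").method == "pearson"

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestPairedComparison:
    @pytest.mark.parametrize("t,n,d", [(4.118, 55, 0.555), (0.989, 28, 0.187)])
    def test_effect_size_convention(self, t, n, d):
        assert round(cohens_d_from_t(t, n), 3) == d

    def test_paired_t_and_d_consistent(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.6, 0.1, 30)
        b = a - rng.normal(0.05, 0.08, 30)
        res = paired_comparison(a, b)
        assert res.df == 29
        assert res.effect_size == pytest.approx(res.statistic / np.sqrt(30))

    def test_zero_variance_rejected(self):
        a = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            paired_comparison(a, a)


class TestPower:
    def test_exact_sample_size_for_expected_correlation(self):
        assert required_n_correlation(0.35, alpha=0.05, power=0.8, tails="one") == 49

    def test_exact_below_fisher_approximation(self):
        exact = required_n_correlation(0.35, 0.05, 0.8, "one")
        fisher = required_n_correlation_fisher(0.35, 0.05, 0.8, "one")
        assert fisher == 50
        assert exact < fisher

    def test_power_boundary(self):
        assert correlation_power_exact(0.35, 48, 0.05, "one") < 0.8
        assert correlation_power_exact(0.35, 49, 0.05, "one") >= 0.8

    def test_monotone_in_rho_alpha_power(self):
        base = required_n_correlation(0.35, 0.05, 0.8, "one")
        assert required_n_correlation(0.5, 0.05, 0.8, "one") <= base
        assert required_n_correlation(0.35, 0.10, 0.8, "one") <= base
        assert required_n_correlation(0.35, 0.05, 0.9, "one") >= base

    def test_near_perfect_correlation_minimal_n(self):
        assert required_n_correlation(0.999, 0.05, 0.8, "one") == 4

    def test_loa_multiplier_is_95_percent_normal_quantile(self):
        from scipy.stats import norm

        assert round(norm.ppf(0.975), 2) == LOA_MULTIPLIER
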