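import math

import numpy as np
import pytest
from scipy import stats

from actisleep.comparison_stats import (
    DegenerateDataError,
    bland_altman,
    effect_size_label,
    gg_epsilon,
    gg_epsilon_from_cov,
    hedges_g,
    mauchly_test,
    outlier_sensitivity,
    posthoc_pairs,
    rm_anova,
)


def random_matrix(n=20, k=4, seed=0):
    rng = np.random.default_rng(seed)
    subj = rng.normal(0, 1, size=(n, 1))
    return subj + rng.normal(0, 1, size=(n, k)) + rng.normal(0, 0.5, size=(1, k))


class TestRmAnova:
    def test_two_conditions_f_equals_squared_paired_t(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=(15, 2))
        res = rm_anova(y)
        t = stats.ttest_rel(y[:, 0], y[:, 1])
        assert res.F == pytest.approx(t.statistic**2, abs=1e-10)
        assert res.p_uncorrected == pytest.approx(t.pvalue, abs=1e-10)

    def test_two_conditions_epsilon_is_one(self):
        res = rm_anova(random_matrix(k=2, seed=2))
        assert res.epsilon_gg == 1.0
        assert res.df_num_adj == res.df_num

    def test_identical_condition_columns_give_f_zero(self):
        rng = np.random.default_rng(3)
        col = rng.normal(size=12)
        y = np.column_stack([col, col, col])
        res = rm_anova(y)
        assert res.F == 0.0 and res.p_adjusted == 1.0

    def test_constant_data_raises(self):
        with pytest.raises(DegenerateDataError):
            rm_anova(np.ones((10, 3)))

    def test_sum_of_squares_partition(self):
        y = random_matrix(seed=4)
        res = rm_anova(y)
        ss_total = ((y - y.mean()) ** 2).sum()
        assert res.ss_condition + res.ss_subject + res.ss_error == pytest.approx(ss_total)

    def test_against_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        y = random_matrix(n=18, k=5, seed=5)
        res = rm_anova(y)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(18), 5),
                "cond": list(range(5)) * 18,
                "y": y.ravel(),
            }
        )
        tab = pg.rm_anova(
            data=long, dv="y", within="cond", subject="subject", detailed=True, correction=True
        )
        assert res.F == pytest.approx(float(tab.loc[0, "F"]), rel=1e-9)
        assert res.epsilon_gg == pytest.approx(float(tab.loc[0, "eps"]), rel=1e-9)
        assert res.p_adjusted == pytest.approx(float(tab.loc[0, "p_GG_corr"]), rel=1e-6)
        assert res.p_uncorrected == pytest.approx(float(tab.loc[0, "p_unc"]), rel=1e-9)
        assert res.eta2_g == pytest.approx(float(tab.loc[0, "ng2"]), rel=1e-9)
        sph = pg.sphericity(data=long, dv="y", within="cond", subject="subject")
        assert res.mauchly_w == pytest.approx(float(sph.W), rel=1e-9)
        assert res.mauchly_p == pytest.approx(float(sph.pval), rel=1e-6)


class TestEpsilon:
    def test_epsilon_one_for_compound_symmetric_covariance(self):
        # equal variances + equal covariances: sphericity holds exactly
        k = 5
        cov = 0.3 * np.ones((k, k)) + 0.7 * np.eye(k)
        assert gg_epsilon_from_cov(cov) == pytest.approx(1.0, abs=1e-12)

    def test_epsilon_within_bounds(self):
        for seed in range(5):
            y = random_matrix(n=15, k=6, seed=seed)
            eps = gg_epsilon(y)
            assert 1.0 / 5 - 1e-12 <= eps <= 1.0 + 1e-12

    def test_mauchly_accepts_spherical_data(self):
        rng = np.random.default_rng(9)
        y = rng.normal(size=(200, 4))  # iid columns satisfy sphericity
        w, chi2, dof, p = mauchly_test(y)
        assert p > 0.01 and 0 < w <= 1


class TestPostHoc:
    def test_identical_pair_g_zero_p_one(self):
        rng = np.random.default_rng(10)
        col = rng.normal(size=10)
        res = posthoc_pairs(np.column_stack([col, col]))
        assert res[0].hedges_g == 0.0 and res[0].p_bonferroni == 1.0

    def test_bonferroni_multiplication(self):
        # m=21 pairs, raw p=0.01 -> adjusted 0.21 (capped at 1)
        rng = np.random.default_rng(11)
        y = rng.normal(size=(30, 7))
        res = posthoc_pairs(y, m=21)
        assert len(res) == 21
        for r in res:
            assert r.p_bonferroni == pytest.approx(min(1.0, r.p_raw * 21))

    def test_planted_half_sd_effect_recovered(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.0, 1.0, size=500)
        b = a + 0.5 + rng.normal(0.0, 0.1, size=500)
        g = hedges_g(b, a)
        assert g == pytest.approx(0.5, abs=0.05)
        assert effect_size_label(g) == "medium"

    def test_effect_size_labels(self):
        assert effect_size_label(0.1) == "very small"
        assert effect_size_label(-0.3) == "small"
        assert effect_size_label(0.6) == "medium"
        assert effect_size_label(-1.2) == "large"


class TestBlandAltman:
    def test_identical_vectors(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_difference == 0 and res.sd_difference == 0
        assert res.loa_low == 0 and res.loa_high == 0
        assert res.prop_bias_slope == 0

    def test_hand_computed_limits(self):
        # differences {-5, 0, 5}: MD=0, sample SD=5, LoA = +/- 9.8
        res = bland_altman([5.0, 10.0, 15.0], [10.0, 10.0, 10.0])
        assert res.mean_difference == pytest.approx(0.0)
        assert res.sd_difference == pytest.approx(5.0)
        assert res.loa_low == pytest.approx(-9.8)
        assert res.loa_high == pytest.approx(9.8)

    def test_proportional_bias_slope_recovery(self):
        rng = np.random.default_rng(13)
        means_true = rng.uniform(100, 500, size=400)
        d = 0.5 * means_true + rng.normal(0, 2, size=400)
        a = means_true + d / 2
        b = means_true - d / 2
        res = bland_altman(a, b)
        assert res.prop_bias_slope == pytest.approx(0.5, abs=0.02)
        assert res.prop_bias_p < 1e-6

    def test_degenerate_means_flagged(self):
        res = bland_altman([1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert res.undefined is not None and math.isnan(res.prop_bias_slope)

    def test_too_few_pairs_raises(self):
        with pytest.raises(DegenerateDataError):
            bland_altman([1.0, 2.0], [1.0, 2.0])


class TestOutlierSensitivity:
    @staticmethod
    def _pipeline(counts):
        def fn(ids):
            vals = [counts[i].mean() for i in ids]
            return {"mean_activity": float(np.mean(vals))}

        return fn

    def test_homogeneous_sample_unflagged(self):
        rng = np.random.default_rng(14)
        counts = {f"p{i}": rng.gamma(2, 50, 960) for i in range(20)}
        rep = outlier_sensitivity(counts, self._pipeline(counts))
        assert rep.flagged == {} and rep.within_criterion

    def test_shifted_participant_flagged_by_z_rule(self):
        rng = np.random.default_rng(15)
        counts = {f"p{i}": rng.gamma(2.0, 50.0, 960) for i in range(20)}
        sample_sd = np.std([c.mean() for c in counts.values()], ddof=1)
        counts["p0"] = counts["p0"] + 5 * sample_sd  # shift the mean well past z=2
        rep = outlier_sensitivity(counts, self._pipeline(counts))
        assert "p0" in rep.flagged and "z_score" in rep.flagged["p0"]

    def test_relative_change_arithmetic(self):
        assert abs(0.80 - 0.78) / 0.80 == pytest.approx(0.025)

    def test_too_few_participants_raises(self):
        counts = {f"p{i}": np.ones(10) for i in range(5)}
        with pytest.raises(DegenerateDataError):
            outlier_sensitivity(counts, self._pipeline(counts))
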