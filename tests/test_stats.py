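import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats as sps

from autoresus.core import (InsufficientDataError, SeparationError,
                            UndefinedResultError)
from autoresus.stats import (ContingencyTable, compare_slopes,
                             coupling_regression, fisher_midp_one_tailed,
                             group_compare, hypergeom_support_pmf,
                             logistic_fit, logistic_mortality, odds_ratio,
                             runs_test_pvalue, variance_f_test)

MORTALITY_TABLE = ContingencyTable(7, 15, 1, 14)


def midp_oracle(a, b, c, d):
    """Exact-rational hypergeometric enumeration, independent of scipy."""
    n = a + b + c + d
    deaths = a + c
    row = a + b
    lo, hi = max(0, row - (n - deaths)), min(row, deaths)
    denom = math.comb(n, row)
    p = Fraction(0)
    for k in range(lo, hi + 1):
        mass = Fraction(math.comb(deaths, k) * math.comb(n - deaths, row - k),
                        denom)
        if k > a:
            p += mass
        elif k == a:
            p += mass / 2
    return float(p)


class TestOddsRatio:
    def test_paper_mortality_table(self):
        assert odds_ratio(MORTALITY_TABLE) == pytest.approx(6.5333333333)
        assert round(odds_ratio(MORTALITY_TABLE), 1) == 6.5

    def test_identity_table(self):
        assert odds_ratio(ContingencyTable(1, 1, 1, 1)) == 1.0

    def test_forced_arithmetic(self):
        assert odds_ratio(ContingencyTable(2, 3, 4, 5)) == pytest.approx(
            (2 / 4) / (3 / 5))

    def test_zero_cell_undefined_without_correction(self):
        with pytest.raises(UndefinedResultError):
            odds_ratio(ContingencyTable(2, 3, 0, 5))
        assert odds_ratio(ContingencyTable(2, 3, 0, 5), correction=0.5) > 0

    def test_invalid_cells_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable(1.5, 2, 3, 4)


class TestFisherMidP:
    def test_paper_mortality_table_three_decimals(self):
        p = fisher_midp_one_tailed(MORTALITY_TABLE)
        assert round(p, 3) == 0.041
        assert p == pytest.approx(midp_oracle(7, 15, 1, 14), rel=1e-12)

    def test_small_table_equals_brute_force(self):
        t = ContingencyTable(2, 1, 1, 2)
        assert fisher_midp_one_tailed(t) == pytest.approx(
            midp_oracle(2, 1, 1, 2), rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_tables_match_oracle_both_directions(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c, d = (int(x) for x in rng.integers(0, 12, 4))
        t = ContingencyTable(a, b, c, d)
        assert fisher_midp_one_tailed(t, "greater") == pytest.approx(
            midp_oracle(a, b, c, d), abs=1e-12)
        mirror = midp_oracle(c, d, a, b)  # swapping rows flips the direction
        assert fisher_midp_one_tailed(t, "less") == pytest.approx(
            1.0 - fisher_midp_one_tailed(t, "greater"), abs=1e-12)
        assert mirror == pytest.approx(1.0 - midp_oracle(a, b, c, d), abs=1e-9)

    def test_midp_not_larger_than_ordinary_fisher(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, 4))
            t = ContingencyTable(a, b, c, d)
            _, fisher_p = sps.fisher_exact([[a, b], [c, d]],
                                           alternative="greater")
            assert fisher_midp_one_tailed(t) <= fisher_p + 1e-12

    def test_support_pmf_sums_to_one(self):
        for t in (MORTALITY_TABLE, ContingencyTable(0, 5, 3, 2),
                  ContingencyTable(9, 0, 0, 9)):
            _, pmf = hypergeom_support_pmf(t)
            assert pmf.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            fisher_midp_one_tailed(MORTALITY_TABLE, "sideways")

    def test_null_type_one_error_and_midp_property(self):
        # Simulated null with the mortality-table margins.  mid-P is not
        # strictly conservative on a discrete support: its type-I error can
        # exceed nominal by at most the point mass of the critical cell, and
        # it always rejects at least as often as ordinary Fisher.
        alpha = 0.05
        rng = np.random.default_rng(0)
        draws = sps.hypergeom.rvs(37, 8, 22, size=3000, random_state=rng)
        rejections_mid = 0
        rejections_fisher = 0
        max_mass_at_boundary = 0.0
        for a in draws:
            t = ContingencyTable(int(a), 22 - int(a), 8 - int(a), 7 + int(a))
            p_mid = fisher_midp_one_tailed(t)
            _, p_f = sps.fisher_exact([[t.a, t.b], [t.c, t.d]],
                                      alternative="greater")
            rejections_mid += p_mid <= alpha
            rejections_fisher += p_f <= alpha
            if p_mid <= alpha:
                max_mass_at_boundary = max(
                    max_mass_at_boundary,
                    float(sps.hypergeom.pmf(int(a), 37, 8, 22)))
        mc_err = 3 * math.sqrt(alpha * (1 - alpha) / draws.size)
        rate = rejections_mid / draws.size
        assert rate <= alpha + max_mass_at_boundary + mc_err
        assert rejections_mid >= rejections_fisher


class TestLogistic:
    def test_grouped_two_level_closed_form(self):
        # x=0: 1 death / 3 survive; x=1: 3 deaths / 1 survives
        x = np.array([0, 0, 0, 0, 1, 1, 1, 1], dtype=float)
        y = np.array([1, 0, 0, 0, 1, 1, 1, 0], dtype=float)
        res = logistic_fit(x[:, None], y, names=["x"])
        assert res.coefficients["intercept"] == pytest.approx(math.log(1 / 3),
                                                              abs=1e-6)
        assert res.coefficients["x"] == pytest.approx(math.log(9), abs=1e-6)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(4)
        x = rng.normal(size=(200, 2))
        eta = -0.5 + 0.8 * x[:, 0] - 0.3 * x[:, 1]
        y = (rng.random(200) < 1 / (1 + np.exp(-eta))).astype(float)
        res = logistic_fit(x, y, names=["u", "v"])
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(
            [res.coefficients["intercept"], res.coefficients["u"],
             res.coefficients["v"]], ref.params, rtol=1e-6)
        np.testing.assert_allclose(
            [res.std_errors["intercept"], res.std_errors["u"],
             res.std_errors["v"]], ref.bse, rtol=1e-5)

    def test_single_binary_predictor_matches_table_odds_ratio(self):
        x = np.array([1] * 22 + [0] * 15, dtype=float)
        y = np.array([1] * 7 + [0] * 15 + [1] * 1 + [0] * 14, dtype=float)
        res = logistic_fit(x[:, None], y, names=["genotype"])
        assert res.odds_ratios["genotype"] == pytest.approx(
            odds_ratio(MORTALITY_TABLE), rel=1e-6)

    def test_null_effect_calibration(self):
        rng = np.random.default_rng(8)
        ors, pvals = [], []
        for _ in range(60):
            x = rng.normal(size=250)
            y = (rng.random(250) < 0.3).astype(float)
            res = logistic_fit(x[:, None], y, names=["x"])
            ors.append(res.odds_ratios["x"])
            pvals.append(res.p_values["x"])
        assert np.mean(ors) == pytest.approx(1.0, abs=0.05)
        assert 0.2 < np.mean(np.asarray(pvals) < 0.5) < 0.8

    def test_complete_separation_flagged(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0])
        y = np.array([0.0, 0, 0, 0, 1, 1, 1, 1])
        with pytest.raises(SeparationError):
            logistic_fit(x[:, None], y, names=["x"])

    def test_ci_brackets_or(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-(x - 0.5)))).astype(float)
        res = logistic_fit(x[:, None], y, names=["x"])
        lo, hi = res.conf_int["x"]
        assert lo < res.odds_ratios["x"] < hi

    def test_logistic_mortality_genotype_covariate(self):
        import pandas as pd
        rng = np.random.default_rng(3)
        n = 400
        genotype = np.where(rng.random(n) < 0.5, "experimental", "control")
        v = rng.normal(16, 3.7, n)
        eta = -8.0 + math.log(1.4) * v + 1.8 * (genotype == "experimental")
        died = rng.random(n) < 1 / (1 + np.exp(-eta))
        df = pd.DataFrame({"died": died, "genotype": genotype, "vevo2": v})
        res = logistic_mortality(df, "vevo2")
        assert res.odds_ratios["vevo2"] == pytest.approx(1.4, abs=0.2)
        assert "genotype" in res.coefficients

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            logistic_fit(np.arange(5.0)[:, None], np.zeros(5))


def runs_oracle(n1, n2, r_obs):
    """P(R <= r_obs) by enumerating every arrangement of n1 '+' among n."""
    n = n1 + n2
    count = 0
    total = 0
    for pos in itertools.combinations(range(n), n1):
        seq = np.full(n, -1)
        seq[list(pos)] = 1
        runs = 1 + int(np.sum(np.diff(seq) != 0))
        count += runs <= r_obs
        total += 1
    return count / total


class TestRunsTest:
    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 2), (5, 5), (6, 4), (2, 7)])
    def test_exact_matches_enumeration(self, n1, n2):
        for r_obs in range(2, n1 + n2 + 1):
            signs = None
            # any sequence with the right composition and run count
            p = sum(v for r, v in
                    __import__("autoresus.stats", fromlist=["_runs_pmf"])
                    ._runs_pmf(n1, n2).items() if r <= r_obs)
            assert min(1.0, p) == pytest.approx(runs_oracle(n1, n2, r_obs),
                                                abs=1e-12)

    def test_alternating_sequence_maximal_runs(self):
        signs = np.array([1, -1] * 5)
        assert runs_test_pvalue(signs) == pytest.approx(1.0)

    def test_two_block_sequence_minimal_runs(self):
        signs = np.array([1] * 5 + [-1] * 5)
        # P(R <= 2) = 2/C(10,5)
        assert runs_test_pvalue(signs) == pytest.approx(2 / math.comb(10, 5),
                                                        rel=1e-12)

    def test_one_sided_sequence_returns_one(self):
        assert runs_test_pvalue(np.ones(6)) == 1.0

    def test_normal_approximation_reasonable(self):
        rng = np.random.default_rng(0)
        signs = np.where(rng.random(200) < 0.5, 1, -1)
        p = runs_test_pvalue(signs)
        assert 0.0 < p <= 1.0


class TestCouplingRegression:
    def test_collinear_points(self):
        x = np.arange(10.0)
        res = coupling_regression(2.0 * x + 1.0, x)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.runs_test_p == 1.0
        assert res.p_nonzero_slope < 1e-6

    def test_matches_scipy_linregress(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 50, 30)
        y = 1.4 * x + rng.normal(0, 5, 30)
        res = coupling_regression(y, x)
        ref = sps.linregress(x, y)
        assert res.slope == pytest.approx(ref.slope, rel=1e-12)
        assert res.intercept == pytest.approx(ref.intercept, rel=1e-9)
        assert res.r_squared == pytest.approx(ref.rvalue ** 2, rel=1e-9)
        assert res.p_nonzero_slope == pytest.approx(ref.pvalue, rel=1e-9)

    def test_parabola_fails_runs_test(self):
        x = np.linspace(-3, 3, 12)
        y = x ** 2
        res = coupling_regression(y, x)
        assert res.runs_test_p < 0.05

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            coupling_regression([1.0, 2.0], [1.0, 2.0])

    def test_censored_values_rejected(self):
        with pytest.raises(ValueError):
            coupling_regression([1.0, np.nan, 3.0], [1.0, 2.0, 3.0])


class TestCompareSlopes:
    def test_identical_datasets_p_one(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, 15)
        y = 2 * x + rng.normal(0, 1, 15)
        assert compare_slopes(x, y, x, y) == pytest.approx(1.0)

    def test_different_slopes_low_noise(self):
        rng = np.random.default_rng(7)
        x = np.linspace(0, 10, 15)
        y1 = 1.0 * x + rng.normal(0, 0.3, 15)
        y2 = 2.0 * x + rng.normal(0, 0.3, 15)
        assert compare_slopes(x, y1, x, y2) < 0.01

    def test_equal_slopes_p_uniformish(self):
        rng = np.random.default_rng(8)
        pvals = []
        for _ in range(40):
            x = np.linspace(0, 10, 12)
            y1 = x + rng.normal(0, 1, 12)
            y2 = x + rng.normal(0, 1, 12)
            pvals.append(compare_slopes(x, y1, x, y2))
        assert np.mean(np.asarray(pvals) < 0.05) < 0.25


class TestVarianceFTest:
    def test_identical_samples_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert variance_f_test(x, x.copy()) == pytest.approx(1.0)

    def test_hand_computed_3v3_matches_cdf_oracle(self):
        x = np.array([1.0, 2.0, 3.0])  # var 1.0
        y = np.array([1.0, 3.0, 5.0])  # var 4.0
        expected = 2 * min(sps.f.cdf(0.25, 2, 2), sps.f.sf(0.25, 2, 2))
        assert variance_f_test(x, y) == pytest.approx(expected, rel=1e-12)

    def test_equal_variance_large_n_uniformish(self):
        rng = np.random.default_rng(9)
        pvals = [variance_f_test(rng.normal(size=50), rng.normal(size=50))
                 for _ in range(60)]
        assert np.mean(np.asarray(pvals) < 0.05) < 0.2

    def test_zero_variance_degenerate(self):
        with pytest.raises(UndefinedResultError):
            variance_f_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestGroupCompare:
    def test_matches_scipy(self):
        rng = np.random.default_rng(10)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 20)
        for kind, ref in (("t", sps.ttest_ind(x, y)),
                          ("welch", sps.ttest_ind(x, y, equal_var=False)),
                          ("mannwhitney", sps.mannwhitneyu(
                              x, y, alternative="two-sided"))):
            stat, p = group_compare(x, y, kind)
            assert p == pytest.approx(float(ref.pvalue))

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            group_compare([1, 2], [3, 4], "anova")
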