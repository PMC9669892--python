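from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import stats as sps
from scipy.optimize import brentq

from feverdq.stats import (
    ContingencyTable2x2,
    chi_square_yates,
    clopper_pearson,
    completeness_rate,
    concordance_rate,
    format_p,
    mann_whitney,
    median_iqr,
    threshold_check,
)


def cp_by_tail_inversion(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Independent oracle: invert the binomial tails by root bisection."""
    if k == 0:
        low = 0.0
    else:
        low = brentq(lambda p: sps.binom.sf(k - 1, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    if k == n:
        high = 1.0
    else:
        high = brentq(lambda p: sps.binom.cdf(k, n, p) - alpha / 2, 1e-12, 1 - 1e-12)
    return low, high


class TestClopperPearson:
    def test_zero_successes_lower_bound_is_zero(self):
        low, high = clopper_pearson(0, 10)
        assert low == 0.0 and 0 < high < 1

    def test_all_successes_upper_bound_is_one(self):
        low, high = clopper_pearson(10, 10)
        assert high == 1.0 and 0 < low < 1

    def test_published_interval_423_of_953(self):
        low, high = clopper_pearson(423, 953)
        assert round(low, 3) == 0.412
        assert round(high, 3) == 0.476

    def test_matches_binomial_tail_inversion(self):
        for k, n in [(3, 8), (1, 5), (7, 9), (50, 200)]:
            lo1, hi1 = clopper_pearson(k, n)
            lo2, hi2 = cp_by_tail_inversion(k, n)
            assert lo1 == pytest.approx(lo2, abs=1e-9)
            assert hi1 == pytest.approx(hi2, abs=1e-9)

    def test_matches_statsmodels_beta_interval(self):
        from statsmodels.stats.proportion import proportion_confint

        for k, n in [(0, 7), (3, 8), (423, 953), (686, 686)]:
            lo, hi = clopper_pearson(k, n)
            slo, shi = proportion_confint(k, n, method="beta")
            assert lo == pytest.approx(float(slo), abs=1e-12)
            assert hi == pytest.approx(float(shi), abs=1e-12)

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(0, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 3)

    def test_exact_interval_coverage_is_conservative(self):
        # >= 95% empirical coverage at nominal 95%, by exactness
        rng = np.random.default_rng(42)
        for p in (0.1, 0.5, 0.9):
            for n in (20, 200):
                ks = rng.binomial(n, p, size=2000)
                lows = np.where(ks == 0, 0.0, sps.beta.ppf(0.025, ks, n - ks + 1))
                highs = np.where(ks == n, 1.0, sps.beta.ppf(0.975, ks + 1, n - ks))
                coverage = np.mean((lows <= p) & (p <= highs))
                assert coverage >= 0.95

    def test_width_non_increasing_in_n_at_fixed_rate(self):
        widths = []
        for n in (10, 20, 40, 80, 160, 320):
            k = n // 4
            lo, hi = clopper_pearson(k, n)
            widths.append(hi - lo)
        assert all(b <= a for a, b in zip(widths, widths[1:]))


class TestRates:
    def test_concordance_examples(self):
        assert round(100 * concordance_rate(423, 686).rate, 1) == 61.7
        assert round(100 * concordance_rate(619, 686).rate, 1) == 90.2

    def test_full_agreement_has_unit_upper_bound(self):
        d = concordance_rate(50, 50)
        assert d.rate == 1.0 and d.ci_high == 1.0

    def test_completeness_examples(self):
        d = completeness_rate(423, 953)
        assert round(100 * d.rate, 1) == 44.4
        assert (round(100 * d.ci_low, 1), round(100 * d.ci_high, 1)) == (41.2, 47.6)
        d2 = completeness_rate(619, 1452)
        assert round(100 * d2.rate, 2) == 42.63
        assert (round(100 * d2.ci_low, 1), round(100 * d2.ci_high, 1)) == (40.1, 45.2)

    def test_zero_agreements_rate_zero(self):
        assert completeness_rate(0, 12).rate == 0.0

    def test_rates_live_inside_their_intervals(self):
        for k, n in [(0, 5), (3, 8), (110, 686), (686, 686)]:
            d = concordance_rate(k, n)
            assert d.ci_low <= d.rate <= d.ci_high


class TestChiSquare:
    def test_published_acute_vs_past_statistic(self):
        stat, df, p = chi_square_yates(ContingencyTable2x2(90, 334, 20, 242))
        assert stat == pytest.approx(21.225, abs=5e-4)
        assert df == 1 and p < 0.001

    def test_proportional_table_gives_zero(self):
        stat, _, p = chi_square_yates(ContingencyTable2x2(10, 20, 30, 60))
        assert stat == 0.0 and p == 1.0

    def test_continuity_capped_when_observed_near_expected(self):
        stat, _, _ = chi_square_yates(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0.0

    def test_random_tables_agree_with_cell_sum_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 30, size=4)
            stat, _, _ = chi_square_yates(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            obs = np.array([[a, b], [c, d]], dtype=float)
            n = obs.sum()
            expected = np.outer(obs.sum(1), obs.sum(0)) / n
            dev = np.abs(obs - expected)
            oracle = float(np.sum(np.maximum(dev - 0.5, 0.0) ** 2 / expected))
            assert stat == pytest.approx(oracle, rel=1e-10)

    def test_agrees_with_scipy_contingency(self):
        obs = np.array([[90, 334], [20, 242]])
        stat, _, p = chi_square_yates(ContingencyTable2x2(90, 334, 20, 242))
        ref = sps.chi2_contingency(obs, correction=True)
        assert stat == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_yates(ContingencyTable2x2(0, 0, 5, 5))


def exact_u_pvalue(x, y):
    """Permutation oracle: exact two-sided p for the Mann-Whitney U."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_of(sample_x, sample_y):
        return sum(1 for a in sample_x for b in sample_y if a > b) + 0.5 * sum(
            1 for a in sample_x for b in sample_y if a == b
        )

    observed = u_of(x, y)
    mu = nx * len(y) / 2
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), nx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        if abs(u_of(xs, ys) - mu) >= abs(observed - mu) - 1e-12:
            count += 1
        total += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_direction_free(self):
        u, p = mann_whitney([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p > 0.9

    def test_complete_separation_gives_zero_u(self):
        u, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0

    def test_small_samples_match_permutation_enumeration(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            pool = rng.choice(1000, size=11, replace=False).astype(float)
            x, y = pool[:5].tolist(), pool[5:].tolist()
            _, p = mann_whitney(x, y)
            assert p == pytest.approx(exact_u_pvalue(x, y), abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])


class TestDescriptives:
    def test_median_and_inclusive_quartiles(self):
        med, q1, q3, lo, hi = median_iqr([1, 2, 3, 4, 5])
        assert (med, q1, q3, lo, hi) == (3, 2, 4, 1, 5)

    def test_single_value_collapses(self):
        assert median_iqr([7.0]) == (7.0, 7.0, 7.0, 7.0, 7.0)

    def test_random_samples_match_sort_and_interpolate_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            v = rng.normal(size=rng.integers(2, 50))
            med, q1, q3, lo, hi = median_iqr(v)
            s = np.sort(v)

            def interp(q):
                pos = q * (len(s) - 1)
                f = int(np.floor(pos))
                c = min(f + 1, len(s) - 1)
                return s[f] + (pos - f) * (s[c] - s[f])

            assert q1 == pytest.approx(interp(0.25))
            assert med == pytest.approx(interp(0.5))
            assert q3 == pytest.approx(interp(0.75))


class TestThreshold:
    def test_pass_fail_and_inclusive_boundary(self):
        assert threshold_check(concordance_rate(1005, 1012))  # 99.3%
        assert not threshold_check(concordance_rate(423, 686))  # 61.7%
        assert threshold_check(concordance_rate(19, 20))  # exactly 0.95


def test_p_value_formatting():
    assert format_p(0.0004) == "<.001"
    assert format_p(0.034) == ".034"
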