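"""Exact burden inference: P-values, odds ratios, intervals, pooling.

Oracles: exact-rational hypergeometric enumeration for the two-sided
P-value, float bisection on the noncentral-hypergeometric tails for the
exact CI, and scipy's independent implementations (``fisher_exact``,
``contingency.odds_ratio``) as cross-checks.
"""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from varburden.stats import (
    ContingencyTable,
    burden_test,
    calibration_synonymous,
    fisher_two_sided,
    meta_pool,
    odds_ratio_ci,
    odds_ratio_cmle,
    odds_ratio_sample,
)

# ---------------------------------------------------------------------------
# independent oracles


def _fisher_oracle(a, n1, b, n2):
    """Two-sided minimum-likelihood P by exact rational enumeration."""
    k = a + b
    lo, hi = max(0, k - n2), min(k, n1)
    denom = math.comb(n1 + n2, k)
    probs = {
        x: Fraction(math.comb(n1, x) * math.comb(n2, k - x), denom)
        for x in range(lo, hi + 1)
    }
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def _nchg_tail_oracle(a, n1, b, n2, psi, upper):
    k = a + b
    lo, hi = max(0, k - n2), min(k, n1)
    weights = {
        x: math.comb(n1, x) * math.comb(n2, k - x) * psi**x
        for x in range(lo, hi + 1)
    }
    total = sum(weights.values())
    if upper:
        return sum(w for x, w in weights.items() if x >= a) / total
    return sum(w for x, w in weights.items() if x <= a) / total


def _ci_oracle(a, n1, b, n2, level=0.95, tol=1e-9):
    """Exact-conditional CI by plain bisection on each tail."""
    alpha = (1 - level) / 2

    def bisect(f, lo, hi):
        # bracket may be passed high-to-low for a decreasing tail
        for _ in range(200):
            mid = (lo + hi) / 2
            if f(mid) > 0:
                hi = mid
            else:
                lo = mid
            if abs(hi - lo) < tol * max(1.0, abs(mid)):
                break
        return (lo + hi) / 2

    low = bisect(lambda p: _nchg_tail_oracle(a, n1, b, n2, p, True) - alpha,
                 1e-8, 1e8)
    high = bisect(lambda p: _nchg_tail_oracle(a, n1, b, n2, p, False) - alpha,
                  1e8, 1e-8)
    return low, high


# ---------------------------------------------------------------------------
# fisher_two_sided


class TestFisherTwoSided:
    @pytest.mark.parametrize(
        ("table", "expected", "decimals"),
        [
            ((4, 793, 4, 4523), 0.02, 2),  # discovery truncating class
            ((5, 10, 5, 10), 1.0, 10),  # identical proportions
        ],
    )
    def test_reference_values(self, table, expected, decimals):
        p = fisher_two_sided(ContingencyTable(*table))
        assert p == pytest.approx(expected, abs=10.0 ** -decimals)

    def test_equals_enumeration_on_all_small_tables(self):
        """Full sweep of tables with both group sizes up to 12."""
        for n1, n2 in product(range(1, 13), range(1, 13)):
            for a in range(n1 + 1):
                for b in range(n2 + 1):
                    t = ContingencyTable(a, n1, b, n2)
                    assert fisher_two_sided(t) == pytest.approx(
                        _fisher_oracle(a, n1, b, n2), rel=1e-9, abs=1e-12
                    ), (a, n1, b, n2)

    @settings(derandomize=True, max_examples=150)
    @given(
        a=st.integers(0, 40), extra1=st.integers(1, 400),
        b=st.integers(0, 60), extra2=st.integers(1, 4000),
    )
    def test_matches_scipy_on_random_tables(self, a, extra1, b, extra2):
        t = ContingencyTable(a, a + extra1, b, b + extra2)
        _, p_scipy = sps.fisher_exact(
            [[t.a, t.n1 - t.a], [t.b, t.n2 - t.b]]
        )
        assert fisher_two_sided(t) == pytest.approx(p_scipy, rel=1e-8, abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.integers(0, 15), extra1=st.integers(1, 50),
        b=st.integers(0, 15), extra2=st.integers(1, 50),
    )
    def test_invariant_under_group_and_outcome_swap(self, a, extra1, b, extra2):
        t = ContingencyTable(a, a + extra1, b, b + extra2)
        swapped = ContingencyTable(t.n1 - t.a, t.n1, t.n2 - t.b, t.n2)
        assert fisher_two_sided(t) == pytest.approx(
            fisher_two_sided(t.swapped_groups()), rel=1e-10
        )
        assert fisher_two_sided(t) == pytest.approx(
            fisher_two_sided(swapped), rel=1e-10
        )

    def test_p_decreases_as_case_carriers_grow(self):
        # starting above the control proportion, more carriers = more extreme
        ps = [fisher_two_sided(ContingencyTable(a, 793, 4, 4523))
              for a in range(8, 30)]
        assert all(p1 >= p2 for p1, p2 in zip(ps, ps[1:]))


# ---------------------------------------------------------------------------
# odds ratios


class TestOddsRatio:
    def test_validation_truncating_point_estimate(self):
        t = ContingencyTable(3, 419, 4, 4523)
        assert odds_ratio_sample(t) == pytest.approx(8.14, abs=0.01)

    def test_validation_missense_point_estimate(self):
        t = ContingencyTable(15, 419, 46, 4523)
        assert odds_ratio_sample(t) == pytest.approx(3.61, abs=0.01)

    @settings(derandomize=True, max_examples=100)
    @given(
        a=st.integers(1, 20), extra1=st.integers(1, 100),
        b=st.integers(1, 20), extra2=st.integers(1, 100),
    )
    def test_group_swap_gives_reciprocal(self, a, extra1, b, extra2):
        t = ContingencyTable(a, a + extra1, b, b + extra2)
        assert odds_ratio_sample(t.swapped_groups()) == pytest.approx(
            1.0 / odds_ratio_sample(t), rel=1e-12
        )

    def test_zero_cells(self):
        assert odds_ratio_sample(ContingencyTable(3, 10, 0, 10)) == math.inf
        assert odds_ratio_sample(ContingencyTable(0, 10, 3, 10)) == 0.0
        assert math.isnan(odds_ratio_sample(ContingencyTable(0, 10, 0, 10)))

    def test_cmle_matches_scipy_conditional_estimate(self):
        for cells in [(3, 419, 4, 4523), (25, 793, 46, 4523), (4, 1212, 1, 4523),
                      (5, 12, 3, 9)]:
            t = ContingencyTable(*cells)
            ref = sps.contingency.odds_ratio(
                [[t.a, t.n1 - t.a], [t.b, t.n2 - t.b]]
            ).statistic
            assert odds_ratio_cmle(t) == pytest.approx(ref, rel=1e-4)

    def test_cmle_slightly_shrinks_the_pooled_deleterious_estimate(self):
        # conditional-MLE < cross-product on this sparse pooled table
        t = ContingencyTable(4, 1212, 1, 4523)
        assert odds_ratio_cmle(t) == pytest.approx(14.96, abs=0.01)
        assert odds_ratio_sample(t) == pytest.approx(14.97, abs=0.01)


class TestOddsRatioCI:
    def test_published_interval_is_exact_conditional(self):
        low, high = odds_ratio_ci(ContingencyTable(3, 419, 4, 4523))
        assert low == pytest.approx(1.19, abs=0.01)
        assert high == pytest.approx(48.30, abs=0.02)

    def test_null_table_interval_contains_one(self):
        for method in ("exact-conditional", "log-woolf"):
            low, high = odds_ratio_ci(ContingencyTable(4, 20, 4, 20),
                                      method=method)
            assert low < 1.0 < high

    @pytest.mark.parametrize(
        "cells",
        [(3, 10, 4, 12), (1, 8, 5, 20), (7, 15, 2, 18), (10, 20, 10, 20),
         (2, 19, 9, 11), (17, 20, 3, 15)],
    )
    def test_exact_ci_matches_bisection_oracle(self, cells):
        t = ContingencyTable(*cells)
        low, high = odds_ratio_ci(t)
        olow, ohigh = _ci_oracle(*cells)
        assert low == pytest.approx(olow, rel=1e-3)
        assert high == pytest.approx(ohigh, rel=1e-3)

    def test_exact_ci_matches_scipy_conditional(self):
        for cells in [(3, 419, 4, 4523), (25, 793, 46, 4523), (6, 793, 15, 4523)]:
            t = ContingencyTable(*cells)
            ref = sps.contingency.odds_ratio(
                [[t.a, t.n1 - t.a], [t.b, t.n2 - t.b]]
            ).confidence_interval(0.95)
            low, high = odds_ratio_ci(t)
            assert low == pytest.approx(ref.low, rel=1e-4)
            assert high == pytest.approx(ref.high, rel=1e-4)

    def test_zero_cell_gives_one_sided_bounds(self):
        low, high = odds_ratio_ci(ContingencyTable(0, 10, 4, 20))
        assert low == 0.0 and high < math.inf
        low, high = odds_ratio_ci(ContingencyTable(4, 10, 0, 20))
        assert low > 0.0 and high == math.inf

    def test_log_woolf_formula(self):
        t = ContingencyTable(10, 30, 5, 40)
        low, high = odds_ratio_ci(t, method="log-woolf")
        log_or = math.log(10 * 35 / (20 * 5))
        se = math.sqrt(1 / 10 + 1 / 20 + 1 / 5 + 1 / 35)
        assert low == pytest.approx(math.exp(log_or - 1.959963985 * se), rel=1e-6)
        assert high == pytest.approx(math.exp(log_or + 1.959963985 * se), rel=1e-6)

    def test_exact_ci_empirical_coverage(self):
        """Coverage of the 95% exact interval at true OR 1 and 5.

        2,000 simulated carrier-count tables per value; exact intervals
        are conservative, so coverage must be at least 93%.
        """
        from varburden.simulate import simulate_tables

        rng = np.random.default_rng(2024)
        n1, n2, p0 = 793, 4523, 46 / 4523
        for true_or in (1.0, 5.0):
            tables = simulate_tables(p0, true_or, n1, n2, 2000, rng)
            cache: dict = {}
            covered = 0
            for a, b in tables:
                key = (int(a), int(b))
                if key not in cache:
                    cache[key] = odds_ratio_ci(ContingencyTable(key[0], n1,
                                                                key[1], n2))
                low, high = cache[key]
                covered += low <= true_or <= high
            assert covered / len(tables) >= 0.93


# ---------------------------------------------------------------------------
# assembled test, pooling, calibration


class TestBurdenTest:
    def test_discovery_missense(self):
        res = burden_test(25, 793, 46, 4523, class_label="missense")
        assert res.p_two_sided == pytest.approx(2.56e-5, abs=5e-8)

    def test_deleterious_missense(self):
        res = burden_test(3, 793, 1, 4523)
        assert round(res.p_two_sided, 2) == 0.01

    def test_degenerate_table(self):
        res = burden_test(0, 100, 0, 100)
        assert res.p_two_sided == 1.0
        assert res.degenerate
        assert math.isnan(res.or_sample)

    def test_result_consistency(self):
        res = burden_test(7, 1212, 4, 4523)
        assert res.ci_low <= res.or_sample <= res.ci_high
        assert res.table.cells == (7, 1205, 4, 4519)


class TestMetaPool:
    def test_pooled_counts_are_sums(self):
        assert meta_pool([(4, 793), (3, 419)]) == (7, 1212)
        assert meta_pool([(25, 793), (15, 419)]) == (40, 1212)

    def test_single_cohort_identity(self):
        assert meta_pool([(4, 793)]) == (4, 793)

    def test_overlapping_ids_rejected(self):
        with pytest.raises(ValueError, match="share"):
            meta_pool([(1, 10), (1, 10)],
                      sample_id_sets=[{"s1", "s2"}, {"s2", "s3"}])

    def test_pooling_identical_cohorts_preserves_odds_ratio(self):
        single = ContingencyTable(4, 793, 4, 4523)
        a, n = meta_pool([(4, 793)] * 3)
        pooled = ContingencyTable(a, n, 12, 3 * 4523)
        assert odds_ratio_sample(pooled) == pytest.approx(
            odds_ratio_sample(single), rel=1e-12
        )

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            meta_pool([])


class TestCalibration:
    def test_discovery_synonymous_is_calibrated(self):
        res = calibration_synonymous(6, 793, 15, 4523)
        assert res.burden.p_two_sided == pytest.approx(0.11, abs=0.005)
        assert res.calibrated

    def test_validation_synonymous_is_calibrated(self):
        res = calibration_synonymous(2, 419, 15, 4523)
        assert res.burden.p_two_sided == pytest.approx(0.65, abs=0.005)
        assert res.calibrated

    def test_gross_imbalance_is_flagged(self):
        assert not calibration_synonymous(50, 100, 5, 100).calibrated


def test_contingency_table_validation():
    with pytest.raises(ValueError):
        ContingencyTable(5, 4, 0, 10)
    with pytest.raises(ValueError):
        ContingencyTable(0, 0, 0, 10)
    with pytest.raises(ValueError):
        ContingencyTable(-1, 10, 0, 10)
    with pytest.raises(TypeError):
        ContingencyTable(1.5, 10, 0, 10)
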