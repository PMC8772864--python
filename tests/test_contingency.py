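"""2×2 statistics: published values, algebraic invariants, exact-p oracle."""

from itertools import product
from math import comb

import pytest
from hypothesis import given, settings, strategies as st

from scfa_assoc.contingency import (ContingencyError, contingency_result,
                                    exact_p, odds_ratio, recover_table,
                                    woolf_ci, woolf_p)

# the two fully recoverable published tables:
# UC vs control x standard diet, and control vs IBD x high valeric acid
T_DIET = (16, 27, 11, 5)
T_VALERIC = (13, 3, 20, 41)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration
    (minimum-likelihood rule)."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    denom = comb(n, c1)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    probs = {x: comb(r1, x) * comb(n - r1, c1 - x) / denom
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12))


class TestPublishedValues:
    def test_diet_table(self):
        assert round(odds_ratio(*T_DIET), 3) == 0.269
        lo, hi = woolf_ci(*T_DIET)
        assert (round(lo, 3), round(hi, 3)) == (0.079, 0.917)
        assert round(exact_p(*T_DIET), 3) == 0.042

    def test_valeric_table(self):
        assert round(odds_ratio(*T_VALERIC), 3) == 8.883
        lo, hi = woolf_ci(*T_VALERIC)
        assert (round(lo, 3), round(hi, 3)) == (2.270, 34.766)
        assert round(exact_p(*T_VALERIC), 3) == 0.001

    def test_woolf_p_more_liberal_here(self):
        # the log-OR z-test gives 0.036 where the exact test gives 0.042
        assert round(woolf_p(*T_DIET), 3) == 0.036


class TestOddsRatioAlgebra:
    def test_null_table(self):
        assert odds_ratio(1, 1, 1, 1) == 1.0

    counts = st.integers(1, 30)

    @given(counts, counts, counts, counts)
    @settings(derandomize=True, max_examples=200)
    def test_inverse_product(self, a, b, c, d):
        assert odds_ratio(a, b, c, d) * odds_ratio(b, a, d, c) \
            == pytest.approx(1.0)

    @given(counts, counts, counts, counts)
    @settings(derandomize=True, max_examples=100)
    def test_double_swap_invariance(self, a, b, c, d):
        assert odds_ratio(a, b, c, d) == pytest.approx(odds_ratio(d, c, b, a))
        assert woolf_ci(a, b, c, d) == pytest.approx(woolf_ci(d, c, b, a))
        assert exact_p(a, b, c, d) == pytest.approx(exact_p(d, c, b, a))

    @given(counts, counts, counts, counts)
    @settings(derandomize=True, max_examples=100)
    def test_ci_contains_point_estimate(self, a, b, c, d):
        lo, hi = woolf_ci(a, b, c, d)
        assert lo < odds_ratio(a, b, c, d) < hi

    def test_symmetric_table_log_symmetric_ci(self):
        lo, hi = woolf_ci(7, 7, 7, 7)
        assert lo * hi == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(ContingencyError):
            odds_ratio(0, 0, 0, 0)

    def test_zero_cell_haldane_corrected(self):
        res = contingency_result(5, 0, 3, 4)
        assert res.corrected
        assert res.oddsratio == pytest.approx((5.5 * 4.5) / (0.5 * 3.5))

    def test_negative_rejected(self):
        with pytest.raises(ContingencyError):
            odds_ratio(-1, 2, 3, 4)


class TestExactP:
    def test_mode_table_p_one(self):
        assert exact_p(1, 1, 1, 1) == pytest.approx(1.0)

    def test_extreme_table(self):
        # margins (5,5,5,5): the two extreme tables each have
        # probability 1/C(10,5)
        assert exact_p(5, 0, 0, 5) == pytest.approx(2 / comb(10, 5))

    def test_exhaustive_small_tables_match_oracle(self):
        """Every 2x2 table with all margins positive and n <= 14 agrees
        with the hypergeometric enumeration oracle."""
        for n in range(4, 15):
            for a, b, c in product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                if min(a + b, c + d, a + c, b + d) == 0:
                    continue
                assert exact_p(a, b, c, d) == pytest.approx(
                    fisher_oracle(a, b, c, d), abs=1e-9), (a, b, c, d)

    @given(st.integers(0, 25), st.integers(0, 25), st.integers(0, 25),
           st.integers(0, 25))
    @settings(derandomize=True, max_examples=150)
    def test_random_tables_match_oracle(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        assert exact_p(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-9)

    def test_doubling_convention(self):
        # doubling doubles the smaller tail; never below min-likelihood
        for t in (T_DIET, T_VALERIC, (3, 7, 6, 2)):
            assert exact_p(*t, convention="doubling") >= exact_p(*t) - 1e-12
        assert exact_p(1, 1, 1, 1, convention="doubling") == 1.0

    def test_unknown_convention_rejected(self):
        with pytest.raises(ContingencyError):
            exact_p(1, 1, 1, 1, convention="mid_p")


class TestRecoverTable:
    def test_diet_table_unique(self):
        hits = recover_table((43, 16), 0.269, (0.079, 0.917))
        assert hits == [T_DIET]

    def test_valeric_table_unique(self):
        hits = recover_table((16, 61), 8.883, (2.270, 34.766))
        assert hits == [(13, 3, 20, 41)]

    def test_impossible_target_empty(self):
        assert recover_table((10, 10), 1e6, (1e5, 1e7)) == []

    @pytest.mark.parametrize("target_or,ci", [
        (4.181, (1.088, 16.063)),   # legume consumption
        (14.800, (2.950, 74.241)),  # alcohol consumption
    ])
    def test_known_nonrecoverable_tables(self, target_or, ci):
        """Two published ORs admit no integer table on the group margins —
        consistent with questionnaire item non-response."""
        assert recover_table((16, 61), target_or, ci) == []

    def test_bad_margins_rejected(self):
        with pytest.raises(ContingencyError):
            recover_table((0, 10), 1.0, (0.5, 2.0))


class TestContingencyResult:
    def test_bundles_consistent(self):
        res = contingency_result(*T_DIET)
        assert res.oddsratio == odds_ratio(*T_DIET)
        assert (res.ci_low, res.ci_high) == woolf_ci(*T_DIET)
        assert res.p == exact_p(*T_DIET)
        assert not res.corrected
        assert res.ci_low < res.oddsratio < res.ci_high
        assert 0 < res.p <= 1
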