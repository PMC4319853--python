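"""Normalization, Audic-Claverie test (against an exact-arithmetic
oracle), multiplicity adjustment and significance calls."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from peony_srna.diffexpr import (CountPair, ac_interval, ac_pvalue,
                                 adjust_pvalues, call_de, log2fc, tpm)
from peony_srna.synthetic_data import simulate_count_pairs


def exact_p_point(x, y, n1, n2):
    """Arbitrary-precision evaluation of the conditional probability
    p(y|x) = r^y (x+y)! / (x! y! (1+r)^(x+y+1)), r = N2/N1."""
    r = Fraction(n2, n1)
    return (r ** y * Fraction(math.factorial(x + y),
                              math.factorial(x) * math.factorial(y))
            / (1 + r) ** (x + y + 1))


class TestTPM:
    def test_definition(self):
        assert tpm(5, 1_000_000) == 5.0
        assert tpm(0, 1234) == 0.0

    def test_reported_library_scale(self):
        """The top conserved family member at the printed library size:
        384671 reads in 7655306 clean reads -> 50248.94 TPM."""
        assert tpm(384671, 7655306) == pytest.approx(50248.94, abs=0.5)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm(1, 0)


class TestLog2FC:
    def test_simple_ratio(self):
        assert log2fc(8, 2, 0.0) == pytest.approx(2.0)

    def test_identity_zero(self):
        assert log2fc(7.3, 7.3, 0.01) == 0.0

    def test_zero_guarded_by_pseudo(self):
        assert log2fc(0, 10, 0.01) == pytest.approx(math.log2(0.01 / 10.01))


class TestACPvalue:
    def test_zero_zero_equal_libraries(self):
        p, c, d, _ = ac_pvalue(CountPair("m", 0, 0, 100, 100))
        assert p == pytest.approx(0.5)
        assert c == pytest.approx(0.5)
        assert d == pytest.approx(1.0)

    def test_small_example_exact(self):
        p, *_ = ac_pvalue(CountPair("m", 2, 1, 500, 500))
        assert p == pytest.approx(3 / 16)

    @pytest.mark.parametrize("ratio", [(1, 2), (1, 1), (2, 1)])
    def test_matches_exact_oracle(self, ratio):
        n1, n2 = 1_000_000 * ratio[0], 1_000_000 * ratio[1]
        for x in (0, 1, 5, 40, 250):
            for y in (0, 3, 17, 120):
                p, *_ = ac_pvalue(CountPair("m", x, y, n1, n2))
                exact = float(exact_p_point(x, y, n1, n2))
                assert p == pytest.approx(exact, rel=1e-10)

    def test_distribution_normalizes(self):
        """Sum over all y of p(y|x) is 1 for every x and library ratio."""
        for n2 in (500_000, 1_000_000, 2_000_000):
            for x in (0, 3, 11, 20):
                pair0 = CountPair("m", x, 0, 1_000_000, n2)
                total, y = 0.0, 0
                while True:
                    p, *_ = ac_pvalue(CountPair("m", x, y, 1_000_000, n2))
                    total += p
                    if p < 1e-15 and y > x * max(1, n2 // 1_000_000):
                        break
                    y += 1
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_tails_are_complementary(self):
        p, c, d, _ = ac_pvalue(CountPair("m", 9, 23, 750_000, 1_250_000))
        assert c + d - p == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 300), st.integers(0, 300))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_library_swap_antisymmetry(self, x, y):
        """Swapping the libraries negates the fold-change exactly.  The
        conditional statistic itself is not symmetric in (x, y) — the
        swapped roles exchange which count is conditioned on — but its
        point masses obey the exact identity p(x|y; 1/r) = r p(y|x; r),
        and for decisive outcomes the light tail changes sides."""
        n1, n2 = 900_000, 1_100_000
        r = n2 / n1
        lfc1 = log2fc(tpm(y, n2), tpm(x, n1))
        lfc2 = log2fc(tpm(x, n1), tpm(y, n2))
        assert lfc1 == pytest.approx(-lfc2)
        p1, c1, d1, ptwo1 = ac_pvalue(CountPair("m", x, y, n1, n2))
        p2, c2, d2, _ = ac_pvalue(CountPair("m", y, x, n2, n1))
        assert p2 == pytest.approx(r * p1, rel=1e-9)
        if ptwo1 < 0.2:  # decisive: lower tail in one view, upper in the other
            assert (c1 <= d1) == (d2 <= c2)

    def test_interval_contains_bulk(self):
        y_min, y_max = ac_interval(100, 1_000_000, 1_000_000, epsilon=0.05)
        assert y_min < 100 < y_max


class TestAdjustment:
    def test_single_p_unchanged(self):
        assert adjust_pvalues([0.004]) == [pytest.approx(0.004)]

    def test_bh_hand_example(self):
        assert adjust_pvalues([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_all_ones_stay_one(self):
        assert adjust_pvalues([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]

    def test_adjusted_at_least_raw(self):
        raw = [0.001, 0.2, 0.04, 0.9]
        adj = adjust_pvalues(raw)
        assert all(a >= r for a, r in zip(adj, raw))


class TestCalls:
    def _results(self, x, y, n=1_000_000):
        return call_de([CountPair("m", x, y, n, n)])

    def test_strong_change_called_up(self):
        (r,) = self._results(100, 450)
        assert r.significant and r.direction == "up"

    def test_lfc_threshold_is_strict(self):
        """|log2fc| exactly 1 does not qualify (strictly greater than 1)."""
        (r,) = call_de([CountPair("m", 200_000, 400_000, 1_000_000, 1_000_000)],
                       pseudo=0.0)
        assert r.log2fc == pytest.approx(1.0)
        assert r.p_adjusted < 0.01
        assert not r.significant

    def test_null_pair_unchanged(self):
        (r,) = self._results(500, 500)
        assert not r.significant and r.direction == "unchanged"

    def test_calibration_under_poisson_null(self):
        """Two-sided p-values are conservative under the null: at most 6%
        fall below 0.05 (discreteness)."""
        pairs, _ = simulate_count_pairs(2000, 0, 0.0, seed=101,
                                        tpm_range=(10, 1000))
        results = call_de(pairs, adjust=False)
        frac = np.mean([r.p_two_sided < 0.05 for r in results])
        assert frac <= 0.06

    def test_planted_changes_recovered(self):
        """20 miRNAs planted at |log2fc| = 2 among 200 are nearly all
        flagged with at most 2 false positives."""
        pairs, de_ids = simulate_count_pairs(200, 20, 2.0, seed=7)
        results = call_de(pairs)
        flagged = {r.mirna_id for r in results if r.significant}
        assert len(flagged & de_ids) >= 18
        assert len(flagged - de_ids) <= 2
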