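"""The two-library exact test: conditional law, tails, FDR and DEG calls."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import nbinom

from tagdge import DegThresholds, ac_probability, ac_pvalue, bh_fdr, call_degs
from conftest import make_pair


def exact_pmf(x: int, y: int, total_a: int, total_b: int) -> Fraction:
    """Brute-force rational evaluation of the conditional law p(y | x)."""
    r = Fraction(total_b, total_a)
    return math.comb(x + y, y) * r**y / (1 + r) ** (x + y + 1)


class TestConditionalLaw:
    def test_zero_zero_equal_totals_is_half(self):
        assert ac_probability(0, 0, 10**6, 10**6) == pytest.approx(0.5, rel=1e-12)

    def test_small_count_closed_form(self):
        # C(6,1) / 2^7
        assert ac_probability(5, 1, 10**6, 10**6) == pytest.approx(6 / 128, rel=1e-12)

    @pytest.mark.parametrize("total_b", [10**5, 10**6, 9 * 10**6])
    @pytest.mark.parametrize("x", [0, 3, 17, 50])
    def test_normalisation(self, x, total_b):
        # sum over y of the conditional law is 1; the range is generous
        total_a = 10**6
        upper = 40 * (x + 2) * max(1, total_b // total_a) + 2000
        total = sum(ac_probability(x, y, total_a, total_b) for y in range(upper))
        assert total == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("totals", [(10**6, 10**6), (3 * 10**6, 10**6), (10**5, 7 * 10**5)])
    def test_matches_exact_rational_arithmetic(self, totals):
        for x in range(0, 31, 3):
            for y in range(0, 31 - x, 2):
                expected = float(exact_pmf(x, y, *totals))
                assert ac_probability(x, y, *totals) == pytest.approx(expected, rel=1e-10)

    def test_pmf_symmetric_in_counts_at_equal_totals(self):
        for x, y in [(0, 5), (12, 3), (40, 41)]:
            assert ac_probability(x, y, 10**6, 10**6) == pytest.approx(
                ac_probability(y, x, 10**6, 10**6), rel=1e-12
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ac_probability(-1, 0, 10, 10)
        with pytest.raises(ValueError):
            ac_pvalue(0, 0, 0, 10)


class TestPValue:
    def test_equal_counts_equal_totals_give_one(self):
        for x in (0, 7, 123):
            assert ac_pvalue(x, x, 5 * 10**5, 5 * 10**5) == pytest.approx(1.0, rel=1e-12)

    def test_closed_form_tail(self):
        # P(Y >= 10 | x=0) at equal totals is 2^-10; doubled gives 2^-9
        assert ac_pvalue(0, 10, 10**6, 10**6) == pytest.approx(2.0**-9, rel=1e-12)

    def test_matches_negative_binomial_tails(self):
        # independent route: Y | x is NB(x+1, N1/(N1+N2))
        for total_a, total_b in [(10**6, 10**6), (2 * 10**6, 10**6), (10**6, 5 * 10**6)]:
            pr = total_a / (total_a + total_b)
            for x in (0, 4, 40, 130):
                for y in (0, 4, 40, 130):
                    lower = nbinom.cdf(y, x + 1, pr)
                    upper = nbinom.sf(y - 1, x + 1, pr)
                    expected = min(1.0, 2.0 * min(lower, upper))
                    assert ac_pvalue(x, y, total_a, total_b) == pytest.approx(
                        expected, rel=1e-9
                    ), (x, y, total_a, total_b)

    def test_upper_tail_monotone_in_y(self):
        # larger observed y can only be more extreme on the upper side
        x, totals = 20, (10**6, 10**6)
        upper_tails = []
        for y in range(30, 80, 5):
            lower = sum(float(exact_pmf(x, k, *totals)) for k in range(y))
            upper_tails.append(1.0 - lower)
        assert all(a >= b for a, b in zip(upper_tails, upper_tails[1:]))
        pvals = [ac_pvalue(x, y, *totals) for y in range(30, 80, 5)]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_swap_asymmetry_vanishes_at_large_counts(self):
        # the conditional-on-x law is not swap-symmetric at small counts,
        # but the two orientations converge as counts grow
        ratios = []
        for x, y in [(25, 40), (100, 130), (2500, 2650), (10000, 10300)]:
            a = ac_pvalue(x, y, 10**6, 10**6)
            b = ac_pvalue(y, x, 10**6, 10**6)
            ratios.append(max(a, b) / min(a, b))
        assert ratios[-1] < ratios[0]
        assert ratios[-1] == pytest.approx(1.0, rel=0.05)


class TestBhFdr:
    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        # p_(i) * n / i, then cumulative minimum from the largest
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert bh_fdr([0.001, 0.01, 0.1, 0.9]) == pytest.approx([0.004, 0.02, 4 / 30, 0.9])

    def test_all_ones_stay_ones(self):
        assert bh_fdr([1.0] * 5) == pytest.approx([1.0] * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_values_monotone_in_bh_order(self, p_values):
        adjusted = bh_fdr(p_values)
        order = np.argsort(p_values, kind="stable")
        ranked = np.asarray(adjusted)[order]
        assert np.all(np.diff(ranked) >= -1e-12)
        assert np.all((ranked >= 0) & (ranked <= 1))


class TestCallDegs:
    def test_identical_libraries_call_nothing(self):
        pair = make_pair([(f"g{i}", 1000, 10 * i + 5, 10 * i + 5) for i in range(20)])
        records = call_degs(pair)
        assert all(r.status == "ns" for r in records)
        assert all(r.p_value == pytest.approx(1.0, rel=1e-9) for r in records)

    def test_planted_extreme_gene_called_up(self):
        rows = [("hit", 1000, 0, 1000)] + [(f"null{i}", 1000, 1000, 1000) for i in range(999)]
        pair = make_pair(rows)
        by_id = {r.gene_id: r for r in call_degs(pair)}
        assert by_id["hit"].status == "up"
        assert by_id["hit"].log2_ratio == math.inf
        assert by_id["hit"].fdr < 1e-100

    def test_ratio_gate_blocks_significant_but_small_changes(self):
        # 12000 vs 10000 tags: wildly significant, |log2 ratio| ~ 0.26
        rows = [("shift", 100, 12000, 10000)] + [(f"null{i}", 100, 500, 500) for i in range(99)]
        by_id = {r.gene_id: r for r in call_degs(make_pair(rows))}
        assert by_id["shift"].fdr < 1e-6
        assert by_id["shift"].status == "ns"

    def test_zero_zero_gene_excluded_from_family(self):
        rows = [("dead", 1000, 0, 0), ("live", 1000, 30, 80)]
        by_id = {r.gene_id: r for r in call_degs(make_pair(rows))}
        assert by_id["dead"].status == "ns"
        assert by_id["dead"].p_value == 1.0 and by_id["dead"].fdr == 1.0
        # the live gene's FDR equals its own p-value: family size 1
        assert by_id["live"].fdr == pytest.approx(by_id["live"].p_value)

    def test_swapping_libraries_maps_up_to_down(self):
        rows = [("a", 1000, 10, 600), ("b", 1000, 700, 15)] + [
            (f"null{i}", 1000, 200, 200) for i in range(50)
        ]
        forward = {r.gene_id: r.status for r in call_degs(make_pair(rows))}
        swapped_rows = [(g, L, cb, ca) for g, L, ca, cb in rows]
        backward = {r.gene_id: r.status for r in call_degs(make_pair(swapped_rows))}
        assert forward["a"] == "up" and backward["a"] == "down"
        assert forward["b"] == "down" and backward["b"] == "up"

    def test_custom_thresholds_respected(self):
        rows = [("mild", 1000, 100, 190)] + [(f"null{i}", 1000, 150, 150) for i in range(30)]
        loose = {r.gene_id: r for r in call_degs(make_pair(rows), DegThresholds(0.05, 0.5))}
        strict = {r.gene_id: r for r in call_degs(make_pair(rows), DegThresholds(1e-6, 2.0))}
        assert loose["mild"].status == "up"
        assert strict["mild"].status == "ns"
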