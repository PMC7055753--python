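"""Agreement statistics: hand-checked values, oracles, and identities."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vitalval import (
    absolute_difference_summary,
    bland_altman,
    correlation,
    percent_difference_summary,
    rmse,
    signed_diff_vs_reference,
    summarize_pairs,
)
from vitalval.errors import EmptyInputError
from vitalval.stats import spearman_coefficient
from vitalval.vitals import Vital

finite_diffs = st.lists(
    st.floats(min_value=-50, max_value=50, allow_nan=False), min_size=2, max_size=40
)


class TestAbsoluteDifference:
    def test_hand_arithmetic(self):
        s = absolute_difference_summary([-5, 2, 1])
        assert s.n == 3
        assert s.mad == pytest.approx(8 / 3)
        assert s.sd == pytest.approx(np.std([5, 2, 1], ddof=1))

    def test_all_zero(self):
        s = absolute_difference_summary([0.0] * 5)
        assert (s.mad, s.sd, s.n) == (0.0, 0.0, 5)

    def test_single_pair_has_undefined_sd(self):
        assert absolute_difference_summary([3.0]).sd is None

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            absolute_difference_summary([])


class TestPercentDifference:
    def test_single_pair(self):
        s = percent_difference_summary([-10.0], [100.0])
        assert s.mean == pytest.approx(10.0)

    def test_identical_values_give_zero(self):
        assert percent_difference_summary([0.0, 0.0], [90.0, 110.0]).mean == 0.0

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            percent_difference_summary([1.0], [0.0])

    def test_folded_normal_oracle(self):
        # d ~ N(0, sigma) with constant reference R: mean |d|/R -> sigma*sqrt(2/pi)/R.
        rng = np.random.default_rng(4)
        sigma, R = 6.0, 120.0
        d = rng.normal(0, sigma, 100_000)
        s = percent_difference_summary(d, np.full_like(d, R))
        assert s.mean == pytest.approx(100 * sigma * math.sqrt(2 / math.pi) / R, rel=0.02)


class TestRmse:
    def test_hand_arithmetic(self):
        assert rmse([3, -4]) == pytest.approx(math.sqrt(12.5))

    def test_all_zero(self):
        assert rmse([0.0] * 4) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            rmse([])


class TestBlandAltman:
    def test_symmetric_two_point_example(self):
        ba = bland_altman([95, 105], [100, 100])
        assert ba.mean_signed_diff == 0.0
        assert ba.sd_used == pytest.approx(math.sqrt(50))
        assert ba.loa_high == pytest.approx(1.96 * math.sqrt(50))
        assert ba.loa_low == pytest.approx(-ba.loa_high)

    def test_constant_difference_collapses_limits(self):
        ba = bland_altman([103, 113, 123], [100, 110, 120])
        assert ba.loa_low == ba.loa_high == ba.mean_signed_diff == 3.0

    def test_absolute_sd_variant_differs_for_mixed_signs(self):
        inv, ref = [95, 105, 98, 107], [100, 100, 100, 100]
        signed = bland_altman(inv, ref)
        absolute = bland_altman(inv, ref, absolute_sd=True)
        assert absolute.sd_used == pytest.approx(np.std(np.abs(np.array(inv) - 100), ddof=1))
        assert absolute.sd_used != signed.sd_used

    def test_coverage_near_95_percent(self):
        rng = np.random.default_rng(8)
        ref = rng.normal(120, 10, 20_000)
        inv = ref + rng.normal(2, 5, ref.size)
        ba = bland_altman(inv, ref)
        inside = np.mean((ba.diffs >= ba.loa_low) & (ba.diffs <= ba.loa_high))
        assert 0.94 < inside < 0.96


class TestCorrelationGating:
    def test_exact_line_gives_coefficient_one(self):
        ref = np.array([100.0, 110.0, 120.0, 130.0, 140.0])
        res = correlation(2 * ref - 50, ref)
        assert res.coefficient == pytest.approx(1.0)

    def test_constant_reference_is_undefined(self):
        res = correlation([100, 101, 102, 103], [120, 120, 120, 120])
        assert res.coefficient is None and "zero variance" in res.reason

    def test_gaussian_residuals_select_pearson(self):
        rng = np.random.default_rng(15)
        ref = rng.normal(120, 15, 100)
        inv = ref + rng.normal(0, 5, 100)
        assert correlation(inv, ref).method == "pearson"

    def test_heavy_tailed_residuals_select_spearman(self):
        rng = np.random.default_rng(16)
        ref = rng.normal(120, 15, 100)
        inv = ref + 3 * rng.standard_cauchy(100)
        assert correlation(inv, ref).method == "spearman"

    def test_spearman_matches_midrank_brute_force_with_ties(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            x = rng.integers(0, 5, size=8).astype(float)
            y = rng.integers(0, 5, size=8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            # Brute-force midranks, then Pearson on the ranks.
            def midrank(a):
                order = np.argsort(a, kind="stable")
                ranks = np.empty(len(a))
                i = 0
                sorted_a = a[order]
                while i < len(a):
                    j = i
                    while j < len(a) and sorted_a[j] == sorted_a[i]:
                        j += 1
                    ranks[order[i:j]] = (i + j + 1) / 2
                    i = j
                return ranks

            rx, ry = midrank(x), midrank(y)
            expected = np.corrcoef(rx, ry)[0, 1]
            assert spearman_coefficient(x, y) == pytest.approx(expected, abs=1e-12)


class TestProportionalBias:
    def test_slope_below_one_gives_minus_one(self):
        ref = np.array([100.0, 110.0, 120.0, 130.0, 140.0])
        inv = 0.5 * ref + 60  # crosses the identity at 120
        res = signed_diff_vs_reference(inv, ref)
        assert res.coefficient == pytest.approx(-1.0)

    def test_constant_offset_is_undefined(self):
        ref = np.array([100.0, 110.0, 120.0, 130.0])
        res = signed_diff_vs_reference(ref + 5, ref)
        assert res.coefficient is None


class TestIdentities:
    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(finite_diffs)
    def test_rmse_decomposition_and_jensen(self, diffs):
        d = np.asarray(diffs)
        r = rmse(d)
        mean = d.mean()
        var = np.var(d, ddof=1)
        assert r**2 == pytest.approx(mean**2 + (len(d) - 1) / len(d) * var, abs=1e-9)
        assert absolute_difference_summary(d).mad <= r + 1e-12

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(finite_diffs)
    def test_limits_symmetric_and_reorder_invariant(self, diffs):
        ref = np.full(len(diffs), 100.0)
        inv = ref + np.asarray(diffs)
        ba = bland_altman(inv, ref)
        assert (ba.loa_high - ba.mean_signed_diff) == pytest.approx(
            ba.mean_signed_diff - ba.loa_low, abs=1e-9
        )
        perm = np.random.default_rng(0).permutation(len(diffs))
        s1 = summarize_pairs("d", Vital.SBP, inv, ref)
        s2 = summarize_pairs("d", Vital.SBP, inv[perm], ref[perm])
        for attr in ("mad", "rmse", "mean_signed_diff", "loa_low", "loa_high"):
            assert getattr(s1, attr) == pytest.approx(getattr(s2, attr), abs=1e-9)
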