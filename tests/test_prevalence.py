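"""Wilson intervals, count pooling, origin extrapolation, 1-in-N framing."""

import math
import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from dup15q._rounding import round_sig
from dup15q.cohort_io import CohortClass, Origin, StudyRecord
from dup15q.prevalence import (
    EmptySelectionError,
    OriginUnavailableError,
    ProportionEstimate,
    as_one_in_n,
    class_origin_ratio,
    extrapolate_origin_split,
    extrapolated_class_prevalence,
    pool_prevalence,
    wilson_interval,
)


def score_inversion_bounds(successes, trials, z=1.96):
    """Independent oracle: solve |p_hat - p| = z*sqrt(p(1-p)/n) by bisection."""
    phat = successes / trials

    def f(p):
        return (phat - p) ** 2 - z * z * p * (1.0 - p) / trials

    low = 0.0 if successes == 0 else brentq(f, 1e-18, phat, xtol=1e-16, rtol=1e-15)
    high = 1.0 if successes == trials else brentq(f, phat, 1 - 1e-18, xtol=1e-16, rtol=1e-15)
    return low, high


class TestWilsonInterval:
    @pytest.mark.parametrize(
        "k, n, low_2sf, high_2sf",
        [
            (24, 28_138, 0.057, 0.13),  # pooled maternal SZ prevalence
            (4, 149_780, 0.001, 0.0069),  # pooled control prevalence
            (1, 28_138, 0.00063, 0.02),  # single paternal SZ carrier
        ],
    )
    def test_published_cohort_bounds(self, k, n, low_2sf, high_2sf):
        low, high = wilson_interval(k, n)
        assert round_sig(100 * low, 2) == pytest.approx(low_2sf)
        assert round_sig(100 * high, 2) == pytest.approx(high_2sf)

    def test_zero_numerator_low_is_exactly_zero(self):
        low, high = wilson_interval(0, 1000)
        assert low == 0.0 and 0 < high < 1

    def test_full_numerator_high_is_exactly_one(self):
        low, high = wilson_interval(50, 50)
        assert high == 1.0 and 0 < low < 1

    def test_matches_score_inversion_oracle(self):
        rng = random.Random(20160506)
        for _ in range(200):
            n = rng.randint(1, 10**6)
            k = rng.randint(0, n)
            low, high = wilson_interval(k, n)
            olow, ohigh = score_inversion_bounds(k, n)
            assert low == pytest.approx(olow, abs=1e-10)
            assert high == pytest.approx(ohigh, abs=1e-10)

    def test_fractional_successes_accepted(self):
        low, high = wilson_interval(44 + 1 / 6, 51_001)
        assert 0 < low < (44 + 1 / 6) / 51_001 < high < 1

    @pytest.mark.parametrize("k, n", [(5, 4), (1, 0), (-1, 10)])
    def test_domain_errors(self, k, n):
        with pytest.raises(ValueError):
            wilson_interval(k, n)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        phat=st.floats(0.0001, 0.9999),
        n=st.integers(2, 10**7),
        scale=st.integers(2, 50),
    )
    def test_bracketing_and_width_monotonicity(self, phat, n, scale):
        """Bounds bracket the point in [0,1]; width shrinks as n grows at fixed p_hat."""
        k = phat * n
        low, high = wilson_interval(k, n)
        assert 0.0 <= low <= phat <= high <= 1.0
        low2, high2 = wilson_interval(k * scale, n * scale)
        assert high2 - low2 < high - low


class TestPooling:
    def test_sz_maternal_pool(self, table1):
        est = pool_prevalence(table1, CohortClass.SZ, Origin.MATERNAL)
        assert (est.numerator, est.denominator) == (24, 28_138)
        assert round_sig(100 * est.point, 2) == pytest.approx(0.085)

    def test_control_paternal_pool(self, table1):
        est = pool_prevalence(table1, CohortClass.CONTROL, Origin.PATERNAL)
        assert (est.numerator, est.denominator) == (4, 149_780)
        assert round_sig(100 * est.point, 2) == pytest.approx(0.0027)

    def test_any_origin_includes_untyped(self, table1):
        est = pool_prevalence(table1, CohortClass.DD_ASD_MCA, Origin.ANY)
        assert (est.numerator, est.denominator) == (53, 51_001)

    def test_order_invariance_and_singleton(self, table1):
        shuffled = list(table1)
        random.Random(7).shuffle(shuffled)
        assert pool_prevalence(shuffled, CohortClass.SZ, Origin.MATERNAL) == \
            pool_prevalence(table1, CohortClass.SZ, Origin.MATERNAL)
        single = [StudyRecord("only", CohortClass.SZ, 0, 0, 0, 400, True)]
        est = pool_prevalence(single, CohortClass.SZ, Origin.ANY)
        assert est.point == 0 and est.ci_low == 0

    def test_no_usable_records_error(self):
        recs = [StudyRecord("r", CohortClass.DD_ASD_MCA, 2, 1, 0, None, False)]
        with pytest.raises(EmptySelectionError):
            pool_prevalence(recs, CohortClass.DD_ASD_MCA)

    def test_all_untyped_origin_error(self):
        recs = [StudyRecord("r", CohortClass.DD_ASD_MCA, 0, 0, 5, 1000, True)]
        with pytest.raises(OriginUnavailableError):
            pool_prevalence(recs, CohortClass.DD_ASD_MCA, Origin.MATERNAL)


class TestOriginSplit:
    def test_published_dd_split(self):
        split = extrapolate_origin_split(53, 50, 10)
        assert split.extrapolated_maternal == pytest.approx(44.1667, abs=1e-4)
        assert split.extrapolated_paternal == pytest.approx(8.8333, abs=1e-4)

    def test_single_origin(self):
        split = extrapolate_origin_split(10, 7, 0)
        assert (split.extrapolated_maternal, split.extrapolated_paternal) == (10, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        total=st.integers(0, 10**4),
        km=st.integers(0, 100),
        kp=st.integers(0, 100),
    )
    def test_proportionality_and_scale_equivariance(self, total, km, kp):
        if km + kp == 0:
            with pytest.raises(ZeroDivisionError):
                extrapolate_origin_split(total, km, kp)
            return
        split = extrapolate_origin_split(total, km, kp)
        assert split.extrapolated_maternal + split.extrapolated_paternal == pytest.approx(
            total, abs=1e-9
        )
        assert split.extrapolated_maternal * kp == pytest.approx(
            split.extrapolated_paternal * km, abs=1e-6
        )
        doubled = extrapolate_origin_split(2 * total, km, kp)
        assert doubled.extrapolated_maternal == pytest.approx(
            2 * split.extrapolated_maternal
        )

    def test_class_prevalence_matches_published_extrapolation(self, table1):
        m = extrapolated_class_prevalence(table1, CohortClass.DD_ASD_MCA, Origin.MATERNAL)
        p = extrapolated_class_prevalence(table1, CohortClass.DD_ASD_MCA, Origin.PATERNAL)
        assert round_sig(100 * m.point, 2) == pytest.approx(0.087)
        assert round_sig(100 * p.point, 2) == pytest.approx(0.017)
        # fully origin-typed classes reduce to the raw pool
        sz = extrapolated_class_prevalence(table1, CohortClass.SZ, Origin.MATERNAL)
        assert sz == pool_prevalence(table1, CohortClass.SZ, Origin.MATERNAL)

    def test_ratio_includes_ratio_only_studies(self, table1):
        assert class_origin_ratio(table1, CohortClass.DD_ASD_MCA) == (50, 10)


class TestOneInN:
    def test_published_sz_framing(self):
        est = ProportionEstimate.from_counts(24, 28_138)
        # at two significant figures the prevalence is 0.085% = 0.00085
        framed = as_one_in_n(
            ProportionEstimate(24, 28_138, 0.00085, 0.00057, 0.0013)
        )
        assert round(framed.point) == 1176
        assert round(framed.low) == 769
        assert round(framed.high) == 1754
        assert framed.low < framed.point < framed.high
        # full-precision framing stays in the same ballpark
        assert round(as_one_in_n(est).point) == 1172

    def test_simple_half(self):
        est = ProportionEstimate(1, 2, 0.5, 0.2, 0.8)
        assert as_one_in_n(est).point == pytest.approx(2.0)

    def test_zero_point_undefined(self):
        est = ProportionEstimate(0, 100, 0.0, 0.0, 0.05)
        with pytest.raises(ZeroDivisionError):
            as_one_in_n(est)
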