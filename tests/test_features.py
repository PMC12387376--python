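"""Feature computations: SampEn vs oracle, MSE behavior, cycle/amplitude math."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_sampen_counts
from respcomplex.breaths import BreathSeries
from respcomplex.features import (
    MSECurve,
    amplitude_features,
    coarse_grain,
    cycle_features,
    mse_curve,
    mse_summary,
    sample_entropy,
)


def _series_from(bbi=None, ra=None, ti=None, te=None):
    n = len(bbi if bbi is not None else ra)
    bbi = np.full(n, 3.0) if bbi is None else np.asarray(bbi, float)
    te = bbi * 0.6 if te is None else np.asarray(te, float)
    ti = bbi - te if ti is None else np.asarray(ti, float)
    ra = np.ones(n) if ra is None else np.asarray(ra, float)
    starts = np.concatenate([[0.0], np.cumsum(bbi)[:-1]])
    return BreathSeries(
        pd.DataFrame(
            {
                "t_valley_start": starts,
                "t_peak": starts + ti,
                "t_valley_end": starts + bbi,
                "TI": ti,
                "TE": te,
                "BBI": bbi,
                "RA": ra,
                "TE_ratio": te / bbi,
                "segment_id": 0,
            }
        )
    )


class TestCoarseGrain:
    def test_block_means(self):
        assert np.array_equal(coarse_grain(np.array([1, 3, 5, 7]), 2), [2, 6])

    def test_identity_at_scale_one(self):
        x = np.arange(7.0)
        assert np.array_equal(coarse_grain(x, 1), x)

    def test_remainder_discarded(self):
        assert np.array_equal(
            coarse_grain(np.array([1, 2, 3, 4, 5]), 2), [1.5, 3.5]
        )

    def test_tau_larger_than_series_gives_empty(self):
        assert coarse_grain(np.arange(3.0), 5).size == 0


class TestSampleEntropy:
    def test_constant_series_has_zero_entropy(self):
        res = sample_entropy(np.full(50, 3.7), m=2, r=0.2)
        assert res.defined and res.value == pytest.approx(0.0)
        assert res.a == res.b  # every m-match extends

    def test_perfect_alternation_has_zero_entropy(self):
        res = sample_entropy(np.array([1, 2, 1, 2, 1, 2, 1, 2], float), 2, 0.1)
        assert res.defined
        assert (res.a, res.b) == (6, 6)
        assert res.value == pytest.approx(0.0)

    def test_too_short_series_flagged_undefined(self):
        res = sample_entropy(np.array([1.0, 2.0, 3.0]), m=2, r=0.5)
        assert not res.defined and math.isnan(res.value)

    def test_no_extending_matches_flagged_undefined(self):
        x = np.array([0, 0, 1, 0, 0, 2, 0, 0, 3], float)
        res = sample_entropy(x, m=2, r=0.1)
        assert res.b > 0 and res.a == 0
        assert not res.defined

    @pytest.mark.parametrize("m", [1, 2, 3])
    @pytest.mark.parametrize("r_frac", [0.1, 0.2, 0.5])
    def test_counts_match_bruteforce_oracle(self, m, r_frac):
        rng = np.random.default_rng(17 * m + int(r_frac * 10))
        for _ in range(10):
            n = int(rng.integers(20, 200))
            x = rng.standard_normal(n)
            r = r_frac * np.std(x, ddof=1)
            res = sample_entropy(x, m=m, r=r)
            a, b = brute_force_sampen_counts(x, m, r)
            assert (res.a, res.b) == (a, b)

    def test_white_noise_analytic_limit(self):
        # iid Gaussian: SampEn -> -ln P(|X-Y| <= r) with r = 0.2 sigma
        expected = -math.log(2 * scipy.stats.norm.cdf(0.2 / math.sqrt(2)) - 1)
        for seed in (0, 1):
            x = np.random.default_rng(seed).standard_normal(10_000)
            res = sample_entropy(x, m=2, r=0.2 * np.std(x, ddof=1))
            assert res.value == pytest.approx(expected, abs=0.1)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_nonincreasing_in_tolerance(self, seed):
        # holds once match counts are stable; at single-digit counts the
        # conditional probability A/B is too noisy to be monotone
        x = np.random.default_rng(seed).standard_normal(500)
        sd = np.std(x, ddof=1)
        vals = [
            sample_entropy(x, 2, f * sd).value
            for f in (0.15, 0.2, 0.3, 0.5, 0.8)
        ]
        vals = [v for v in vals if not math.isnan(v)]
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_time_reversal_invariance(self, seed):
        # the (m+1)-template set is reversal-closed, so A is exactly
        # invariant; B uses the first N-m of the N-m+1 m-templates, so
        # reversal can shift it by the matches of one boundary template
        x = np.random.default_rng(seed).standard_normal(200)
        r = 0.25 * np.std(x, ddof=1)
        fwd = sample_entropy(x, 2, r)
        rev = sample_entropy(x[::-1], 2, r)
        assert fwd.a == rev.a
        assert abs(fwd.b - rev.b) <= len(x) - 3
        if fwd.defined and rev.defined:
            assert fwd.value == pytest.approx(rev.value, abs=0.15)


class TestMSECurve:
    def test_constant_series_is_zero_at_every_scale(self):
        curve = mse_curve(np.full(400, 2.0), scales=range(1, 21))
        assert np.allclose(curve.sampen[curve.defined], 0.0)

    def test_scale_one_equals_sample_entropy(self):
        x = np.random.default_rng(3).standard_normal(500)
        curve = mse_curve(x)
        direct = sample_entropy(x, 2, 0.2 * np.std(x, ddof=1))
        assert curve.value_at(1) == pytest.approx(direct.value)

    def test_white_noise_curve_decreases_with_scale(self):
        x = np.random.default_rng(5).standard_normal(6000)
        curve = mse_curve(x, scales=range(1, 11))
        vals = curve.sampen
        assert curve.defined.all()
        assert np.all(np.diff(vals) < 0)

    def test_scale_invariance_under_positive_rescaling(self):
        x = np.random.default_rng(8).standard_normal(300)
        c1 = mse_curve(x, scales=range(1, 11))
        c2 = mse_curve(1000.0 * x, scales=range(1, 11))
        assert np.allclose(c1.sampen, c2.sampen, equal_nan=True)

    def test_short_series_flagged_low_confidence(self):
        curve = mse_curve(np.random.default_rng(0).standard_normal(50))
        assert curve.low_confidence
        assert (curve.n_effective == [50 // tau for tau in range(1, 21)]).all()


class TestMSESummary:
    def _curve(self, values):
        scales = np.arange(1, 21)
        vals = np.asarray(values, float)
        return MSECurve(
            "BBI", scales, vals, ~np.isnan(vals), 2, 0.2, 400 // scales
        )

    def test_constant_curve_areas_and_slope(self):
        c = 1.3
        s = mse_summary(self._curve(np.full(20, c)))
        assert s.area_1_5 == pytest.approx(4 * c)
        assert s.area_6_20 == pytest.approx(14 * c)
        assert s.slope_1_5 == pytest.approx(0.0, abs=1e-12)

    def test_linear_curve(self):
        s = mse_summary(self._curve(np.arange(1, 21, dtype=float)))
        assert s.slope_1_5 == pytest.approx(1.0)
        assert s.area_1_5 == pytest.approx(12.0)

    def test_undefined_scale_propagates(self):
        vals = np.full(20, 1.0)
        vals[2] = np.nan
        s = mse_summary(self._curve(vals))
        assert math.isnan(s.area_1_5) and math.isnan(s.slope_1_5)
        assert s.area_6_20 == pytest.approx(14.0)

    def test_sum_quadrature_option(self):
        s = mse_summary(self._curve(np.full(20, 2.0)), quadrature="sum")
        assert s.area_1_5 == pytest.approx(10.0)
        assert s.area_6_20 == pytest.approx(30.0)


class TestCycleFeatures:
    def test_identical_breaths_have_zero_cv(self):
        f = cycle_features(_series_from(bbi=np.full(10, 3.0)))
        assert f.mean_BR == pytest.approx(20.0)
        assert f.BR_cv == pytest.approx(0.0)
        assert f.mean_TE_ratio == pytest.approx(60.0)
        assert f.TE_ratio_cv == pytest.approx(0.0)

    def test_mean_rate_is_mean_of_per_breath_rates(self):
        f = cycle_features(_series_from(bbi=[2.0, 4.0]))
        assert f.mean_BR == pytest.approx(22.5)  # (30 + 15) / 2

    def test_cv_uses_sample_standard_deviation(self):
        f = cycle_features(_series_from(bbi=[3.0, 3.0, 3.0], ti=[1.0, 2.0, 3.0]))
        assert f.TI_cv == pytest.approx(50.0)

    def test_single_breath_rejected(self):
        with pytest.raises(ValueError, match="2 breaths"):
            cycle_features(_series_from(bbi=[3.0]))


class TestAmplitudeFeatures:
    def test_identical_breaths_have_zero_variability(self):
        f = amplitude_features(_series_from(bbi=np.full(6, 3.0)))
        assert f.RA_cv == pytest.approx(0.0)
        assert f.R_RSBI_cv == pytest.approx(0.0)
        assert f.RII == pytest.approx(0.0)

    def test_rii_linear_interpolation_quartiles(self):
        # RA/BBI values {1,2,3,4}: Q3=3.25, Q1=1.75 -> IQR 1.5
        f = amplitude_features(
            _series_from(bbi=np.ones(4), ra=[1.0, 2.0, 3.0, 4.0])
        )
        assert f.RII == pytest.approx(1.5)

    def test_scaling_equivariance(self):
        ra = np.array([0.8, 1.1, 0.9, 1.4, 1.0])
        f1 = amplitude_features(_series_from(bbi=np.full(5, 3.0), ra=ra))
        f2 = amplitude_features(_series_from(bbi=np.full(5, 3.0), ra=2 * ra))
        assert f2.RA_cv == pytest.approx(f1.RA_cv)
        assert f2.RII == pytest.approx(2 * f1.RII)

    def test_too_few_breaths_rejected(self):
        with pytest.raises(ValueError, match="4 breaths"):
            amplitude_features(_series_from(bbi=np.full(3, 3.0)))
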