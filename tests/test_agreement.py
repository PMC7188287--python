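"""Tests for the paired-agreement statistics battery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gfrcompare import (
    PairedSample,
    bias,
    bland_altman_data,
    ccc,
    ccc_band,
    compute_agreement,
    deming,
    limits_of_agreement,
    p30,
    precision_sd,
    rmse_log,
    tdi,
)


def sample_from_diffs(diffs, base=200.0):
    m = np.full(len(diffs), base)
    return PairedSample(m + np.asarray(diffs, dtype=float), m)


def type7_quantile(values, q):
    """Independent order-statistic oracle: linear interpolation rule."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = math.floor(h)
    return v[lo] + (h - lo) * (v[min(lo + 1, len(v) - 1)] - v[lo])


class TestBiasAndPrecision:
    def test_bias_examples(self):
        assert bias(sample_from_diffs([0, 0, 0])) == 0.0
        assert bias(sample_from_diffs([5, 5, 5])) == pytest.approx(5.0)
        assert bias(sample_from_diffs([-2, 0, 8])) == pytest.approx(2.0)

    def test_sd_examples(self):
        assert precision_sd(sample_from_diffs([3, 3, 3])) == 0.0
        assert precision_sd(sample_from_diffs([-1, 1])) == pytest.approx(math.sqrt(2))
        # translation invariance
        assert precision_sd(sample_from_diffs([-1 + 7, 1 + 7])) == pytest.approx(math.sqrt(2))


class TestLimitsOfAgreement:
    def test_empirical_matches_order_statistic_oracle(self):
        diffs = np.arange(1.0, 101.0)
        lo, hi = limits_of_agreement(sample_from_diffs(diffs))
        assert lo == pytest.approx(type7_quantile(diffs, 0.025), rel=1e-12)
        assert hi == pytest.approx(type7_quantile(diffs, 0.975), rel=1e-12)

    def test_parametric_symmetric_around_bias(self):
        diffs = np.array([-4.0, -2.0, 0.0, 2.0, 4.0, -3.0, 3.0, 1.0, -1.0, 0.0])
        s = sample_from_diffs(diffs)
        lo, hi = limits_of_agreement(s, mode="parametric")
        b = bias(s)
        assert hi - b == pytest.approx(b - lo)
        assert lo <= b <= hi

    def test_constant_differences_collapse(self):
        s = sample_from_diffs([2.0] * 12)
        assert limits_of_agreement(s) == (2.0, 2.0)
        assert limits_of_agreement(s, mode="parametric") == (2.0, 2.0)

    def test_small_sample_rejected_in_empirical_mode(self):
        with pytest.raises(ValueError):
            limits_of_agreement(sample_from_diffs([1, 2, 3]))


class TestP30:
    def test_perfect_and_all_outside(self):
        m = np.array([40.0, 50.0, 60.0])
        assert p30(PairedSample(m, m)) == 100.0
        assert p30(PairedSample(1.31 * m, m)) == 0.0

    def test_boundary_counts_as_within(self):
        # bounds at mGFR 50 are [35, 65]; 35, 36 and 65 are within
        # (boundary inclusive), 66 is outside -> 3/4
        m = np.array([50.0, 50.0, 50.0, 50.0])
        e = np.array([35.0, 36.0, 65.0, 66.0])
        assert p30(PairedSample(e, m)) == pytest.approx(75.0)


class TestRmseLog:
    def test_exact_power_law_gives_zero(self):
        m = np.array([20.0, 35.0, 48.0, 60.0, 90.0])
        e = 1.3 * m**0.8
        assert rmse_log(PairedSample(e, m)) == pytest.approx(0.0, abs=1e-12)

    def test_matches_closed_form_ols_oracle(self, rng):
        m = rng.uniform(15, 100, 5)
        e = m * np.exp(rng.normal(0, 0.2, 5))
        x, y = np.log10(m), np.log10(e)
        sl = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        resid = y - y.mean() - sl * (x - x.mean())
        assert rmse_log(PairedSample(e, m)) == pytest.approx(
            math.sqrt(np.mean(resid**2)), rel=1e-10
        )

    def test_invariant_to_multiplicative_rescale_of_estimates(self, rng):
        m = rng.uniform(15, 100, 30)
        e = m * np.exp(rng.normal(0, 0.2, 30))
        assert rmse_log(PairedSample(3.7 * e, m)) == pytest.approx(
            rmse_log(PairedSample(e, m)), rel=1e-10
        )


class TestTdi:
    def test_perfect_agreement_is_zero(self):
        m = np.linspace(20, 90, 12)
        assert tdi(PairedSample(m, m)) == pytest.approx(0.0, abs=1e-10)

    def test_relative_convention_matches_quantile_oracle(self):
        m = np.full(100, 100.0)
        e = m * (1 + np.arange(1.0, 101.0) / 100.0)
        got = tdi(PairedSample(e, m), coverage=0.90, convention="relative")
        assert got == pytest.approx(type7_quantile(np.arange(1.0, 101.0), 0.90), rel=1e-12)

    def test_boundary_covers_at_least_the_coverage(self, rng):
        m = rng.uniform(15, 100, 200)
        e = m * np.exp(rng.normal(0, 0.2, 200))
        for convention in ("log_ratio", "relative"):
            b = tdi(PairedSample(e, m), coverage=0.90, convention=convention)
            rel = (
                np.abs(np.log(e / m))
                if convention == "log_ratio"
                else np.abs(e - m) / m
            )
            boundary = math.log(1 + b / 100) if convention == "log_ratio" else b / 100
            assert np.mean(rel <= boundary + 1e-12) >= 0.90

    def test_non_decreasing_in_coverage(self, rng):
        m = rng.uniform(15, 100, 150)
        e = m * np.exp(rng.normal(0, 0.25, 150))
        s = PairedSample(e, m)
        values = [tdi(s, coverage=c) for c in (0.5, 0.7, 0.8, 0.9, 0.95)]
        assert values == sorted(values)

    def test_parametric_and_empirical_agree_under_lognormal_errors(self, rng):
        sigma = 0.15
        m = rng.uniform(20, 90, 20_000)
        e = m * np.exp(rng.normal(0, sigma, 20_000))
        s = PairedSample(e, m)
        emp = tdi(s, mode="empirical")
        par = tdi(s, mode="parametric")
        assert emp == pytest.approx(par, rel=0.03)

    def test_scale_invariance_of_relative_statistics(self, rng):
        m = rng.uniform(15, 100, 50)
        e = m * np.exp(rng.normal(0, 0.2, 50))
        s, s2 = PairedSample(e, m), PairedSample(2.5 * e, 2.5 * m)
        assert tdi(s2) == pytest.approx(tdi(s), rel=1e-12)
        assert p30(s2) == pytest.approx(p30(s), rel=1e-12)

    def test_invalid_coverage_rejected(self):
        with pytest.raises(ValueError):
            tdi(sample_from_diffs(np.zeros(12)), coverage=1.5)


class TestCcc:
    def test_perfect_concordance(self):
        m = np.array([20.0, 40.0, 60.0, 80.0])
        assert ccc(PairedSample(m, m)) == pytest.approx(1.0)

    def test_location_shift_penalises_agreement_not_correlation(self):
        m = np.array([20.0, 40.0, 60.0, 80.0, 100.0])
        s = PairedSample(m + 15.0, m)
        c = ccc(s, log_transform=False)
        r = np.corrcoef(m, m + 15.0)[0, 1]
        assert c < 1.0
        assert c < r

    def test_matches_moment_formula_oracle(self, rng):
        m = rng.uniform(15, 100, 6)
        e = m * np.exp(rng.normal(0, 0.3, 6))
        x, y = np.log(m), np.log(e)
        sxy = np.sum((x - x.mean()) * (y - y.mean())) / 5
        expected = 2 * sxy / (np.var(x, ddof=1) + np.var(y, ddof=1) + (x.mean() - y.mean()) ** 2)
        assert ccc(PairedSample(e, m)) == pytest.approx(expected, rel=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, derandomize=True)
    def test_bounded_by_absolute_pearson(self, seed):
        r = np.random.default_rng(seed)
        m = r.uniform(15, 100, 25)
        e = m * np.exp(r.normal(0, 0.3, 25))
        c = ccc(PairedSample(e, m))
        pearson = np.corrcoef(np.log(m), np.log(e))[0, 1]
        assert c <= abs(pearson) + 1e-12

    @pytest.mark.parametrize(
        "value,band",
        [
            (0.995, "almost_perfect"),
            (0.990, "substantial"),
            (0.950, "substantial"),
            (0.949, "moderate"),
            (0.900, "moderate"),
            (0.746, "poor"),
        ],
    )
    def test_band_edges_as_defined(self, value, band):
        assert ccc_band(value) == band

    def test_band_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ccc_band(1.2)


class TestDeming:
    def test_exact_line_any_variance_ratio(self):
        m = np.array([20.0, 35.0, 50.0, 70.0, 90.0])
        s = PairedSample(2 * m + 1, m)
        for lam in (0.25, 1.0, 4.0):
            slope, intercept = deming(s, variance_ratio=lam)
            assert slope == pytest.approx(2.0, rel=1e-10)
            assert intercept == pytest.approx(1.0, rel=1e-8)

    def test_swap_symmetry_at_unit_ratio(self, rng):
        m = rng.uniform(20, 90, 40)
        e = 0.8 * m + 10 + rng.normal(0, 4, 40)
        s_xy = deming(PairedSample(e, m))[0]
        s_yx = deming(PairedSample(m, e))[0]
        assert s_xy == pytest.approx(1.0 / s_yx, rel=1e-10)

    def test_recovers_generating_slope_with_symmetric_noise(self):
        r = np.random.default_rng(7)
        n = 10_000
        true_x = r.uniform(20, 100, n)
        x = true_x + r.normal(0, 5, n)
        y = 0.7 * true_x + 12 + r.normal(0, 5 * 0.7, n)
        # lambda = var_y_err / var_x_err = 0.49
        slope, intercept = deming(PairedSample(y, x), variance_ratio=0.49)
        assert slope == pytest.approx(0.7, abs=0.02)
        assert intercept == pytest.approx(12, abs=1.5)


class TestBlandAltman:
    def test_zero_differences_flat_trend(self):
        m = np.linspace(20, 90, 10)
        ba = bland_altman_data(PairedSample(m, m))
        assert np.all(ba.difference == 0)
        assert ba.trend_slope == pytest.approx(0.0, abs=1e-12)

    def test_proportional_error_trend(self):
        m = np.linspace(20, 90, 10)
        ba = bland_altman_data(PairedSample(1.2 * m, m))
        assert ba.trend_slope == pytest.approx(0.2, rel=1e-10)
        assert ba.trend_intercept == pytest.approx(0.0, abs=1e-9)

    def test_trend_matches_ols_oracle(self, rng):
        m = rng.uniform(20, 90, 5)
        e = m + rng.normal(0, 5, 5)
        ba = bland_altman_data(PairedSample(e, m))
        d = e - m
        sl = np.sum((m - m.mean()) * (d - d.mean())) / np.sum((m - m.mean()) ** 2)
        assert ba.trend_slope == pytest.approx(sl, rel=1e-10)
        assert ba.trend_intercept == pytest.approx(d.mean() - sl * m.mean(), rel=1e-8)


class TestInvariancesAndReport:
    def test_permutation_invariance_of_all_statistics(self, rng):
        m = rng.uniform(15, 100, 60)
        e = m * np.exp(rng.normal(0, 0.2, 60))
        perm = rng.permutation(60)
        r1 = compute_agreement(PairedSample(e, m))
        r2 = compute_agreement(PairedSample(e[perm], m[perm]))
        for k, v in r1.as_dict().items():
            assert v == pytest.approx(getattr(r2, k), rel=1e-10), k

    def test_report_internal_consistency(self, rng):
        m = rng.uniform(15, 100, 80)
        e = m * np.exp(rng.normal(0, 0.2, 80))
        rep = compute_agreement(PairedSample(e, m))
        assert rep.loa_low <= rep.bias <= rep.loa_high
        assert 0 <= rep.p30 <= 100
        assert rep.tdi >= 0
        assert -1 <= rep.ccc <= 1
        assert rep.n == 80
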