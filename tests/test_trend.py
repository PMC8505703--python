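"""Trend characterization: smoothing, OLS fit, band checks, permutation
contrast, and external-series correlation.

The OLS path is cross-checked against statsmodels (an independent
matrix-algebra implementation) and the permutation p-value against
exhaustive enumeration at small n.
"""

import itertools
from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from negindex import (
    ExternalSeries,
    IndexSeries,
    align_and_correlate,
    compare_windows,
    fit_linear_trend,
    range_check,
    read_external_series,
    rolling_mean,
)

D0 = date(2020, 3, 1)


def make_series(values, start=D0):
    """IndexSeries whose I(d) equals the given floats (NaN = missing day)."""
    values = np.asarray(values, dtype=float)
    idx = pd.date_range(start, periods=len(values), freq="D")
    frame = pd.DataFrame(
        {
            "total_tweets": np.where(np.isnan(values), 0, 1).astype(np.int64),
            "negative_words": np.zeros(len(values), dtype=np.int64),
            "index": values,
        },
        index=idx,
    )
    return IndexSeries(frame)


def win(start_off, end_off, start=D0):
    return (start + timedelta(days=start_off), start + timedelta(days=end_off))


class TestRollingMean:
    def test_constant_series_unchanged(self):
        out = rolling_mean(make_series([0.18] * 20), 7)
        np.testing.assert_allclose(out.to_numpy(), 0.18)

    def test_window_one_is_identity(self):
        vals = [0.1, 0.2, 0.15, 0.3]
        out = rolling_mean(make_series(vals), 1)
        np.testing.assert_allclose(out.to_numpy(), vals)

    def test_linear_series_interior_unchanged(self):
        # centered mean of a linear sequence equals its center value
        vals = 0.1 + 0.001 * np.arange(30)
        out = rolling_mean(make_series(vals), 7).to_numpy()
        np.testing.assert_allclose(out[3:-3], vals[3:-3], atol=1e-15)

    def test_even_or_oversized_window_rejected(self):
        series = make_series([0.1] * 5)
        with pytest.raises(ValueError):
            rolling_mean(series, 4)
        with pytest.raises(ValueError):
            rolling_mean(series, 7)

    def test_missing_days_do_not_contaminate(self):
        vals = [0.1, np.nan, 0.1, 0.1, 0.1]
        out = rolling_mean(make_series(vals), 3).to_numpy()
        assert np.isnan(out[1]) or out[1] == pytest.approx(0.1)
        np.testing.assert_allclose(out[[0, 2, 3, 4]], 0.1)


class TestFitLinearTrend:
    def test_exact_line(self):
        fit = fit_linear_trend(make_series([0.0, 1.0, 2.0]))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.n_days == 3

    def test_constant_series_zero_slope(self):
        fit = fit_linear_trend(make_series([0.17] * 10))
        assert fit.slope == pytest.approx(0.0, abs=1e-15)

    def test_noisy_decline_recovered_within_ci(self):
        rng = np.random.default_rng(7)
        true_slope = -0.0004
        y = 0.17 + true_slope * np.arange(180) + rng.normal(0, 0.005, 180)
        fit = fit_linear_trend(make_series(y))
        lo, hi = fit.slope_ci95
        assert lo < true_slope < hi
        assert lo < hi

    def test_matches_statsmodels_on_100_random_series(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(20200301)
        for _ in range(100):
            n = int(rng.integers(5, 60))
            y = rng.normal(0.16, 0.01, n) + rng.normal(0, 0.001) * np.arange(n)
            fit = fit_linear_trend(make_series(y))
            x = sm.add_constant(np.arange(n, dtype=float))
            ref = sm.OLS(y, x).fit()
            assert fit.intercept == pytest.approx(ref.params[0], abs=1e-10)
            assert fit.slope == pytest.approx(ref.params[1], abs=1e-10)
            assert fit.slope_stderr == pytest.approx(ref.bse[1], abs=1e-10)
            assert fit.r_squared == pytest.approx(ref.rsquared, abs=1e-10)
            lo, hi = ref.conf_int(0.05)[1]
            assert fit.slope_ci95 == (pytest.approx(lo, abs=1e-10),
                                      pytest.approx(hi, abs=1e-10))

    def test_time_axis_translation_changes_only_parameterization(self):
        y = np.linspace(0.18, 0.12, 40) + np.sin(np.arange(40)) * 0.002
        a = fit_linear_trend(make_series(y, start=D0))
        b = fit_linear_trend(make_series(y, start=D0 + timedelta(days=365)))
        assert a.slope == pytest.approx(b.slope, abs=1e-15)
        assert a.intercept == pytest.approx(b.intercept, abs=1e-15)
        assert a.r_squared == pytest.approx(b.r_squared, abs=1e-15)

    def test_window_subsets_fit(self):
        y = np.concatenate([np.full(10, 0.17), 0.17 - 0.001 * np.arange(20)])
        fit = fit_linear_trend(make_series(y), win(10, 29))
        assert fit.slope == pytest.approx(-0.001)
        assert fit.n_days == 20

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_trend(make_series([0.1, 0.2]))
        with pytest.raises(ValueError):
            fit_linear_trend(make_series([0.1, np.nan, np.nan, 0.2]))


class TestRangeCheck:
    def test_constant_inside_band(self):
        rc = range_check(make_series([0.16] * 10), band=(0.15, 0.18))
        assert rc.fraction_in_band == 1.0
        assert rc.min_index == rc.max_index == 0.16

    def test_constant_outside_band(self):
        rc = range_check(make_series([0.20] * 10), band=(0.15, 0.18))
        assert rc.fraction_in_band == 0.0

    def test_mixed_fraction_counts_non_missing_days(self):
        rc = range_check(
            make_series([0.16, 0.16, 0.20, np.nan]), band=(0.15, 0.18)
        )
        assert rc.n_days == 3
        assert rc.fraction_in_band == pytest.approx(2 / 3)


class TestCompareWindows:
    def test_identical_constant_windows(self):
        series = make_series([0.17] * 20)
        comp = compare_windows(series, win(0, 9), win(10, 19), seed=0)
        assert comp.difference == 0.0
        assert comp.p_value == pytest.approx(1.0)

    def test_clear_separation_gives_tiny_p(self):
        rng = np.random.default_rng(3)
        vals = np.concatenate(
            [0.17 + rng.normal(0, 1e-4, 15), 0.12 + rng.normal(0, 1e-4, 15)]
        )
        comp = compare_windows(make_series(vals), win(0, 14), win(15, 29), seed=1)
        assert comp.difference == pytest.approx(0.05, abs=0.001)
        assert comp.p_value < 0.001

    def test_matches_exhaustive_enumeration_at_small_n(self):
        vals = [0.18, 0.11, 0.15, 0.13, 0.17, 0.12]
        a, b = np.array(vals[:3]), np.array(vals[3:])
        obs = abs(a.mean() - b.mean())
        pooled = np.array(vals)
        hits = total = 0
        for combo in itertools.combinations(range(6), 3):
            rest = [i for i in range(6) if i not in combo]
            diff = abs(pooled[list(combo)].mean() - pooled[rest].mean())
            hits += diff >= obs - 1e-15
            total += 1
        exact_p = hits / total
        comp = compare_windows(make_series(vals), win(0, 2), win(3, 5), seed=5)
        assert comp.p_value == pytest.approx(exact_p, abs=0.02)

    def test_overlapping_or_short_windows_rejected(self):
        series = make_series([0.1] * 20)
        with pytest.raises(ValueError, match="disjoint"):
            compare_windows(series, win(0, 10), win(5, 19))
        with pytest.raises(ValueError, match=">= 3"):
            compare_windows(series, win(0, 9), win(18, 19))

    def test_p_value_uniform_under_null(self):
        # exchangeable windows: the permutation p-value must be ~Uniform(0,1)
        rng = np.random.default_rng(11)
        pvals = []
        for rep in range(500):
            vals = rng.normal(0.16, 0.01, 20)
            comp = compare_windows(
                make_series(vals), win(0, 9), win(10, 19), seed=int(rep)
            )
            pvals.append(comp.p_value)
        ks = sp_stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.001


class TestAlignAndCorrelate:
    def test_perfectly_correlated(self):
        vals = np.linspace(0.18, 0.12, 30)
        series = make_series(vals)
        ext = ExternalSeries(
            pd.Series(vals, index=series.frame.index), label="copy"
        )
        res = align_and_correlate(series, ext)
        assert res.r == pytest.approx(1.0)
        assert res.n == 30

    def test_anticorrelated(self):
        vals = np.linspace(0.18, 0.12, 30) + np.sin(np.arange(30)) * 0.01
        series = make_series(vals)
        ext = ExternalSeries(pd.Series(-vals, index=series.frame.index), label="neg")
        assert align_and_correlate(series, ext).r == pytest.approx(-1.0)

    def test_lag_shifts_alignment(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0.16, 0.01, 55)
        # the index repeats the external signal 5 days later
        series = make_series(base, start=D0 + timedelta(days=5))
        ext_idx = pd.date_range(D0, periods=55, freq="D")
        ext = ExternalSeries(pd.Series(base, index=ext_idx), label="lead")
        at_lag = align_and_correlate(series, ext, lag_days=5).r
        at_zero = align_and_correlate(series, ext, lag_days=0).r
        assert at_lag == pytest.approx(1.0)
        assert abs(at_zero) < 0.5

    def test_insufficient_overlap_rejected(self):
        series = make_series([0.1] * 5)
        far = pd.date_range(D0 + timedelta(days=100), periods=5, freq="D")
        ext = ExternalSeries(pd.Series(np.arange(5.0), index=far), label="far")
        with pytest.raises(ValueError, match="overlap"):
            align_and_correlate(series, ext)

    def test_forward_fill_is_capped(self):
        idx = pd.DatetimeIndex([pd.Timestamp(D0), pd.Timestamp(D0) + pd.Timedelta(days=10)])
        ext = ExternalSeries(pd.Series([1.0, 2.0], index=idx), label="weekly")
        filled = ext.forward_filled(max_days=6)
        assert len(filled.values) == 8  # day 0 + 6 filled + day 10
        assert filled.values.iloc[6] == 1.0

    def test_read_external_csv(self, tmp_path):
        path = tmp_path / "deaths.csv"
        path.write_text("date,deaths\n2020-03-01,10\n2020-03-02,12\n2020-03-03,9\n")
        ext = read_external_series(path)
        assert ext.label == "deaths"
        assert list(ext.values) == [10.0, 12.0, 9.0]
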