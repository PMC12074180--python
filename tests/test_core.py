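"""Unit tests for the curve data model, OLS fitting and validation metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from calconsensus import (
    CalibrationPoint,
    DegenerateInputError,
    LEVEL_GRID,
    SingularDesignError,
    accuracy_table,
    back_calc,
    back_calc_error,
    chrom_factors,
    fit_ols,
    lod_loq,
    matrix_effect,
    origin_inclusion,
    percent_recovery,
    residual_diagnostics,
    se_from_ci,
    selectivity_factor,
    threshold_rules,
)
from conftest import make_curve


class TestDataModel:
    def test_zero_or_negative_level_rejected(self):
        with pytest.raises(ValueError):
            CalibrationPoint(level=0.0, response=1.0)
        with pytest.raises(ValueError):
            CalibrationPoint(level=-2.5, response=1.0)

    def test_nonfinite_response_rejected(self):
        with pytest.raises(ValueError):
            CalibrationPoint(level=1.0, response=float("nan"))

    def test_negative_response_allowed(self):
        p = CalibrationPoint(level=2.5, response=-0.095)
        assert p.response < 0


class TestFitOLS:
    def test_exact_collinear(self, collinear_curve):
        f = fit_ols(collinear_curve)
        assert f.slope == pytest.approx(2.0, abs=1e-12)
        assert f.intercept == pytest.approx(0.0, abs=1e-12)
        assert f.r_squared == pytest.approx(1.0)
        assert f.rss == pytest.approx(0.0, abs=1e-20)

    def test_constant_response(self):
        f = fit_ols(make_curve([(1, 5), (2, 5), (3, 5)]))
        assert f.slope == pytest.approx(0.0, abs=1e-12)
        assert f.intercept == pytest.approx(5.0)

    def test_matches_normal_equation_oracle(self, rng):
        # independent closed-form normal equations on an 8-level noisy curve
        x = np.array(LEVEL_GRID)
        y = 0.1 * x - 0.01 + rng.normal(0, 0.005, size=len(x))
        f = fit_ols(make_curve(zip(x, y)))
        n = len(x)
        sxx = np.sum((x - x.mean()) ** 2)
        a = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        b = y.mean() - a * x.mean()
        resid = y - a * x - b
        s2 = np.sum(resid**2) / (n - 2)
        se_a = math.sqrt(s2 / sxx)
        se_b = math.sqrt(s2 * (1 / n + x.mean() ** 2 / sxx))
        tq = stats.t.ppf(0.975, n - 2)
        assert f.slope == pytest.approx(a, abs=1e-10)
        assert f.intercept == pytest.approx(b, abs=1e-10)
        assert f.se_slope == pytest.approx(se_a, abs=1e-10)
        assert f.se_intercept == pytest.approx(se_b, abs=1e-10)
        assert f.ci95_slope[0] == pytest.approx(a - tq * se_a, abs=1e-10)
        assert f.ci95_intercept[1] == pytest.approx(b + tq * se_b, abs=1e-10)
        assert f.df == n - 2
        np.testing.assert_allclose(f.residuals, resid, atol=1e-10)

    def test_too_few_levels(self):
        with pytest.raises(DegenerateInputError):
            fit_ols(make_curve([(1, 1), (2, 2), (2, 2.1)]))

    def test_identical_levels_singular(self):
        with pytest.raises(SingularDesignError):
            fit_ols(make_curve([(2, 1), (2, 2), (2, 3)]))

    def test_ci_brackets_estimate(self, rng):
        x = np.array(LEVEL_GRID)
        y = 0.05 * x + 0.1 + rng.normal(0, 0.01, len(x))
        f = fit_ols(make_curve(zip(x, y)))
        assert f.ci95_slope[0] <= f.slope <= f.ci95_slope[1]
        assert f.ci95_intercept[0] <= f.intercept <= f.ci95_intercept[1]
        assert f.r_squared <= 1.0


class TestOriginInclusion:
    @pytest.mark.parametrize(
        "interval,expected", [((-0.05, 0.25), True), ((0.02, 0.18), False)]
    )
    def test_bracketing(self, collinear_curve, interval, expected):
        f = fit_ols(collinear_curve)
        fake = f.__class__(**{**f.__dict__, "ci95_intercept": interval})
        decision, used = origin_inclusion(fake)
        assert decision is expected
        assert used == interval

    def test_matches_t_based_oracle(self):
        f = fit_ols(make_curve([(1, 2), (2, 4), (3, 6.01)]))
        lo, hi = f.ci95_intercept
        decision, _ = origin_inclusion(f)
        assert decision == (lo <= 0 <= hi)
        # oracle interval via direct t computation
        x = np.array([1.0, 2, 3])
        y = np.array([2.0, 4, 6.01])
        a = np.polyfit(x, y, 1)[0]
        b = y.mean() - a * x.mean()
        s2 = np.sum((y - a * x - b) ** 2) / 1
        se_b = math.sqrt(s2 * (1 / 3 + x.mean() ** 2 / np.sum((x - x.mean()) ** 2)))
        tq = stats.t.ppf(0.975, 1)
        assert lo == pytest.approx(b - tq * se_b, rel=1e-9)
        assert hi == pytest.approx(b + tq * se_b, rel=1e-9)


class TestResidualDiagnostics:
    def test_zero_residuals_flat_qq(self):
        d = residual_diagnostics(fit_ols(make_curve([(1, 2), (2, 4), (3, 6), (4, 8)])))
        assert np.allclose(d.qq_sample, 0.0, atol=1e-12)
        assert d.normality_p == 1.0

    def test_symmetric_residuals_median_zero(self):
        # slope-2 line with symmetric perturbation -> median QQ point at 0
        f = fit_ols(make_curve([(1, 2.0), (2, 4.1), (3, 5.9), (4, 8.0)]))
        d = residual_diagnostics(f)
        assert abs(np.median(d.qq_sample)) < 1e-9

    def test_normal_residuals_not_rejected(self, rng):
        resid = rng.standard_normal(200)
        x = np.linspace(1, 20, 200)
        f = fit_ols(make_curve(zip(x, 2 * x + resid)))
        d = residual_diagnostics(f, levels=x)
        assert d.normality_test == "dagostino-pearson"
        assert 0 <= d.normality_p <= 1
        assert d.normality_p > 0.05
        assert len(d.fitted) == 200

    def test_too_few_points(self):
        with pytest.raises(DegenerateInputError):
            residual_diagnostics(fit_ols(make_curve([(1, 1), (2, 2.1), (3, 2.9)])))


class TestFormulas:
    def test_se_from_ci(self):
        assert se_from_ci(0, 3.92) == pytest.approx(1.0)
        assert se_from_ci(5, 5) == 0.0
        # SE recovered from a printed Deming slope CI of (0.69, 0.83)
        assert se_from_ci(0.69, 0.83) == pytest.approx(0.0357, abs=5e-5)
        with pytest.raises(ValueError):
            se_from_ci(1.0, 0.5)

    def test_lod_loq_trivials(self):
        assert lod_loq(1.0, 3.3)[0] == pytest.approx(1.0)
        assert lod_loq(1.0, 10.0)[1] == pytest.approx(1.0)
        with pytest.raises(ZeroDivisionError):
            lod_loq(1.0, 0.0)

    def test_negative_slope_gives_positive_limits(self):
        lod, loq = lod_loq(0.005, -24.96e-3)
        assert lod > 0 and loq > 0

    @given(
        sd=st.floats(1e-9, 1e3, allow_nan=False),
        slope=st.floats(1e-6, 1e3, allow_nan=False),
    )
    @settings(derandomize=True, max_examples=50)
    def test_loq_lod_ratio_invariant(self, sd, slope):
        lod, loq = lod_loq(sd, slope)
        assert loq / lod == pytest.approx(10 / 3.3, rel=1e-12)

    def test_lod_recovers_known_sigma(self, rng):
        # Monte-Carlo: LOD from fitted curves ~ 3.3 * se_b(true sigma) / a
        x = np.array(LEVEL_GRID)
        sigma, a_true = 0.01, 0.1
        n, sims = len(x), 400
        sxx = np.sum((x - x.mean()) ** 2)
        se_b_true = sigma * math.sqrt(1 / n + x.mean() ** 2 / sxx)
        expected = 3.3 * se_b_true / a_true
        lods = []
        for _ in range(sims):
            y = a_true * x + rng.normal(0, sigma, n)
            f = fit_ols(make_curve(zip(x, y)))
            lods.append(lod_loq(f.se_intercept, f.slope)[0])
        assert np.mean(lods) == pytest.approx(expected, rel=0.1)


class TestAccuracy:
    def test_recovery_matches_reference_qc_rows(self):
        # rounded %Rec from reported QC means at MQC / HQC / ULOQ
        assert round(percent_recovery(9.34, 10)) == 93
        assert round(percent_recovery(20.06, 20)) == 100
        assert round(percent_recovery(16.61, 16)) == 104

    def test_mean_equals_nominal_gives_100(self):
        rows = accuracy_table({10.0: [10.0, 10.0, 10.0]})
        assert rows[0].rec_pct == pytest.approx(100.0)
        assert rows[0].rsd_pct == pytest.approx(0.0)

    def test_table_statistics_and_rounding(self):
        vals = [9.1, 9.5, 9.3, 9.2, 9.6, 9.4]
        (row,) = accuracy_table({10.0: vals}, labels={10.0: "MQC"})
        v = np.array(vals)
        assert row.mean == pytest.approx(v.mean())
        assert row.rsd_pct == pytest.approx(100 * v.std(ddof=1) / v.mean())
        assert row.rec_pct == pytest.approx(100 * v.mean() / 10)
        half = stats.t.ppf(0.975, 5) * 100 * v.std(ddof=1) / (math.sqrt(6) * 10)
        assert row.rec_ci95 == pytest.approx((row.rec_pct - half, row.rec_pct + half))
        r = row.rounded()
        assert r["mean"] == round(v.mean(), 2)
        assert r["level"] == "MQC"
        assert isinstance(r["rec_pct"], int)

    def test_unbiased_noise_converges_to_100(self, rng):
        # %Rec -> 100 with growing replicates (tolerance 3 SEM)
        n = 4000
        vals = 10 + rng.normal(0, 0.5, n)
        (row,) = accuracy_table({10.0: vals})
        sem_pct = 3 * 100 * 0.5 / (math.sqrt(n) * 10)
        assert abs(row.rec_pct - 100) < sem_pct

    def test_nonpositive_nominal_rejected(self):
        with pytest.raises(ValueError):
            accuracy_table({-1.0: [1, 2]})

    def test_back_calculation_through_fit(self, collinear_curve):
        f = fit_ols(collinear_curve)
        rows = accuracy_table({5.0: [10.0, 10.2, 9.8]}, fit=f)
        assert rows[0].mean == pytest.approx(5.0)


class TestBackCalc:
    def test_trivial_roundtrips(self, collinear_curve):
        f = fit_ols(collinear_curve)
        assert back_calc(f, 10.0) == pytest.approx(5.0)
        assert back_calc_error(f, 10.0, 5.0) == pytest.approx(0.0)

    @given(x=st.floats(0.1, 1e3), a=st.floats(0.01, 10), b=st.floats(-5, 5))
    @settings(derandomize=True, max_examples=50)
    def test_exact_inverse_property(self, x, a, b):
        f = fit_ols(make_curve([(1, a + b), (2, 2 * a + b), (3, 3 * a + b)]))
        assert back_calc(f, a * x + b) == pytest.approx(x, rel=1e-6, abs=1e-9)

    def test_cross_day_error_largest_at_grid_extremes(self):
        # day-1 line applied to noiseless day-2 responses (slope ratio 0.75)
        day1 = fit_ols(make_curve([(lv, -24.96e-3 * lv - 3.29e-2) for lv in LEVEL_GRID]))
        day2_resp = {lv: -18.81e-3 * lv - 1.38e-2 for lv in LEVEL_GRID}
        errs = {lv: back_calc_error(day1, day2_resp[lv], lv) for lv in LEVEL_GRID}
        centroid = errs[10.0]
        assert max(errs[2.5], errs[20.0]) > centroid
        assert max(errs.values()) == max(errs[2.5], errs[20.0])


class TestMatrixEffect:
    def test_equal_slopes_zero(self):
        me, strong = matrix_effect(1.0, 1.0)
        assert me == 0.0 and not strong

    def test_boundary_20_percent_not_strong(self):
        me, strong = matrix_effect(1.2, 1.0)
        assert me == pytest.approx(20.0)
        assert not strong  # strictly greater than 20 flags strong

    def test_configured_suppression_recovered(self, rng):
        x = np.array(LEVEL_GRID)
        solvent = fit_ols(make_curve(zip(x, 0.1 * x + rng.normal(0, 0.002, len(x)))))
        post = fit_ols(make_curve(zip(x, 0.085 * x + rng.normal(0, 0.002, len(x)))))
        me, _ = matrix_effect(post.slope, solvent.slope)
        assert me == pytest.approx(-15.0, abs=2.0)

    @given(r=st.floats(0.05, 20))
    @settings(derandomize=True, max_examples=50)
    def test_antisymmetric_sign_under_ratio_inversion(self, r):
        me1, _ = matrix_effect(r, 1.0)
        me2, _ = matrix_effect(1.0, r)
        if r != 1.0:
            assert me1 * me2 < 0


class TestChromatography:
    def test_reported_selectivity_factor(self):
        assert round(selectivity_factor(38.6, 32.9), 1) == 1.2
        assert selectivity_factor(5.0, 5.0) == 1.0

    def test_capacity_factor_from_retention(self):
        # dead time chosen so k reproduces the reported 38.6 at t_r=11.9
        cf = chrom_factors(t_r=11.9, t_0=0.3005)
        assert round(cf.k, 1) == 38.6

    def test_invalid_times(self):
        with pytest.raises(ValueError):
            chrom_factors(t_r=1.0, t_0=0.0)
        with pytest.raises(ValueError):
            chrom_factors(t_r=0.1, t_0=0.5)


class TestThresholdRules:
    def test_clean_blank_passes_selectivity(self):
        f = threshold_rules(0.0, 100.0, 0.0, 50.0, 0.0, 5.0)
        assert f.selectivity_pass and f.is_interference_pass and f.carryover_pass

    def test_is_interference_boundary_inclusive(self):
        f = threshold_rules(0.0, 100.0, 2.5, 50.0, 0.0, 5.0)
        assert f.is_interference_pass  # exactly 5% still passes

    def test_carryover_boundary_strict(self):
        f = threshold_rules(0.0, 100.0, 0.0, 50.0, 5.0, 5.0)
        assert not f.carryover_pass

    def test_selectivity_boundary_strict(self):
        f = threshold_rules(20.0, 100.0, 0.0, 50.0, 0.0, 5.0)
        assert not f.selectivity_pass

    def test_negative_signal_rejected(self):
        with pytest.raises(ValueError):
            threshold_rules(-1.0, 100.0, 0.0, 50.0, 0.0, 5.0)
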