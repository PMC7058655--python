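"""Broken-stick regression: prediction, exact recovery, grid-oracle
equivalence, nesting, equivariance, consistency and bootstrap CIs."""
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsikinetics import (
    Biomarker,
    BrokenStickFit,
    DailySeries,
    FitError,
    TrueKinetics,
    breakpoint_cis,
    daily_means,
    fit_broken_stick,
    generate_cohort,
    predict,
    select_cohort,
)
from conftest import make_scenario


def stick_series(c, level, pre, post, days=None, noise_sd=0.0, seed=0):
    days = np.arange(-30, 2) if days is None else np.asarray(days)
    kin = TrueKinetics(c, level, pre, post)
    values = kin.mean_at(days)
    if noise_sd > 0:
        values = values + np.random.default_rng(seed).normal(0, noise_sd,
                                                             len(days))
    return DailySeries(Biomarker.CRP, days, values, np.ones(len(days), int))


def make_fit(c, level, pre, post, day_min=-30.0, day_max=1.0):
    return BrokenStickFit(c=c, level_at_c=level, slope_pre=pre,
                          slope_post=post, sse=0.0, n_days=32,
                          day_min=day_min, day_max=day_max)


class TestPredict:
    def test_anchored_at_change_point(self):
        assert predict(make_fit(-3.0, 80.0, 0.0, 40.0), -3.0) == 80.0

    def test_hand_arithmetic_after_change(self):
        # 80 + 40 * ((-1) - (-3)) = 160
        assert predict(make_fit(-3.0, 80.0, 0.0, 40.0), -1.0) == 160.0

    def test_equal_slopes_degenerate_to_single_line(self):
        fit = make_fit(-10.0, 50.0, 2.0, 2.0)
        t = np.linspace(-30, 1, 64)
        np.testing.assert_allclose(predict(fit, t), 50.0 + 2.0 * (t + 10.0),
                                   atol=1e-12)

    def test_continuity_at_change_point(self):
        fit = make_fit(-3.1, 70.0, -1.5, 36.3)
        eps = 1e-9
        assert abs(predict(fit, -3.1 - eps) - predict(fit, -3.1 + eps)) < 1e-6

    def test_extrapolation_warns_but_returns(self):
        fit = make_fit(-3.0, 80.0, 0.0, 40.0)
        with pytest.warns(UserWarning, match="outside the fitted"):
            assert predict(fit, 3.0) == 80.0 + 40.0 * 6.0


class TestFit:
    @pytest.mark.parametrize("c_true", [-3.0, -7.4, -12.5])
    def test_noiseless_recovery_to_numerical_tolerance(self, c_true):
        series = stick_series(c_true, 100.0, -2.0, 35.0)
        fit = fit_broken_stick(series)
        assert fit.c == pytest.approx(c_true, abs=1e-8)
        assert fit.level_at_c == pytest.approx(100.0, abs=1e-8)
        assert fit.slope_pre == pytest.approx(-2.0, abs=1e-8)
        assert fit.slope_post == pytest.approx(35.0, abs=1e-8)
        assert fit.sse <= 1e-16

    def test_matches_exhaustive_candidate_search(self):
        """Profiled minimiser equals an independent per-candidate solver."""
        series = stick_series(-4.2, 90.0, -1.0, 30.0, noise_sd=8.0, seed=1)
        fit = fit_broken_stick(series, refine=False)
        best_c, best_sse = None, np.inf
        for c in np.round(np.arange(-28.9, -0.05, 0.1), 10):
            t = series.days - c
            X = np.column_stack([np.ones_like(t), np.minimum(t, 0),
                                 np.maximum(t, 0)])
            beta, res, *_ = np.linalg.lstsq(X, series.means, rcond=None)
            sse = float(np.sum((series.means - X @ beta) ** 2))
            if sse < best_sse - 1e-12:
                best_c, best_sse = c, sse
        assert fit.c == pytest.approx(best_c, abs=1e-12)
        assert fit.sse == pytest.approx(best_sse, rel=1e-9)

    def test_never_worse_than_single_straight_line(self):
        for seed in range(5):
            series = stick_series(-5.0, 60.0, 0.5, 10.0, noise_sd=15.0,
                                  seed=seed)
            fit = fit_broken_stick(series)
            line = np.polyfit(series.days, series.means, 1)
            line_sse = float(np.sum(
                (series.means - np.polyval(line, series.days)) ** 2))
            assert fit.sse <= line_sse + 1e-9

    def test_ties_break_toward_latest_change(self):
        # perfectly linear data: every candidate fits exactly, so the
        # change-point closest to day 0 wins
        days = np.arange(-30, 2)
        series = DailySeries(Biomarker.CRP, days, 50.0 + 2.0 * days,
                             np.ones(len(days), int))
        fit = fit_broken_stick(series)
        assert fit.c == pytest.approx(-0.1, abs=1e-9)

    def test_too_few_points_raises(self):
        series = DailySeries(Biomarker.CRP, np.array([-5, -4, 0]),
                             np.array([1.0, 2.0, 3.0]), np.ones(3, int))
        with pytest.raises(FitError, match="at least 4"):
            fit_broken_stick(series)

    def test_refinement_recovers_off_grid_change_point(self):
        series = stick_series(-6.137, 80.0, -1.0, 20.0)
        fit = fit_broken_stick(series, refine=True)
        assert fit.c == pytest.approx(-6.137, abs=1e-6)

    @given(
        value_shift=st.floats(min_value=-200, max_value=200),
        day_shift=st.integers(min_value=-5, max_value=5),
        seed=st.integers(min_value=0, max_value=50),
    )
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_shift_equivariance(self, value_shift, day_shift, seed):
        """Adding k to values shifts the level by k; shifting days by d
        shifts the change-point by d; slopes never move."""
        series = stick_series(-5.5, 70.0, -1.0, 25.0, noise_sd=5.0, seed=seed)
        base = fit_broken_stick(series, refine=False)

        shifted_vals = DailySeries(series.biomarker, series.days,
                                   series.means + value_shift, series.counts)
        fv = fit_broken_stick(shifted_vals, refine=False)
        assert fv.c == pytest.approx(base.c, abs=1e-9)
        assert fv.level_at_c == pytest.approx(base.level_at_c + value_shift,
                                              rel=1e-6, abs=1e-6)
        assert fv.slope_pre == pytest.approx(base.slope_pre, rel=1e-6, abs=1e-9)
        assert fv.slope_post == pytest.approx(base.slope_post, rel=1e-6,
                                              abs=1e-9)

        shifted_days = DailySeries(series.biomarker, series.days + day_shift,
                                   series.means, series.counts)
        fd = fit_broken_stick(
            shifted_days, refine=False,
            c_search=(-29.0 + day_shift, 0.0 + day_shift))
        assert fd.c == pytest.approx(base.c + day_shift, abs=1e-9)
        assert fd.slope_pre == pytest.approx(base.slope_pre, rel=1e-6, abs=1e-9)

    def test_estimation_error_shrinks_with_noise(self):
        """|c_hat - c_true| is non-increasing in expectation as noise falls."""
        errors = []
        for sd in (0.8, 0.2, 0.0):
            errs = []
            for seed in range(6):
                cohort = generate_cohort(
                    make_scenario(n_patients=150, crp_noise_sd_log=sd,
                                  sampling_p=0.5, seed=seed))
                fit = fit_broken_stick(daily_means(cohort, Biomarker.CRP))
                errs.append(abs(fit.c - (-3.1)))
            errors.append(np.mean(errs))
        assert errors[0] >= errors[1] >= errors[2]
        assert errors[2] < 1e-6


class TestBreakpointCis:
    def test_zero_noise_gives_degenerate_intervals(self, zero_noise_cohort):
        fit = breakpoint_cis(zero_noise_cohort, Biomarker.CRP, n_reps=40,
                             rng=0)
        assert fit.ci_c[0] == pytest.approx(fit.ci_c[1], abs=1e-9)
        assert fit.ci_c[0] == pytest.approx(fit.c, abs=1e-9)
        assert fit.n_failed == 0

    def test_deterministic_under_fixed_seed(self):
        cohort = generate_cohort(make_scenario(n_patients=60,
                                               crp_noise_sd_log=0.4,
                                               sampling_p=0.4, seed=2))
        eligible = select_cohort(cohort, Biomarker.CRP)
        a = breakpoint_cis(eligible, Biomarker.CRP, n_reps=50, rng=9)
        b = breakpoint_cis(eligible, Biomarker.CRP, n_reps=50, rng=9)
        assert a == b

    def test_interval_brackets_the_point_estimate(self):
        cohort = generate_cohort(make_scenario(n_patients=120,
                                               crp_noise_sd_log=0.4,
                                               sampling_p=0.5, seed=6))
        fit = breakpoint_cis(cohort, Biomarker.CRP, n_reps=80, rng=1)
        assert fit.ci_c[0] <= fit.ci_c[1]
        assert fit.ci_slope_pre[0] <= fit.slope_pre <= fit.ci_slope_pre[1]
        assert fit.n_boot + fit.n_failed == 80
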