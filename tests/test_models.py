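"""Growth-model evaluation and fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenocurve import (
    CHParams, CIgParams, ObservationSeries, compare_models, evaluate_ch_model,
    evaluate_cig_model, fit_ch_model, fit_cig_model, goodness_of_fit,
)
from phenocurve.models import CIG_INITIAL_VALUES

from conftest import WEEKLY_DAYS


class TestModelEvaluation:
    @pytest.mark.parametrize("x, p, expected", [
        # logistic midpoint: y(d0) = K/2
        (50.0, CHParams(K=100, r1=0.1, d0=50, d1=120, a=0.005), 50.0),
        # hand evaluation: 100/(1+e^-4) - 0.01*10^2
        (90.0, CHParams(K=100, r1=0.1, d0=50, d1=80, a=0.01), 97.20137900),
    ])
    def test_ch_hand_values(self, x, p, expected):
        assert evaluate_ch_model(x, p) == pytest.approx(expected, abs=1e-6)

    def test_ch_asymptote_without_decline(self):
        p = CHParams(K=80, r1=0.1, d0=50, d1=1e6, a=0.0)
        assert evaluate_ch_model(5000.0, p) == pytest.approx(80.0, abs=1e-9)

    def test_cig_identical_terms_cancel(self):
        p_eps = CIgParams(ymax=6, r2=0.1, r3=0.1, d2=50, d3=50 + 1e-9)
        assert evaluate_cig_model(33.0, p_eps) == pytest.approx(0.0, abs=1e-8)

    def test_cig_hand_value(self):
        p = CIgParams(ymax=6, r2=0.1, r3=0.1, d2=30, d3=100)
        # 6 * (0.5 - 1/(1+e^7))
        assert evaluate_cig_model(30.0, p) == pytest.approx(2.994533693, abs=1e-6)

    def test_cig_vanishes_far_out(self):
        p = CIgParams(ymax=6, r2=0.05, r3=0.06, d2=40, d3=100)
        assert abs(evaluate_cig_model(1000.0, p)) < 1e-6

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(50, 150), st.floats(0.02, 0.5), st.floats(10, 60),
           st.floats(0, 60), st.floats(0, 0.05))
    def test_ch_continuity_at_d1(self, K, r1, d0, offset, a):
        p = CHParams(K=K, r1=r1, d0=d0, d1=d0 + offset, a=a)
        left = evaluate_ch_model(p.d1 - 1e-9, p)
        right = evaluate_ch_model(p.d1 + 1e-9, p)
        assert abs(left - right) < 1e-6

    def test_ch_monotone_before_d1_without_decline(self):
        p = CHParams(K=100, r1=0.08, d0=45, d1=200, a=0.0)
        x = np.linspace(0, 200, 500)
        assert np.all(np.diff(evaluate_ch_model(x, p)) >= 0)

    def test_cig_unimodal_equal_rates(self):
        p = CIgParams(ymax=5, r2=0.1, r3=0.1, d2=35, d3=110)
        y = evaluate_cig_model(np.linspace(0, 160, 800), p)
        k = int(np.argmax(y))
        assert np.all(np.diff(y[:k + 1]) >= -1e-12) and np.all(np.diff(y[k:]) <= 1e-12)


class TestGoodnessOfFit:
    def test_values(self):
        y = np.array([1.0, 2.0, 3.0])
        assert goodness_of_fit(y, y) == 1.0
        assert goodness_of_fit(y, np.full(3, y.mean())) == 0.0
        assert goodness_of_fit(y, np.array([1.0, 2.0, 4.0])) == pytest.approx(0.5)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            goodness_of_fit(np.ones(5), np.ones(5))


class TestCHFitting:
    def test_noiseless_self_consistency(self):
        true = CHParams(K=105, r1=0.11, d0=43, d1=78, a=0.009)
        y = evaluate_ch_model(WEEKLY_DAYS, true)
        fit = fit_ch_model(ObservationSeries("l", "CH", WEEKLY_DAYS, y))
        assert fit.converged
        assert fit.params.K == pytest.approx(true.K, rel=0.01)
        assert fit.params.d0 == pytest.approx(true.d0, abs=1.0)
        assert fit.params.d1 == pytest.approx(true.d1, abs=1.0)
        assert fit.params.a == pytest.approx(true.a, rel=0.10)
        assert fit.r_squared > 0.9999

    def test_pure_logistic_gives_zero_decline(self):
        true = CHParams(K=95, r1=0.1, d0=40, d1=1e9, a=0.0)
        y = evaluate_ch_model(WEEKLY_DAYS, true)
        fit = fit_ch_model(ObservationSeries("l", "CH", WEEKLY_DAYS, y))
        assert fit.params.a <= 1e-4
        assert fit.sse == pytest.approx(0.0, abs=1e-6)

    def test_flat_series_flagged_nonconvergent(self):
        fit = fit_ch_model(ObservationSeries("l", "CH", WEEKLY_DAYS,
                                             np.zeros_like(WEEKLY_DAYS)))
        assert not fit.converged and fit.params is None

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            fit_ch_model(ObservationSeries("l", "CH", WEEKLY_DAYS[:5],
                                           np.arange(5.0)))

    def test_refit_from_optimum_is_fixed_point(self):
        true = CHParams(K=100, r1=0.1, d0=42, d1=75, a=0.008)
        rng = np.random.default_rng(2)
        y = np.maximum(evaluate_ch_model(WEEKLY_DAYS, true)
                       + rng.normal(0, 1, WEEKLY_DAYS.size), 0)
        fit1 = fit_ch_model(ObservationSeries("l", "CH", WEEKLY_DAYS, y))
        refit = fit_ch_model(ObservationSeries("l", "CH", WEEKLY_DAYS, fit1.fitted))
        assert refit.params.K == pytest.approx(fit1.params.K, rel=1e-3)
        assert refit.params.d1 == pytest.approx(fit1.params.d1, abs=0.5)
        assert refit.sse <= fit1.sse + 1e-9


class TestCIgFitting:
    def test_conventional_initial_vector(self):
        assert CIG_INITIAL_VALUES == (0.05, 0.05, 40.0, 100.0)

    def test_noiseless_self_consistency_with_peak_observation(self):
        true = CIgParams(ymax=5.5, r2=0.15, r3=0.12, d2=38, d3=112)
        x = np.linspace(0, 150, 1000)
        peak = x[np.argmax(evaluate_cig_model(x, true))]
        days = np.sort(np.unique(np.append(WEEKLY_DAYS, round(peak))))
        y = evaluate_cig_model(days, true)
        fit = fit_cig_model(ObservationSeries("l", "CIg", days, y))
        assert fit.converged
        assert fit.params.r2 == pytest.approx(true.r2, rel=0.05)
        assert fit.params.r3 == pytest.approx(true.r3, rel=0.05)
        assert fit.params.d2 == pytest.approx(true.d2, abs=1.0)
        assert fit.params.d3 == pytest.approx(true.d3, abs=1.0)

    def test_ymax_fixed_at_observed_maximum(self):
        true = CIgParams(ymax=6.0, r2=0.15, r3=0.12, d2=35, d3=110)
        y = evaluate_cig_model(WEEKLY_DAYS, true)
        fit = fit_cig_model(ObservationSeries("l", "CIg", WEEKLY_DAYS, y))
        assert fit.params.ymax == y.max()

    def test_underdetermined_series_rejected(self):
        with pytest.raises(ValueError):
            fit_cig_model(ObservationSeries("l", "CIg", np.arange(4.0),
                                            np.arange(4.0)))


class TestModelComparison:
    def test_ch_generated_data_fits_ch_model(self):
        true = CHParams(K=100, r1=0.11, d0=42, d1=76, a=0.008)
        y = evaluate_ch_model(WEEKLY_DAYS, true)
        rep = compare_models(ObservationSeries("l", "CH", WEEKLY_DAYS, y))
        assert rep["r_squared_3param"] >= 0.99

    def test_double_logistic_data_prefers_double(self):
        true = CIgParams(ymax=5.5, r2=0.15, r3=0.12, d2=38, d3=112)
        y = evaluate_cig_model(WEEKLY_DAYS, true)
        rep = compare_models(ObservationSeries("l", "CIg", WEEKLY_DAYS, y))
        assert rep["preferred"] == "double_logistic"

    def test_policy_override_keeps_ch_model(self):
        true = CIgParams(ymax=5.5, r2=0.15, r3=0.12, d2=38, d3=112)
        y = evaluate_cig_model(WEEKLY_DAYS, true)
        rep = compare_models(ObservationSeries("l", "CH", WEEKLY_DAYS, y),
                             policy="ch_logistic")
        assert rep["preferred"] == "ch_logistic"
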