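"""VIF computation, backward selection, and OLS trait models."""

import numpy as np
import pandas as pd
import pytest

from phenocurve import (MODEL_SPECS, ModelSpec, backward_vif_selection,
                        compute_vif, fit_trait_model, predict_trait)

from conftest import make_correlated_pair


class TestVIF:
    def test_orthogonal_predictors_have_unit_vif(self):
        df = make_correlated_pair(50, 0.0, seed=1)
        assert np.allclose(compute_vif(df), 1.0, atol=1e-10)

    def test_closed_form_at_correlation_08(self):
        df = make_correlated_pair(60, 0.8, seed=2)
        vifs = compute_vif(df)
        assert vifs["x1"] == pytest.approx(1 / (1 - 0.64), abs=1e-8)
        assert vifs["x2"] == pytest.approx(2.7778, abs=1e-3)

    def test_duplicated_column_is_infinite(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(30)
        df = pd.DataFrame({"a": x, "b": x, "c": rng.standard_normal(30)})
        assert np.isinf(compute_vif(df)["a"])

    def test_affine_rescaling_invariance(self):
        df = make_correlated_pair(40, 0.6, seed=4)
        scaled = pd.DataFrame({"x1": 3.0 * df.x1 - 7.0, "x2": 0.01 * df.x2 + 2.0})
        assert np.allclose(compute_vif(df).to_numpy(),
                           compute_vif(scaled).to_numpy(), atol=1e-8)

    def test_input_requirements(self):
        df = make_correlated_pair(40, 0.5)
        with pytest.raises(ValueError):
            compute_vif(df[["x1"]])
        with pytest.raises(ValueError):
            compute_vif(df.head(3))


class TestBackwardSelection:
    def test_below_threshold_unchanged(self):
        df = make_correlated_pair(50, 0.3, seed=5)
        assert backward_vif_selection(df) == ["x1", "x2"]

    def test_population_parameter_table(self, population_2022):
        lines = population_2022[~population_2022["is_parent"]]
        pool = list(MODEL_SPECS["Hybrid-full"].predictors)
        design = lines[lines["protocol"] == "R"][pool]
        kept = backward_vif_selection(design, threshold=5.0)
        assert 2 <= len(kept) < len(pool)
        assert compute_vif(design[kept]).max() < 5.0
        # every removal was justified: adding any dropped predictor back
        # pushes some VIF to or beyond the threshold region it was removed at
        removed = [p for p in pool if p not in kept]
        assert removed

    def test_canonical_selected_sets_are_frozen(self):
        assert MODEL_SPECS["CH-selected"].predictors == ("K", "d0", "d1")
        assert MODEL_SPECS["CIg-selected"].predictors == ("r2", "d2", "d3", "ymax")
        assert set(MODEL_SPECS["Hybrid-selected"].predictors) == {
            "K", "d0", "d1", "r2", "d2", "d3", "ymax"}
        assert len(MODEL_SPECS["Hybrid-full"].predictors) == 10


class TestTraitModels:
    def test_exact_line_recovered(self):
        spec = ModelSpec("one", ("x",))
        params = pd.DataFrame({"x": [0.0, 1.0, 2.0]})
        traits = pd.DataFrame({"y": [1.0, 3.0, 5.0]})
        fit = fit_trait_model(spec, params, traits, "y")
        assert fit.intercept == pytest.approx(1.0)
        assert fit.coefficients["x"] == pytest.approx(2.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_exact_affine_multivariate_recovery(self):
        rng = np.random.default_rng(6)
        params = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        y = 2.0 - 1.5 * params.a + 0.5 * params.b + 3.0 * params.c
        fit = fit_trait_model(ModelSpec("m", ("a", "b", "c")), params,
                              pd.DataFrame({"t": y}), "t")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients["a"] == pytest.approx(-1.5, abs=1e-8)

    def test_pure_noise_has_null_r2(self):
        rng = np.random.default_rng(7)
        params = pd.DataFrame({"a": rng.standard_normal(200),
                               "b": rng.standard_normal(200)})
        traits = pd.DataFrame({"t": rng.standard_normal(200)})
        fit = fit_trait_model(ModelSpec("m", ("a", "b")), params, traits, "t")
        assert fit.r_squared < 0.05
        assert all(0 <= p <= 1 for p in fit.p_values.values())

    def test_residual_orthogonality_and_r2_identity(self, population_2022):
        lines = population_2022[(~population_2022["is_parent"])
                                & (population_2022["protocol"] == "R")]
        spec = MODEL_SPECS["CH-selected"]
        fit = fit_trait_model(spec, lines, lines, "DTH")
        pred = predict_trait(fit, lines)
        resid = lines["DTH"].to_numpy() - pred
        assert abs(resid.sum()) < 1e-8 * len(lines)
        for p in spec.predictors:
            assert abs(resid @ lines[p].to_numpy()) < 1e-6 * len(lines)
        assert fit.r_squared == pytest.approx(
            np.corrcoef(pred, lines["DTH"])[0, 1] ** 2, abs=1e-10)

    def test_selected_r2_bounded_by_full(self, population_2022):
        lines = population_2022[(~population_2022["is_parent"])
                                & (population_2022["protocol"] == "R")]
        for sel, full in [("CH-selected", "CH-full"), ("CIg-selected", "CIg-full"),
                          ("Hybrid-selected", "Hybrid-full")]:
            r2_sel = fit_trait_model(MODEL_SPECS[sel], lines, lines, "DTH").r_squared
            r2_full = fit_trait_model(MODEL_SPECS[full], lines, lines, "DTH").r_squared
            assert r2_sel <= r2_full + 1e-12

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(30)
        params = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="collinear"):
            fit_trait_model(ModelSpec("m", ("a", "b")), params,
                            pd.DataFrame({"t": x + rng.standard_normal(30)}), "t")


class TestPrediction:
    @pytest.fixture()
    def simple_fit(self):
        rng = np.random.default_rng(9)
        params = pd.DataFrame({"a": rng.standard_normal(30),
                               "b": rng.standard_normal(30)})
        y = 1.0 + 2.0 * params.a - 0.5 * params.b
        return fit_trait_model(ModelSpec("m", ("a", "b")), params,
                               pd.DataFrame({"t": y}), "t"), params, y

    def test_training_rows_reproduce_fitted_values(self, simple_fit):
        fit, params, y = simple_fit
        assert np.allclose(predict_trait(fit, params), y, atol=1e-8)

    def test_all_zero_predictors_give_intercept(self, simple_fit):
        fit, _, _ = simple_fit
        zeros = pd.DataFrame({"a": [0.0], "b": [0.0]})
        assert predict_trait(fit, zeros)[0] == pytest.approx(fit.intercept)

    def test_translation_linearity(self, simple_fit):
        fit, params, _ = simple_fit
        shifted = params.assign(a=params.a + 3.0)
        delta = predict_trait(fit, shifted) - predict_trait(fit, params)
        assert np.allclose(delta, 3.0 * fit.coefficients["a"], atol=1e-10)

    def test_missing_predictor_rejected(self, simple_fit):
        fit, params, _ = simple_fit
        with pytest.raises(ValueError, match="missing predictor"):
            predict_trait(fit, params[["a"]])
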