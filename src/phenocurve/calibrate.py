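"""Parental-cultivar calibration of cross-condition trait predictions.

When a prediction model is trained under one transplanting protocol or year
and applied under another, the predictions acquire a systematic bias.  The
parental cultivars of the population, grown alongside the lines in the test
condition, serve as anchors: a simple regression of their observed on their
predicted trait values yields an affine calibration that is then applied to
the line predictions.  The five steps: (1) fit the prediction model on the
training condition, (2) predict the test-condition lines, (3) predict the
test-condition parents, (4) regress parent observed on parent predicted,
(5) apply that line to the line predictions.  Metrics exclude the parents
to avoid anchor leakage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluate import pearson_cor, rmse
from .regression import ModelSpec, fit_trait_model, predict_trait

__all__ = ["CalibrationModel", "fit_calibration", "apply_calibration",
           "calibrated_robustness"]


@dataclass
class CalibrationModel:
    """Affine map calibrated = intercept + slope · predicted."""

    intercept: float
    slope: float
    n_anchors: int
    anchor_residual_sd: float


def fit_calibration(pred_parents, obs_parents) -> CalibrationModel:
    """Least-squares line observed = intercept + slope · predicted over anchors."""
    pred = np.asarray(pred_parents, dtype=float)
    obs = np.asarray(obs_parents, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise ValueError("predicted and observed anchor values must be equal-length vectors")
    if pred.size < 2:
        raise ValueError("calibration needs at least 2 anchors")
    if np.ptp(pred) == 0:
        raise ValueError("anchor predicted values are identical; calibration degenerate")
    slope, intercept = np.polyfit(pred, obs, 1)
    resid = obs - (intercept + slope * pred)
    sd = float(np.std(resid, ddof=min(2, pred.size - 1))) if pred.size > 2 else 0.0
    return CalibrationModel(intercept=float(intercept), slope=float(slope),
                            n_anchors=int(pred.size), anchor_residual_sd=sd)


def apply_calibration(model: CalibrationModel, predictions) -> np.ndarray:
    """Elementwise affine correction of predictions."""
    return model.intercept + model.slope * np.asarray(predictions, dtype=float)


def calibrated_robustness(train: pd.DataFrame, test: pd.DataFrame,
                          spec: ModelSpec, trait: str) -> dict:
    """Run the five-step calibration and report metrics before and after.

    ``train`` and ``test`` hold predictor columns, the trait and an
    ``is_parent`` flag; the test condition must contain flagged parents
    with observed traits.  Returns rmse/cor before and after calibration
    (computed on non-parent lines) plus the calibration model.
    """
    if "is_parent" not in test.columns or not test["is_parent"].any():
        raise ValueError("test condition contains no parental cultivars")
    fit = fit_trait_model(spec, train, train, trait)

    lines = test[~test["is_parent"].astype(bool)]
    parents = test[test["is_parent"].astype(bool)]
    if len(lines) == 0:
        raise ValueError("test condition contains no non-parent lines")

    pred_lines = predict_trait(fit, lines)
    pred_parents = predict_trait(fit, parents)
    cal = fit_calibration(pred_parents, parents[trait].to_numpy(dtype=float))
    calibrated = apply_calibration(cal, pred_lines)

    obs = lines[trait].to_numpy(dtype=float)
    return {
        "rmse_before": rmse(pred_lines, obs),
        "rmse_after": rmse(calibrated, obs),
        "cor_before": pearson_cor(pred_lines, obs),
        "cor_after": pearson_cor(calibrated, obs),
        "calibration": cal,
        "predictions": pd.DataFrame({
            "line_id": lines["line_id"].to_numpy() if "line_id" in lines else np.arange(len(lines)),
            "observed": obs, "predicted": pred_lines, "calibrated": calibrated}),
    }
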