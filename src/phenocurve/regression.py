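"""Linear trait-prediction models on growth-curve parameters.

Six model specifications predict each manually measured trait from the
canopy-height and/or CIg curve parameters: CH, CIg or Hybrid predictor
pools, each either in full or reduced by backward variance-inflation-factor
(VIF) selection.  The canonical selected sets — {K, d0, d1} for CH and
{r2, d2, d3, ymax} for CIg — are frozen defaults; data-driven re-selection
is available behind an explicit call.  Fits are ordinary least squares with
an intercept; coefficient p-values are two-sided t-tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "CH_PARAMS",
    "CIG_PARAMS",
    "MODEL_SPECS",
    "ModelSpec",
    "RegressionFit",
    "compute_vif",
    "backward_vif_selection",
    "fit_trait_model",
    "predict_trait",
]

log = logging.getLogger(__name__)

CH_PARAMS = ("K", "r1", "d0", "d1", "a")
CIG_PARAMS = ("ymax", "r2", "r3", "d2", "d3")

#: canonical tie-break / removal ordering for backward selection
PARAM_ORDER = ("K", "r1", "d0", "d1", "a", "ymax", "r2", "r3", "d2", "d3")


@dataclass(frozen=True)
class ModelSpec:
    """A named, ordered predictor set."""

    name: str
    predictors: tuple[str, ...]


MODEL_SPECS: dict[str, ModelSpec] = {
    "CH-selected": ModelSpec("CH-selected", ("K", "d0", "d1")),
    "CIg-selected": ModelSpec("CIg-selected", ("r2", "d2", "d3", "ymax")),
    "Hybrid-selected": ModelSpec("Hybrid-selected",
                                 ("K", "d0", "d1", "r2", "d2", "d3", "ymax")),
    "CH-full": ModelSpec("CH-full", CH_PARAMS),
    "CIg-full": ModelSpec("CIg-full", CIG_PARAMS),
    "Hybrid-full": ModelSpec("Hybrid-full", CH_PARAMS + CIG_PARAMS),
}


@dataclass
class RegressionFit:
    """An OLS fit of one trait on one predictor set."""

    spec: ModelSpec
    trait: str
    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    p_values: dict[str, float]
    n: int
    residual_sd: float = field(default=float("nan"))


def compute_vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each predictor.

    VIF_j = 1 / (1 − R²_j) with R²_j from regressing predictor j on the
    remaining predictors (with intercept).  Exact collinearity yields +inf
    with a logged warning.
    """
    if design.shape[1] < 2:
        raise ValueError("VIF needs at least 2 predictors")
    if len(design) <= design.shape[1] + 1:
        raise ValueError("VIF needs n > number of predictors + 1")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=[col]).to_numpy(dtype=float))
        r2 = sm.OLS(design[col].to_numpy(dtype=float), others).fit().rsquared
        if r2 >= 1.0 - 1e-12:
            log.warning("compute_vif: predictor %r is exactly collinear", col)
            out[col] = float("inf")
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="VIF")


def backward_vif_selection(design: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Drop the largest-VIF predictor until all VIFs fall below ``threshold``.

    Ties are broken by the canonical parameter order (earlier kept last,
    i.e. the later-ordered of two tied predictors is removed first), so the
    procedure is deterministic.  Returns the kept predictors in input order.
    """
    kept = list(design.columns)
    while len(kept) >= 2:
        vifs = compute_vif(design[kept])
        if vifs.max() < threshold:
            break
        worst = vifs.max()
        tied = [c for c in kept if vifs[c] >= worst - 1e-12]
        order = {n: i for i, n in enumerate(PARAM_ORDER)}
        drop = max(tied, key=lambda c: order.get(c, len(order)))
        kept.remove(drop)
    return kept


def fit_trait_model(spec: ModelSpec, params: pd.DataFrame, traits: pd.DataFrame,
                    trait: str) -> RegressionFit:
    """OLS fit of ``trait`` on ``spec.predictors`` over matched line_ids.

    ``params`` and ``traits`` are joined on ``line_id`` when both carry it;
    otherwise they must be row-aligned.  Incomplete rows are dropped with a
    logged count.
    """
    missing = [p for p in spec.predictors if p not in params.columns]
    if missing:
        raise ValueError(f"params table missing predictor(s): {missing}")
    if "line_id" in params.columns and "line_id" in traits.columns:
        merged = params[["line_id", *spec.predictors]].merge(
            traits[["line_id", trait]], on="line_id", how="inner")
    else:
        if len(params) != len(traits):
            raise ValueError("params and traits must be row-aligned or share line_id")
        merged = pd.concat([params[list(spec.predictors)].reset_index(drop=True),
                            traits[[trait]].reset_index(drop=True)], axis=1)
    n_before = len(merged)
    merged = merged.dropna(subset=[*spec.predictors, trait])
    if len(merged) < n_before:
        log.info("fit_trait_model: dropped %d incomplete row(s)", n_before - len(merged))
    if len(merged) <= len(spec.predictors) + 1:
        raise ValueError("too few complete cases for OLS")

    X = sm.add_constant(merged[list(spec.predictors)].to_numpy(dtype=float))
    if np.linalg.matrix_rank(X) < X.shape[1]:
        vifs = compute_vif(merged[list(spec.predictors)])
        bad = [c for c, v in vifs.items() if not np.isfinite(v)]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad or list(spec.predictors)}")
    res = sm.OLS(merged[trait].to_numpy(dtype=float), X).fit()
    return RegressionFit(
        spec=spec, trait=trait, intercept=float(res.params[0]),
        coefficients={p: float(c) for p, c in zip(spec.predictors, res.params[1:])},
        r_squared=float(res.rsquared),
        p_values={p: float(v) for p, v in zip(spec.predictors, res.pvalues[1:])},
        n=int(res.nobs), residual_sd=float(np.sqrt(res.mse_resid)))


def predict_trait(fit: RegressionFit, params: pd.DataFrame) -> np.ndarray:
    """Vectorised ŷ = intercept + Σ coef·param over the rows of ``params``."""
    missing = [p for p in fit.coefficients if p not in params.columns]
    if missing:
        raise ValueError(f"params table missing predictor(s): {missing}")
    yhat = np.full(len(params), fit.intercept, dtype=float)
    for p, c in fit.coefficients.items():
        yhat += c * params[p].to_numpy(dtype=float)
    return yhat
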