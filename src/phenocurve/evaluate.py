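"""Validation schemes for the trait-prediction models.

Four schemes: *fitness* (R² of the model refit on all data of one
protocol × year), *accuracy* (10-fold cross-validation repeated 100 times
with random refolds; per repetition the held-out predictions of all folds
are pooled before computing RMSE and Pearson correlation, and the mean and
sd across repetitions are reported), *type-1 robustness* (train on one
transplanting protocol, test on the other) and *type-2 robustness* (train
on one year, test on the next).  Plus summary statistics and pairwise
correlations among traits and parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold

from .regression import ModelSpec, fit_trait_model, predict_trait

__all__ = ["EvalResult", "rmse", "pearson_cor", "repeated_kfold_cv",
           "cross_condition_eval", "summarize"]

log = logging.getLogger(__name__)


@dataclass
class EvalResult:
    """Metrics of one scheme × model × trait combination."""

    scheme: str  # fitness | accuracy | type1 | type2
    spec_name: str
    trait: str
    rmse: float
    cor: float
    train_condition: str = ""
    test_condition: str = ""
    r_squared: float = float("nan")   # fitness only
    rmse_sd: float = float("nan")     # accuracy only
    cor_sd: float = float("nan")      # accuracy only
    predictions: pd.DataFrame | None = None


def rmse(pred, obs) -> float:
    """Root mean squared error."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size == 0 or pred.shape != obs.shape:
        raise ValueError("pred and obs must be non-empty and equally shaped")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def pearson_cor(pred, obs) -> float:
    """Pearson product-moment correlation; ValueError on degenerate input."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if np.std(pred) == 0 or np.std(obs) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(pred, obs)[0])


def repeated_kfold_cv(data: pd.DataFrame, spec: ModelSpec, trait: str,
                      k: int = 10, reps: int = 100, seed: int = 0) -> EvalResult:
    """Repeated unstratified k-fold cross-validation of one model on one trait.

    ``data`` holds predictor columns and the trait for a single
    protocol × year.  Deterministic given ``seed``.
    """
    data = data.reset_index(drop=True)
    n = len(data)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    rmses, cors = [], []
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**32 - 1)
    for rep in range(reps):
        kf = KFold(n_splits=k, shuffle=True, random_state=int(rep_seeds[rep]))
        pooled_pred = np.empty(n)
        for train_idx, test_idx in kf.split(data):
            fit = fit_trait_model(spec, data.iloc[train_idx], data.iloc[train_idx], trait)
            pooled_pred[test_idx] = predict_trait(fit, data.iloc[test_idx])
        obs = data[trait].to_numpy(dtype=float)
        rmses.append(rmse(pooled_pred, obs))
        cors.append(pearson_cor(pooled_pred, obs))
    return EvalResult(scheme="accuracy", spec_name=spec.name, trait=trait,
                      rmse=float(np.mean(rmses)), cor=float(np.mean(cors)),
                      rmse_sd=float(np.std(rmses, ddof=1)) if reps > 1 else 0.0,
                      cor_sd=float(np.std(cors, ddof=1)) if reps > 1 else 0.0)


def training_fitness(data: pd.DataFrame, spec: ModelSpec, trait: str) -> EvalResult:
    """Goodness of fit of the model refit on all rows of one condition."""
    fit = fit_trait_model(spec, data, data, trait)
    pred = predict_trait(fit, data)
    obs = data[trait].to_numpy(dtype=float)
    return EvalResult(scheme="fitness", spec_name=spec.name, trait=trait,
                      rmse=rmse(pred, obs), cor=pearson_cor(pred, obs),
                      r_squared=fit.r_squared)


def cross_condition_eval(train: pd.DataFrame, test: pd.DataFrame,
                         spec: ModelSpec, trait: str,
                         scheme: str = "type1") -> EvalResult:
    """Train on one condition, evaluate on a disjoint one.

    Predictions are retained in the result for downstream calibration.
    """
    if len(test) == 0:
        raise ValueError("empty test set")
    fit = fit_trait_model(spec, train, train, trait)
    pred = predict_trait(fit, test)
    obs = test[trait].to_numpy(dtype=float)
    preds = test.copy()
    preds["predicted"] = pred
    return EvalResult(scheme=scheme, spec_name=spec.name, trait=trait,
                      rmse=rmse(pred, obs), cor=pearson_cor(pred, obs),
                      predictions=preds)


def summarize(table: pd.DataFrame, columns: list[str] | None = None) -> dict:
    """Summary statistics, pairwise correlations, and R-vs-D trait correlations.

    Returns ``{"stats": per-column mean/var/max/min, "correlations":
    correlation matrix, "protocol_correlations": per-trait correlation of
    matched line_ids between the two protocols (when a protocol column with
    exactly two levels is present)}``.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    num = table[columns] if columns else table.select_dtypes(include=[np.number])
    num = num.drop(columns=[c for c in ("year",) if c in num.columns])
    stats_df = pd.DataFrame({"mean": num.mean(), "variance": num.var(ddof=1),
                             "max": num.max(), "min": num.min()})
    out = {"stats": stats_df, "correlations": num.corr(method="pearson")}

    if "protocol" in table.columns and table["protocol"].nunique() == 2:
        p1, p2 = sorted(table["protocol"].unique())
        a = table[table["protocol"] == p1].set_index("line_id")
        b = table[table["protocol"] == p2].set_index("line_id")
        common = a.index.intersection(b.index)
        dropped = len(set(a.index).symmetric_difference(b.index))
        if dropped:
            log.warning("summarize: %d unmatched line_id(s) dropped", dropped)
        proto_cor = {}
        for col in num.columns:
            if col in a.columns and len(common) >= 3:
                proto_cor[col] = pearson_cor(a.loc[common, col], b.loc[common, col])
        out["protocol_correlations"] = pd.Series(proto_cor)
    return out
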