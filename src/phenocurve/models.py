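"""Time-series growth models for canopy height (CH) and chlorophyll index green (CIg).

Two model families describe one season of rice growth as a function of
``x`` = days after transplanting:

* **Modified three-parameter logistic** (CH, cm).  A logistic rise to a
  plateau ``K`` followed, after day ``d1``, by a quadratic decline::

      y(x) = K / (1 + exp(r1 * (d0 - x)))                     x <= d1
      y(x) = K / (1 + exp(r1 * (d0 - x))) - a * (x - d1)**2   x >  d1

  ``K`` is the maximum canopy height, ``r1`` the growth rate before the
  peak, ``d0`` the day of maximum growth rate, ``d1`` the day the maximum
  is reached and ``a`` the late decrease rate.  The curve is continuous at
  ``d1`` (the quadratic term vanishes there).

* **Double logistic** (CIg, unitless).  A rise phase minus a fall phase::

      y(x) = ymax * (1 / (1 + exp(r2 * (d2 - x)))
                     - 1 / (1 + exp(r3 * (d3 - x))))

  ``d2``/``d3`` are the days of maximum increase/decrease, ``r2``/``r3``
  the corresponding rates, ``ymax`` the scale.

Fitting is bounded nonlinear least squares (scipy ``least_squares``,
trust-region reflective).  The CH fit profiles over a grid of candidate
``d1`` values and then polishes all five parameters jointly; the CIg fit
fixes ``ymax`` at the observed maximum and estimates the remaining four
parameters from the conventional starting point (0.05, 0.05, 40, 100),
with a small multi-start fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "CHParams",
    "CIgParams",
    "ObservationSeries",
    "FitResult",
    "evaluate_ch_model",
    "evaluate_cig_model",
    "fit_ch_model",
    "fit_cig_model",
    "goodness_of_fit",
    "compare_models",
    "CIG_INITIAL_VALUES",
]

#: Conventional starting values for (r2, r3, d2, d3) of the double logistic.
CIG_INITIAL_VALUES = (0.05, 0.05, 40.0, 100.0)

_RATE_LO, _RATE_HI = 1e-4, 1.0


@dataclass(frozen=True)
class CHParams:
    """Parameters of the modified three-parameter logistic CH model."""

    K: float
    r1: float
    d0: float
    d1: float
    a: float

    def __post_init__(self) -> None:
        if self.K <= 0:
            raise ValueError(f"K must be positive, got {self.K}")
        if self.r1 <= 0:
            raise ValueError(f"r1 must be positive, got {self.r1}")
        if self.a < 0:
            raise ValueError(f"a must be non-negative, got {self.a}")
        if self.d0 > self.d1:
            raise ValueError(f"d0 ({self.d0}) must not exceed d1 ({self.d1})")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class CIgParams:
    """Parameters of the double logistic CIg model."""

    ymax: float
    r2: float
    r3: float
    d2: float
    d3: float

    def __post_init__(self) -> None:
        if self.ymax <= 0:
            raise ValueError(f"ymax must be positive, got {self.ymax}")
        if self.r2 <= 0 or self.r3 <= 0:
            raise ValueError(f"rates must be positive, got r2={self.r2}, r3={self.r3}")
        if self.d2 >= self.d3:
            raise ValueError(f"d2 ({self.d2}) must be below d3 ({self.d3})")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass
class ObservationSeries:
    """One line's time series of CH or CIg against days after transplanting."""

    line_id: str
    variable: str  # "CH" or "CIg"
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.variable not in ("CH", "CIg"):
            raise ValueError(f"variable must be 'CH' or 'CIg', got {self.variable!r}")
        if self.x.ndim != 1 or self.x.shape != self.y.shape:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(self.x) >= 2 and not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class FitResult:
    """Outcome of fitting one model family to one observation series."""

    params: CHParams | CIgParams | None
    r_squared: float
    sse: float
    converged: bool
    n_obs: int
    model: str = ""
    fitted: np.ndarray | None = field(default=None, repr=False)


def _logistic(x: np.ndarray, K: float, r1: float, d0: float) -> np.ndarray:
    # clip the exponent so extreme search points stay finite
    z = np.clip(r1 * (d0 - x), -700.0, 700.0)
    return K / (1.0 + np.exp(z))


def evaluate_ch_model(x, p: CHParams) -> np.ndarray | float:
    """Canopy height (cm) at day(s) ``x`` under the modified logistic model."""
    xa = np.asarray(x, dtype=float)
    y = _logistic(xa, p.K, p.r1, p.d0)
    late = xa > p.d1
    y = np.where(late, y - p.a * (xa - p.d1) ** 2, y)
    return float(y) if np.isscalar(x) else y


def evaluate_cig_model(x, p: CIgParams) -> np.ndarray | float:
    """CIg at day(s) ``x`` under the double logistic model."""
    xa = np.asarray(x, dtype=float)
    y = p.ymax * (
        1.0 / (1.0 + np.exp(np.clip(p.r2 * (p.d2 - xa), -700, 700)))
        - 1.0 / (1.0 + np.exp(np.clip(p.r3 * (p.d3 - xa), -700, 700)))
    )
    return float(y) if np.isscalar(x) else y


def goodness_of_fit(y_obs, y_fit) -> float:
    """Coefficient of determination R² = 1 - SSE/SST.

    Raises ``ValueError`` on series shorter than 2 or with zero variance.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    y_fit = np.asarray(y_fit, dtype=float)
    if y_obs.size < 2:
        raise ValueError("need at least 2 observations for R²")
    sst = float(np.sum((y_obs - y_obs.mean()) ** 2))
    if sst == 0.0:
        raise ValueError("R² undefined for a zero-variance series")
    sse = float(np.sum((y_obs - y_fit) ** 2))
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# CH fitting: profiled multi-start over d1, then joint polish
# ---------------------------------------------------------------------------

def _ch_curve_vec(theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    K, r1, d0, d1, a = theta
    y = _logistic(x, K, r1, d0)
    late = x > d1
    return np.where(late, y - a * (x - d1) ** 2, y)


def fit_ch_model(series: ObservationSeries, *, max_nfev: int = 500) -> FitResult:
    """Fit the modified three-parameter logistic to a CH series.

    Profiles over a grid of candidate ``d1`` values spanning the observed
    day range (step = median observation interval), fitting (K, r1, d0, a)
    at each, then polishes all five parameters jointly from the best grid
    point with ``d1`` reparametrised as ``d0 + delta`` (delta >= 0) so the
    ordering constraint holds exactly.  Deterministic: no random starts.
    """
    if series.variable != "CH":
        raise ValueError("fit_ch_model expects a CH series")
    x, y = series.x, series.y
    n = len(x)
    if n < 6:
        raise ValueError(f"need at least 6 observations to fit the CH model, got {n}")
    if np.ptp(y) == 0.0:
        return FitResult(None, float("nan"), float("nan"), False, n, model="ch_logistic")

    ymax_obs = float(np.max(y))
    step = float(np.median(np.diff(x)))
    d1_grid = np.arange(float(x[0]), float(x[-1]) + step / 2, step)
    half = ymax_obs / 2.0
    d0_init = float(x[np.argmin(np.abs(y - half))])

    lo4 = np.array([1e-6, _RATE_LO, 0.0, 0.0])
    best_sse = np.inf
    best = None  # (theta5, result)
    for d1 in d1_grid:
        def resid4(t, d1=d1):
            return _ch_curve_vec(np.array([t[0], t[1], t[2], d1, t[3]]), x) - y

        hi4 = np.array([2.0 * ymax_obs, _RATE_HI, d1, 1.0])
        t0 = np.array(
            [ymax_obs, 0.05, min(max(d0_init, 0.0), d1), 0.0]
        )
        t0 = np.clip(t0, lo4 + 1e-9, hi4 - 1e-12)
        try:
            res = least_squares(
                resid4, t0, bounds=(lo4, hi4), xtol=1e-10, ftol=1e-10,
                gtol=1e-10, max_nfev=max_nfev,
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if sse < best_sse:
            best_sse = sse
            best = np.array([res.x[0], res.x[1], res.x[2], d1, res.x[3]])

    if best is None:
        return FitResult(None, float("nan"), float("nan"), False, n, model="ch_logistic")

    # joint polish; parametrise d1 = d0 + delta to keep d0 <= d1
    K0, r10, d00, d10, a0 = best

    def resid5(t):
        K, r1, d0, delta, a = t
        return _ch_curve_vec(np.array([K, r1, d0, d0 + delta, a]), x) - y

    lo5 = np.array([1e-6, _RATE_LO, 0.0, 0.0, 0.0])
    hi5 = np.array([2.0 * ymax_obs, _RATE_HI, float(x[-1]) + 30.0,
                    float(x[-1]) + 30.0, 1.0])
    t0 = np.clip(np.array([K0, r10, d00, max(d10 - d00, 0.0), a0]),
                 lo5 + 1e-9, hi5 - 1e-12)
    res = least_squares(resid5, t0, bounds=(lo5, hi5), xtol=1e-10, ftol=1e-10,
                        gtol=1e-10, max_nfev=max_nfev)
    sse5 = float(2.0 * res.cost)
    if sse5 <= best_sse:
        best_sse = sse5
        best = np.array([res.x[0], res.x[1], res.x[2], res.x[2] + res.x[3], res.x[4]])

    params = CHParams(K=float(best[0]), r1=float(max(best[1], _RATE_LO)),
                      d0=float(best[2]), d1=float(best[3]), a=float(best[4]))
    fitted = _ch_curve_vec(best, x)
    try:
        r2 = goodness_of_fit(y, fitted)
    except ValueError:
        r2 = float("nan")
    return FitResult(params, r2, best_sse, True, n, model="ch_logistic", fitted=fitted)


# ---------------------------------------------------------------------------
# CIg fitting: ymax fixed at observed maximum, four free parameters
# ---------------------------------------------------------------------------

def _dl_curve(t: np.ndarray, ymax: float, x: np.ndarray) -> np.ndarray:
    r2, r3, d2, d3 = t
    return ymax * (
        1.0 / (1.0 + np.exp(np.clip(r2 * (d2 - x), -700, 700)))
        - 1.0 / (1.0 + np.exp(np.clip(r3 * (d3 - x), -700, 700)))
    )


def fit_cig_model(series: ObservationSeries, *, max_nfev: int = 500,
                  initial: Sequence[float] = CIG_INITIAL_VALUES) -> FitResult:
    """Fit the double logistic with ``ymax`` fixed at the series maximum.

    (r2, r3, d2, d3) start from ``initial``; if that start fails to
    converge or leaves an invalid parameter ordering, a small deterministic
    multi-start over shifted day anchors is tried and the best SSE kept.
    """
    if series.variable not in ("CIg", "CH"):
        raise ValueError("fit_cig_model expects a CIg (or CH) series")
    x, y = series.x, series.y
    n = len(x)
    if n < 5:
        raise ValueError(f"need at least 5 observations to fit the double logistic, got {n}")
    if np.ptp(y) == 0.0:
        return FitResult(None, float("nan"), float("nan"), False, n, model="double_logistic")

    ymax = float(np.max(y))
    if ymax <= 0:
        return FitResult(None, float("nan"), float("nan"), False, n, model="double_logistic")

    lo = np.array([_RATE_LO, _RATE_LO, 0.0, 0.0])
    hi = np.array([_RATE_HI, _RATE_HI, float(x[-1]) + 30.0, float(x[-1]) + 30.0])

    starts = [np.asarray(initial, dtype=float)]
    x_peak = float(x[np.argmax(y)])
    for shift in (0.0, -14.0, 14.0):
        starts.append(np.array([0.1, 0.1,
                                max(x_peak / 2.0 + shift, 1.0),
                                min(x_peak * 1.5 + shift, hi[3] - 1.0)]))

    best_sse = np.inf
    best_t = None
    for k, t0 in enumerate(starts):
        t0 = np.clip(t0, lo + 1e-9, hi - 1e-9)
        try:
            res = least_squares(
                lambda t: _dl_curve(t, ymax, x) - y, t0, bounds=(lo, hi),
                xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=max_nfev,
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if res.x[2] < res.x[3] and sse < best_sse:
            best_sse = sse
            best_t = res.x
        if k == 0 and best_t is not None and best_sse <= float(
            np.sum((_dl_curve(t0, ymax, x) - y) ** 2)
        ) and sse / max(np.sum(y**2), 1e-12) < 1e-8:
            break  # conventional start already explains the series

    if best_t is None:
        return FitResult(None, float("nan"), float("nan"), False, n, model="double_logistic")

    params = CIgParams(ymax=ymax, r2=float(best_t[0]), r3=float(best_t[1]),
                       d2=float(best_t[2]), d3=float(best_t[3]))
    fitted = _dl_curve(best_t, ymax, x)
    try:
        r2 = goodness_of_fit(y, fitted)
    except ValueError:
        r2 = float("nan")
    return FitResult(params, r2, best_sse, True, n, model="double_logistic", fitted=fitted)


def compare_models(series: ObservationSeries, *, policy: str | None = None) -> dict:
    """Fit both model families to one series and report both R².

    ``preferred`` is the family with the larger R²; ties (within 1e-12) go
    to the policy default for the variable — the three-parameter logistic
    for CH, the double logistic for CIg.  ``policy="ch_logistic"`` forces
    the CH choice regardless of R², reflecting the convention of keeping
    the logistic model for canopy height.
    """
    fit3 = None
    if len(series) >= 6:
        ser_ch = ObservationSeries(series.line_id, "CH", series.x, series.y)
        fit3 = fit_ch_model(ser_ch)
    ser_cig = ObservationSeries(series.line_id, "CIg", series.x, series.y)
    fitd = fit_cig_model(ser_cig)

    r2_3 = fit3.r_squared if fit3 is not None and fit3.converged else None
    r2_d = fitd.r_squared if fitd.converged else None
    default = "ch_logistic" if series.variable == "CH" else "double_logistic"
    if policy is not None:
        preferred = policy
    elif r2_3 is None or r2_d is None:
        preferred = None
    elif abs(r2_3 - r2_d) <= 1e-12:
        preferred = default
    else:
        preferred = "ch_logistic" if r2_3 > r2_d else "double_logistic"
    return {
        "r_squared_3param": r2_3,
        "r_squared_double": r2_d,
        "preferred": preferred,
        "fit_3param": fit3,
        "fit_double": fitd,
    }
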