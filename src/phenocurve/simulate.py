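"""Synthetic field campaigns with the statistical structure of a MAGIC rice trial.

The generator emulates a two-protocol (regular R / delayed D transplanting),
two-year trial of ~100 recombinant inbred lines plus four parental
cultivars.  Per line and condition it draws the ten growth-curve
parameters — (K, r1, d0, d1, a) of the modified logistic canopy-height
model and (ymax, r2, r3, d2, d3) of the double logistic CIg model — from a
truncated multivariate Gaussian whose correlation matrix encodes the
empirical cluster structure of such trials: the timing parameters
(d0, d1, d3) move together, the scales (K, ymax) move together, the rates
(r1, r2, r3) move together, and timing and rate clusters are negatively
correlated (fast growers finish early).  A latent per-line genotype effect
shared across conditions gives realistic cross-protocol and cross-year
trait correlations.

Manually measured traits (DTH, CL, SLW, PW; ADW = SLW + PW exactly) are
affine functions of the parameters plus Gaussian noise, on the regular-2022
scale; configurable additive protocol/year offsets inject the prediction
bias that the robustness and calibration stages exist to measure and
correct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import CHParams, CIgParams, ObservationSeries, evaluate_ch_model, evaluate_cig_model

__all__ = [
    "PARAM_NAMES",
    "TRAIT_NAMES",
    "SimulationConfig",
    "default_correlation",
    "simulate_population",
    "simulate_series",
    "simulate_plot_raster",
    "simulate_campaign",
]

PARAM_NAMES = ("K", "r1", "d0", "d1", "a", "ymax", "r2", "r3", "d2", "d3")
TRAIT_NAMES = ("DTH", "CL", "ADW", "SLW", "PW")

# parameters that must stay strictly positive
_POSITIVE = ("K", "r1", "ymax", "r2", "r3")

_DEFAULT_MEANS = {
    # regular transplanting, 2022 scale
    "R": {"K": 100.0, "r1": 0.11, "d0": 42.0, "d1": 76.0, "a": 0.008,
          "ymax": 5.5, "r2": 0.15, "r3": 0.12, "d2": 38.0, "d3": 112.0},
    # delayed transplanting: earlier phenology on the days-after-transplanting
    # axis and faster early growth (warmer establishment conditions)
    "D": {"K": 98.0, "r1": 0.13, "d0": 35.0, "d1": 64.0, "a": 0.008,
          "ymax": 5.2, "r2": 0.18, "r3": 0.125, "d2": 31.0, "d3": 103.0},
}

_DEFAULT_SDS = {"K": 8.0, "r1": 0.012, "d0": 3.5, "d1": 5.5, "a": 0.0015,
                "ymax": 0.45, "r2": 0.018, "r3": 0.012, "d2": 3.0, "d3": 5.5}

# trait = intercept + sum(coef * param) + N(0, noise_sd); ADW = SLW + PW
_DEFAULT_LOADINGS = {
    "DTH": {"intercept": -18.0, "d1": 0.9, "d3": 0.25},
    "CL": {"intercept": -4.0, "K": 0.75, "d0": 0.2},
    "SLW": {"intercept": -28.0, "d1": 0.55, "d3": 0.3, "ymax": 0.2},
    "PW": {"intercept": 54.5, "ymax": 4.5, "d3": -0.35},
}

_DEFAULT_NOISE_TRAIT = {"DTH": 2.0, "CL": 2.5, "SLW": 4.0, "PW": 3.5}

# additive trait offsets of the non-reference conditions (bias the
# robustness schemes see and the parental calibration corrects)
_DEFAULT_PROTOCOL_BIAS = {"DTH": -2.0, "CL": 5.0, "SLW": -4.0, "PW": 3.0}
_DEFAULT_YEAR_BIAS = {"DTH": 4.0, "CL": -4.0, "SLW": 5.0, "PW": -4.0}


# loadings on three latent factors: phenology timing, canopy scale, and a
# rate-specific factor.  The implied correlations show the empirical cluster
# structure of such trials — timing parameters (d0, d1, d3) tightly positive
# (d0–d1 ≈ 0.9), scale parameters (K, ymax) moderately positive, rates
# (r1, r2, r3) positive among themselves and negative against timing
# (fast growers finish early), d2 mildly timing-aligned but opposed to r2 —
# and is positive definite by construction.
_FACTOR_LOADINGS = {
    "K":    (0.10, 0.60, 0.00),
    "r1":   (-0.78, 0.00, 0.38),
    "d0":   (0.95, 0.00, 0.00),
    "d1":   (0.95, 0.00, 0.00),
    "a":    (-0.45, 0.00, 0.40),
    "ymax": (0.10, 0.55, 0.00),
    "r2":   (-0.72, 0.00, 0.50),
    "r3":   (-0.68, 0.00, 0.45),
    "d2":   (0.45, 0.00, -0.20),
    "d3":   (0.92, 0.00, 0.00),
}


def default_correlation() -> pd.DataFrame:
    """Default parameter correlation matrix with the three-cluster structure."""
    lam = np.array([_FACTOR_LOADINGS[n] for n in PARAM_NAMES])
    c = lam @ lam.T
    np.fill_diagonal(c, 1.0)
    return pd.DataFrame(c, index=list(PARAM_NAMES), columns=list(PARAM_NAMES))


def _default_covariance() -> pd.DataFrame:
    sd = np.array([_DEFAULT_SDS[n] for n in PARAM_NAMES])
    corr = default_correlation().to_numpy()
    return pd.DataFrame(corr * np.outer(sd, sd),
                        index=list(PARAM_NAMES), columns=list(PARAM_NAMES))


@dataclass
class SimulationConfig:
    """Configuration of one synthetic campaign.

    ``param_means`` maps protocol → mean of each of the ten model
    parameters; ``param_covariance`` is a single positive-semidefinite
    10×10 matrix shared by the protocols.  ``repeatability`` is the share
    of parameter variance carried by the latent per-line genotype effect
    common to all conditions of a line (the remainder is condition
    specific), which controls cross-protocol/year trait correlations.
    """

    n_lines: int = 100
    n_parents: int = 4
    protocols: tuple[str, ...] = ("R", "D")
    years: tuple[int, ...] = (2022, 2023)
    observation_days: tuple[int, ...] = tuple(range(7, 141, 7))
    param_means: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {p: dict(m) for p, m in _DEFAULT_MEANS.items()})
    param_covariance: pd.DataFrame = field(default_factory=_default_covariance)
    trait_loadings: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {t: dict(l) for t, l in _DEFAULT_LOADINGS.items()})
    noise_sd_series: Mapping[str, float] = field(
        default_factory=lambda: {"CH": 1.0, "CIg": 0.1})
    noise_sd_trait: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_NOISE_TRAIT))
    protocol_trait_bias: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROTOCOL_BIAS))
    year_trait_bias: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_YEAR_BIAS))
    repeatability: float = 0.75
    parents_span_range: bool = True
    parent_span_fraction: float = 0.8
    max_attempts: int = 1000
    seed: int = 0

    def validate(self) -> None:
        cov = np.asarray(self.param_covariance, dtype=float)
        if cov.shape != (len(PARAM_NAMES),) * 2:
            raise ValueError("param_covariance must be 10x10 in the canonical parameter order")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("param_covariance must be symmetric")
        w = np.linalg.eigvalsh((cov + cov.T) / 2.0)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise ValueError("param_covariance must be positive semidefinite")
        if not (0.0 <= self.repeatability <= 1.0):
            raise ValueError("repeatability must lie in [0, 1]")
        for proto in self.protocols:
            m = self.param_means[proto]
            for r in _POSITIVE:
                if m[r] <= 0:
                    raise ValueError(f"mean of {r} must be positive (protocol {proto})")
            if m["d0"] > m["d1"]:
                raise ValueError(f"d0 mean must not exceed d1 mean (protocol {proto})")
            if m["d2"] > m["d3"]:
                raise ValueError(f"d2 mean must not exceed d3 mean (protocol {proto})")
        for t in ("DTH", "CL", "SLW", "PW"):
            if t not in self.trait_loadings:
                raise ValueError(f"trait_loadings missing {t}")


def _valid_params(v: np.ndarray) -> bool:
    p = dict(zip(PARAM_NAMES, v))
    return (all(p[r] > 0 for r in _POSITIVE) and p["a"] >= 0
            and p["d0"] <= p["d1"] and p["d2"] < p["d3"] and p["d0"] > 0 and p["d2"] > 0)


def _clip_valid(v: np.ndarray) -> np.ndarray:
    # deterministic fallback when rejection sampling exhausts its attempts
    p = dict(zip(PARAM_NAMES, v))
    for r in _POSITIVE:
        p[r] = max(p[r], 1e-3)
    p["a"] = max(p["a"], 0.0)
    p["d0"] = max(p["d0"], 1.0)
    p["d2"] = max(p["d2"], 1.0)
    p["d1"] = max(p["d1"], p["d0"])
    p["d3"] = max(p["d3"], p["d2"] + 1.0)
    return np.array([p[n] for n in PARAM_NAMES])


def _draw_condition(rng: np.random.Generator, mean: np.ndarray, g: np.ndarray,
                    chol_e: np.ndarray, max_attempts: int) -> np.ndarray:
    for _ in range(max_attempts):
        v = mean + g + chol_e @ rng.standard_normal(len(PARAM_NAMES))
        if _valid_params(v):
            return v
    return _clip_valid(v)


def _traits_from_params(params: Mapping[str, float],
                        loadings: Mapping[str, Mapping[str, float]],
                        noise: Mapping[str, float],
                        rng: np.random.Generator) -> dict[str, float]:
    out: dict[str, float] = {}
    for trait in ("DTH", "CL", "SLW", "PW"):
        lo = loadings[trait]
        val = lo.get("intercept", 0.0)
        for name, coef in lo.items():
            if name != "intercept":
                val += coef * params[name]
        sd = noise.get(trait, 0.0)
        if sd > 0:
            val += rng.normal(0.0, sd)
        out[trait] = val
    out["ADW"] = out["SLW"] + out["PW"]
    return out


def _span_ratio(parents: pd.DataFrame, lines: pd.DataFrame) -> float:
    ratios = []
    for t in TRAIT_NAMES:
        rng_l = lines[t].max() - lines[t].min()
        if rng_l <= 0:
            continue
        ratios.append((parents[t].max() - parents[t].min()) / rng_l)
    return min(ratios) if ratios else 0.0


def simulate_population(config: SimulationConfig) -> pd.DataFrame:
    """Draw the population table: true parameters and traits per line/condition.

    Returns one row per line × protocol × year with columns ``line_id``,
    ``protocol``, ``year``, ``is_parent``, the ten parameters and the five
    traits.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cov = np.asarray(config.param_covariance, dtype=float)
    # split covariance into shared (genotype) and condition-specific parts
    jitter = 1e-12 * np.eye(len(PARAM_NAMES))
    chol_g = np.linalg.cholesky(config.repeatability * cov + jitter)
    chol_e = np.linalg.cholesky((1.0 - config.repeatability) * cov + jitter)

    conditions = [(p, y) for y in config.years for p in config.protocols]
    means = {p: np.array([config.param_means[p][n] for n in PARAM_NAMES])
             for p in config.protocols}

    def draw_individual(line_id: str, is_parent: bool) -> list[dict]:
        g = chol_g @ rng.standard_normal(len(PARAM_NAMES))
        rows = []
        for proto, year in conditions:
            v = _draw_condition(rng, means[proto], g, chol_e, config.max_attempts)
            params = dict(zip(PARAM_NAMES, v))
            traits = _traits_from_params(params, config.trait_loadings,
                                         config.noise_sd_trait, rng)
            if proto != config.protocols[0]:
                for t in ("DTH", "CL", "SLW", "PW"):
                    traits[t] += config.protocol_trait_bias.get(t, 0.0)
            if year != config.years[0]:
                for t in ("DTH", "CL", "SLW", "PW"):
                    traits[t] += config.year_trait_bias.get(t, 0.0)
            traits["ADW"] = traits["SLW"] + traits["PW"]
            rows.append({"line_id": line_id, "protocol": proto, "year": year,
                         "is_parent": is_parent, **params, **traits})
        return rows

    rows: list[dict] = []
    for i in range(config.n_lines):
        rows.extend(draw_individual(f"L{i + 1:03d}", False))
    lines_df = pd.DataFrame(rows)

    # parents: same distribution, optionally rejected until they span the
    # line trait range; best-spanning attempt kept if the target is not met
    ref = lines_df[(lines_df["protocol"] == config.protocols[0])
                   & (lines_df["year"] == config.years[0])]
    best_rows: list[dict] | None = None
    best_span = -1.0
    attempts = config.max_attempts if config.parents_span_range else 1
    for _ in range(attempts):
        cand: list[dict] = []
        for j in range(config.n_parents):
            cand.extend(draw_individual(f"P{j + 1}", True))
        cand_df = pd.DataFrame(cand)
        sub = cand_df[(cand_df["protocol"] == config.protocols[0])
                      & (cand_df["year"] == config.years[0])]
        span = _span_ratio(sub, ref) if len(ref) else 1.0
        if span > best_span:
            best_span, best_rows = span, cand
        if not config.parents_span_range or span >= config.parent_span_fraction:
            break
    rows.extend(best_rows or [])

    df = pd.DataFrame(rows)
    df.attrs["parent_span_achieved"] = best_span
    return df


def true_ch_params(row: Mapping[str, float]) -> CHParams:
    return CHParams(K=row["K"], r1=row["r1"], d0=row["d0"], d1=row["d1"], a=row["a"])


def true_cig_params(row: Mapping[str, float]) -> CIgParams:
    return CIgParams(ymax=row["ymax"], r2=row["r2"], r3=row["r3"],
                     d2=row["d2"], d3=row["d3"])


def _peak_day(params: CIgParams, days: Sequence[float]) -> float:
    grid = np.linspace(min(days), max(days), 2000)
    return float(grid[np.argmax(evaluate_cig_model(grid, params))])


def simulate_series(true_params: CHParams | CIgParams, days: Sequence[float],
                    noise_sd: float, seed: int, *, line_id: str = "sim",
                    include_peak_day: bool = False) -> ObservationSeries:
    """One noisy observation series from a true curve.

    ``include_peak_day`` inserts the (rounded) day of the noiseless curve
    maximum into the observation days — useful for oracles that rely on the
    observed maximum approximating the curve supremum.
    """
    days = np.asarray(list(days), dtype=float)
    if days.size == 0:
        raise ValueError("days must be non-empty")
    if np.any(days < 0) or not np.all(np.diff(days) > 0):
        raise ValueError("days must be non-negative and strictly increasing")
    rng = np.random.default_rng(seed)
    if isinstance(true_params, CHParams):
        variable = "CH"
        y_true = np.asarray(evaluate_ch_model(days, true_params), dtype=float)
    else:
        variable = "CIg"
        if include_peak_day:
            days = np.unique(np.append(days, round(_peak_day(true_params, days))))
        y_true = np.asarray(evaluate_cig_model(days, true_params), dtype=float)
    y = y_true + (rng.normal(0.0, noise_sd, days.size) if noise_sd > 0 else 0.0)
    if variable == "CH":
        y = np.maximum(y, 0.0)
    return ObservationSeries(line_id=line_id, variable=variable, x=days, y=y)


def simulate_plot_raster(target_ch: float, target_cig: float,
                         shape: tuple[int, int] = (40, 40), seed: int = 0,
                         *, ground_level: float = 10.0,
                         dsm_units: str = "cm") -> dict:
    """A heterogeneous plot raster whose extraction statistics are forced.

    The DSM is shifted so its 95th percentile (linear interpolation) minus
    ``ground_level`` equals ``target_ch`` exactly; the per-pixel NIR/green
    ratios are rescaled so their mean equals ``target_cig`` exactly.
    """
    if target_ch < 0:
        raise ValueError("target_ch must be non-negative")
    if target_cig <= 0:
        raise ValueError("target_cig must be positive")
    rows, cols = shape
    if rows < 20 or cols < 20:
        raise ValueError("raster must be at least 20x20 pixels")
    rng = np.random.default_rng(seed)

    dsm = rng.normal(0.0, 3.0, size=shape)
    p95 = np.percentile(dsm, 95, method="linear")
    dsm = dsm - p95 + ground_level + target_ch  # percentile is shift-equivariant

    green = rng.uniform(0.05, 0.25, size=shape)
    ratio = rng.uniform(0.5, 1.5, size=shape)
    ratio *= target_cig / ratio.mean()
    nir = green * ratio
    scale = max(nir.max(), 1.0 - 1e-12)  # keep reflectances within [0, 1]
    return {"dsm": dsm, "nir": nir / scale, "green": green / scale,
            "ground_level": ground_level, "dsm_units": dsm_units}


def simulate_campaign(config: SimulationConfig) -> dict[str, pd.DataFrame]:
    """Population plus per-line noisy CH and CIg series.

    Returns ``{"population": ..., "series": ...}`` where ``series`` is the
    long table (line_id, protocol, year, variable, day, value).
    """
    pop = simulate_population(config)
    seed_seq = np.random.SeedSequence(config.seed)
    noise = config.noise_sd_series
    rows = []
    child_seeds = iter(seed_seq.spawn(2 * len(pop)))
    for _, row in pop.iterrows():
        for variable in ("CH", "CIg"):
            tp = true_ch_params(row) if variable == "CH" else true_cig_params(row)
            sub_seed = int(next(child_seeds).generate_state(1)[0] % (2**31))
            ser = simulate_series(tp, config.observation_days,
                                  noise.get(variable, 0.0), sub_seed,
                                  line_id=str(row["line_id"]))
            for d, v in zip(ser.x, ser.y):
                rows.append({"line_id": row["line_id"], "protocol": row["protocol"],
                             "year": row["year"], "variable": variable,
                             "day": int(d), "value": v})
    series = pd.DataFrame(rows)
    return {"population": pop, "series": series}
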