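"""CSV/YAML interfaces for series, trait and parameter tables.

Schemas (long form):

* ``series.csv`` — line_id, protocol, year, variable ∈ {CH, CIg}, day, value
* ``traits.csv`` — line_id, protocol, year, is_parent, DTH, CL, ADW, SLW, PW
* ``params.csv`` — line_id, protocol, year, plus any of the ten model
  parameters and per-variable fit diagnostics

Unknown columns are preserved on read; days parse as integers, values as
floats.  An ADW ≠ SLW + PW discrepancy beyond tolerance is logged as a
warning but the row is kept.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

__all__ = ["read_series_csv", "write_series_csv", "read_traits_csv",
           "write_traits_csv", "read_params_csv", "write_params_csv",
           "load_config_yaml"]

log = logging.getLogger(__name__)

SERIES_COLUMNS = ("line_id", "protocol", "year", "variable", "day", "value")
TRAIT_COLUMNS = ("line_id", "protocol", "year", "is_parent",
                 "DTH", "CL", "ADW", "SLW", "PW")

_ADW_TOL = 0.51  # rounding slack on ADW = SLW + PW


def _require(df: pd.DataFrame, columns: tuple[str, ...], path: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


def read_series_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, SERIES_COLUMNS, str(path))
    bad = ~df["variable"].isin(["CH", "CIg"])
    if bad.any():
        row = int(df.index[bad][0])
        raise ValueError(f"{path}: row {row}: variable must be CH or CIg")
    df["day"] = df["day"].astype(int)
    df["value"] = df["value"].astype(float)
    df["year"] = df["year"].astype(int)
    return df


def write_series_csv(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, SERIES_COLUMNS, "series table")
    df.to_csv(path, index=False)


def read_traits_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, TRAIT_COLUMNS, str(path))
    df["year"] = df["year"].astype(int)
    df["is_parent"] = df["is_parent"].astype(bool)
    for t in ("DTH", "CL", "ADW", "SLW", "PW"):
        df[t] = df[t].astype(float)
    mismatch = (df["ADW"] - df["SLW"] - df["PW"]).abs() > _ADW_TOL
    for row in df.index[mismatch]:
        log.warning("%s: row %d: ADW != SLW + PW beyond tolerance (kept)", path, row)
    return df


def write_traits_csv(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, TRAIT_COLUMNS, "trait table")
    df.to_csv(path, index=False)


def read_params_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ("line_id", "protocol", "year"), str(path))
    df["year"] = df["year"].astype(int)
    return df


def write_params_csv(df: pd.DataFrame, path: str | Path) -> None:
    _require(df, ("line_id", "protocol", "year"), "parameter table")
    df.to_csv(path, index=False)


def load_config_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg
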