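"""Plot-level canopy height and CIg extraction from cut-out raster grids.

Canopy height is the 95th percentile of the plot's digital surface model
(DSM) minus the bare-ground level; CIg is the plot mean of the per-pixel
ratio of NIR to green reflectance.  Plot geometry is a thin helper that
cuts 0-based half-open pixel rectangles out of field-level band matrices;
georeferencing is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PlotRaster", "compute_canopy_height", "compute_plot_cig", "cut_plots"]

log = logging.getLogger(__name__)

_M_TO_CM = 100.0


@dataclass
class PlotRaster:
    """One plot's cut-out grids: DSM heights plus NIR and green reflectance.

    ``dsm_units`` declares the DSM/ground-level unit ("m" or "cm"); missing
    pixels are NaN.  Reflectance grids are unitless in [0, 1].
    """

    dsm: np.ndarray
    nir: np.ndarray
    green: np.ndarray
    ground_level: float
    dsm_units: str = "m"

    def __post_init__(self) -> None:
        self.dsm = np.asarray(self.dsm, dtype=float)
        self.nir = np.asarray(self.nir, dtype=float)
        self.green = np.asarray(self.green, dtype=float)
        if not (self.dsm.shape == self.nir.shape == self.green.shape):
            raise ValueError("dsm, nir and green grids must share shape")
        if self.dsm.size == 0:
            raise ValueError("empty raster")
        if self.dsm_units not in ("m", "cm"):
            raise ValueError(f"dsm_units must be 'm' or 'cm', got {self.dsm_units!r}")
        for name, band in (("nir", self.nir), ("green", self.green)):
            valid = band[np.isfinite(band)]
            if valid.size and (valid.min() < 0 or valid.max() > 1):
                raise ValueError(f"{name} reflectance outside [0, 1]")


def compute_canopy_height(plot: PlotRaster) -> float:
    """Plot canopy height in cm: 95th percentile of valid DSM pixels minus ground.

    The percentile uses linear interpolation between order statistics.
    """
    valid = plot.dsm[np.isfinite(plot.dsm)]
    if valid.size == 0:
        raise ValueError("all DSM pixels are missing")
    ch = float(np.percentile(valid, 95, method="linear")) - plot.ground_level
    if plot.dsm_units == "m":
        ch *= _M_TO_CM
    return ch


def compute_plot_cig(plot: PlotRaster, *, minus_one: bool = False) -> float:
    """Plot CIg: mean over valid pixels of the per-pixel NIR/green ratio.

    Pixels with zero or missing green reflectance are masked (logged), not
    propagated as infinities.  ``minus_one`` switches to the
    ρNIR/ρgreen − 1 form of the index.
    """
    mask = np.isfinite(plot.nir) & np.isfinite(plot.green) & (plot.green > 0)
    n_masked = plot.green.size - int(mask.sum())
    if n_masked:
        log.info("compute_plot_cig: masked %d invalid pixel(s)", n_masked)
    if not mask.any():
        raise ValueError("no valid pixel for CIg")
    cig = float(np.mean(plot.nir[mask] / plot.green[mask]))
    return cig - 1.0 if minus_one else cig


def cut_plots(dsm: np.ndarray, nir: np.ndarray, green: np.ndarray,
              layout: pd.DataFrame, *, ground_level: float,
              dsm_units: str = "m") -> dict[str, PlotRaster]:
    """Cut per-plot rasters out of field-level band matrices.

    ``layout`` needs columns (plot_id, row0, row1, col0, col1) with 0-based
    half-open pixel rectangles.
    """
    required = {"plot_id", "row0", "row1", "col0", "col1"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"plot layout missing column(s): {sorted(missing)}")
    dsm = np.asarray(dsm, dtype=float)
    out: dict[str, PlotRaster] = {}
    for _, r in layout.iterrows():
        r0, r1, c0, c1 = (int(r["row0"]), int(r["row1"]), int(r["col0"]), int(r["col1"]))
        if not (0 <= r0 < r1 <= dsm.shape[0] and 0 <= c0 < c1 <= dsm.shape[1]):
            raise ValueError(f"plot {r['plot_id']}: rectangle outside the field raster")
        out[str(r["plot_id"])] = PlotRaster(
            dsm=dsm[r0:r1, c0:c1], nir=np.asarray(nir)[r0:r1, c0:c1],
            green=np.asarray(green)[r0:r1, c0:c1],
            ground_level=ground_level, dsm_units=dsm_units)
    return out
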