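"""Bioclimatic variables from monthly climate series.

Eight variables summarise the monthly temperature and precipitation
climatology of a window of years: annual means, seasonality (population
SD of the monthly means; for precipitation the coefficient of
variation), and monthly extremes.  Variables are computed on the
window-mean climatology by default; a per-year variant (bioclim per
year, then averaged) is available via ``average="per_year"``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

#: canonical variable order; the first four are thermal, the last four hydric
BIOCLIM_VARS = [
    "tmean_annual",
    "temp_seasonality",
    "tmax_warmest",
    "tmin_coldest",
    "prec_annual",
    "prec_seasonality",
    "prec_wettest",
    "prec_driest",
]

THERMO_VARS = frozenset(BIOCLIM_VARS[:4])
HYDRO_VARS = frozenset(BIOCLIM_VARS[4:])

CLIMATE_COLUMNS = ["cell_id", "year", "month", "tmean_c", "prec_mm"]


class ClimateError(ValueError):
    pass


def read_climate(path: str | Path) -> pd.DataFrame:
    """Read a long-format monthly climate table (one row per cell-year-month)."""
    tab = pd.read_csv(path, dtype={"cell_id": str})
    missing = set(CLIMATE_COLUMNS) - set(tab.columns)
    if missing:
        raise ClimateError(f"climate table missing columns: {sorted(missing)}")
    if (tab["prec_mm"] < 0).any():
        raise ClimateError("negative precipitation")
    counts = tab.groupby(["cell_id", "year"])["month"].nunique()
    if (counts != 12).any():
        cell, year = counts.index[counts != 12][0]
        raise ClimateError(f"cell {cell!r} year {year} does not have 12 months")
    return tab


def window_mean(series: pd.DataFrame, window: tuple[int, int]) -> pd.DataFrame:
    """Per-cell 12-month climatology averaged over the window years.

    Returns a frame indexed by (cell_id, month) with columns ``tmean_c``
    and ``prec_mm``; month m is the arithmetic mean of month m across
    the window years.
    """
    y0, y1 = window
    years = series["year"]
    if y0 > y1:
        raise ClimateError(f"window {window} reversed")
    if y0 < years.min() or y1 > years.max():
        raise ClimateError(
            f"window {window} outside series coverage {years.min()}-{years.max()}"
        )
    sub = series[(years >= y0) & (years <= y1)]
    clim = sub.groupby(["cell_id", "month"])[["tmean_c", "prec_mm"]].mean()
    return clim


def derive_bioclim(climatology: pd.DataFrame) -> pd.DataFrame:
    """Eight bioclim variables from a 12-month climatology.

    Seasonality uses the population SD (ddof=0) over the 12 months;
    precipitation seasonality is the CV (SD/mean), defined as 0 when the
    annual mean is 0.
    """
    temps = climatology["tmean_c"].unstack("month")
    precs = climatology["prec_mm"].unstack("month")
    if temps.shape[1] != 12:
        raise ClimateError("climatology must cover exactly 12 months")
    t = temps.to_numpy()
    p = precs.to_numpy()
    pmean = p.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_cv = np.where(pmean > 0, p.std(axis=1, ddof=0) / np.where(pmean > 0, pmean, 1.0), 0.0)
    out = pd.DataFrame(
        {
            "tmean_annual": t.mean(axis=1),
            "temp_seasonality": t.std(axis=1, ddof=0),
            "tmax_warmest": t.max(axis=1),
            "tmin_coldest": t.min(axis=1),
            "prec_annual": p.sum(axis=1),
            "prec_seasonality": prec_cv,
            "prec_wettest": p.max(axis=1),
            "prec_driest": p.min(axis=1),
        },
        index=temps.index,
    )
    out.index.name = "cell_id"
    return out[BIOCLIM_VARS]


def bioclim_for_window(
    series: pd.DataFrame, window: tuple[int, int], average: str = "climatology"
) -> pd.DataFrame:
    """Bioclim table (cells x 8 variables) for one window of years.

    ``average="climatology"`` derives the variables from the window-mean
    monthly climatology; ``"per_year"`` derives them separately per year
    and averages the eight variables across years.
    """
    if average == "climatology":
        return derive_bioclim(window_mean(series, window))
    if average == "per_year":
        y0, y1 = window
        per_year = [
            derive_bioclim(window_mean(series, (y, y))) for y in range(y0, y1 + 1)
        ]
        return sum(per_year[1:], per_year[0].copy()) / len(per_year)
    raise ValueError(f"average {average!r}")
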