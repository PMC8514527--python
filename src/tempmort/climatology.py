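"""Population-weighted country climatology.

Turns a gridded 12-month temperature climatology plus a gridded population
and country mask into one record per country: the population-weighted mean
temperature of each calendar month, and the hottest- and coldest-month
values that enter the damage functions as covariates.

The grid travels in long format, one row per cell:
``lat_idx, lon_idx, country, pop, t01..t12`` (an in-memory
``xarray.Dataset`` with dims (lat, lon, month) can be converted with
:func:`grid_from_dataset`).  Cells are assigned wholly to the country in the
mask column; multi-year monthly series are assumed pre-averaged to a single
12-month climatology.  The order of operations is fixed: weight first
(population-weighted monthly means per country), then pick the extreme
month of that weighted cycle — the covariate is a property of the country's
aggregate climate, not an aggregate of per-cell extremes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MONTH_COLS = [f"t{m:02d}" for m in range(1, 13)]


class ClimatologyError(ValueError):
    """Raised for grids that cannot be aggregated (e.g. zero-population country)."""


def monthly_country_climatology(grid: pd.DataFrame) -> pd.DataFrame:
    """Population-weighted monthly mean temperatures per country.

    Returns a DataFrame indexed by country with columns t01..t12 plus
    ``weight_mass`` (total population used).  Zero-population cells carry no
    weight and are dropped; a country whose total population is zero is an
    error (its climatology would be undefined, never silently NaN).
    """
    required = {"country", "pop", *MONTH_COLS}
    missing = required - set(grid.columns)
    if missing:
        raise ClimatologyError(f"grid is missing columns: {sorted(missing)}")
    if (grid["pop"] < 0).any():
        raise ClimatologyError("cell populations must be nonnegative")
    totals = grid.groupby("country")["pop"].sum()
    empty = sorted(totals.index[totals <= 0])
    if empty:
        raise ClimatologyError(
            f"zero total population for countries: {', '.join(map(str, empty))}"
        )
    g = grid[grid["pop"] > 0]
    weighted = g[MONTH_COLS].multiply(g["pop"], axis=0)
    out = weighted.groupby(g["country"]).sum().divide(totals, axis=0)
    out["weight_mass"] = totals
    out.index.name = "country"
    return out


def extreme_months(climatology) -> tuple[float, float, int, int]:
    """Hottest/coldest values and 1-based month indices of a 12-month cycle.

    Accepts a length-12 sequence or a climatology row.  Ties break toward
    the earliest calendar month (January = 1).
    """
    values = np.asarray(
        climatology[MONTH_COLS] if isinstance(climatology, pd.Series) and
        set(MONTH_COLS) <= set(climatology.index) else climatology,
        dtype=float,
    )
    if values.shape != (12,):
        raise ClimatologyError(f"expected 12 monthly values, got shape {values.shape}")
    hot_idx = int(np.argmax(values))  # argmax/argmin take the first, i.e. earliest
    cold_idx = int(np.argmin(values))
    return float(values[hot_idx]), float(values[cold_idx]), hot_idx + 1, cold_idx + 1


def country_extremes(climatology: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`extreme_months` to every country of a climatology table."""
    rows = {}
    for country, row in climatology.iterrows():
        hot, cold, hot_m, cold_m = extreme_months(row[MONTH_COLS].to_numpy(float))
        rows[country] = {
            "hottest_month_temp": hot,
            "coldest_month_temp": cold,
            "hottest_month": hot_m,
            "coldest_month": cold_m,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "country"
    return out


def grid_from_dataset(ds) -> pd.DataFrame:
    """Convert an xarray Dataset (dims lat, lon, month; variables
    temperature, population, country) to the long grid format."""
    import xarray as xr  # optional dependency, only needed for this path

    if not isinstance(ds, xr.Dataset):
        raise ClimatologyError("expected an xarray.Dataset")
    temp = ds["temperature"].transpose("lat", "lon", "month").values
    pop = ds["population"].transpose("lat", "lon").values
    country = ds["country"].transpose("lat", "lon").values
    nlat, nlon, nmonth = temp.shape
    if nmonth != 12:
        raise ClimatologyError(f"expected 12 months, got {nmonth}")
    lat_idx, lon_idx = np.meshgrid(range(nlat), range(nlon), indexing="ij")
    rows = {
        "lat_idx": lat_idx.ravel(),
        "lon_idx": lon_idx.ravel(),
        "country": country.ravel(),
        "pop": pop.ravel(),
    }
    for m in range(12):
        rows[MONTH_COLS[m]] = temp[:, :, m].ravel()
    df = pd.DataFrame(rows)
    return df[df["country"].astype(str) != ""].reset_index(drop=True)
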