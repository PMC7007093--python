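"""Receptor exposure via precomputed adjoint sensitivity fields.

The source-receptor relationship is linear for primary smoke aerosol: the
population-weighted PM2.5 at a receptor is the contraction of an emissions
flux field (g/m^2/s) with a monthly mean adjoint sensitivity field in
(ug/m^3)/(g/m^2/s). Sensitivities are computed once per meteorological year
and reused for any emissions scenario; future years recycle the available
met years in sequence. Population weighting lives inside the sensitivity
fields (it is part of the adjoint cost function), so this module never
touches population rasters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "MONTH_DAYS",
    "to_flux",
    "build_schedule",
    "apply_sensitivities",
    "seasonal_stats",
    "annual_means",
    "FIRE_SEASON",
]

#: days per calendar month (non-leap)
MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])

#: the Jul-Oct burning season used for seasonal reporting
FIRE_SEASON = (7, 8, 9, 10)

_TO_GRAMS = {"kg": 1e3, "t": 1e6, "Gg": 1e9, "Tg": 1e15}


def to_flux(E: xr.DataArray, cell_area_km2, month_days=MONTH_DAYS) -> xr.DataArray:
    """Convert mass-per-cell-per-month emissions to mean flux in g/m^2/s.

    flux = mass[g] / (area[m^2] x seconds in that month). The input field
    must carry ``units`` metadata; the output records the unit conversion.
    """
    if "units" not in E.attrs:
        raise ValueError("emissions field is missing units metadata")
    units = E.attrs["units"]
    if units not in _TO_GRAMS:
        raise ValueError(f"unsupported mass units {units!r}")
    from .grids import row_areas

    area_m2 = row_areas(cell_area_km2, E.shape[1:]) * 1e6
    month_days = np.asarray(month_days, dtype=float)
    seconds = month_days[E.coords["month"].values - 1] * 86400.0
    flux = E * _TO_GRAMS[units] / (area_m2[None] * seconds[:, None, None])
    flux.attrs = dict(
        E.attrs, units="g/m^2/s",
        note=f"converted from {units}/cell/month over {E.shape[1:]} grid",
    )
    return flux


def build_schedule(start_year: int, end_year: int, met_years) -> dict[int, int]:
    """Map each simulation year to a meteorological year, cycling through
    the available met years in order (e.g. 2020->2005 ... 2024->2009,
    2025->2005 for the 2005-2009 ensemble)."""
    met_years = list(met_years)
    if not met_years:
        raise ValueError("met_years must be nonempty")
    if end_year < start_year:
        raise ValueError("end_year before start_year")
    return {
        y: met_years[(y - start_year) % len(met_years)]
        for y in range(start_year, end_year + 1)
    }


def apply_sensitivities(flux: xr.DataArray, S: xr.DataArray,
                        schedule: dict[int, int]) -> pd.DataFrame:
    """Contract a flux field with adjoint sensitivities.

    X_r(year, month) = sum over cells of
    S_r(cell, month, schedule[year]) x flux(cell, year, month).

    ``S`` has dims (receptor, met_year, month, y, x); species must already
    be summed in ``flux`` (OC+BC). Returns a long-form exposure series with
    columns receptor, year, month, pm25 (ug/m^3).
    """
    if np.any(S.values < 0):
        raise ValueError("sensitivities must be nonnegative")
    if S.shape[-2:] != flux.shape[-2:]:
        raise ValueError(
            f"sensitivity grid {S.shape[-2:]} != flux grid {flux.shape[-2:]}"
        )
    met_avail = set(np.asarray(S.coords["met_year"].values).tolist())
    years = flux.coords["year"].values
    months = flux.coords["month"].values
    rows = []
    for r in S.coords["receptor"].values:
        s_r = S.sel(receptor=r)
        for t in range(flux.shape[0]):
            year, month = int(years[t]), int(months[t])
            if year not in schedule:
                raise KeyError(f"simulation year {year} not in met schedule")
            met = schedule[year]
            if met not in met_avail:
                raise KeyError(f"met year {met} missing from sensitivity field")
            kernel = s_r.sel(met_year=met, month=month).values
            rows.append(
                (str(r), year, month, float(np.sum(kernel * flux.values[t])))
            )
    return pd.DataFrame(rows, columns=["receptor", "year", "month", "pm25"])


def seasonal_stats(X: pd.DataFrame, months=FIRE_SEASON, years=None) -> pd.Series:
    """Per-receptor arithmetic mean of exposure over the requested
    month/year set (Jul-Oct by default)."""
    sel = X[X["month"].isin(months)]
    if years is not None:
        sel = sel[sel["year"].isin(list(years))]
    if sel.empty:
        raise ValueError("empty month/year selection")
    return sel.groupby("receptor")["pm25"].mean()


def annual_means(X: pd.DataFrame) -> pd.DataFrame:
    """Annual mean exposure per receptor and year (seasonal smoke diluted
    over 12 months) — the concentration the annual-average
    concentration-response functions apply to."""
    out = (
        X.groupby(["receptor", "year"])["pm25"]
        .mean()
        .rename("pm25_annual")
        .reset_index()
    )
    return out
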