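"""Fire-emissions modelling: FRP downscaling, per-transition emission
rates, future projection, and speciation of dry matter to OC and BC.

Coarse-grid monthly dry-matter (DM) emissions are distributed to the fine
grid using fire radiative power (FRP) as a spatial weight within each
coarse cell; coarse cells with emissions but no FRP detections fall back to
distributing by the area of each land-cover transition class — uniform per
unit area within a class, which collapses to plain cell-area weighting.
Downscaling conserves per-coarse-cell monthly mass exactly.

From downscaled emissions and the land-cover maps, a scaling-factor table
gives the climatological emission rate (mass per km^2 per calendar month)
of every transition/stable class in every coarse cell, averaged over the
observation years; locations that burn repeatedly contribute through this
average. Future emissions are the product of projected class areas and
these rates. Emission factors (g species per kg DM) convert dry matter to
organic-carbon and black-carbon aerosol by fire type (peat burning,
deforestation, agricultural/other).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import xarray as xr

from . import grids
from .lulc_model import (
    DEGRADED,
    INTACT,
    N_LABELS,
    NONFOREST,
    PLANTATION,
    LulcMap,
    decode_label,
    transition_labels,
)

__all__ = [
    "MONTHS",
    "make_field",
    "aggregate",
    "downscale",
    "ScalingFactorTable",
    "estimate_scaling_factors",
    "project_emissions",
    "EmissionFactorTable",
    "default_emission_factors",
    "speciate",
    "combine_oc_bc",
]

MONTHS = np.arange(1, 13)

#: multiplicative factors to kilograms
UNIT_TO_KG = {"kg": 1.0, "t": 1e3, "Gg": 1e6, "Tg": 1e9}


def make_field(data: np.ndarray, years, species: str = "DM",
               units: str = "kg") -> xr.DataArray:
    """Wrap a (n_months, rows, cols) array as an emissions field.

    The time axis is monthly, spanning ``years`` in order; ``year`` and
    ``month`` coordinates are attached. ``species`` and ``units`` metadata
    are mandatory for every emissions field.
    """
    data = np.asarray(data, dtype=float)
    years = np.asarray(years, dtype=int)
    if data.ndim != 3 or data.shape[0] != 12 * years.size:
        raise ValueError(
            f"expected (12*{years.size}, rows, cols) data, got {data.shape}"
        )
    if np.any(data < 0):
        raise ValueError("emissions must be nonnegative")
    time = np.arange(data.shape[0])
    return xr.DataArray(
        data,
        dims=("time", "y", "x"),
        coords={
            "time": time,
            "year": ("time", np.repeat(years, 12)),
            "month": ("time", np.tile(MONTHS, years.size)),
        },
        attrs={"species": species, "units": units},
    )


def _require_meta(E: xr.DataArray) -> None:
    for key in ("species", "units"):
        if key not in E.attrs:
            raise ValueError(f"emissions field is missing {key!r} metadata")


def aggregate(fine: xr.DataArray, factor: int) -> xr.DataArray:
    """Sum a fine-grid field onto the nesting coarse grid."""
    _require_meta(fine)
    out = xr.DataArray(
        grids.coarsen_sum(fine.values, factor),
        dims=fine.dims,
        coords={k: v for k, v in fine.coords.items() if v.dims == ("time",)},
        attrs=dict(fine.attrs),
    )
    return out


def downscale(coarse: xr.DataArray, frp: xr.DataArray,
              fine_area_km2: np.ndarray) -> xr.DataArray:
    """Distribute coarse-cell monthly emissions onto the nested fine grid.

    Within each coarse cell and month, fine-cell shares are proportional to
    FRP; where total FRP is zero but emissions are positive, shares are
    proportional to cell area (the class-area-ratio fallback: uniform per
    unit area within each class). Per-coarse-cell monthly sums equal the
    coarse input exactly.
    """
    _require_meta(coarse)
    cvals = np.asarray(coarse.values, dtype=float)
    fvals = np.asarray(frp.values, dtype=float)
    if np.any(cvals < 0) or np.any(fvals < 0):
        raise ValueError("emissions and FRP must be nonnegative")
    n_t, cr, cc = cvals.shape
    if fvals.shape[0] != n_t:
        raise ValueError("coarse emissions and FRP time axes differ")
    fr, fc = fvals.shape[1:]
    if fr % cr or fc % cc or fr // cr != fc // cc:
        raise ValueError(
            f"fine grid {fvals.shape[1:]} does not nest into coarse {(cr, cc)}"
        )
    f = fr // cr

    area = grids.row_areas(fine_area_km2, (fr, fc))
    w = grids.block_view(fvals, f)                       # (t, cr, f, cc, f)
    wsum = w.sum(axis=(-3, -1))                          # (t, cr, cc)
    aw = grids.block_view(area, f)                       # (cr, f, cc, f)
    asum = aw.sum(axis=(-3, -1))                         # (cr, cc)

    with np.errstate(invalid="ignore", divide="ignore"):
        frp_share = w / wsum[:, :, None, :, None]
        area_share = aw / asum[:, None, :, None]
    share = np.where(
        (wsum > 0)[:, :, None, :, None], frp_share, area_share[None]
    )
    fine = cvals[:, :, None, :, None] * share
    fine = fine.reshape(n_t, fr, fc)
    return xr.DataArray(
        fine,
        dims=("time", "y", "x"),
        coords={k: v for k, v in coarse.coords.items() if v.dims == ("time",)},
        attrs=dict(coarse.attrs),
    )


@dataclass
class ScalingFactorTable:
    """Emission rate per (coarse cell, transition class, calendar month).

    ``rates`` has shape (coarse_rows, coarse_cols, 32, 12) in mass per km^2
    per month; NaN marks class/cell combinations never observed (a class
    absent from a coarse cell has no entry — which is not a zero rate).
    ``areas`` records the class area (km^2) used in the denominator,
    averaged over observation years.
    """

    rates: np.ndarray
    areas: np.ndarray
    units: str = "kg/km^2/month"

    @property
    def coarse_shape(self) -> tuple[int, int]:
        return self.rates.shape[:2]

    def to_frame(self) -> pd.DataFrame:
        cy, cx, lbl, mon = np.nonzero(~np.isnan(self.rates))
        peat, src, dst = zip(*(decode_label(int(l)) for l in lbl)) if lbl.size else ((), (), ())
        return pd.DataFrame(
            {
                "coarse_y": cy,
                "coarse_x": cx,
                "label": lbl,
                "peat": np.asarray(peat, dtype=bool) if lbl.size else [],
                "from_class": src,
                "to_class": dst,
                "month": mon + 1,
                "rate": self.rates[cy, cx, lbl, mon],
                "area_km2": self.areas[cy, cx, lbl],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, coarse_shape: tuple[int, int],
                   units: str = "kg/km^2/month") -> "ScalingFactorTable":
        rates = np.full((*coarse_shape, N_LABELS, 12), np.nan)
        areas = np.zeros((*coarse_shape, N_LABELS))
        idx = (
            frame["coarse_y"].to_numpy(),
            frame["coarse_x"].to_numpy(),
            frame["label"].to_numpy(),
        )
        rates[(*idx, frame["month"].to_numpy() - 1)] = frame["rate"].to_numpy()
        areas[idx] = frame["area_km2"].to_numpy()
        return cls(rates, areas, units)


def _labels_for_year(lulc_series: list[LulcMap], year: int) -> np.ndarray:
    """Transition labels of the map interval containing ``year``."""
    for m0, m1 in zip(lulc_series, lulc_series[1:]):
        if m0.year <= year < m1.year:
            return transition_labels(m0, m1)
    raise ValueError(
        f"year {year} outside land-cover coverage "
        f"[{lulc_series[0].year}, {lulc_series[-1].year})"
    )


def estimate_scaling_factors(fine: xr.DataArray, lulc_series: list[LulcMap],
                             factor: int) -> ScalingFactorTable:
    """Learn per-coarse-cell, per-class monthly emission rates.

    rate(c, T, m) = mean over observation years of
    [sum of emissions in cells of class T within c during calendar month m]
    / area(c, T). All 12 calendar months enter, zeros included, so the
    rates form a climatology; interannual variability is reintroduced
    downstream by the meteorological-year schedule.
    """
    _require_meta(fine)
    fr, fc = fine.shape[1:]
    cr, cc = grids.check_nesting((fr, fc), factor)
    years = np.unique(fine.coords["year"].values)
    area = lulc_series[0].area_grid()
    coarse_idx = grids.refine(
        np.arange(cr * cc).reshape(cr, cc), factor
    ).ravel()

    rate_sum = np.zeros((cr * cc, N_LABELS, 12))
    rate_cnt = np.zeros((cr * cc, N_LABELS, 12), dtype=int)
    area_sum = np.zeros((cr * cc, N_LABELS))
    area_cnt = np.zeros((cr * cc, N_LABELS), dtype=int)

    for year in years:
        labels = _labels_for_year(lulc_series, int(year)).ravel()
        flat_idx = coarse_idx * N_LABELS + labels
        areas_y = np.bincount(
            flat_idx, weights=area.ravel(), minlength=cr * cc * N_LABELS
        ).reshape(cr * cc, N_LABELS)
        sel = fine.coords["year"].values == year
        em_y = fine.values[sel].reshape(12, -1)
        em_clm = np.stack(
            [
                np.bincount(flat_idx, weights=em_y[m], minlength=cr * cc * N_LABELS)
                for m in range(12)
            ],
            axis=-1,
        ).reshape(cr * cc, N_LABELS, 12)
        present = areas_y > 0
        if np.any(em_clm[~present] > 0):
            raise ValueError(
                "emissions attributed to a class with zero area in a coarse cell"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            ry = em_clm / areas_y[:, :, None]
        rate_sum[present] += ry[present]
        rate_cnt[present] += 1
        area_sum[present] += areas_y[present]
        area_cnt[present] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(rate_cnt > 0, rate_sum / np.maximum(rate_cnt, 1), np.nan)
        areas = np.where(area_cnt > 0, area_sum / np.maximum(area_cnt, 1), 0.0)
    return ScalingFactorTable(
        rates.reshape(cr, cc, N_LABELS, 12),
        areas.reshape(cr, cc, N_LABELS),
        units=f"{fine.attrs['units']}/km^2/month",
    )


def project_emissions(factors: ScalingFactorTable,
                      future_lulc: list[LulcMap], years,
                      factor: int, fine: bool = False) -> xr.DataArray:
    """Project monthly DM emissions from future land cover and learned rates.

    E(c, m, y) = sum over classes T of area(c, T, period(y)) x rate(c, T, m),
    where period(y) is the 5-year map interval containing y. Future classes
    with positive area but no calibrated rate contribute zero (with a
    warning). With ``fine=True`` the per-cell field (cell area x rate) is
    returned instead of the coarse aggregate — the form scenario masks act
    on.
    """
    years = np.asarray(years, dtype=int)
    cr, cc = factors.coarse_shape
    fr, fc = future_lulc[0].shape
    f = fr // cr
    if (fr, fc) != (cr * f, cc * f) or f != factor:
        raise ValueError("future land-cover grid does not nest into rate table grid")
    area = future_lulc[0].area_grid()
    coarse_idx = grids.refine(np.arange(cr * cc).reshape(cr, cc), factor)

    out = np.zeros((12 * years.size, fr, fc))
    missing = False
    rates_flat = factors.rates.reshape(cr * cc, N_LABELS, 12)
    for i, year in enumerate(years):
        labels = _labels_for_year(future_lulc, int(year))
        cell_rates = rates_flat[coarse_idx, labels, :]        # (fr, fc, 12)
        if np.isnan(cell_rates).any():
            missing = True
            cell_rates = np.nan_to_num(cell_rates)
        out[12 * i:12 * (i + 1)] = np.moveaxis(
            cell_rates * area[:, :, None], -1, 0
        )
    if missing:
        warnings.warn(
            "future land-cover classes without a calibrated emission rate "
            "contribute zero emissions",
            stacklevel=2,
        )
    units = factors.units.split("/")[0]
    field = make_field(out, years, species="DM", units=units)
    return field if fine else aggregate(field, factor)


@dataclass
class EmissionFactorTable:
    """Species emission factors (g per kg DM) by fire type, plus the total
    mapping from transition/stable class to fire type."""

    factors: pd.DataFrame
    mapping: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.factors[["ef_oc", "ef_bc"]] <= 0).any().any():
            raise ValueError("emission factors must be positive")
        if not self.mapping:
            self.mapping = {
                lbl: _default_fire_type(*decode_label(lbl))
                for lbl in range(N_LABELS)
            }
        unmapped = set(range(N_LABELS)) - set(self.mapping)
        if unmapped:
            raise ValueError(f"unmapped transition labels: {sorted(unmapped)}")
        unknown = set(self.mapping.values()) - set(self.factors.index)
        if unknown:
            raise KeyError(f"fire types without emission factors: {sorted(unknown)}")

    def ef_by_label(self, species: str) -> np.ndarray:
        col = {"OC": "ef_oc", "BC": "ef_bc"}[species]
        return np.array(
            [self.factors.loc[self.mapping[lbl], col] for lbl in range(N_LABELS)]
        )


def _default_fire_type(peat: bool, src: int, dst: int) -> str:
    if peat:
        return "peat"
    if src in (INTACT, DEGRADED) and dst in (PLANTATION, NONFOREST):
        return "deforestation"
    return "agricultural"


def default_emission_factors() -> EmissionFactorTable:
    """GFED4-style default OC/BC emission factors (g per kg DM)."""
    with resources.files("peatfire.data").joinpath("emission_factors.csv").open() as fh:
        table = pd.read_csv(fh).set_index("fire_type")
    return EmissionFactorTable(table)


def speciate(dm: xr.DataArray, ef: EmissionFactorTable,
             labels: np.ndarray) -> xr.Dataset:
    """Convert a DM field to OC and BC: species = DM x EF / 1000 (g/kg).

    ``labels`` gives each cell's transition label, either as a static 2-D
    grid or as one grid per time step.
    """
    _require_meta(dm)
    if dm.attrs["species"] != "DM":
        raise ValueError("speciation applies to dry-matter fields")
    labels = np.asarray(labels)
    out = {}
    for species in ("OC", "BC"):
        ef_map = ef.ef_by_label(species)[labels] / 1000.0
        arr = dm.copy(data=dm.values * ef_map)
        arr.attrs = dict(dm.attrs, species=species)
        out[species] = arr
    return xr.Dataset(out, attrs={"units": dm.attrs["units"]})


def combine_oc_bc(species: xr.Dataset) -> xr.DataArray:
    """Total primary smoke aerosol: OC + BC, summed before the adjoint
    contraction."""
    total = species["OC"] + species["BC"]
    total.attrs = dict(species["OC"].attrs, species="OC+BC")
    return total
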