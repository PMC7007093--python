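"""File I/O for pipeline artifacts.

Gridded fields travel as NetCDF (written through xarray's scipy backend);
tables as CSV. Land-cover maps are stored as a NetCDF dataset with
``classes`` and ``peat`` variables plus a sidecar class-codebook CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .emissions import ScalingFactorTable
from .health import PopulationTable
from .lulc_model import CLASS_NAMES, LulcMap

__all__ = [
    "save_field",
    "load_field",
    "save_lulc",
    "load_lulc",
    "save_codebook",
    "save_scaling_factors",
    "load_scaling_factors",
    "save_population",
    "load_population",
]

_ENGINE = "scipy"


def save_field(field: xr.DataArray, path) -> None:
    field.to_dataset(name="data").to_netcdf(path, engine=_ENGINE)


def load_field(path) -> xr.DataArray:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return ds["data"].load()


def save_lulc(maps: list[LulcMap], path) -> None:
    years = [m.year for m in maps]
    ds = xr.Dataset(
        {
            "classes": (("year", "y", "x"),
                        np.stack([m.classes for m in maps]).astype(np.int8)),
            "peat": (("y", "x"), maps[0].peat.astype(np.int8)),
            "cell_area_km2": (("y", "x"), maps[0].area_grid()),
        },
        coords={"year": years},
    )
    ds.to_netcdf(path, engine=_ENGINE)


def load_lulc(path) -> list[LulcMap]:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        peat = ds["peat"].values.astype(bool)
        area = ds["cell_area_km2"].values
        return [
            LulcMap(ds["classes"].sel(year=y).values, peat, int(y), area)
            for y in ds.coords["year"].values
        ]


def save_codebook(path) -> None:
    pd.DataFrame(
        [{"code": k, "name": v} for k, v in CLASS_NAMES.items()]
    ).to_csv(path, index=False)


def save_scaling_factors(table: ScalingFactorTable, path) -> None:
    frame = table.to_frame()
    frame.attrs = {}
    header = f"# coarse_shape={table.coarse_shape[0]}x{table.coarse_shape[1]} units={table.units}\n"
    with open(path, "w") as fh:
        fh.write(header)
        frame.to_csv(fh, index=False)


def load_scaling_factors(path) -> ScalingFactorTable:
    with open(path) as fh:
        header = fh.readline()
        meta = dict(tok.split("=") for tok in header.lstrip("# ").split())
        shape = tuple(int(v) for v in meta["coarse_shape"].split("x"))
        frame = pd.read_csv(fh)
    return ScalingFactorTable.from_frame(frame, shape, units=meta["units"])


def save_population(pop: PopulationTable, path) -> None:
    pop.table.to_csv(path)


def load_population(path) -> PopulationTable:
    return PopulationTable(pd.read_csv(path, index_col="receptor"))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
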