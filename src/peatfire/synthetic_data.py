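"""Seeded generators for every pipeline input.

No observational archive ships with this package, so each stage is
exercised on synthetic inputs that reproduce the statistical structure the
analysis assumes: a fine land-cover grid whose cells nest exactly into a
coarse emissions grid; fire emissions concentrated in peat and non-forest
classes with a Jul-Oct burning season and El Nino-like interannual
variability on a 5-year cycle; nonnegative plume-shaped adjoint sensitivity
kernels peaking at and upwind of receptor population centres; and
population concentrated at those centres.

Every generator is a pure function of its configuration: the same config
(including the seed) gives bit-identical output. Each generator draws from
its own pseudo-random stream, derived from the master seed by a fixed
offset, so adding a generator never shifts the outputs of existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import xarray as xr
from scipy import ndimage

from . import grids
from .emissions import make_field
from .health import PopulationTable
from .lulc_model import N_CLASSES, LulcMap

__all__ = ["SyntheticConfig", "gen_lulc_series", "gen_fire_truth",
           "gen_sensitivities", "gen_population"]

# fixed per-generator stream offsets
_STREAM_LULC = 11
_STREAM_FIRE = 22
_STREAM_SENS = 33
_STREAM_POP = 44


def _default_transition_rates() -> np.ndarray:
    # per-5-year transition probabilities (rows: from, cols: to);
    # diagonal (persistence) is implied
    P = np.zeros((4, 4))
    P[0, 1] = 0.10   # intact -> degraded (logging)
    P[0, 3] = 0.02   # intact -> nonforest
    P[1, 2] = 0.08   # degraded -> plantation/secondary
    P[1, 3] = 0.06   # degraded -> nonforest
    P[2, 3] = 0.03   # plantation -> nonforest
    P[3, 2] = 0.03   # nonforest -> plantation (regrowth/planting)
    return P


def _default_propensity() -> np.ndarray:
    # kg DM per km^2 per month at peak season, indexed class + 4*peat;
    # intact forest essentially never burns, drained peat burns hardest
    nonpeat = np.array([0.0, 300.0, 1500.0, 1200.0])
    peat = nonpeat * 8.0
    peat[0] = 50.0
    return np.concatenate([nonpeat, peat])


def _default_seasonality() -> np.ndarray:
    # monthly weights peaking Jul-Oct with a small spring shoulder
    return np.array(
        [0.05, 0.08, 0.15, 0.12, 0.10, 0.25, 0.80, 1.00, 1.00, 0.70, 0.15, 0.05]
    )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study domain.

    The defaults define the standard test fixture: a 120x120 fine grid of
    1-km^2 cells nesting 10x10 into a 12x12 coarse grid, four cover
    classes crossed with a peat flag, a 2005-style start year, and three
    receptors — one large population inside the source region and two
    smaller ones downwind — with masses on the scale of the Indonesia /
    Malaysia / Singapore populations the framework was built around.
    """

    seed: int = 0
    fine_grid: tuple[int, int] = (120, 120)
    coarsening_factor: int = 10
    cell_area_km2: object = 1.0
    start_year: int = 2005
    n_classes: int = N_CLASSES
    class_fractions: np.ndarray = field(
        default_factory=lambda: np.array([0.30, 0.15, 0.25, 0.30])
    )
    peat_fraction: float = 0.25
    annual_transition_rates: np.ndarray = field(
        default_factory=_default_transition_rates
    )
    fire_propensity: np.ndarray = field(default_factory=_default_propensity)
    seasonality: np.ndarray = field(default_factory=_default_seasonality)
    elnino_cycle: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 4.0, 1.0, 0.5, 2.0])
    )
    noise_sigma: float = 0.3
    frp_scale: float = 1.0e-3
    frp_dropout: float = 0.1
    receptor_centers: list = field(
        default_factory=lambda: [
            ("receptor_large", 70, 80, 2.0e8),
            ("receptor_mid", 25, 35, 3.0e7),
            ("receptor_small", 15, 85, 5.6e6),
        ]
    )
    wind_bearing: float = 135.0
    anisotropy: float = 0.7
    kernel_scale: float = 2.5
    sens_amplitude: float = 2.0e7
    met_perturbation: float = 0.3
    pop_sigma: float = 3.0
    adult_fraction: float = 0.60
    child_fraction: float = 0.09
    adult_mortality: float = 0.0075
    alri_mortality: float = 0.0010

    def __post_init__(self) -> None:
        self.class_fractions = np.asarray(self.class_fractions, dtype=float)
        self.annual_transition_rates = np.asarray(
            self.annual_transition_rates, dtype=float
        )
        self.fire_propensity = np.asarray(self.fire_propensity, dtype=float)
        self.seasonality = np.asarray(self.seasonality, dtype=float)
        self.elnino_cycle = np.asarray(self.elnino_cycle, dtype=float)
        if abs(self.class_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("class_fractions must sum to 1")
        grids.check_nesting(self.fine_grid, self.coarsening_factor)
        for name in ("fire_propensity", "seasonality", "elnino_cycle"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")
        offdiag = self.annual_transition_rates.copy()
        np.fill_diagonal(offdiag, 0.0)
        if np.any(offdiag < 0) or np.any(offdiag.sum(axis=1) > 1):
            raise ValueError("transition rates must be probabilities per row")

    @property
    def coarse_grid(self) -> tuple[int, int]:
        return grids.check_nesting(self.fine_grid, self.coarsening_factor)

    @property
    def receptor_names(self) -> list[str]:
        return [r[0] for r in self.receptor_centers]

    def rng(self, offset: int) -> np.random.Generator:
        return np.random.default_rng([offset, self.seed])


def gen_lulc_series(cfg: SyntheticConfig, n_periods: int) -> list[LulcMap]:
    """Generate a series of land-cover maps in 5-year steps.

    The initial map samples classes i.i.d. from ``class_fractions``; the
    peat mask is a smoothed-noise blob field occupying ``peat_fraction`` of
    the domain and is immutable across the series. Each step realises the
    configured per-5-year transition probabilities by seeded per-cell
    sampling.
    """
    if n_periods < 2:
        raise ValueError("need at least two periods (a calibration interval)")
    rng = cfg.rng(_STREAM_LULC)
    shape = cfg.fine_grid

    blur = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=min(shape) / 12)
    if cfg.peat_fraction > 0:
        peat = blur >= np.quantile(blur, 1 - cfg.peat_fraction)
    else:
        peat = np.zeros(shape, dtype=bool)

    classes = rng.choice(
        cfg.n_classes, size=shape, p=cfg.class_fractions
    ).astype(np.int8)
    maps = [LulcMap(classes, peat, cfg.start_year, cfg.cell_area_km2)]

    P = cfg.annual_transition_rates.copy()
    np.fill_diagonal(P, 0.0)
    stay = 1.0 - P.sum(axis=1)
    full = P.copy()
    full[np.arange(cfg.n_classes), np.arange(cfg.n_classes)] = stay
    cum = np.cumsum(full, axis=1)

    for step in range(1, n_periods):
        prev = maps[-1].classes
        u = rng.random(prev.size)
        rows = cum[prev.ravel()]
        new = (u[:, None] > rows).sum(axis=1).astype(np.int8)
        maps.append(
            LulcMap(
                new.reshape(shape), peat,
                cfg.start_year + 5 * step, cfg.cell_area_km2,
            )
        )
    return maps


def gen_fire_truth(cfg: SyntheticConfig,
                   lulc: list[LulcMap]) -> tuple[xr.DataArray, xr.DataArray]:
    """Generate fine-grid monthly DM emissions and matching FRP.

    emissions(cell, month, year) = propensity(class, peat) x
    seasonality(month) x elnino(year mod 5) x cell area x lognormal noise
    (unit mean). FRP is proportional to emissions except for seeded
    dropout: a fraction of fire cell-months report no FRP, exercising the
    area-ratio downscaling fallback.
    """
    if not lulc:
        raise ValueError("need at least one land-cover map")
    rng = cfg.rng(_STREAM_FIRE)
    n_years = max(1, len(lulc) - 1) * 5
    years = np.arange(cfg.start_year, cfg.start_year + n_years)
    area = lulc[0].area_grid()
    shape = lulc[0].shape

    em = np.zeros((12 * n_years, *shape))
    for i, year in enumerate(years):
        m = lulc[min(i // 5, len(lulc) - 1)]
        combined = m.classes.astype(int) + cfg.n_classes * m.peat
        base = cfg.fire_propensity[combined] * area
        amp = cfg.elnino_cycle[i % cfg.elnino_cycle.size]
        for mon in range(12):
            if cfg.noise_sigma > 0:
                noise = rng.lognormal(
                    -cfg.noise_sigma ** 2 / 2, cfg.noise_sigma, shape
                )
            else:
                noise = 1.0
            em[12 * i + mon] = base * cfg.seasonality[mon] * amp * noise

    frp = cfg.frp_scale * em
    if cfg.frp_dropout > 0:
        drop = rng.random(em.shape) < cfg.frp_dropout
        frp = np.where(drop, 0.0, frp)

    fine = make_field(em, years, species="DM", units="kg")
    frp_field = make_field(frp, years, species="FRP", units="MW")
    return fine, frp_field


def gen_sensitivities(cfg: SyntheticConfig, met_years) -> xr.DataArray:
    """Generate plume-shaped adjoint sensitivity kernels on the coarse grid.

    Each receptor's kernel is an anisotropic Gaussian peaking at the
    receptor centre and elongated toward the upwind bearing (sources
    upwind contribute most), decaying monotonically with distance along
    any ray. Fields differ across meteorological years and months by a
    seeded multiplicative perturbation; ``met_perturbation=0`` gives
    identical fields. Units: (ug/m^3) / (g/m^2/s), population weighting
    already folded in.
    """
    met_years = list(met_years)
    if not met_years:
        raise ValueError("met_years must be nonempty")
    if not cfg.receptor_centers:
        raise ValueError("receptor_centers must be nonempty")
    rng = cfg.rng(_STREAM_SENS)
    cr, cc = cfg.coarse_grid
    f = cfg.coarsening_factor

    theta = math.radians(cfg.wind_bearing)
    # row axis points south; bearing measured clockwise from north
    up = np.array([-math.cos(theta), math.sin(theta)])
    perp = np.array([-up[1], up[0]])

    yy, xx = np.mgrid[0:cr, 0:cc] + 0.5
    L = cfg.kernel_scale
    a = cfg.anisotropy
    kernels = []
    for (_, row, col, _mass) in cfg.receptor_centers:
        dy = yy - (row / f)
        dx = xx - (col / f)
        along = dy * up[0] + dx * up[1]
        cross = dy * perp[0] + dx * perp[1]
        scale_along = np.where(along > 0, L * (1 + 2.5 * a), L * max(1 - 0.6 * a, 0.2))
        kernels.append(
            cfg.sens_amplitude
            * np.exp(-0.5 * ((along / scale_along) ** 2 + (cross / L) ** 2))
        )

    n_r, n_my = len(kernels), len(met_years)
    data = np.empty((n_r, n_my, 12, cr, cc))
    for r in range(n_r):
        for j in range(n_my):
            for mon in range(12):
                jitter = 1.0 + cfg.met_perturbation * rng.standard_normal()
                data[r, j, mon] = kernels[r] * max(jitter, 0.0)
    return xr.DataArray(
        data,
        dims=("receptor", "met_year", "month", "y", "x"),
        coords={
            "receptor": cfg.receptor_names,
            "met_year": met_years,
            "month": np.arange(1, 13),
        },
        attrs={"units": "(ug/m^3)/(g/m^2/s)"},
    )


def gen_population(cfg: SyntheticConfig) -> PopulationTable:
    """Generate gridded adult/child population and baseline mortality rates.

    Population mass is a normalised Gaussian blob around each receptor
    centre, so the gridded total equals the configured masses exactly.
    Returns a :class:`~peatfire.health.PopulationTable` whose
    ``adult_grid``/``child_grid`` attributes carry the fine-grid counts.
    """
    import pandas as pd

    rng = cfg.rng(_STREAM_POP)  # reserved stream; placement is deterministic
    del rng
    shape = cfg.fine_grid
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    adult_grid = np.zeros(shape)
    child_grid = np.zeros(shape)
    rows = []
    for (name, row, col, mass) in cfg.receptor_centers:
        w = np.exp(
            -((yy - row) ** 2 + (xx - col) ** 2) / (2 * cfg.pop_sigma ** 2)
        )
        w /= w.sum()
        adult_grid += mass * cfg.adult_fraction * w
        child_grid += mass * cfg.child_fraction * w
        rows.append(
            {
                "receptor": name,
                "adults": mass * cfg.adult_fraction,
                "children": mass * cfg.child_fraction,
                "adult_mortality": cfg.adult_mortality,
                "alri_mortality": cfg.alri_mortality,
            }
        )
    table = PopulationTable(pd.DataFrame(rows).set_index("receptor"))
    table.adult_grid = adult_grid
    table.child_grid = child_grid
    return table
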