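"""Shared fixtures: the standard synthetic study domain at two scales.

The full-scale fixture (120x120 fine grid nesting 10x10 into 12x12 coarse,
10 simulated years) matches the conditions the property suite is defined
on; the small fixture trades domain size for speed in per-module tests.
"""

import warnings

import numpy as np
import pytest

from peatfire import emissions as em
from peatfire import scenarios as sc
from peatfire.synthetic_data import (
    SyntheticConfig,
    gen_fire_truth,
    gen_lulc_series,
    gen_population,
    gen_sensitivities,
)

MET_YEARS = list(range(2005, 2010))
STUDY_YEARS = np.arange(2020, 2030)


def build_engine(cfg: SyntheticConfig, years=STUDY_YEARS, n_periods: int = 6):
    maps = gen_lulc_series(cfg, n_periods)
    fine, _ = gen_fire_truth(cfg, maps[:2])
    factors = em.estimate_scaling_factors(fine, maps[:2], cfg.coarsening_factor)
    sens = gen_sensitivities(cfg, MET_YEARS)
    pop = gen_population(cfg)
    with warnings.catch_warnings():
        # future maps may contain transitions never observed in calibration
        warnings.simplefilter("ignore", UserWarning)
        engine = sc.ScenarioEngine(
            factors=factors,
            future_lulc=maps[1:],
            years=np.asarray(years),
            sensitivities=sens,
            met_years=MET_YEARS,
            population=pop,
            coarsening_factor=cfg.coarsening_factor,
        )
    return engine, maps, fine


@pytest.fixture(scope="session")
def full_cfg() -> SyntheticConfig:
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def full_domain(full_cfg):
    return build_engine(full_cfg)


@pytest.fixture(scope="session")
def full_engine(full_domain):
    return full_domain[0]


@pytest.fixture(scope="session")
def small_cfg() -> SyntheticConfig:
    return SyntheticConfig(
        seed=7,
        fine_grid=(36, 36),
        coarsening_factor=6,
        receptor_centers=[
            ("r_in", 20, 24, 5.0e7),
            ("r_down", 8, 10, 8.0e6),
        ],
    )


@pytest.fixture(scope="session")
def small_domain(small_cfg):
    return build_engine(small_cfg, years=np.arange(2020, 2023))


@pytest.fixture(scope="session")
def small_engine(small_domain):
    return small_domain[0]
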