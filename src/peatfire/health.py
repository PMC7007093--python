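"""Concentration-response functions and attributable mortality.

Adults (25+): all-cause mortality risk rises 1.03% per ug/m^3 of annual
average PM2.5 (95% CI 0.97-1.11%), a linear approximation from a
meta-analysis of long-term exposure studies. Children (<5): acute lower
respiratory infection (ALRI) mortality risk rises 12% per 10 ug/m^3
(95% CI 3-30%), linear up to 50 ug/m^3 and log-linear above, matching the
flattening of risk at very high ambient concentrations.

The piecewise child curve continues above the breakpoint B as

    dR(C) = (1 + s*B) * exp(k * (C - B)) - 1,   k = s / (1 + s*B)

which makes relative risk 1 + dR value- and slope-continuous (C^1) at B.

Attributable deaths difference the with-fire and without-fire
concentrations:

    D = population x baseline rate x [dR(C_with) - dR(C_without)]

with confidence bounds obtained by substituting the CI slopes. Population
counts and baseline rates are held constant over the projection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "ConcentrationResponse",
    "ADULT_ALL_CAUSE",
    "CHILD_ALRI",
    "PopulationTable",
    "delta_risk",
    "attributable_deaths",
    "burden_table",
    "round_sig",
]


@dataclass(frozen=True)
class ConcentrationResponse:
    """Fractional mortality-risk increase per ug/m^3 annual PM2.5."""

    slope: float
    ci_low: float
    ci_high: float
    breakpoint: Optional[float] = None
    form: str = "linear"

    def __post_init__(self) -> None:
        if not (0 < self.ci_low <= self.slope <= self.ci_high):
            raise ValueError("require 0 < ci_low <= slope <= ci_high")
        if self.form not in ("linear", "linear-then-loglinear"):
            raise ValueError(f"unknown CRF form {self.form!r}")
        if self.form == "linear-then-loglinear":
            if self.breakpoint is None or self.breakpoint <= 0:
                raise ValueError("piecewise CRF needs a positive breakpoint")


ADULT_ALL_CAUSE = ConcentrationResponse(slope=0.0103, ci_low=0.0097, ci_high=0.0111)
CHILD_ALRI = ConcentrationResponse(
    slope=0.012, ci_low=0.003, ci_high=0.030,
    breakpoint=50.0, form="linear-then-loglinear",
)


def delta_risk(C, crf: ConcentrationResponse, slope: float | None = None):
    """Fractional increase in mortality risk at concentration C (ug/m^3).

    ``slope`` substitutes a CI bound for the central slope (the breakpoint
    and form are unchanged). Vectorized over C.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentration must be nonnegative")
    s = crf.slope if slope is None else slope
    if crf.form == "linear":
        out = s * C
    else:
        B = crf.breakpoint
        k = s / (1 + s * B)
        out = np.where(
            C <= B,
            s * C,
            (1 + s * B) * np.exp(k * np.maximum(C - B, 0)) - 1,
        )
    return out if out.ndim else float(out)


def attributable_deaths(C_with, C_without, population: float, rate: float,
                        crf: ConcentrationResponse) -> tuple[float, float, float]:
    """Excess deaths attributable to the concentration difference.

    Returns (central, low, high); bounds substitute the CI slopes.
    """
    C_with = np.asarray(C_with, dtype=float)
    C_without = np.asarray(C_without, dtype=float)
    if np.any(C_with < C_without):
        raise ValueError("C_with must be >= C_without")
    out = tuple(
        float(
            np.sum(
                population
                * rate
                * (delta_risk(C_with, crf, s) - delta_risk(C_without, crf, s))
            )
        )
        for s in (crf.slope, crf.ci_low, crf.ci_high)
    )
    return out


@dataclass
class PopulationTable:
    """Per-receptor population counts and baseline mortality rates.

    ``table`` is indexed by receptor with columns ``adults`` (25+ count),
    ``children`` (<5 count), ``adult_mortality`` (all-cause deaths per
    person per year) and ``alri_mortality`` (child ALRI deaths per child
    per year).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"adults", "children", "adult_mortality", "alri_mortality"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"population table missing columns {sorted(missing)}")
        if (self.table[["adults", "children"]] < 0).any().any():
            raise ValueError("population counts must be nonnegative")
        rates = self.table[["adult_mortality", "alri_mortality"]]
        if ((rates <= 0) | (rates >= 1)).any().any():
            raise ValueError("baseline mortality rates must lie in (0, 1)")


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (report convention for death
    counts)."""
    if x == 0 or not np.isfinite(x):
        return x
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def burden_table(X_base: pd.DataFrame, X_scn: pd.DataFrame,
                 pop: PopulationTable,
                 crf_adult: ConcentrationResponse = ADULT_ALL_CAUSE,
                 crf_child: ConcentrationResponse = CHILD_ALRI,
                 baseline_concentration: float = 0.0,
                 exposure_mode: str = "annual_mean") -> pd.DataFrame:
    """Per-receptor exposure and mortality report for a scenario vs baseline.

    For each receptor: Jul-Oct mean smoke exposure under both runs, and
    annual-average attributable deaths (adult all-cause and child ALRI)
    with CI ranges, averaged over the simulated years. ``exposure_mode``
    selects the concentration fed to the annual CRFs: ``annual_mean``
    (seasonal exposure diluted over 12 months, the default) or
    ``seasonal`` (the Jul-Oct mean treated as the annual level).
    ``baseline_concentration`` is the non-fire PM2.5 both runs sit on top
    of (0 by default).
    """
    from .exposure import annual_means, seasonal_stats

    if set(X_base["receptor"]) != set(X_scn["receptor"]):
        raise ValueError("baseline and scenario receptor sets differ")
    if exposure_mode not in ("annual_mean", "seasonal"):
        raise ValueError(f"unknown exposure_mode {exposure_mode!r}")

    rows = []
    for name, X in (("baseline", X_base), ("scenario", X_scn)):
        jul_oct = seasonal_stats(X)
        if exposure_mode == "annual_mean":
            ann = annual_means(X)
        else:
            ann = (
                X[X["month"].isin((7, 8, 9, 10))]
                .groupby(["receptor", "year"])["pm25"]
                .mean()
                .rename("pm25_annual")
                .reset_index()
            )
        for receptor, grp in ann.groupby("receptor"):
            p = pop.table.loc[receptor]
            C = grp["pm25_annual"].to_numpy() + baseline_concentration
            C0 = np.full_like(C, baseline_concentration)
            n_years = C.size
            adult = attributable_deaths(
                C, C0, p["adults"], p["adult_mortality"], crf_adult
            )
            child = attributable_deaths(
                C, C0, p["children"], p["alri_mortality"], crf_child
            )
            rows.append(
                {
                    "run": name,
                    "receptor": receptor,
                    "jul_oct_exposure": float(jul_oct[receptor]),
                    "adult_deaths": adult[0] / n_years,
                    "adult_deaths_low": adult[1] / n_years,
                    "adult_deaths_high": adult[2] / n_years,
                    "child_deaths": child[0] / n_years,
                    "child_deaths_low": child[1] / n_years,
                    "child_deaths_high": child[2] / n_years,
                }
            )
    return pd.DataFrame(rows)
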