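# peatfire

Fire emissions, smoke exposure, and health-burden scenario modelling for
peatland fire management.

Land-management fires — especially on drained tropical peatlands — drive
severe regional PM2.5 haze and excess mortality downwind. `peatfire`
implements an integrated source-to-health pipeline for scoring
fire-reduction policies: it projects land-use/land-cover (LULC) change,
derives fire emissions per land-use transition, maps emissions to
receptor-country population-weighted PM2.5 through precomputed adjoint
sensitivity fields, converts exposure to attributable mortality with
concentration-response functions, and ranks fire-blocking interventions
(peatland protection, concession or conservation-area enforcement,
candidate restoration sites) by the deaths they avert.

It is written for land-use and air-quality researchers and for analysts
supporting restoration agencies who need to compare spatially explicit
interventions without rerunning a chemical transport model for each one.

## Model

The pipeline chains five linear-by-construction stages:

1. **LULC projection** (`lulc_model`). An 8-class map (intact primary
   forest, degraded primary forest, tree plantation / secondary forest,
   nonforest; each peat or non-peat) evolves in 5-year steps under a
   Bayesian Weights-of-Evidence model. For transition *T* and binned
   evidence layer value *b*,
   `W+(T, b) = ln[P(b | T) / P(b | ¬T)]`,
   and cells are converted in order of `logit(prior) + Σ_layers W+` until
   the per-step demand (default: observed calibration-period counts,
   i.e. business-as-usual) is met. Candidate evidence layers are screened
   for multicollinearity at VIF < 5.
2. **Emissions** (`emissions`). Coarse-grid monthly dry-matter emissions
   are downscaled to the fine grid with fire radiative power (FRP)
   weights (area-ratio fallback where FRP is absent, mass conserved
   exactly), yielding per-coarse-cell, per-transition-class, per-calendar-
   month emission rates `rate(c, T, m)` (kg km⁻² month⁻¹). Future
   emissions are `E(c, m, y) = Σ_T area(c, T, period(y)) · rate(c, T, m)`,
   speciated to OC and BC with per-fire-type emission factors.
3. **Exposure** (`exposure`). Monthly OC+BC mass becomes mean flux
   (g m⁻² s⁻¹) and contracts against adjoint sensitivity fields
   `S_r(cell, month, met_year)` in (µg/m³)/(g/m²/s):
   `X_r(m, y) = Σ_cells S_r · flux`. Meteorological years cycle in
   sequence (2020→2005, …, 2024→2009, 2025→2005, …). Population weighting
   is inside the adjoint fields.
4. **Health** (`health`). Adults 25+: all-cause mortality risk rises
   1.03% per µg/m³ annual PM2.5 (95% CI 0.97–1.11%). Children <5: ALRI
   mortality rises 1.2% per µg/m³ up to 50 µg/m³ and log-linearly above,
   C¹-continuous at the breakpoint. Attributable deaths:
   `D = pop × rate × [ΔR(C_with) − ΔR(C_without)]`.
5. **Scenarios** (`scenarios`). Boolean fine-grid masks zero emissions in
   targeted areas before aggregation; because the exposure operator is
   linear and nonnegative, blocking never worsens any receptor metric,
   nonoverlapping site benefits add exactly, and greedy top-k restoration
   site selection is optimal.

Because no observational archive is bundled, `synthetic_data` generates
every input — seeded LULC series, fire truth with Jul–Oct seasonality and
an El Niño-like 5-year cycle, plume-shaped sensitivity kernels peaking
upwind of receptor population centres, and gridded population — so the
whole pipeline is testable offline.

## Worked example

```python
import numpy as np
from peatfire import emissions as em, scenarios as sc
from peatfire.synthetic_data import (
    SyntheticConfig, gen_fire_truth, gen_lulc_series,
    gen_population, gen_sensitivities)

cfg = SyntheticConfig(seed=1)
maps = gen_lulc_series(cfg, 6)                      # 2005..2030 in 5-yr steps
fine, frp = gen_fire_truth(cfg, maps[:2])           # 2005-2009 monthly, 1 km
rates = em.estimate_scaling_factors(fine, maps[:2], cfg.coarsening_factor)
sens = gen_sensitivities(cfg, range(2005, 2010))
pop = gen_population(cfg)

engine = sc.ScenarioEngine(
    factors=rates, future_lulc=maps[1:], years=np.arange(2020, 2030),
    sensitivities=sens, met_years=list(range(2005, 2010)),
    population=pop, coarsening_factor=cfg.coarsening_factor)

bau = engine.baseline()
peat = engine.run(sc.ScenarioMask("peatlands", maps[0].peat, "peatlands"))
report = sc.compare(bau, peat)
```

Output for the default synthetic domain:

```
Jul-Oct OC+BC emissions (Gg): 11.1 -> 1.7 (84% reduction)
      receptor  exposure_baseline  exposure_scenario  adult_deaths_baseline  averted_adult_deaths
receptor_large               4.45               0.85                18000.0               14000.0
  receptor_mid               6.66               1.52                 3800.0                2900.0
receptor_small               3.82               0.87                  420.0                 330.0
burden shares (%): {'receptor_large': 81, 'receptor_mid': 17, 'receptor_small': 2}
```

Reading: under business-as-usual land change, the 2020–2029 fire seasons
emit 11.1 Gg of OC+BC and produce mean Jul–Oct smoke exposures of
3.8–6.7 µg/m³ at the three receptors, with ~22,000 attributable adult
deaths per year, 81% of them at the large in-domain receptor. Blocking
all fires on peatland — 25% of the domain but 84% of seasonal emissions,
much of it directly upwind of the receptors — averts about four fifths of
that burden. Deaths are reported to 2 significant figures and percent
reductions to integers, matching the reporting convention of published
scenario tables.

The same pipeline is scriptable from the shell: `peatfire make-synthetic`
materialises a fixture directory, and `simulate-lulc`, `downscale`,
`fit-rates`, `project-emissions`, `exposure`, `health`, `scenario` and
`rank-sites` mirror the stages above over NetCDF/CSV files
(`peatfire --help` for details).

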