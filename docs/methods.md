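# Methods

## Scope and model structure

`peatfire` couples a cellular land-change model to a linearised
atmospheric source-receptor operator and annual-average
concentration-response functions. The coupling quantity is monthly
dry-matter (DM) fire emissions per fine-grid cell; everything downstream
of emissions is linear, which is what makes scenario differencing and
restoration-site ranking cheap and exact.

Key structural assumptions:

* **Linearity of smoke transport.** Receptor population-weighted PM2.5
  responds linearly to primary OC/BC emissions at each source cell and
  month. This holds for primary aerosol in a chemical transport model and
  is the premise of using precomputed adjoint sensitivities; secondary
  aerosol and trace gases are out of scope.
* **Monthly collapse.** Monthly mean sensitivities multiply monthly mean
  fluxes. Sub-monthly covariance between emissions and transport is
  deliberately discarded; the adjoint fields are monthly means.
* **Climatological emission rates.** The rate table stores 12 calendar-
  month rates per coarse cell and transition class, averaged over all
  observation years with zero months included. Interannual variability
  re-enters through the meteorological-year schedule (and, in synthetic
  data, the El Niño-like emission multipliers), not through the rates.
* **Frozen demography.** Population counts and baseline mortality rates
  are constant over the projection.

## Land-change model

Weights of Evidence with ranked allocation. Evidence layers are binned by
deciles (configurable); weights use +0.5 pseudo-count smoothing in every
cell of the per-bin 2×2 table so they stay finite; the per-transition
prior is the calibration-period transition fraction of eligible cells.
Conditional independence of layers is assumed after VIF screening at
threshold 5 (a constant layer is an error, not a pass). Allocation
converts exactly the demanded number of cells per transition per 5-year
step, highest score first, with a seeded uniform tie-break drawn for the
whole grid each step — this makes selections nested in demand under a
fixed seed. Dynamic distance-to-class layers are recomputed from the
current map at each step. Patch-geometry machinery (patcher/expander
style growth of contiguous patches) is intentionally omitted: emissions
are consumed at coarse-cell resolution, where patch shape is invisible.
Default demand is the observed calibration-period transition count per
step, i.e. business-as-usual continuation.

## Emissions

Downscaling distributes each coarse cell-month's mass over its nested
fine cells proportionally to FRP. Where a coarse cell has emissions but
no FRP detections, mass is distributed by transition-class area, uniform
per unit area within each class — which is algebraically identical to
plain cell-area weighting, the form implemented. Nesting is exact by
construction (the coarsening factor must divide the grid), so no
area-weight interpolation exists anywhere in the pipeline.

Rates are `rate(c, T, m) = mean over years of [Σ emissions in cells of
class T within c during month m] / area(c, T)`; repeated burning at a
location contributes through this average. A class absent from a coarse
cell has *no entry* (NaN), distinct from a zero rate. A future class with
area but no calibrated rate contributes zero with a warning.

Speciation multiplies DM by per-fire-type emission factors (g/kg):
`data/emission_factors.csv` ships GFED4-style defaults — peat 6.02 OC /
0.04 BC, deforestation 4.71 / 0.52, agricultural 2.30 / 0.75 — and the
default class→fire-type mapping is: any peat label → peat; non-peat
forest-to-plantation/nonforest → deforestation; everything else →
agricultural. Both the table and mapping are configuration, not code.

## Exposure and health

Mass (kg/cell/month) converts to flux as `g / (area·m² × seconds in
month)` using real month lengths (non-leap). The met-year schedule maps
simulation year *y* to `met_years[(y − start) mod n]`, repeating the
available meteorology (default five years) in sequence.

Adult all-cause CRF: linear, slope 0.0103 per µg/m³ (CI 0.0097–0.0111).
Child ALRI CRF: slope 0.012 per µg/m³ to a 50 µg/m³ breakpoint, then
`ΔR(C) = (1 + sB)·exp(k(C − B)) − 1` with `k = s/(1 + sB)`. The
published source for the high-concentration regime states only
"log-linear above 50 µg/m³"; this parameterisation is our declared
choice — the unique exponential continuation that is value- and
slope-continuous at the breakpoint — and is flagged for sensitivity
analysis rather than treated as settled.

Two further declared choices, both configurable on `burden_table` /
`ScenarioEngine`:

* **Annual exposure convention** (`exposure_mode`): annual CRFs are
  applied to the annual mean fire PM2.5 (Jul–Oct smoke diluted over 12
  months, the default) rather than to the Jul–Oct mean itself
  (`"seasonal"`). Published scenario tables report seasonal exposures but
  annual CRFs without stating the conversion.
* **Non-fire baseline** (`baseline_concentration`): the "without fires"
  concentration both runs sit on top of defaults to 0, since non-fire
  PM2.5 is external model output the pipeline does not compute. The CRFs
  being (piecewise-)nonlinear, a nonzero baseline changes absolute deaths
  but not the ordering of scenarios.

Deaths are reported to 2 significant figures and percent reductions to
the nearest integer, fixing the reporting precision that comparisons are
made at.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not any real geography: a single rectangular landmass of 1-km² cells
(default 120×120 nesting 10×10 into a 12×12 coarse grid); i.i.d. initial
classes at configured fractions with a smoothed-noise peat blob field
(25% of the domain); per-5-year class transition sampling; fire
propensity per class×peat (kg DM km⁻² month⁻¹ at season peak) with
intact forest essentially non-flammable and drained peat burning ~8×
harder than its non-peat counterpart; a Jul–Oct-peaking monthly
seasonality with a small spring shoulder; a fixed 5-year El Niño-like
multiplier cycle `[1, 4, 1, 0.5, 2]` mirroring a mid-2000s window with
one strong event; unit-mean lognormal noise (σ = 0.3); FRP proportional
to emissions with 10% dropout to exercise the downscaling fallback; and
anisotropic Gaussian sensitivity kernels elongated upwind of each
receptor, perturbed across met years. Receptor population masses default
to 2×10⁸ / 3×10⁷ / 5.6×10⁶ — the scale of the three countries the
framework was designed around — with adult fraction 0.60, child fraction
0.09, adult all-cause mortality 7.5×10⁻³ yr⁻¹ and child ALRI mortality
1×10⁻³ yr⁻¹.

Each generator draws from its own stream (`default_rng([offset, seed])`
with fixed offsets), so outputs are bit-reproducible and adding a
generator never shifts existing ones.

What the generator does **not** emulate — and hence what green tests do
not establish about real data: multi-island geography and coastlines,
spatially autocorrelated land-cover patches, satellite orbital sampling
and detection biases in FRP, fuel-load depletion after repeated burns,
drought-fire nonlinearity, and realistic adjoint plume shapes from actual
meteorology. Tests demonstrate that the pipeline's mathematics is
implemented correctly (conservation, recovery of planted parameters,
linearity, ranking optimality), not that its outputs are accurate for
Indonesia.

## Numerical choices

* Downscaling shares are computed per coarse block in one vectorised
  pass; conservation is exact to floating point (verified at 1e-12
  relative).
* Rate recovery and reprojection on noise-free synthetic truth are exact
  to 1e-10 relative; the estimation averages per-year ratios, so a year
  with zero emissions scales rates by (n−1)/n as the mean requires.
* WoE scores are log-odds sums; priors are clamped away from {0, 1} by
  1e-9 before the logit. Ties within an evidence bin are broken by a
  seeded uniform draw.
* Degenerate inputs are errors, not silent passes: constant VIF layers,
  infeasible demand, peat-flag changes over time, negative
  concentrations, rates outside (0, 1), zero-total burden shares,
  emissions attributed to zero-area classes.

## Problem sizes

The standard fixture used by the test suite and the acceptance script is
the default configuration: 120×120 fine grid, 12×12 coarse, five
calibration years and ten projected years of monthly fields, three
receptors, five met years. Per-module tests use a 36×36 variant of the
same configuration. A full scenario evaluation at the standard scale
takes well under a second, so exhaustive single-site enumeration (the
ranking oracle) is run directly.

## Limitations

Beyond the synthetic-data caveats above: no secondary aerosol or trace
gases; no climate-driven changes in transport (met years only recycle);
no demographic projections; no morbidity or cause-specific adult
endpoints; no small-fire burned-area correction; scenario masks are
boolean rasters, so a "restoration site" blocks all fire rather than
reducing fire probability by a site-specific efficacy.
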