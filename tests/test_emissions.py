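"""Downscaling, emission-rate estimation, projection, and speciation."""

import numpy as np
import pytest

from peatfire import grids
from peatfire.emissions import (
    aggregate,
    combine_oc_bc,
    default_emission_factors,
    downscale,
    estimate_scaling_factors,
    make_field,
    project_emissions,
    speciate,
)
from peatfire.lulc_model import DEGRADED, NONFOREST, PLANTATION, LulcMap
from peatfire.synthetic_data import SyntheticConfig, gen_fire_truth, gen_lulc_series


def _coarse_field(data, years=(2005,)):
    return make_field(np.asarray(data, dtype=float), years)


class TestDownscale:
    def test_uniform_frp_splits_equally(self):
        coarse = _coarse_field(np.full((12, 1, 1), 8.0))
        frp = make_field(np.ones((12, 2, 2)), [2005], species="FRP", units="MW")
        fine = downscale(coarse, frp, 1.0)
        np.testing.assert_allclose(fine.values, 2.0)

    def test_no_frp_falls_back_to_area_ratio(self):
        # one coarse cell, class areas 3:1 over four equal-area fine cells
        coarse = _coarse_field(np.full((12, 1, 1), 4.0))
        frp = make_field(np.zeros((12, 2, 2)), [2005], species="FRP", units="MW")
        classes = np.array([[PLANTATION, PLANTATION], [PLANTATION, NONFOREST]])
        fine = downscale(coarse, frp, 1.0)
        by_class = {
            k: fine.values[0][classes == k].sum() for k in (PLANTATION, NONFOREST)
        }
        assert by_class[PLANTATION] == pytest.approx(3.0)
        assert by_class[NONFOREST] == pytest.approx(1.0)

    def test_mass_conserved_per_coarse_cell_and_month(self):
        rng = np.random.default_rng(0)
        coarse = _coarse_field(rng.random((12, 3, 3)))
        frp_data = rng.random((12, 12, 12))
        frp_data[:, :4, :4] = 0.0          # force the fallback in one block
        frp = make_field(frp_data, [2005], species="FRP", units="MW")
        fine = downscale(coarse, frp, 1.0)
        np.testing.assert_allclose(
            grids.coarsen_sum(fine.values, 4), coarse.values, rtol=1e-12
        )

    def test_round_trip_with_proportional_frp(self):
        cfg = SyntheticConfig(fine_grid=(20, 20), coarsening_factor=4,
                              frp_dropout=0.0, seed=2)
        maps = gen_lulc_series(cfg, 2)
        fine, frp = gen_fire_truth(cfg, maps)
        coarse = aggregate(fine, 4)
        recovered = downscale(coarse, frp, maps[0].area_grid())
        np.testing.assert_allclose(recovered.values, fine.values, rtol=1e-10,
                                   atol=1e-12)

    def test_nesting_mismatch_rejected(self):
        coarse = _coarse_field(np.ones((12, 2, 2)))
        frp = make_field(np.ones((12, 5, 5)), [2005], species="FRP", units="MW")
        with pytest.raises(ValueError, match="nest"):
            downscale(coarse, frp, 1.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            make_field(-np.ones((12, 2, 2)), [2005])


def _stable_pair(classes, peat=None, area=1.0, years=(2005, 2010)):
    classes = np.asarray(classes)
    peat = np.zeros_like(classes, dtype=bool) if peat is None else peat
    return [
        LulcMap(classes, peat, years[0], area),
        LulcMap(classes, peat, years[1], area),
    ]


class TestScalingFactors:
    def test_recovers_known_rates_exactly(self):
        cfg = SyntheticConfig(fine_grid=(20, 20), coarsening_factor=4,
                              noise_sigma=0.0, elnino_cycle=np.ones(5), seed=4)
        maps = gen_lulc_series(cfg, 2)
        fine, _ = gen_fire_truth(cfg, maps)
        table = estimate_scaling_factors(fine, maps, 4)
        frame = table.to_frame()
        # truth: rate = propensity(from-class, peat) x seasonality(month)
        expected = (
            cfg.fire_propensity[
                frame["from_class"].to_numpy()
                + 4 * frame["peat"].to_numpy().astype(int)
            ]
            * cfg.seasonality[frame["month"].to_numpy() - 1]
        )
        np.testing.assert_allclose(frame["rate"].to_numpy(), expected, rtol=1e-10)

    def test_reprojection_reproduces_input_emissions(self):
        cfg = SyntheticConfig(fine_grid=(20, 20), coarsening_factor=4,
                              noise_sigma=0.0, elnino_cycle=np.ones(5), seed=4)
        maps = gen_lulc_series(cfg, 2)
        fine, _ = gen_fire_truth(cfg, maps)
        table = estimate_scaling_factors(fine, maps, 4)
        years = np.unique(fine.coords["year"].values)
        redo = project_emissions(table, maps, years, 4, fine=True)
        np.testing.assert_allclose(redo.values, fine.values, rtol=1e-10,
                                   atol=1e-12)

    def test_zero_emission_year_scales_mean(self):
        classes = np.full((2, 2), PLANTATION)
        maps = _stable_pair(classes, years=(2005, 2010))
        one_year = np.tile(np.full((1, 2, 2), 3.0), (12, 1, 1))
        both = np.concatenate([one_year, np.zeros((12, 2, 2))])
        with_zero = estimate_scaling_factors(
            make_field(both, [2005, 2006]), maps, 2
        )
        without = estimate_scaling_factors(
            make_field(one_year, [2005]), maps, 2
        )
        np.testing.assert_allclose(
            with_zero.rates[~np.isnan(with_zero.rates)],
            without.rates[~np.isnan(without.rates)] / 2,
        )

    def test_absent_class_has_no_entry(self):
        maps = _stable_pair(np.full((2, 2), PLANTATION))
        table = estimate_scaling_factors(
            make_field(np.ones((12, 2, 2)), [2005]), maps, 2
        )
        frame = table.to_frame()
        assert set(frame["from_class"]) == {PLANTATION}
        # absent classes are NaN (no entry), not zero
        assert np.isnan(table.rates[0, 0, 0, :]).all()

    def test_hand_computed_two_class_cell(self):
        classes = np.array([[PLANTATION, PLANTATION], [PLANTATION, NONFOREST]])
        maps = _stable_pair(classes)
        em = np.zeros((12, 2, 2))
        em[0] = [[2.0, 2.0], [2.0, 6.0]]     # January only
        table = estimate_scaling_factors(make_field(em, [2005]), maps, 2)
        frame = table.to_frame().set_index(["from_class", "month"])
        assert frame.loc[(PLANTATION, 1), "rate"] == pytest.approx(6.0 / 3)
        assert frame.loc[(NONFOREST, 1), "rate"] == pytest.approx(6.0)
        # spreadsheet check of the projection: area x rate summed per class
        coarse = project_emissions(table, maps, [2005], 2)
        assert coarse.values[0, 0, 0] == pytest.approx(3 * 2.0 + 1 * 6.0)

    def test_projection_linear_in_area(self):
        classes = np.full((2, 2), PLANTATION)
        maps = _stable_pair(classes)
        table = estimate_scaling_factors(
            make_field(np.ones((12, 2, 2)), [2005]), maps, 2
        )
        single = project_emissions(table, maps, [2005], 2)
        doubled = project_emissions(
            table, _stable_pair(classes, area=2.0), [2005], 2
        )
        np.testing.assert_allclose(doubled.values, 2 * single.values)

    def test_fixed_point_projection_is_observed_climatology(self):
        cfg = SyntheticConfig(fine_grid=(20, 20), coarsening_factor=4,
                              noise_sigma=0.0, seed=6)
        maps = gen_lulc_series(cfg, 2)
        fine, _ = gen_fire_truth(cfg, maps)   # 5 years, El Nino cycle active
        table = estimate_scaling_factors(fine, maps, 4)
        proj = project_emissions(table, maps, [2005], 4)
        observed = aggregate(fine, 4)
        months = observed.coords["month"].values
        climatology = np.stack(
            [observed.values[months == m].mean(axis=0) for m in range(1, 13)]
        )
        np.testing.assert_allclose(proj.values, climatology, rtol=1e-10)

    def test_year_outside_coverage_rejected(self):
        maps = _stable_pair(np.full((2, 2), PLANTATION))
        table = estimate_scaling_factors(
            make_field(np.ones((12, 2, 2)), [2005]), maps, 2
        )
        with pytest.raises(ValueError, match="outside"):
            project_emissions(table, maps, [2031], 2)


class TestSpeciate:
    def test_unit_arithmetic(self):
        # 1 kg DM with EF 10 g/kg -> 0.01 kg species
        ef = default_emission_factors()
        ef.factors.loc["agricultural", "ef_oc"] = 10.0
        dm = make_field(np.ones((12, 1, 1)), [2005])
        labels = np.full((1, 1), PLANTATION * 4 + PLANTATION)   # stable, nonpeat
        out = speciate(dm, ef, labels)
        assert out["OC"].values[0, 0, 0] == pytest.approx(0.01)

    def test_peat_vs_nonpeat_ratio_equals_ef_ratio(self):
        ef = default_emission_factors()
        dm = make_field(np.ones((12, 1, 2)), [2005])
        stable = PLANTATION * 4 + PLANTATION
        labels = np.array([[stable, 16 + stable]])   # nonpeat, peat
        out = speciate(dm, ef, labels)
        ratio = out["OC"].values[0, 0, 1] / out["OC"].values[0, 0, 0]
        assert ratio == pytest.approx(
            ef.factors.loc["peat", "ef_oc"] / ef.factors.loc["agricultural", "ef_oc"]
        )

    def test_deforestation_mapping_and_combination(self):
        ef = default_emission_factors()
        dm = make_field(np.ones((12, 1, 1)), [2005])
        labels = np.full((1, 1), DEGRADED * 4 + NONFOREST)   # clearing, nonpeat
        out = speciate(dm, ef, labels)
        total = combine_oc_bc(out)
        expected = (
            ef.factors.loc["deforestation", ["ef_oc", "ef_bc"]].sum() / 1000
        )
        assert total.values[0, 0, 0] == pytest.approx(expected)
        assert total.attrs["species"] == "OC+BC"

    def test_zero_ef_rejected(self):
        ef = default_emission_factors()
        ef.factors.loc["peat", "ef_oc"] = 0.0
        from peatfire.emissions import EmissionFactorTable

        with pytest.raises(ValueError, match="positive"):
            EmissionFactorTable(ef.factors)
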