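"""Grain-to-residue conversion: the three methods and country rescaling."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from resalloc.grid import CountryMask, CountrySeries, GridField
from resalloc.params import CROPS, HarvestIndexParams
from resalloc.production import (
    mean_production,
    residue_from_ratio,
    residue_from_yield,
    residue_yield_exponential,
    residue_yield_linear,
    scale_grain_to_country,
    total_cereal_residue,
)
from conftest import toy_field


class TestExponentialMethod:
    # frozen oracle values: direct scalar evaluation of a*Y*exp(-b*Y) and
    # the plateau a/(b*e) with wheat's coefficients a=2.183, b=0.127
    def test_wheat_unit_yield(self):
        assert residue_yield_exponential(1.0, "wheat") == pytest.approx(
            2.183 * math.exp(-0.127), abs=1e-12
        )
        assert residue_yield_exponential(1.0, "wheat") == pytest.approx(
            1.92264, abs=1e-4
        )

    def test_wheat_plateau_above_turnover(self):
        # Y=10 exceeds 1/b ~ 7.874, so the plateau value a/(b e) applies
        expected = 2.183 / (0.127 * math.e)
        assert residue_yield_exponential(10.0, "wheat") == pytest.approx(
            expected, abs=1e-12
        )
        assert expected == pytest.approx(6.3235, abs=1e-3)

    def test_zero_yield_gives_zero(self):
        for crop in CROPS:
            assert residue_yield_exponential(0.0, crop) == 0.0

    @pytest.mark.parametrize("crop", CROPS)
    def test_continuous_and_maximal_at_turnover(self, crop):
        params = HarvestIndexParams()
        a, b, _, _ = params.abcd(crop)
        y_star = 1.0 / b
        below = residue_yield_exponential(y_star * (1 - 1e-13), crop)
        above = residue_yield_exponential(y_star * (1 + 1e-13), crop)
        at = residue_yield_exponential(y_star, crop)
        assert abs(below - at) < 1e-12 and abs(above - at) < 1e-12
        grid = np.linspace(0, 3 * y_star, 2001)
        vals = residue_yield_exponential(grid, crop)
        assert vals.max() <= at + 1e-12

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0.0, max_value=50.0))
    def test_nonnegative_and_bounded_by_plateau(self, y):
        r = residue_yield_exponential(y, "maize")
        assert 0.0 <= r <= 2.656 / (0.103 * math.e) + 1e-12

    def test_negative_yield_rejected(self):
        with pytest.raises(ValueError):
            residue_yield_exponential(-1.0, "wheat")


class TestLinearMethod:
    def test_rice_hand_value(self):
        # rice c=2.56, d=0.22: 2*(2.56 - 0.44) = 4.24
        assert residue_yield_linear(2.0, "rice") == pytest.approx(4.24, abs=1e-12)

    def test_clamped_at_zero_for_extreme_yield(self):
        # wheat c=1.96, d=0.14 at Y=15 gives -2.1 -> clamped
        assert residue_yield_linear(15.0, "wheat") == 0.0

    def test_zero_yield(self):
        assert residue_yield_linear(0.0, "barley") == 0.0

    def test_unknown_cereal_falls_back_to_other_cereals(self):
        assert residue_yield_linear(2.0, "teff") == residue_yield_linear(
            2.0, "other_cereals"
        )


def two_country_mask(values=None):
    codes = np.array([[0, 1]]) if values is None else np.asarray(values)
    nlat, nlon = codes.shape
    lat = 0.25 + 0.5 * np.arange(nlat)
    lon = 0.25 + 0.5 * np.arange(nlon)
    return CountryMask(codes, lat, lon, 0.5,
                       {"constant_ratio": {0: "low", 1: "high"}})


class TestConstantRatioMethod:
    def params(self):
        return HarvestIndexParams(constant_ratios={
            "low": {c: 1.0 for c in CROPS},
            "high": {c: 2.0 for c in CROPS},
        })

    def test_simple_multiplication(self):
        mask = two_country_mask([[0, 0]])
        prod = toy_field([[10.0, 0.0]])
        out = residue_from_ratio(prod, mask, HarvestIndexParams(constant_ratios={
            "low": {c: 1.5 for c in CROPS}}), "wheat")
        assert out.values[0, 0] == 15.0
        assert out.values[0, 1] == 0.0

    def test_region_specific_ratios(self):
        mask = two_country_mask()
        prod = toy_field([[10.0, 10.0]])
        out = residue_from_ratio(prod, mask, self.params(), "maize")
        assert out.values[0, 1] == 2 * out.values[0, 0]

    def test_missing_ratio_names_region_and_crop(self):
        mask = two_country_mask()
        prod = toy_field([[10.0, 10.0]])
        params = HarvestIndexParams(constant_ratios={"low": {"maize": 1.0}})
        with pytest.raises(KeyError, match="high.*maize"):
            residue_from_ratio(prod, mask, params, "maize")


class TestYieldMethodsOnGrids:
    def test_zero_area_means_zero_residue(self):
        prod = toy_field([[100.0, 50.0]])
        area = toy_field([[0.0, 10.0]], units="ha")
        out = residue_from_yield(prod, area, "wheat", "exponential")
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] > 0.0

    def test_equals_residue_yield_times_area(self):
        prod = toy_field([[60.0]])
        area = toy_field([[12.0]], units="ha")
        out = residue_from_yield(prod, area, "maize", "linear")
        assert out.values[0, 0] == pytest.approx(
            residue_yield_linear(5.0, "maize") * 12.0, rel=1e-12
        )


class TestScaleGrainToCountry:
    def make_inputs(self, base_vals, table_total, year=2011):
        mask = two_country_mask([[0, 0]])
        base = toy_field([base_vals], year=2010)
        area = toy_field([[1.0] * len(base_vals)], year=2010, units="ha")
        df = pd.DataFrame(
            {
                "grain_production_wheat": [base.total(), table_total],
                "harvested_area_wheat": [len(base_vals), len(base_vals)],
            },
            index=[2010, year],
        )
        countries = {0: CountrySeries(0, df)}
        return base, area, countries, mask

    def test_single_cell_country_gets_full_total(self):
        base, area, countries, _ = self.make_inputs([5.0], 200.0)
        mask = two_country_mask([[0]])
        prod, _ = scale_grain_to_country(base, area, countries, mask, 2011, "wheat")
        assert prod.values[0, 0] == pytest.approx(200.0)

    def test_proportional_allocation_by_base_share(self):
        base, area, countries, mask = self.make_inputs([25.0, 75.0], 200.0)
        prod, _ = scale_grain_to_country(base, area, countries, mask, 2011, "wheat")
        assert prod.values[0, 0] == pytest.approx(50.0)
        assert prod.values[0, 1] == pytest.approx(150.0)

    def test_base_year_identity(self):
        base, area, countries, mask = self.make_inputs([25.0, 75.0], 100.0)
        prod, _ = scale_grain_to_country(base, area, countries, mask, 2010, "wheat")
        assert np.allclose(prod.values, base.values)

    def test_negative_table_value_rejected(self):
        base, area, countries, mask = self.make_inputs([25.0, 75.0], -1.0)
        with pytest.raises(ValueError, match="negative"):
            scale_grain_to_country(base, area, countries, mask, 2011, "wheat")

    def test_zero_coverage_with_table_production_flagged(self):
        base, area, countries, mask = self.make_inputs([0.0, 0.0], 100.0)
        with pytest.warns(UserWarning, match="cannot downscale"):
            prod, _ = scale_grain_to_country(base, area, countries, mask,
                                             2011, "wheat")
        assert prod.total() == 0.0

    def test_country_sums_match_tables_on_synthetic_world(self, standard_world):
        from resalloc.ensemble import PipelineEngine

        eng = PipelineEngine(standard_world)
        year = 2012
        scaled = eng.scaled_grain(year)
        for code, series in standard_world.countries.items():
            cells = standard_world.mask.cells(code)
            for crop, (prod, _) in scaled.items():
                table = series.value(f"grain_production_{crop}", year)
                assert prod.values[cells].sum() == pytest.approx(table, rel=1e-9)


class TestTotalsAndMean:
    def test_total_sums_crops_cellwise(self):
        fields = {c: toy_field([[1.0]]) for c in CROPS}
        assert total_cereal_residue(fields).values[0, 0] == 7.0

    def test_single_crop_identity(self):
        f = toy_field([[3.5]])
        assert total_cereal_residue({"wheat": f}).values[0, 0] == 3.5

    def test_mean_of_methods(self):
        fields = [toy_field([[0.0]]), toy_field([[3.0]]), toy_field([[6.0]])]
        assert mean_production(fields).values[0, 0] == 3.0

    def test_mean_requires_three_inputs(self):
        with pytest.raises(ValueError, match="3"):
            mean_production([toy_field([[1.0]]), toy_field([[2.0]])])

    def test_mean_within_envelope(self):
        rng = np.random.default_rng(0)
        fields = [toy_field(rng.random((4, 4))) for _ in range(3)]
        m = mean_production(fields).values
        stack = np.stack([f.values for f in fields])
        assert (m >= stack.min(axis=0) - 1e-12).all()
        assert (m <= stack.max(axis=0) + 1e-12).all()
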