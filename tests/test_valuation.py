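import itertools
import math

import numpy as np
import pandas as pd
import pytest

from esvopt import accounting as acct
from esvopt import valuation as val
from esvopt.grids import LULCGrid
from esvopt.jenks import classify, natural_breaks
from esvopt.synthetic import SocioSeries


class TestStandardEquivalent:
    @pytest.mark.parametrize("year,ea", [(1990, 2006), (2000, 2043),
                                         (2010, 2107), (2020, 2181)])
    def test_packaged_constants(self, year, ea):
        assert val.standard_equivalent(None, year) == ea

    def _series(self, yield_kg, price):
        mk = lambda v: SocioSeries("s", [2004, 2005], [v, v])
        return {"grain_yield": mk(yield_kg), "grain_price": mk(price)}

    def test_one_seventh_of_output_value(self):
        assert val.standard_equivalent(self._series(7000, 1.0), 2005) == 1000.0

    def test_linear_in_price_and_yield(self):
        base = val.standard_equivalent(self._series(5000, 1.2), 2005)
        doubled = val.standard_equivalent(self._series(10000, 2.4), 2005)
        assert doubled == pytest.approx(4 * base)

    def test_missing_series_rejected(self):
        with pytest.raises(ValueError):
            val.standard_equivalent({}, 2005)


class TestEngelL:
    def test_one_third_gives_half(self):
        assert val.engel_L(1 / 3) == pytest.approx(0.5)

    def test_unit_engel(self):
        assert val.engel_L(1.0) == pytest.approx(1 / (1 + math.e**2))

    def test_limit_toward_one(self):
        assert val.engel_L(1e-3) > 0.999

    def test_monotone_decreasing(self):
        grid = np.linspace(0.01, 1.0, 100)
        vals = [val.engel_L(e) for e in grid]
        # non-increasing everywhere; strictly decreasing away from the
        # saturated L→1 region where float precision flattens the curve
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        body = [val.engel_L(e) for e in np.linspace(0.05, 1.0, 100)]
        assert all(a > b for a, b in zip(body, body[1:]))

    @pytest.mark.parametrize("bad", [0.0, -0.2, 1.5])
    def test_domain_enforced(self, bad):
        with pytest.raises(ValueError):
            val.engel_L(bad)


class TestCorrectionFactors:
    def test_region_equals_nation_gives_unity(self):
        assert val.biomass_factor(val.BiomassCorrection(5, 5, 0.4, 0.4)) == 1.0
        assert val.social_coefficient(
            val.SocialCorrection(100, 100, 0.4, 0.4)) == pytest.approx(1.0)

    def test_q_is_mean_of_ratios(self):
        bc = val.BiomassCorrection(1.2, 1.0, 0.8, 1.0)
        assert val.biomass_factor(bc) == pytest.approx(1.0)
        bc = val.BiomassCorrection(0.5, 1.0, 0.5, 1.0)
        assert val.biomass_factor(bc) == pytest.approx(0.5)

    def test_zero_national_mean_rejected(self):
        with pytest.raises(ValueError):
            val.biomass_factor(val.BiomassCorrection(1, 0, 1, 1))

    def test_pi_composition(self):
        sc = val.SocialCorrection(80, 100, 0.30, 1 / 3)
        expected = 0.8 * val.engel_L(0.30) / 0.5
        assert val.social_coefficient(sc) == pytest.approx(expected)


class TestCorrectedCoefficients:
    def test_reduction_identity(self):
        eq = val.load_equivalent_table("2003")
        vc = val.corrected_coefficients(eq, 2006.0, 1.0, 1.0)
        assert np.allclose(vc.values, eq.table.values * 2006.0)

    def test_single_function_unit_equivalent(self):
        eq = val.EquivalentTable(
            "x", pd.DataFrame({"f": [1.0]}, index=[1]), {"f": "regulation"})
        vc = val.corrected_coefficients(eq, 2006.0)
        assert vc.loc[1, "f"] == 2006.0

    def test_linearity_in_ea(self):
        eq = val.load_equivalent_table("2015")
        a = val.corrected_coefficients(eq, 1000.0)
        b = val.corrected_coefficients(eq, 2000.0)
        assert np.allclose(b.values, 2 * a.values)

    def test_monotone_in_corrections(self):
        eq = val.load_equivalent_table("2003")
        lo = val.corrected_coefficients(eq, 2006.0, 0.8, 0.9)
        hi = val.corrected_coefficients(eq, 2006.0, 0.9, 0.9)
        pos = eq.table.values > 0
        assert np.all(hi.values[pos] > lo.values[pos])

    def test_construction_land_stays_zero(self):
        for version in ("2003", "2015"):
            eq = val.load_equivalent_table(version)
            vc = val.corrected_coefficients(eq, 2181.0, 1.3, 1.2)
            assert vc.loc[5].sum() == 0.0

    def test_2015_table_adds_new_functions(self):
        eq = val.load_equivalent_table("2015")
        assert {"water_supply", "nutrient_cycling"} <= set(eq.functions)


class TestESVAggregation:
    def test_single_class_hand_value(self):
        eq = val.EquivalentTable(
            "x", pd.DataFrame({"f": [1.0]}, index=[3]), {"f": "support"})
        vc = val.corrected_coefficients(eq, 1e4)
        rep = val.esv_total(acct.AreaTable("y", {3: 1.0}), vc, eq.categories)
        assert rep.total == pytest.approx(1e4)

    def test_scaling_areas_scales_total(self):
        eq = val.load_equivalent_table("2003")
        vc = val.corrected_coefficients(eq, 2006.0)
        at1 = acct.AreaTable("a", {1: 100.0, 3: 500.0, 4: 50.0})
        at3 = acct.AreaTable("a", {1: 300.0, 3: 1500.0, 4: 150.0})
        r1 = val.esv_total(at1, vc, eq.categories)
        r3 = val.esv_total(at3, vc, eq.categories)
        assert r3.total == pytest.approx(3 * r1.total)

    def test_margins_agree(self, lulc_pair):
        eq = val.load_equivalent_table("2015")
        vc = val.corrected_coefficients(eq, 2181.0, 0.9, 1.1)
        at = acct.class_areas(lulc_pair[1], "b")
        rep = val.esv_total(at, vc, eq.categories)
        assert sum(rep.per_class.values()) == pytest.approx(rep.total)
        assert sum(rep.per_function.values()) == pytest.approx(rep.total)
        assert sum(rep.per_category.values()) == pytest.approx(rep.total)

    def test_raster_equals_tabular(self, lulc_pair):
        grid = lulc_pair[0]
        eq = val.load_equivalent_table("2003")
        vc = val.corrected_coefficients(eq, 2006.0)
        raster = val.esv_grid(grid, val.class_coefficients(vc))
        tab = val.esv_total(acct.class_areas(grid, "a"), vc, eq.categories)
        assert np.nansum(raster) * grid.cell_area == pytest.approx(tab.total)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            acct.AreaTable("a", {1: -5.0})


class TestDerivedStats:
    def test_published_increment(self):
        assert val.increment(18.62, 67.28) == pytest.approx(48.66)

    def test_published_contribution_share(self):
        share = val.contribution_share(30.64 + 14.61, 48.66)
        assert round(share) == 93

    def test_equal_totals_zero_change(self):
        assert val.pct_change(10.0, 10.0) == 0.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError):
            val.pct_change(0.0, 5.0)

    def test_stats_frame(self):
        df = val.derived_stats({"1990": 18.62, "2020": 67.28})
        assert df.loc[0, "increment"] == 48.66


class TestJenks:
    def _sse(self, v, breaks):
        lv = classify(v, breaks)
        return sum(((v[lv == i] - v[lv == i].mean()) ** 2).sum()
                   for i in np.unique(lv))

    def test_two_clusters_split_between(self):
        v = np.array([1.0, 1.1, 1.2, 9.0, 9.1, 9.2])
        breaks = natural_breaks(v, 2)
        assert 1.2 <= breaks[0] < 9.0
        assert breaks[1] == 9.2

    def test_k1_single_class(self):
        v = np.array([3.0, 5.0, 8.0])
        breaks = natural_breaks(v, 1)
        assert np.all(classify(v, breaks) == 1)

    def test_constant_data_rejected(self):
        with pytest.raises(ValueError):
            natural_breaks(np.full(10, 2.5), 5)

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_exhaustive_partition_search(self, k, rng):
        """Oracle: brute force over all contiguous partitions of ≤20 values."""
        v = np.sort(rng.random(14) * 100)
        best = min(
            (sum(((v[a:b] - v[a:b].mean()) ** 2).sum()
                 for a, b in zip((0,) + cuts, cuts + (len(v),)))
             for cuts in itertools.combinations(range(1, len(v)), k - 1)),
        )
        assert self._sse(v, natural_breaks(v, k)) == pytest.approx(best)

    def test_every_cell_gets_level(self, lulc_pair):
        eq = val.load_equivalent_table("2015")
        vc = val.class_coefficients(val.corrected_coefficients(eq, 2181.0))
        raster = val.esv_grid(lulc_pair[1], vc)
        levels, breaks = val.jenks_levels(raster, 5)
        assert np.all(np.diff(breaks) > 0)
        assert np.all(levels[np.isfinite(raster)] >= 1)


def test_fvc_dimidiate_pixel_model():
    ndvi = np.linspace(0, 1, 101)
    fvc = val.fvc_from_ndvi(ndvi)
    assert fvc.min() == 0.0 and fvc.max() == 1.0
    assert np.all(np.diff(fvc) >= 0)
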