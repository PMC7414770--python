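"""Equivalent-factor valuation: E_a, bilinear ESV accounting, change rates,
contribution shares, zonal additivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esvland import (
    AreaTable,
    ESVCoefficientTable,
    GrainEconomyTable,
    LandCoverGrid,
    SIX_CLASS_SCHEME,
    change_rate,
    compute_esv,
    contribution_shares,
    equivalent_factor,
    esv_by_function,
    esv_by_zone,
    round_half_up,
)
from esvland.study import PRINTED_TOTAL_ROW, study_area_table
from esvland.synthetic_data import SyntheticLandscapeSpec, generate_initial, generate_zones


def _grain(rows):
    return GrainEconomyTable(
        crops=pd.DataFrame(rows, columns=["area_hm2", "price_yuan_per_t", "yield_t_per_hm2"])
    )


class TestEquivalentFactor:
    def test_single_crop_unit_case(self):
        # 1/7 × 7 yuan/t × 1 t/hm² = 1 yuan/hm², for any area
        assert equivalent_factor(_grain([[123.0, 7.0, 1.0]])) == pytest.approx(1.0)

    def test_two_crops_by_hand(self):
        g = _grain([[60.0, 2000.0, 3.0], [40.0, 1000.0, 2.0]])
        expected = (60 * 2000 * 3 + 40 * 1000 * 2) / 100 / 7
        assert equivalent_factor(g) == pytest.approx(expected)
        assert expected == pytest.approx(628.5714, abs=1e-3)

    def test_invalid_grain_rows_rejected(self):
        with pytest.raises(ValueError):
            _grain([[0.0, 2000.0, 3.0]])


class TestCoefficientTable:
    def test_printed_total_row_matches_column_sums(self, coeffs):
        # the printed totals are themselves rounded to 0.01 per cell; summing
        # nine cells can accumulate a couple of last-digit units
        coeffs.check_total_row(PRINTED_TOTAL_ROW, tol=0.025)

    def test_negative_coefficients_only_for_built_up(self, coeffs):
        vc = coeffs.VC.copy()
        vc.loc["food production", "grassland"] = -1.0
        with pytest.raises(ValueError, match="grassland"):
            ESVCoefficientTable(VC=vc)

    def test_csv_round_trip(self, tmp_path, coeffs):
        back = ESVCoefficientTable.from_csv(coeffs.to_csv(tmp_path / "vc.csv"))
        pd.testing.assert_frame_equal(back.VC, coeffs.VC)


class TestComputeESV:
    def test_published_grassland_cell(self, areas_1980, coeffs):
        r = compute_esv(areas_1980, coeffs)
        assert r.report()["grassland"] == pytest.approx(3.87)

    def test_published_negative_built_up_cell(self, areas_1980, coeffs):
        r = compute_esv(areas_1980, coeffs)
        assert r.report()["built-up land"] == pytest.approx(-0.08)

    def test_zero_area_landscape(self, coeffs):
        zero = AreaTable(areas_km2=pd.Series(0.0, index=list(SIX_CLASS_SCHEME.names)))
        assert compute_esv(zero, coeffs).total_yuan == 0.0

    def test_strict_si_is_hundredfold(self, areas_1980, coeffs):
        a = compute_esv(areas_1980, coeffs, unit_convention="paper-table")
        b = compute_esv(areas_1980, coeffs, unit_convention="strict-si")
        assert b.total_yuan == pytest.approx(100.0 * a.total_yuan)

    def test_class_mismatch_lists_offenders(self, coeffs):
        odd = AreaTable(
            areas_km2=pd.Series(1.0, index=list(SIX_CLASS_SCHEME.names)[::-1])
        )
        with pytest.raises(ValueError, match="mismatch"):
            compute_esv(odd, coeffs)


class TestESVByFunction:
    def test_published_food_production_cell(self, areas_1980, coeffs):
        f = esv_by_function(areas_1980, coeffs)
        assert f.report()["food production"] == pytest.approx(0.31)

    def test_function_sum_equals_class_total(self, coeffs):
        for year in (1980, 2010, 2030):
            areas = study_area_table(year)
            total_cls = compute_esv(areas, coeffs).total_yuan
            total_fun = esv_by_function(areas, coeffs).total_yuan
            assert total_fun == pytest.approx(total_cls, rel=1e-12)

    def test_zero_coefficient_gives_zero_value(self, coeffs):
        only_unutilized = AreaTable(
            areas_km2=pd.Series(
                [0, 0, 0, 0, 0, 100.0], index=list(SIX_CLASS_SCHEME.names)
            )
        )
        f = esv_by_function(only_unutilized, coeffs)
        assert f.values_yuan["gas regulation"] == 0.0


class TestESVByZone:
    def test_single_zone_equals_global(self, coeffs):
        g = generate_initial(SyntheticLandscapeSpec(shape=(40, 40), seed=1))
        zonal = esv_by_zone(g, np.ones((40, 40), dtype=int), coeffs)
        from esvland import tabulate_areas

        assert list(zonal) == [1]
        assert zonal[1].total_yuan == pytest.approx(
            compute_esv(tabulate_areas(g), coeffs).total_yuan
        )

    def test_two_zone_hand_computation(self, coeffs):
        # left half forest (code 1), right half water (code 4); 1 km cells
        values = np.ones((2, 4), dtype=int)
        values[:, 2:] = 4
        g = LandCoverGrid(values, cell_size=1000.0)
        zones = np.repeat([[1, 1, 2, 2]], 2, axis=0)
        zonal = esv_by_zone(g, zones, coeffs)
        assert zonal[1].total_yuan == pytest.approx(4 * float(coeffs.totals["forestland"]))
        assert zonal[2].total_yuan == pytest.approx(4 * float(coeffs.totals["water body"]))

    def test_additivity_over_sixteen_zones(self, coeffs):
        spec = SyntheticLandscapeSpec(shape=(80, 80), n_zones=16, seed=6)
        g = generate_initial(spec)
        zones = generate_zones(spec)
        from esvland import tabulate_areas

        zonal = esv_by_zone(g, zones, coeffs)
        total = sum(r.total_yuan for r in zonal.values())
        assert total == pytest.approx(compute_esv(tabulate_areas(g), coeffs).total_yuan, rel=1e-9)

    def test_misaligned_zone_grid_rejected(self, coeffs):
        g = generate_initial(SyntheticLandscapeSpec(shape=(10, 10), seed=0))
        with pytest.raises(ValueError, match="shape"):
            esv_by_zone(g, np.ones((5, 5), dtype=int), coeffs)


class TestChangeRateAndShares:
    def test_published_area_change_rates(self):
        cr = change_rate(study_area_table(1980), study_area_table(2030))
        rep = cr.report()
        assert rep["cropland"] == pytest.approx(34.38)
        assert rep["built-up land"] == pytest.approx(196.66)

    def test_identical_tables_change_zero(self, areas_1980):
        cr = change_rate(areas_1980, areas_1980)
        assert (cr.pct_change == 0).all()
        assert cr.total_pct_change == 0.0

    def test_zero_start_flagged_not_silent(self):
        idx = list(SIX_CLASS_SCHEME.names)
        s = AreaTable(areas_km2=pd.Series([1, 0, 1, 1, 1, 1.0], index=idx))
        e = AreaTable(areas_km2=pd.Series([1, 5, 1, 1, 1, 1.0], index=idx))
        cr = change_rate(s, e)
        assert "grassland" in cr.undefined
        assert np.isnan(cr.pct_change["grassland"])

    def test_published_grassland_share(self, areas_1980, coeffs):
        shares = contribution_shares(compute_esv(areas_1980, coeffs))
        assert round_half_up(shares["grassland"]) == pytest.approx(49.43)

    def test_single_category_is_whole_total(self, coeffs):
        only = AreaTable(
            areas_km2=pd.Series([100.0, 0, 0, 0, 0, 0], index=list(SIX_CLASS_SCHEME.names))
        )
        shares = contribution_shares(compute_esv(only, coeffs))
        assert shares["forestland"] == pytest.approx(100.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0.1, 10.0))
def test_bilinearity_in_areas(seed, scale):
    """Scaling every area scales every reported value by the same factor."""
    from esvland.study import study_coefficients

    coeffs = study_coefficients()
    rng = np.random.default_rng(seed)
    base = pd.Series(rng.random(6) * 1e4, index=list(SIX_CLASS_SCHEME.names))
    r1 = compute_esv(AreaTable(areas_km2=base), coeffs)
    r2 = compute_esv(AreaTable(areas_km2=base * scale), coeffs)
    np.testing.assert_allclose(r2.values_yuan, scale * r1.values_yuan, rtol=1e-9)


def test_round_half_up_matches_report_convention():
    assert round_half_up(2.345) == 2.35
    assert round_half_up(2.344) == 2.34
    assert round_half_up(-0.075) == -0.08
    assert round_half_up(196.655) == 196.66
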