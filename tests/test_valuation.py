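import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esvtrend import (
    LandUseClass,
    Raster,
    ServiceType,
    SocioEconomicSeries,
    build_value_table,
    calibrate_unit_value,
    comparable_esv,
    deflate_series,
    dynamic_adjust,
    esv_raster,
    esv_totals,
)
from esvtrend.core import DEFAULT_NODATA
from tests.conftest import D_BASE


class TestUnitValueCalibration:
    @pytest.mark.parametrize(
        "y, p, expected",
        [
            (4405, 3.05, 1919.32),  # the benchmark grain-value calibration
            (7, 1, 1.0),
            (7000, 2.5, 2500.0),
        ],
    )
    def test_examples(self, y, p, expected):
        assert calibrate_unit_value(y, p) == pytest.approx(expected, abs=5e-3)

    @pytest.mark.parametrize("y, p", [(0, 3.05), (4405, 0), (-1, 1)])
    def test_nonpositive_inputs_rejected(self, y, p):
        with pytest.raises(ValueError):
            calibrate_unit_value(y, p)


class TestValueTable:
    @pytest.mark.parametrize(
        "k, f, expected",
        [
            (LandUseClass.Woodland, ServiceType.GR, 4510.402),
            (LandUseClass.Grassland, ServiceType.WS, 153.5456),
        ],
    )
    def test_reconstructed_cells_match_printed_values(self, vc, k, f, expected):
        assert vc.vc(k, f) == pytest.approx(expected, abs=1e-4)

    def test_zero_weight_gives_zero_value(self, vc):
        assert vc.vc(LandUseClass.UnusedLand, ServiceType.GR) == 0.0

    def test_builtup_row_total_is_negative(self, vc):
        assert vc.row_total(LandUseClass.BuiltUp) == pytest.approx(-12.37 * D_BASE)

    def test_nonpositive_base_value_rejected(self, weights):
        with pytest.raises(ValueError):
            build_value_table(weights, 0.0)

    @pytest.mark.parametrize(
        "k, total", [(LandUseClass.Woodland, 19.37), (LandUseClass.Cropland, 3.74)]
    )
    def test_row_sums_match_consistent_printed_totals(self, weights, k, total):
        assert weights.row_total(k) == pytest.approx(total, abs=1e-9)


class TestStaticTotals:
    def test_one_hectare_woodland(self, vc):
        acct = esv_totals({LandUseClass.Woodland: 1.0}, vc)
        # independent oracle: sum of the nine reconstructed woodland coefficients
        expected = sum(vc.vc(LandUseClass.Woodland, f) for f in ServiceType)
        assert expected == pytest.approx(37_177.2284, abs=1e-3)
        assert acct.esv_static == pytest.approx(expected)

    def test_all_zero_areas(self, vc):
        acct = esv_totals({}, vc)
        assert acct.esv_static == 0.0
        assert all(v == 0.0 for v in acct.esv_by_service.values())

    def test_negative_area_rejected(self, vc):
        with pytest.raises(ValueError, match="negative"):
            esv_totals({LandUseClass.Grassland: -1.0}, vc)

    @settings(deadline=None, max_examples=50)
    @given(
        areas=st.lists(
            st.floats(0, 1e6, allow_nan=False), min_size=7, max_size=7
        ),
        scale=st.floats(0.1, 10),
    )
    def test_consistency_and_linearity(self, vc, areas, scale):
        """sum_f ESV_f == sum_k ESV_k == ESV_s, and valuation is linear in areas."""
        av = dict(zip(LandUseClass, areas))
        acct = esv_totals(av, vc)
        tol = max(1.0, abs(acct.esv_static)) * 1e-9
        assert sum(acct.esv_by_service.values()) == pytest.approx(acct.esv_static, abs=tol)
        assert sum(acct.esv_by_class.values()) == pytest.approx(acct.esv_static, abs=tol)
        doubled = esv_totals({k: v * scale for k, v in av.items()}, vc)
        assert doubled.esv_static == pytest.approx(acct.esv_static * scale, rel=1e-9)


class TestDeflation:
    def _socio(self, gdp, idx):
        n = len(gdp)
        return SocioEconomicSeries(
            years=np.arange(1990, 1990 + n),
            gdp=gdp,
            gdp_index=idx,
            engel=np.full(n, 0.35),
            grain_yield=np.full(n, 4405.0),
            grain_price=np.full(n, 3.05),
        )

    def test_unit_indices_leave_series_unchanged(self):
        socio = self._socio([100, 105, 99], [1.0, 1.0, 1.0])
        e_an, e_avg = deflate_series(socio, 1990)
        assert np.allclose(e_an, [100, 105, 99])
        assert e_avg == pytest.approx(np.mean([100, 105, 99]))

    def test_single_step_deflation(self):
        socio = self._socio([100, 110], [1.0, 1.10])
        e_an, _ = deflate_series(socio, 1990)
        assert e_an[0] == pytest.approx(100)
        assert e_an[1] == pytest.approx(100)

    def test_chain_matches_cumulative_product_loop(self):
        gdp = [100.0, 120.0, 150.0, 160.0]
        idx = [1.0, 1.08, 1.12, 1.02]
        socio = self._socio(gdp, idx)
        e_an, _ = deflate_series(socio, 1990)
        # independent oracle: explicit running product
        prod = 1.0
        expected = [gdp[0]]
        for m in range(1, 4):
            prod *= idx[m]
            expected.append(gdp[m] / prod)
        assert np.allclose(e_an, expected)

    def test_year_before_base_rejected(self):
        socio = self._socio([100, 110], [1.0, 1.1])
        with pytest.raises(KeyError):
            deflate_series(socio, 1980)


class TestComparableAndDynamic:
    def test_identity_when_at_average(self):
        assert comparable_esv(123.0, 50.0, 50.0) == pytest.approx(123.0)

    def test_half_value(self):
        assert comparable_esv(100.0, 50.0, 25.0) == pytest.approx(50.0)

    def test_zero_average_rejected(self):
        with pytest.raises(ValueError):
            comparable_esv(1.0, 0.0, 1.0)

    @pytest.mark.parametrize(
        "engel, t_exp, ac_exp",
        [
            (1 / 3, 0.0, 0.5),  # logistic midpoint
            (0.25, 1.0, 1 / (1 + math.exp(-1))),
            (0.1, 7.0, 1 / (1 + math.exp(-7))),
        ],
    )
    def test_logistic_adjustment(self, engel, t_exp, ac_exp):
        t, ac, esvd = dynamic_adjust(200.0, engel)
        assert t == pytest.approx(t_exp, abs=1e-12)
        assert ac == pytest.approx(ac_exp, abs=1e-9)
        assert esvd == pytest.approx(200.0 * ac_exp)

    @pytest.mark.parametrize("engel", [0.0, -0.2, 1.2])
    def test_engel_domain(self, engel):
        with pytest.raises(ValueError):
            dynamic_adjust(1.0, engel)

    @given(st.floats(0.1, 1.0), st.floats(0.1, 1.0))
    def test_ac_strictly_decreasing_and_bounded(self, e1, e2):
        _, a1, _ = dynamic_adjust(1.0, e1)
        _, a2, _ = dynamic_adjust(1.0, e2)
        assert 0 < a1 < 1
        if e1 < e2 - 1e-6:  # gap above float resolution of the logistic
            assert a1 > a2


class TestEsvRaster:
    def test_uniform_woodland_per_hectare(self, uniform_woodland, vc):
        out = esv_raster(uniform_woodland, vc, per="hectare")
        assert np.allclose(out.data, 37_177.2284, atol=1e-3)

    def test_builtup_pixels_are_negative(self, transform_1ha, vc):
        r = Raster(np.full((2, 2), int(LandUseClass.BuiltUp), dtype=np.uint8), transform_1ha)
        out = esv_raster(r, vc)
        assert np.all(out.data < 0)
        assert out.data[0, 0] == pytest.approx(-12.37 * D_BASE)

    def test_nodata_propagates(self, transform_1ha, vc):
        grid = np.full((2, 2), int(LandUseClass.Grassland), dtype=np.uint8)
        grid[0, 0] = DEFAULT_NODATA
        out = esv_raster(Raster(grid, transform_1ha), vc)
        assert np.isnan(out.data[0, 0])
        assert np.isfinite(out.data[1, 1])

    def test_per_pixel_scales_by_area(self, uniform_woodland, vc):
        per_ha = esv_raster(uniform_woodland, vc, per="hectare")
        per_px = esv_raster(uniform_woodland, vc, per="pixel")
        assert np.allclose(per_px.data, per_ha.data * uniform_woodland.pixel_area_ha)
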