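import numpy as np
import pytest

from esvtrend import (
    GridTransform,
    LandUseClass,
    LandUseSeries,
    Raster,
    build_value_table,
    calibrate_unit_value,
    default_weight_table,
)

#: base unit value at the printed precision of the calibration example
D_BASE = 1919.32


@pytest.fixture(scope="session")
def weights():
    return default_weight_table()


@pytest.fixture(scope="session")
def vc(weights):
    return build_value_table(weights, D_BASE)


@pytest.fixture
def transform_1ha():
    # 100 m pixels => exactly 1 ha per pixel
    return GridTransform(0.0, 1000.0, 100.0, 100.0)


@pytest.fixture
def uniform_woodland(transform_1ha):
    data = np.full((2, 2), int(LandUseClass.Woodland), dtype=np.uint8)
    return Raster(data, transform_1ha)


def make_series(arrays, transform, years=None):
    rasters = [Raster(np.asarray(a, dtype=np.uint8), transform) for a in arrays]
    years = years or list(range(2000, 2000 + len(arrays)))
    return LandUseSeries(years, rasters)


@pytest.fixture
def make_landuse_series(transform_1ha):
    def _make(arrays, years=None):
        return make_series(arrays, transform_1ha, years)

    return _make
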