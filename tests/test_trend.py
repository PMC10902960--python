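import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from esvtrend import (
    GridTransform,
    Raster,
    TrendClass,
    classify_trend,
    mk_test,
    sen_slope,
    summarize_classes,
    trend_analysis,
    trend_raster,
)


def brute_sen(values, times):
    slopes = [
        (values[j] - values[i]) / (times[j] - times[i])
        for i in range(len(values))
        for j in range(i + 1, len(values))
    ]
    return float(np.median(slopes))


def brute_s(values):
    return sum(
        np.sign(values[j] - values[i])
        for i in range(len(values))
        for j in range(i + 1, len(values))
    )


class TestSenSlope:
    def test_exact_linear(self):
        assert sen_slope([1, 2, 3, 4]) == pytest.approx(1.0)

    def test_constant(self):
        assert sen_slope([5, 5, 5]) == 0.0

    def test_median_of_pairwise_slopes(self):
        # pairwise slopes {1.0, 4.5, 8.0} -> median 4.5
        assert sen_slope([1, 2, 10], [0, 1, 2]) == pytest.approx(4.5)

    def test_too_short(self):
        with pytest.raises(ValueError):
            sen_slope([1.0])

    @given(
        vals=st.lists(st.floats(-100, 100), min_size=2, max_size=8),
        shift=st.floats(-50, 50),
        scale=st.floats(0.1, 10),
    )
    def test_shift_invariance_and_scale_equivariance(self, vals, shift, scale):
        v = np.asarray(vals)
        b = sen_slope(v)
        assert sen_slope(v + shift) == pytest.approx(b, abs=1e-9)
        assert sen_slope(v * scale) == pytest.approx(b * scale, rel=1e-9, abs=1e-9)


class TestMannKendall:
    def test_strictly_increasing_n5(self):
        s, var, z = mk_test([1, 2, 3, 4, 5])
        assert s == 10
        assert var == pytest.approx(5 * 4 * 15 / 18)
        assert z == pytest.approx(9 / np.sqrt(var))

    def test_constant_series(self):
        s, _, z = mk_test([3, 3, 3, 3])
        assert s == 0 and z == 0.0

    def test_time_reversal_negates_s_and_z(self):
        v = [1.0, 5.0, 2.0, 8.0, 3.0]
        s, _, z = mk_test(v)
        s_r, _, z_r = mk_test(v[::-1])
        assert s_r == -s
        assert z_r == pytest.approx(-z)

    def test_floor_enforced(self):
        with pytest.raises(ValueError):
            mk_test([1, 2, 3])

    def test_exhaustive_small_series_oracle(self):
        """S matches pair enumeration on every length-4..5 series over {0,1,2}."""
        for n in (4, 5):
            for combo in itertools.product([0.0, 1.0, 2.0], repeat=n):
                s, var, z = mk_test(combo)
                s_expected = brute_s(combo)
                assert s == s_expected
                if s > 0:
                    assert z == pytest.approx((s - 1) / np.sqrt(var))
                elif s < 0:
                    assert z == pytest.approx((s + 1) / np.sqrt(var))
                else:
                    assert z == 0.0

    @given(st.lists(st.integers(-1000, 1000), min_size=4, max_size=10, unique=True))
    def test_z_invariant_under_monotone_transform(self, vals):
        v = np.asarray(vals, dtype=float) / 100.0
        _, _, z1 = mk_test(v)
        _, _, z2 = mk_test(np.exp(v / 10))  # strictly monotone map
        assert z1 == pytest.approx(z2)


class TestClassification:
    @pytest.mark.parametrize(
        "beta, z, expected",
        [
            (0.01, 3.0, TrendClass.SignificantIncrease),
            (0.01, 1.0, TrendClass.SlightIncrease),
            (0.001, 5.0, TrendClass.NoTrend),
            (-0.001, -5.0, TrendClass.NoTrend),
            (-0.01, -1.0, TrendClass.SlightDecrease),
            (-0.01, -3.0, TrendClass.SignificantDecrease),
        ],
    )
    def test_five_classes(self, beta, z, expected):
        assert classify_trend(beta, z) == expected

    def test_thresholds_must_be_positive(self):
        with pytest.raises(ValueError):
            classify_trend(0.1, 1.0, beta_threshold=0.0)

    def test_scalar_pipeline_on_trending_series(self):
        res = trend_analysis(np.arange(31) * 0.1 + 1.0)
        assert res.trend_class == TrendClass.SignificantIncrease
        assert np.sign(res.z) == np.sign(res.s)


@pytest.fixture
def tr():
    return GridTransform(0.0, 400.0, 100.0, 100.0)


class TestTrendRaster:
    def test_uniform_increasing_stack(self, tr):
        stack = [Raster(np.full((3, 3), float(t)), tr, nodata=float("nan")) for t in range(6)]
        beta, z, cls = trend_raster(stack)
        assert np.allclose(beta.data, 1.0)
        assert np.all(cls.data == int(TrendClass.SignificantIncrease))

    def test_matches_scalar_path_per_pixel(self, tr):
        rng = np.random.default_rng(11)
        cube = rng.normal(size=(8, 2, 2)).cumsum(axis=0)
        stack = [Raster(cube[t], tr, nodata=float("nan")) for t in range(8)]
        beta, z, cls = trend_raster(stack)
        for r in range(2):
            for c in range(2):
                series = cube[:, r, c]
                assert beta.data[r, c] == pytest.approx(sen_slope(series))
                _, _, z_exp = mk_test(series)
                assert z.data[r, c] == pytest.approx(z_exp)
                assert cls.data[r, c] == int(classify_trend(sen_slope(series), z_exp))

    def test_nodata_hole_propagates(self, tr):
        cube = np.tile(np.arange(5.0)[:, None, None], (1, 3, 3))
        cube[2, 1, 1] = np.nan
        stack = [Raster(cube[t], tr, nodata=float("nan")) for t in range(5)]
        beta, z, cls = trend_raster(stack)
        assert np.isnan(beta.data[1, 1]) and cls.data[1, 1] == 0
        assert np.isfinite(beta.data[0, 0])

    def test_mismatched_grids_rejected(self, tr):
        a = Raster(np.zeros((3, 3)), tr, nodata=float("nan"))
        b = Raster(np.zeros((4, 4)), tr, nodata=float("nan"))
        with pytest.raises(ValueError, match="grid"):
            trend_raster([a, b, a, a])


class TestSummary:
    def test_uniform_raster_is_100_percent_one_class(self, tr):
        cls = Raster(np.full((4, 4), int(TrendClass.SlightIncrease), dtype=np.uint8), tr, nodata=0)
        table = summarize_classes(cls).set_index("trend_class")
        assert table.loc["SlightIncrease", "percent"] == pytest.approx(100.0)
        assert table.loc["Improved", "percent"] == pytest.approx(100.0)
        assert table.loc["Degraded", "percent"] == pytest.approx(0.0)

    def test_percentages_sum_to_100_and_aggregates_add_up(self, tr):
        rng = np.random.default_rng(5)
        data = rng.integers(1, 6, size=(10, 10)).astype(np.uint8)
        table = summarize_classes(Raster(data, tr, nodata=0)).set_index("trend_class")
        base = table.loc[[c.name for c in TrendClass], "percent"]
        assert base.sum() == pytest.approx(100.0)
        assert table.loc["Improved", "percent"] == pytest.approx(
            table.loc["SlightIncrease", "percent"] + table.loc["SignificantIncrease", "percent"]
        )
        assert table.loc["Degraded", "percent"] == pytest.approx(
            table.loc["SlightDecrease", "percent"] + table.loc["SignificantDecrease", "percent"]
        )

    def test_empty_raster_rejected(self, tr):
        cls = Raster(np.zeros((3, 3), dtype=np.uint8), tr, nodata=0)
        with pytest.raises(ValueError):
            summarize_classes(cls)


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**31 - 1))
def test_injected_linear_trend_recovered(seed):
    """Sen slope on noisy linear series recovers the injected slope."""
    rng = np.random.default_rng(seed)
    slope = rng.uniform(-2, 2)
    t = np.arange(31.0)
    y = slope * t + rng.normal(0, 0.5, 31)
    assert sen_slope(y, t) == pytest.approx(slope, abs=0.25)
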