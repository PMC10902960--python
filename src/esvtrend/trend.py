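"""Theil-Sen slope + Mann-Kendall trend test, per series and per pixel.

The Theil-Sen estimator is the median of all pairwise slopes
(v_j - v_i)/(t_j - t_i), j > i: robust to outliers and to the distribution
of the series. The Mann-Kendall statistic S counts concordant minus
discordant pairs; its standardized form Z (continuity-corrected) is
compared against a normal quantile to flag significance. Pixels are
classified into five trend classes from (beta, Z):

    beta >= +thr, |Z| >= z  -> significant increase
    beta >= +thr, |Z| <  z  -> slight increase
    |beta| < thr            -> no trend
    beta <= -thr, |Z| <  z  -> slight decrease
    beta <= -thr, |Z| >= z  -> significant decrease

with default thresholds thr = 0.005 (slope units/yr) and z = 2.58 (~ the
1 % two-sided normal quantile).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .core import Raster

__all__ = [
    "TrendClass",
    "TrendResult",
    "sen_slope",
    "mk_test",
    "classify_trend",
    "trend_raster",
    "summarize_classes",
    "DEFAULT_BETA_THRESHOLD",
    "DEFAULT_Z_THRESHOLD",
]

DEFAULT_BETA_THRESHOLD = 0.005
DEFAULT_Z_THRESHOLD = 2.58


class TrendClass(enum.IntEnum):
    SignificantDecrease = 1
    SlightDecrease = 2
    NoTrend = 3
    SlightIncrease = 4
    SignificantIncrease = 5


@dataclass
class TrendResult:
    beta: float
    s: int
    var_s: float
    z: float
    trend_class: TrendClass


def _pair_indices(n: int) -> tuple[np.ndarray, np.ndarray]:
    pairs = np.array(list(combinations(range(n), 2)))
    return pairs[:, 0], pairs[:, 1]


def sen_slope(values, times=None) -> float:
    """Median of all pairwise slopes (value per unit time)."""
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 2:
        raise ValueError("Sen slope requires at least two observations")
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)
    if len(t) != n:
        raise ValueError("times and values lengths differ")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    i, j = _pair_indices(n)
    return float(np.median((v[j] - v[i]) / (t[j] - t[i])))


def _var_s(n: int, tie_counts: np.ndarray | None = None) -> float:
    var = n * (n - 1) * (2 * n + 5) / 18.0
    if tie_counts is not None:
        tc = tie_counts[tie_counts > 1]
        var -= float(np.sum(tc * (tc - 1) * (2 * tc + 5))) / 18.0
    return var


def mk_test(values, min_n: int = 4, tie_correction: bool = False) -> tuple[int, float, float]:
    """Mann-Kendall test: returns (S, Var(S), Z).

    S = sum over pairs j>i of sign(v_j - v_i); Var(S) = n(n-1)(2n+5)/18
    (optionally tie-corrected); Z uses the continuity correction
    (S-1)/sqrt(Var) for S>0, (S+1)/sqrt(Var) for S<0, 0 for S=0.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < min_n:
        raise ValueError(f"Mann-Kendall normal approximation needs n >= {min_n}")
    i, j = _pair_indices(n)
    s = int(np.sum(np.sign(v[j] - v[i])))
    ties = pd.Series(v).value_counts().to_numpy() if tie_correction else None
    var = _var_s(n, ties)
    if s > 0:
        z = (s - 1) / np.sqrt(var)
    elif s < 0:
        z = (s + 1) / np.sqrt(var)
    else:
        z = 0.0
    return s, var, float(z)


def classify_trend(
    beta: float,
    z: float,
    beta_threshold: float = DEFAULT_BETA_THRESHOLD,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> TrendClass:
    """Five-class trend label from slope magnitude and MK significance."""
    if beta_threshold <= 0 or z_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if abs(beta) < beta_threshold:
        return TrendClass.NoTrend
    significant = abs(z) >= z_threshold
    if beta > 0:
        return TrendClass.SignificantIncrease if significant else TrendClass.SlightIncrease
    return TrendClass.SignificantDecrease if significant else TrendClass.SlightDecrease


def trend_analysis(
    values,
    times=None,
    beta_threshold: float = DEFAULT_BETA_THRESHOLD,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> TrendResult:
    """Full scalar pipeline: Sen slope, MK test, classification."""
    beta = sen_slope(values, times)
    s, var, z = mk_test(values)
    return TrendResult(beta, s, var, z, classify_trend(beta, z, beta_threshold, z_threshold))


def trend_raster(
    stack: list[Raster],
    times=None,
    beta_threshold: float = DEFAULT_BETA_THRESHOLD,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    block_rows: int = 256,
) -> tuple[Raster, Raster, Raster]:
    """Per-pixel Sen+MK over a stack of annual rasters.

    Returns (beta raster, Z raster, class raster). Pixels with any no-data
    year become no-data (NaN for beta/Z, 0 for the byte class raster).
    Computation is vectorised over all n(n-1)/2 year pairs and chunked by
    row blocks so memory stays modest on large grids.
    """
    n = len(stack)
    if n < 4:
        raise ValueError("trend mapping needs at least four annual rasters")
    ref = stack[0]
    for r in stack[1:]:
        if not ref.same_grid(r):
            raise ValueError("rasters in the stack do not share a common grid")
    t = np.arange(n, dtype=float) if times is None else np.asarray(times, dtype=float)
    data = np.stack([r.data.astype(float) for r in stack])  # (n, H, W)
    valid = np.stack([r.valid_mask() for r in stack]).all(axis=0)
    i, j = _pair_indices(n)
    dt = (t[j] - t[i])[:, None, None]
    var = _var_s(n)
    H, W = ref.shape
    beta = np.full((H, W), np.nan)
    z = np.full((H, W), np.nan)
    cls = np.zeros((H, W), dtype=np.uint8)
    for r0 in range(0, H, block_rows):
        r1 = min(r0 + block_rows, H)
        block = data[:, r0:r1, :]
        diffs = block[j] - block[i]  # (pairs, rows, W)
        b = np.median(diffs / dt, axis=0)
        s = np.sign(diffs).sum(axis=0)
        zb = np.where(s > 0, (s - 1) / np.sqrt(var), np.where(s < 0, (s + 1) / np.sqrt(var), 0.0))
        cb = np.full(b.shape, int(TrendClass.NoTrend), dtype=np.uint8)
        sig = np.abs(zb) >= z_threshold
        up = b >= beta_threshold
        down = b <= -beta_threshold
        cb[up & sig] = int(TrendClass.SignificantIncrease)
        cb[up & ~sig] = int(TrendClass.SlightIncrease)
        cb[down & ~sig] = int(TrendClass.SlightDecrease)
        cb[down & sig] = int(TrendClass.SignificantDecrease)
        vmask = valid[r0:r1]
        beta[r0:r1] = np.where(vmask, b, np.nan)
        z[r0:r1] = np.where(vmask, zb, np.nan)
        cls[r0:r1] = np.where(vmask, cb, 0)
    nan = float("nan")
    return (
        Raster(beta, ref.transform, nodata=nan, crs=ref.crs),
        Raster(z, ref.transform, nodata=nan, crs=ref.crs),
        Raster(cls, ref.transform, nodata=0, crs=ref.crs),
    )


def summarize_classes(class_raster: Raster, mask: np.ndarray | None = None) -> pd.DataFrame:
    """Area (km^2) and percentage per trend class, plus improved/degraded rows.

    Percentages are over valid (classified) pixels. "improved" aggregates
    slight + significant increase; "degraded" slight + significant decrease.
    """
    valid = class_raster.valid_mask()
    if mask is not None:
        valid = valid & mask
    total = int(valid.sum())
    if total == 0:
        raise ValueError("class raster has no valid pixels")
    km2_per_pixel = class_raster.pixel_area_ha / 100.0
    rows = []
    counts = {}
    for tc in TrendClass:
        c = int(np.count_nonzero(class_raster.data[valid] == int(tc)))
        counts[tc] = c
        rows.append((tc.name, c * km2_per_pixel, 100.0 * c / total))
    improved = counts[TrendClass.SlightIncrease] + counts[TrendClass.SignificantIncrease]
    degraded = counts[TrendClass.SlightDecrease] + counts[TrendClass.SignificantDecrease]
    rows.append(("Improved", improved * km2_per_pixel, 100.0 * improved / total))
    rows.append(("Degraded", degraded * km2_per_pixel, 100.0 * degraded / total))
    return pd.DataFrame(rows, columns=["trend_class", "area_km2", "percent"])
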