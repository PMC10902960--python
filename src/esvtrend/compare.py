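"""Mining-impact vs control comparison on sample points and grid cells.

Sample points are drawn uniformly inside the study polygon and labelled
mining-impact or control by containment in the (optionally buffered)
concession polygons. Each point's value is the mean of a value raster over
a disc buffer (default radius 1 km); groups are compared with the
Mann-Whitney U rank test (two-sided, tie-corrected), with an independent
t-test available as a secondary check. A 10 km x 10 km grid aggregation
mirrors the coarse-scale evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import stats

from .core import Raster

__all__ = [
    "SamplePointSet",
    "sample_points",
    "buffer_extract",
    "grid_aggregate",
    "mann_whitney",
    "t_test",
    "group_summary",
]

MINING = "mining_impact"
CONTROL = "control"


@dataclass
class SamplePointSet:
    """Random sample points with group labels in raster coordinates."""

    x: np.ndarray
    y: np.ndarray
    group: np.ndarray  # "mining_impact" | "control"
    buffer_radius: float = 1000.0

    def __len__(self) -> int:
        return len(self.x)

    def subset(self, group: str) -> "SamplePointSet":
        m = self.group == group
        return SamplePointSet(self.x[m], self.y[m], self.group[m], self.buffer_radius)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "group": self.group})


def sample_points(
    study_polygon: shapely.Geometry,
    impact_polygons: shapely.Geometry | list[shapely.Geometry],
    n: int = 300,
    seed: int = 0,
    buffer_radius: float = 1000.0,
    influence_buffer: float = 0.0,
) -> SamplePointSet:
    """n uniform random points in the study polygon, labelled by impact containment.

    ``influence_buffer`` dilates the concession polygons (metres) before the
    containment test; the default 0 labels only points inside the
    concessions themselves.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if study_polygon.is_empty or study_polygon.area == 0:
        raise ValueError("study polygon is empty")
    if not isinstance(impact_polygons, shapely.Geometry):
        impact_polygons = shapely.union_all(list(impact_polygons))
    if influence_buffer:
        impact_polygons = impact_polygons.buffer(influence_buffer)
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = study_polygon.bounds
    xs, ys = [], []
    needed = n
    while needed > 0:
        m = max(needed * 4, 64)  # rejection sampling against the bounding box
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        inside = shapely.contains_xy(study_polygon, cx, cy)
        xs.append(cx[inside][:needed])
        ys.append(cy[inside][:needed])
        needed -= len(xs[-1])
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    grp = np.where(shapely.contains_xy(impact_polygons, x, y), MINING, CONTROL)
    return SamplePointSet(x, y, grp, buffer_radius)


def buffer_extract(raster: Raster, points: SamplePointSet) -> pd.DataFrame:
    """Mean raster value per point over its disc buffer.

    The disc membership rule is pixel-center-in-circle. Points whose buffer
    contains no valid pixel get NaN and are flagged; edge points average
    whatever valid pixels remain.
    Returns a DataFrame with columns x, y, group, mean, n_pixels, missing.
    """
    X, Y = raster.transform.cell_centers(raster.shape)
    valid = raster.valid_mask()
    vals = raster.data.astype(float)
    r2 = points.buffer_radius**2
    means = np.empty(len(points))
    counts = np.empty(len(points), dtype=int)
    for i, (px, py) in enumerate(zip(points.x, points.y)):
        disc = (X - px) ** 2 + (Y - py) ** 2 <= r2
        sel = disc & valid
        c = int(sel.sum())
        counts[i] = c
        means[i] = vals[sel].mean() if c else np.nan
    return pd.DataFrame(
        {
            "x": points.x,
            "y": points.y,
            "group": points.group,
            "mean": means,
            "n_pixels": counts,
            "missing": counts == 0,
        }
    )


def grid_aggregate(raster: Raster, cell_size: float = 10_000.0) -> tuple[pd.DataFrame, Raster]:
    """Aggregate a value raster onto a coarse square grid anchored at the origin.

    Returns (per-cell table with mean/total/pixel count, coarse mean
    raster). Partial edge cells are kept; per-cell totals conserve the
    raster total over valid pixels.
    """
    tr = raster.transform
    if cell_size < tr.dx or cell_size < tr.dy:
        raise ValueError("cell size must be at least the pixel size")
    ny = int(np.ceil(tr.dy * raster.shape[0] / cell_size))
    nx = int(np.ceil(tr.dx * raster.shape[1] / cell_size))
    rows_per = cell_size / tr.dy
    cols_per = cell_size / tr.dx
    data = raster.data.astype(float)
    valid = raster.valid_mask()
    rec = []
    coarse = np.full((ny, nx), np.nan)
    for gy in range(ny):
        r0, r1 = int(round(gy * rows_per)), min(int(round((gy + 1) * rows_per)), raster.shape[0])
        for gx in range(nx):
            c0, c1 = int(round(gx * cols_per)), min(int(round((gx + 1) * cols_per)), raster.shape[1])
            block = data[r0:r1, c0:c1]
            vmask = valid[r0:r1, c0:c1]
            c = int(vmask.sum())
            tot = float(block[vmask].sum()) if c else 0.0
            mean = tot / c if c else np.nan
            coarse[gy, gx] = mean
            rec.append((gy, gx, c, tot, mean))
    table = pd.DataFrame(rec, columns=["row", "col", "n_pixels", "total", "mean"])
    coarse_tr = type(tr)(tr.x0, tr.y0, cell_size, cell_size)
    return table, Raster(coarse, coarse_tr, nodata=float("nan"), crs=raster.crs)


def _clean(values) -> tuple[np.ndarray, int]:
    v = np.asarray(values, dtype=float)
    out = v[~np.isnan(v)]
    return out, len(v) - len(out)


def mann_whitney(group_a, group_b, alpha: float = 0.05) -> dict:
    """Two-sided Mann-Whitney U test with tie-corrected normal p (exact for tiny n).

    Returns U (for group A), p, significance flag at ``alpha``, per-group
    medians and interquartile ranges, and counts of dropped missing values.
    """
    a, drop_a = _clean(group_a)
    b, drop_b = _clean(group_b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("a group is empty after dropping missing values")
    method = "exact" if max(len(a), len(b)) <= 8 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    q1a, q3a = np.percentile(a, [25, 75])
    q1b, q3b = np.percentile(b, [25, 75])
    return {
        "U": float(res.statistic),
        "p": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "iqr_a": float(q3a - q1a),
        "iqr_b": float(q3b - q1b),
        "n_a": len(a),
        "n_b": len(b),
        "dropped_a": drop_a,
        "dropped_b": drop_b,
    }


def t_test(group_a, group_b, alpha: float = 0.05) -> dict:
    """Independent-samples t-test (secondary parametric check)."""
    a, _ = _clean(group_a)
    b, _ = _clean(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("t-test needs at least two values per group")
    res = stats.ttest_ind(a, b)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "significant": bool(res.pvalue < alpha),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }


def group_summary(values) -> dict:
    """Boxplot-style summary: median, quartiles, IQR, Tukey-fence outlier count."""
    v, _ = _clean(values)
    if len(v) == 0:
        raise ValueError("no values to summarise")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return {
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "iqr": float(iqr),
        "n_outliers": int(np.count_nonzero((v < lo) | (v > hi))),
        "n": len(v),
    }
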