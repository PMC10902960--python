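"""Shared domain types: land-use legend, service legend, rasters, tables.

Conventions used throughout the package:

* rasters live on a projected, north-up grid with square-ish pixels in
  metres; pixel area is derived from the grid and expressed in hectares,
  the unit all value coefficients are quoted in;
* land-use rasters are integer-coded with one designated no-data value
  (default 255);
* monetary quantities are plain floats in a single currency (CNY in the
  bundled coefficient set).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely

__all__ = [
    "ServiceType",
    "LandUseClass",
    "GridTransform",
    "Raster",
    "EquivalentWeightTable",
    "SocioEconomicSeries",
    "LandUseSeries",
    "AreaByClass",
    "tabulate_areas",
    "DEFAULT_NODATA",
]

DEFAULT_NODATA = 255


class ServiceType(enum.Enum):
    """The nine ecosystem service types priced by the equivalent-factor method."""

    GR = "gas regulation"
    CR = "climate regulation"
    WS = "water supply"
    SFR = "soil formation and retention"
    WT = "waste treatment"
    BP = "biodiversity protection"
    F = "food"
    RM = "raw material"
    RC = "recreation and culture"

    @property
    def long_name(self) -> str:
        return self.value


class LandUseClass(enum.IntEnum):
    """Seven-class land-use/land-cover legend with fixed integer raster codes."""

    Woodland = 1
    Grassland = 2
    Cropland = 3
    Wetland = 4
    Waterbody = 5
    UnusedLand = 6
    BuiltUp = 7

    @classmethod
    def legend(cls) -> dict[int, str]:
        return {int(c): c.name for c in cls}


@dataclass(frozen=True)
class GridTransform:
    """North-up affine grid: world x = x0 + col*dx, world y = y0 - row*dy.

    (x0, y0) is the outer corner of the upper-left pixel; dx, dy are pixel
    sizes in metres and must be positive.
    """

    x0: float
    y0: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("pixel sizes dx, dy must be positive")

    @property
    def pixel_area_ha(self) -> float:
        return self.dx * self.dy / 10_000.0

    def cell_centers(self, shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of pixel-center coordinates for a raster shape."""
        rows, cols = shape
        xs = self.x0 + (np.arange(cols) + 0.5) * self.dx
        ys = self.y0 - (np.arange(rows) + 0.5) * self.dy
        return np.meshgrid(xs, ys)

    def extent_polygon(self, shape: tuple[int, int]) -> shapely.Polygon:
        rows, cols = shape
        return shapely.box(
            self.x0, self.y0 - rows * self.dy, self.x0 + cols * self.dx, self.y0
        )


@dataclass
class Raster:
    """A single-band raster: numpy array + grid + no-data sentinel.

    Categorical rasters use integer dtypes with an integer ``nodata``;
    continuous rasters use float dtypes with ``nodata=nan``.
    """

    data: np.ndarray
    transform: GridTransform
    nodata: float | int | None = DEFAULT_NODATA
    crs: str = "local-metric"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def pixel_area_ha(self) -> float:
        return self.transform.pixel_area_ha

    def valid_mask(self) -> np.ndarray:
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        if isinstance(self.nodata, float) and np.isnan(self.nodata):
            return ~np.isnan(self.data)
        return self.data != self.nodata

    def same_grid(self, other: "Raster") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def mask_for(self, geoms: Sequence[shapely.Geometry] | shapely.Geometry) -> np.ndarray:
        """Boolean mask of pixels whose centers fall inside the given geometry."""
        if isinstance(geoms, shapely.Geometry):
            geom = geoms
        else:
            geom = shapely.union_all(list(geoms))
        X, Y = self.transform.cell_centers(self.shape)
        return shapely.contains_xy(geom, X, Y)


class EquivalentWeightTable:
    """Dimensionless service weights per land-use class (7 x 9 matrix).

    A weight of 1 corresponds to the base unit value D (one-seventh of the
    mean per-hectare grain production value); negative entries encode
    disservices of built-up land. Row totals are always recomputed from the
    cells.
    """

    def __init__(self, weights: Mapping[LandUseClass, Mapping[ServiceType, float]]):
        missing = []
        self._w: dict[LandUseClass, dict[ServiceType, float]] = {}
        for k in LandUseClass:
            row = weights.get(k)
            self._w[k] = {}
            for f in ServiceType:
                if row is None or f not in row:
                    missing.append((k.name, f.name))
                else:
                    self._w[k][f] = float(row[f])
        if missing:
            raise ValueError(f"incomplete weight table; missing cells: {missing}")

    def weight(self, k: LandUseClass, f: ServiceType) -> float:
        return self._w[k][f]

    def row(self, k: LandUseClass) -> dict[ServiceType, float]:
        return dict(self._w[k])

    def row_total(self, k: LandUseClass) -> float:
        return float(sum(self._w[k].values()))

    def as_matrix(self) -> np.ndarray:
        """(n_class, n_service) array in enum order."""
        return np.array(
            [[self._w[k][f] for f in ServiceType] for k in LandUseClass]
        )

    @classmethod
    def from_matrix(cls, m: np.ndarray) -> "EquivalentWeightTable":
        m = np.asarray(m, dtype=float)
        if m.shape != (len(LandUseClass), len(ServiceType)):
            raise ValueError(f"expected shape {(len(LandUseClass), len(ServiceType))}")
        return cls(
            {
                k: {f: m[i, j] for j, f in enumerate(ServiceType)}
                for i, k in enumerate(LandUseClass)
            }
        )


@dataclass
class SocioEconomicSeries:
    """Annual socioeconomic drivers of the dynamic valuation.

    gdp_index is the year-over-year GDP ratio (1.05 = 5 % nominal growth);
    engel is the Engel coefficient, the food share of household spending,
    in (0, 1].
    """

    years: np.ndarray
    gdp: np.ndarray
    gdp_index: np.ndarray
    engel: np.ndarray
    grain_yield: np.ndarray
    grain_price: np.ndarray

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        for name in ("gdp", "gdp_index", "engel", "grain_yield", "grain_price"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.years.shape:
                raise ValueError(f"{name} length does not match years")
            setattr(self, name, arr)
        d = np.diff(self.years)
        if len(self.years) and not np.all(d == 1):
            raise ValueError("years must be strictly increasing and contiguous")
        if np.any(self.gdp_index <= 0):
            raise ValueError("gdp_index must be positive")
        if np.any((self.engel <= 0) | (self.engel > 1)):
            raise ValueError("engel coefficient must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.years)

    def index_of(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if len(idx) == 0:
            raise KeyError(f"year {year} not in series ({self.years[0]}-{self.years[-1]})")
        return int(idx[0])


@dataclass
class LandUseSeries:
    """Ordered annual categorical rasters on one shared grid."""

    years: list[int]
    rasters: list[Raster]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.rasters):
            raise ValueError("one raster per year required")
        if len(set(self.years)) != len(self.years):
            raise ValueError("duplicate years")
        ref = self.rasters[0]
        for r in self.rasters[1:]:
            if not ref.same_grid(r):
                raise ValueError("all rasters must share shape and grid transform")

    @property
    def pixel_area_ha(self) -> float:
        return self.rasters[0].pixel_area_ha

    def raster_for(self, year: int) -> Raster:
        try:
            return self.rasters[self.years.index(year)]
        except ValueError:
            raise KeyError(f"year {year} not in land-use series {self.years}") from None


AreaByClass = dict  # Mapping[LandUseClass, float], hectares


def tabulate_areas(
    series: LandUseSeries,
    year: int,
    mask: shapely.Geometry | Sequence[shapely.Geometry] | None = None,
) -> AreaByClass:
    """Per-class areas (hectares) in one year, optionally inside polygons.

    A pixel counts toward a class if its value is that class's code, it is
    not no-data, and (when a mask is given) its center lies inside the mask
    geometry. Returns a dict over all seven classes; classes absent from
    the raster get 0.0.
    """
    raster = series.raster_for(year)
    valid = raster.valid_mask()
    if mask is not None:
        inmask = raster.mask_for(mask)
        if not inmask.any():
            warnings.warn(
                "mask is disjoint from the raster extent; all areas are zero",
                stacklevel=2,
            )
        valid = valid & inmask
    if not valid.any() and mask is None:
        warnings.warn("raster contains no valid pixels", stacklevel=2)
    pa = raster.pixel_area_ha
    areas: AreaByClass = {}
    vals = raster.data[valid]
    known = set()
    for k in LandUseClass:
        areas[k] = float(np.count_nonzero(vals == int(k)) * pa)
        known.add(int(k))
    stray = set(np.unique(vals).tolist()) - known
    if stray:
        raise ValueError(f"raster contains values outside the legend: {sorted(stray)}")
    return areas
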