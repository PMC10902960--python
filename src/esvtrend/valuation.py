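"""Benefit-transfer valuation: static, comparable and dynamic ESV.

The pipeline is:

1. calibrate the base unit value ``D`` (CNY/ha) as one-seventh of the mean
   grain production value per hectare;
2. multiply ``D`` into the equivalent-weight table to obtain per-class,
   per-service value coefficients VC[k, f] (CNY/ha/yr);
3. static ESV is the area-weighted sum: ESV_s = sum_k sum_f A_k * VC[k, f];
4. the comparable ESV deflates the static total to a constant-price base
   year through the chained year-over-year GDP index;
5. the dynamic ESV scales the comparable ESV by a logistic
   willingness-to-pay coefficient Ac = 1/(1+exp(-t)), t = 1/Engel - 3,
   so richer societies (lower Engel coefficient) value services more.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import (
    AreaByClass,
    EquivalentWeightTable,
    LandUseClass,
    Raster,
    ServiceType,
    SocioEconomicSeries,
)

__all__ = [
    "GRAIN_VALUE_DIVISOR",
    "ValueCoefficientTable",
    "EsvAccount",
    "calibrate_unit_value",
    "build_value_table",
    "esv_totals",
    "deflate_series",
    "comparable_esv",
    "dynamic_adjust",
    "esv_raster",
]

#: the conventional fraction of grain production value defining one weight unit
GRAIN_VALUE_DIVISOR = 7.0


def calibrate_unit_value(
    grain_yield: float, grain_price: float, divisor: float = GRAIN_VALUE_DIVISOR
) -> float:
    """Base unit value D (currency/ha): yield * price / divisor.

    Parameters
    ----------
    grain_yield : mean grain yield, kg/ha.
    grain_price : grain price, currency/kg.
    divisor : the one-weight-unit convention, default 7.
    """
    if grain_yield <= 0 or grain_price <= 0:
        raise ValueError("grain yield and price must be positive")
    return grain_yield * grain_price / divisor


class ValueCoefficientTable:
    """Monetary value coefficients VC[k, f] = weight[k, f] * D (currency/ha/yr)."""

    def __init__(self, weights: EquivalentWeightTable, base_unit_value: float):
        if base_unit_value <= 0:
            raise ValueError("base unit value D must be positive")
        self.weights = weights
        self.base_unit_value = float(base_unit_value)
        self._m = weights.as_matrix() * self.base_unit_value

    def vc(self, k: LandUseClass, f: ServiceType) -> float:
        return self.weights.weight(k, f) * self.base_unit_value

    def row_total(self, k: LandUseClass) -> float:
        """Total value per hectare of class k across all nine services."""
        return self.weights.row_total(k) * self.base_unit_value

    def as_matrix(self) -> np.ndarray:
        """(n_class, n_service) coefficient array in enum order."""
        return self._m.copy()


def build_value_table(
    weights: EquivalentWeightTable, base_unit_value: float
) -> ValueCoefficientTable:
    """Scale a complete weight table by the base unit value D."""
    return ValueCoefficientTable(weights, base_unit_value)


@dataclass
class EsvAccount:
    """Per-year valuation totals. Currency units follow the coefficient table."""

    year: int
    esv_by_service: dict[ServiceType, float]
    esv_by_class: dict[LandUseClass, float]
    esv_static: float
    esv_comparable: float | None = None
    esv_dynamic: float | None = None
    adjustment: "AdjustmentState | None" = None


@dataclass
class AdjustmentState:
    """Socioeconomic adjustment factors for one year."""

    e_an: float  # deflated economic level, constant prices of the base year
    e_avg: float  # period mean of e_an
    e_m: float  # nominal economic level (GDP by default)
    t: float  # development stage, 1/Engel - 3
    ac: float  # logistic willingness-to-pay coefficient in (0, 1)


def esv_totals(areas: AreaByClass, vc: ValueCoefficientTable, year: int = 0) -> EsvAccount:
    """Static valuation of a class-area vector.

    ESV_f = sum_k A_k VC[k,f]; ESV_k = sum_f A_k VC[k,f]; ESV_s sums both ways.
    """
    a = np.zeros(len(LandUseClass))
    for i, k in enumerate(LandUseClass):
        ak = float(areas.get(k, 0.0))
        if ak < 0:
            raise ValueError(f"negative area for {k.name}")
        a[i] = ak
    m = vc.as_matrix()  # (class, service)
    by_service_arr = a @ m
    by_class_arr = m.sum(axis=1) * a
    return EsvAccount(
        year=year,
        esv_by_service={f: float(by_service_arr[j]) for j, f in enumerate(ServiceType)},
        esv_by_class={k: float(by_class_arr[i]) for i, k in enumerate(LandUseClass)},
        esv_static=float(by_service_arr.sum()),
    )


def deflate_series(
    socio: SocioEconomicSeries, base_year: int, measure: str = "gdp"
) -> tuple[np.ndarray, float]:
    """Deflate the nominal series to constant base-year prices.

    E_an(m) = E_m(m) / prod_{i=base+1..m} gdp_index(i); the product is empty
    at the base year, so E_an(base) = E_m(base). Returns (E_an per year from
    the base year on, E_avg = mean of E_an).
    """
    b = socio.index_of(base_year)
    e_m = getattr(socio, measure)
    idx = socio.gdp_index
    # cumulative chained deflator, anchored at 1 in the base year
    deflator = np.ones(len(socio) - b)
    if len(deflator) > 1:
        deflator[1:] = np.cumprod(idx[b + 1 :])
    e_an = e_m[b:] / deflator
    return e_an, float(e_an.mean())


def comparable_esv(esv_static: float, e_avg: float, e_an: float) -> float:
    """Constant-price comparable ESV: ESV_c = ESV_s * E_an / E_avg."""
    if e_avg == 0:
        raise ValueError("E_avg must be non-zero")
    return esv_static / e_avg * e_an


def dynamic_adjust(esv_comparable: float, engel: float) -> tuple[float, float, float]:
    """Willingness-to-pay adjustment from the Engel coefficient.

    Returns (t, Ac, ESV_d) with t = 1/Engel - 3, Ac = 1/(1+exp(-t)) and
    ESV_d = ESV_c * Ac. Ac is a Pearl S-curve of the development stage:
    strictly decreasing in the Engel coefficient, bounded in (0, 1).
    """
    if not (0 < engel <= 1):
        raise ValueError("Engel coefficient must lie in (0, 1]")
    t = 1.0 / engel - 3.0
    ac = 1.0 / (1.0 + math.exp(-t))
    return t, ac, esv_comparable * ac


def esv_raster(
    landuse: Raster, vc: ValueCoefficientTable, per: str = "hectare"
) -> Raster:
    """Continuous ESV raster from a categorical land-use raster.

    Each valid pixel carries the total per-hectare value of its class
    (sum over the nine services); with ``per="pixel"`` values are scaled
    by the pixel area so the raster sums to the territory total. No-data
    propagates as NaN.
    """
    if per not in ("hectare", "pixel"):
        raise ValueError('per must be "hectare" or "pixel"')
    lut = np.full(256, np.nan)
    for k in LandUseClass:
        lut[int(k)] = vc.row_total(k)
    valid = landuse.valid_mask()
    codes = landuse.data
    stray = np.setdiff1d(np.unique(codes[valid]), [int(k) for k in LandUseClass])
    if stray.size:
        raise ValueError(f"pixel classes missing from the coefficient table: {stray.tolist()}")
    out = np.where(valid, lut[codes.astype(np.intp)], np.nan)
    if per == "pixel":
        out = out * landuse.pixel_area_ha
    return Raster(out.astype(np.float64), landuse.transform, nodata=float("nan"), crs=landuse.crs)
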