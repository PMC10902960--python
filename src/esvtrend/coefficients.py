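"""Bundled equivalent-weight factors for an arid/semi-arid grassland region.

The weights follow the Chinese equivalent-factor benefit-transfer tradition
(Costanza-style service list, regionally adapted): one weight unit equals
the base unit value D, itself calibrated as one-seventh of the mean
per-hectare grain production value. Built-up land carries negative weights
for water supply, gas regulation and waste treatment (sealed surfaces are a
net disservice for these).

The Waterbody water-supply weight (20.97) is reconstructed from the row
total, the source table being ambiguous for that single cell; open water
dominating the water-supply service makes this the natural placement.
Row totals are never stored - always recomputed from the cells.
"""

from __future__ import annotations

from .core import EquivalentWeightTable, LandUseClass, ServiceType

__all__ = ["default_weight_table", "STEPPE_WEIGHTS"]

# service order: GR, CR, WS, SFR, WT, BP, F, RM, RC
STEPPE_WEIGHTS: dict[LandUseClass, tuple[float, ...]] = {
    LandUseClass.Woodland: (2.35, 7.03, 0.37, 3.08, 1.99, 2.60, 0.10, 0.71, 1.14),
    LandUseClass.Grassland: (0.51, 1.34, 0.08, 1.95, 0.44, 0.56, 0.30, 0.14, 0.25),
    LandUseClass.Cropland: (0.67, 0.36, 0.02, 1.15, 0.10, 0.13, 0.85, 0.40, 0.06),
    LandUseClass.Wetland: (1.91, 7.11, 5.50, 2.49, 3.60, 7.87, 0.51, 0.50, 4.73),
    LandUseClass.Waterbody: (0.77, 14.62, 20.97, 0.41, 5.55, 2.55, 0.80, 0.23, 4.34),
    LandUseClass.UnusedLand: (0.00, 0.00, 0.02, 0.14, 0.01, 0.12, 0.01, 0.03, 0.01),
    LandUseClass.BuiltUp: (-2.42, 0.00, -7.51, 0.02, -2.46, 0.00, 0.00, 0.00, 0.00),
}


def default_weight_table() -> EquivalentWeightTable:
    """The bundled 7-class x 9-service weight table."""
    return EquivalentWeightTable(
        {
            k: {f: v for f, v in zip(ServiceType, row)}
            for k, row in STEPPE_WEIGHTS.items()
        }
    )
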