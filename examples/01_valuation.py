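"""Benefit-transfer valuation of a small landscape.

Calibrates the base unit value from grain statistics, builds the
coefficient table, and values a hypothetical class-area vector through
the static -> comparable -> dynamic chain.
"""

from esvtrend import (
    LandUseClass,
    build_value_table,
    calibrate_unit_value,
    comparable_esv,
    default_weight_table,
    dynamic_adjust,
    esv_totals,
)

# one equivalent-weight unit = 1/7 of the mean grain value per hectare
D = calibrate_unit_value(grain_yield=4405, grain_price=3.05)
print(f"base unit value D = {D:.2f} CNY/ha")

vc = build_value_table(default_weight_table(), D)
print(f"woodland, all nine services: {vc.row_total(LandUseClass.Woodland):,.2f} CNY/ha/yr")
print(f"built-up (net disservice):   {vc.row_total(LandUseClass.BuiltUp):,.2f} CNY/ha/yr")

# a 1000-ha steppe catchment: mostly grassland, some cropland and bare ground
areas = {
    LandUseClass.Grassland: 780.0,
    LandUseClass.Cropland: 120.0,
    LandUseClass.Woodland: 60.0,
    LandUseClass.UnusedLand: 30.0,
    LandUseClass.BuiltUp: 10.0,
}
acct = esv_totals(areas, vc)
print(f"\nstatic ESV of the 1000-ha catchment: {acct.esv_static:,.0f} CNY/yr")

# deflate to constant prices (here: the economy is 20% above the period mean)
esv_c = comparable_esv(acct.esv_static, e_avg=100.0, e_an=120.0)
# willingness-to-pay adjustment at an Engel coefficient of 0.35
t, ac, esv_d = dynamic_adjust(esv_c, engel=0.35)
print(f"comparable ESV (constant prices):    {esv_c:,.0f} CNY/yr")
print(f"dynamic ESV (Ac = {ac:.3f} at Engel 0.35): {esv_d:,.0f} CNY/yr")
print("\nThe dynamic total is what a trend analysis should track: it folds in")
print("both price comparability and society's evolving willingness to pay.")
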