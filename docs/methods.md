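# Methods

## Valuation model

The valuation follows the equivalent-factor benefit-transfer tradition:
ecosystem services are priced relative to a base unit value *D*, defined
as one-seventh of the mean per-hectare grain production value
(*D* = yield × price / 7). The divisor is the conventional
"one-seventh-of-grain-value" rule; it is exposed as a parameter
(`calibrate_unit_value(..., divisor=7)`) for users working with other
conventions. With the bundled statistics (4405 kg/ha, 3.05 CNY/kg) the
base value is 1919.32 CNY/ha.

The bundled 7-class × 9-service weight table targets an arid/semi-arid,
grassland-dominated region. Three caveats are recorded here rather than
hidden:

* the Waterbody × water-supply weight (20.97) is **reconstructed** from
  the row total, the source material being ambiguous for that single
  cell; open water dominating the water-supply service makes this the
  natural placement;
* row totals are always recomputed from the cells and never read from a
  printed summary (two rows of the source material have inconsistent
  printed totals: Grassland cells sum to 5.57 against a printed 5.49, and
  Wetland to 34.22 against 54.2 — the cells win);
* built-up land carries negative weights for gas regulation, water supply
  and waste treatment, so heavily built-up mosaics can have negative
  per-hectare totals. Downstream stages must tolerate negative values
  (the trend stage does; the log-linear joinpoint stage, by construction,
  requires positive series and raises otherwise).

The monetary coefficient table is always rebuilt as weight × *D*; no
pre-multiplied table is ever read as authority.

### Temporal adjustment

Nominal economic levels are deflated through the chained year-over-year
GDP index, with an empty product at the base year (the base year is
unchanged — deflating it by its own index would contradict the notion of
a base year). `E_avg` is the arithmetic mean of the deflated series over
the study period. The economic measure bound to the deflation is GDP by
default; `deflate_series(..., measure=...)` accepts any column of the
socioeconomic series (e.g. per-capita net income).

The willingness-to-pay coefficient is a Pearl (logistic) curve of the
development stage, A_c = 1/(1+e^(−t)) with t = 1/Engel − 3: at an Engel
coefficient of 1/3 the society is at the curve's midpoint (A_c = 0.5),
and A_c is strictly decreasing in the Engel coefficient. The Engel
coefficient is supplied per year, so A_c varies annually; a constant
value is the degenerate configuration.

Constant-price base year defaults to 1990 throughout.

## Trend stage

Theil-Sen slope: the median of all n(n−1)/2 pairwise slopes, with the
mean of the two central values at even counts. Mann-Kendall: S is the
concordant-minus-discordant pair count; Var(S) = n(n−1)(2n+5)/18, with a
tie correction available but off by default; Z applies the continuity
correction (S−1)/√Var for S>0 and (S+1)/√Var for S<0 (the corrected form
preserves the antisymmetry Z(−series) = −Z(series)). The minimum length
for the normal approximation is 4 (configurable).

Classification thresholds default to |β| ≥ 0.005 per year for a
non-negligible slope and |Z| ≥ 2.58 (≈1 % two-sided) for significance;
both are parameters, and 1.96 is the natural alternative when working at
the 5 % level. Note the slope threshold is in the value's own units per
year: series scaled to different units need a rescaled threshold.

The raster path vectorises all pairs and processes row blocks
(`block_rows=256`) so memory stays flat in the grid height; pixels with
any missing year are masked out (complete-case, the default) rather than
computed on pairwise-complete data.

## Joinpoint stage

The hinge-basis model ln y = β₀ + β₁t + Σ βᵢ₊₁(t−Tᵢ)₊ is continuous at
every joinpoint by construction; segment slopes accumulate as
bᵢ = β₁ + Σ_{j≤i} βⱼ₊₁. Fits are plain OLS on ln y. Confidence intervals
for APC use the t distribution on the residual degrees of freedom, and
the AAPC interval comes from the delta method on the weighted slope sum
(a linear combination of coefficients, so its variance is exact under the
model); both are asymptotic, not permutation-based.

Breakpoint candidates are restricted to observed (integer-year) time
points, and each segment must keep at least two observations
(`min_seg=2`). The search is exhaustive — for k ≤ 3 on n ≤ 50 that is at
most a few thousand OLS fits, well within interactive use.

The number of joinpoints is chosen by an information criterion
n ln(SSE/n) + p ln(n). The default penalty (`"weighted_bic"`) charges
p = 3k + 2: each joinpoint costs its slope change plus a
*double-weighted* location parameter. The doubling compensates for the
exhaustive location search: the maximal SSE reduction over ~n candidate
placements is stochastically larger than a single χ² draw, so the plain
parameter count (p = 2(k+1), available as `"bic"`) systematically
overfits k in low-noise series. In simulation (one kink, n = 31,
log-noise σ = 0.01, 200 replicates) the weighted penalty recovers the
true model ~97 % of the time against ~85 % for the plain count. Ties
between k values resolve toward fewer joinpoints, making selection
deterministic.

## Comparison stage

Sample points are drawn uniformly in the study polygon by seeded
rejection sampling and labelled by containment in the concession
polygons; an optional influence buffer dilates the concessions first
(default 0 — concession boundary only, since no influence distance is
canonical). Buffer extraction uses the pixel-center-in-disc rule; edge
points average whatever valid pixels remain and points with empty buffers
are flagged and excluded from tests. The Mann-Whitney U test (two-sided,
midranks, tie-corrected normal approximation, exact for groups ≤ 8) is
the primary test, with an independent-samples t-test as the parametric
secondary; boxplot summaries use Tukey fences. Grid aggregation anchors
10-km cells at the raster origin and conserves totals over valid pixels,
keeping partial edge cells.

## Synthetic data

The generator emulates a steppe mining landscape: a seeded
region-growing mosaic with exact per-class pixel quotas (default ~76 %
grassland on a 100 × 100 grid of 1-ha pixels, 1990–2020), rectangular
concession polygons, contiguous BFS mining growth from each concession's
centre converting 30 ha/yr to unused land with a 12 % built-up fringe
from 2002 (the coal-boom onset), and restoration of the oldest mined
pixels to grassland at 5 ha/yr from 2016. A 0.2 %/yr background
class-flip noise outside concessions mimics classification churn. A
transition log records every (from, to) count per year, so class areas
are exactly reconstructible — the conservation bookkeeping used in tests.
Mining demand beyond the remaining concession area is capped with a
warning. When the generator is used at other grid sizes, the expansion
rate should be scaled with concession area to hold the disturbance
fraction (~2.4 %/yr of concession area) — the CLI's `simulate` does this
automatically.

The socioeconomic generator compounds GDP at 10 %/yr (optionally with
log-normal noise) and defines the GDP index as the *realized*
year-over-year ratio, so deflation telescopes exactly and the deflated
economic level is constant — making the willingness-to-pay curve the sole
temporal driver of the control area's dynamic ESV. The Engel coefficient
interpolates 0.38 → 0.33 over the period, which moves A_c by ≈0.7 %/yr —
the default scenario's control-area growth rate, mirroring the
steadily-rising-control vs flat-then-declining-mining contrast the
comparison stage is designed to detect. The bundled piecewise scenarios
(`CONTROL_SCENARIO`, `MINING_SCENARIO`) encode that contrast directly for
the joinpoint harness.

What the generator does **not** emulate: real landscape-metric structure
(patch-size distributions, anisotropy), spatially correlated
classification error, autocorrelated economic shocks, or any real
geography. Passing tests therefore demonstrate the correctness and
statistical calibration of the methods under known-truth conditions, not
the realism of any particular region's numbers.

## Numerical and design notes

* Pixel areas derive from the grid transform and are expressed in
  hectares; rasters are assumed to be in a projected, equal-area-adequate
  CRS with north-up orientation. No reprojection/resampling is provided.
* The land-use legend is fixed at seven classes with one configurable
  no-data code (default 255); encoding/decoding is a bijection and stray
  codes raise rather than silently drop.
* Valuation is linear in areas and in *D*, and the three static
  aggregates (by service, by class, total) are computed from one matrix
  product, so their consistency is exact to floating tolerance whether
  areas are tabulated first or pixels are valued first.
* Degenerate inputs fail loudly: non-positive series in the log model,
  empty groups after dropping missing values, masks disjoint from the
  raster, infeasible joinpoint counts (the error states the feasible
  maximum).
* Problem sizes used in the shipped simulations (100 × 100 pixels,
  31 years, 200–10,000 statistical replicates) were chosen to make every
  calibration check statistically meaningful at interactive run times;
  all scale linearly if enlarged.

## Known limitations

* The equivalent-factor method itself is a transfer approach: absolute
  totals inherit the weight table and the grain-value convention, so
  cross-study comparability of levels is weaker than of trends.
* No pre-whitening for serial autocorrelation in the MK test, and no
  seasonal variant; annual series with strong AR(1) structure will show
  inflated significance.
* Joinpoint inference is conditional on the selected breakpoints
  (post-selection uncertainty is not propagated), matching common
  practice of the reference tools.
* The comparison stage treats sample points as independent; spatial
  autocorrelation within 1-km buffers is not modelled (a spatial-error
  framework is out of scope).
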