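# esvtrend

Ecosystem-services valuation of annual land-use raster series, with trend
mapping and mining-impact analysis. The package is aimed at landscape
ecologists and environmental economists who need to quantify how the
monetary value of ecosystem services evolves over decades in a
human-disturbed region — the motivating setting is opencast coal mining in
an arid/semi-arid steppe, where concessions progressively convert
grassland to bare ground while the surrounding economy (and society's
willingness to pay for services) grows.

## What it computes

**Benefit-transfer valuation.** Each land-use class *k* (woodland,
grassland, cropland, wetland, waterbody, unused land, built-up) carries a
dimensionless equivalent weight *e<sub>kf</sub>* for each of nine services
*f* (gas regulation, climate regulation, water supply, soil formation and
retention, waste treatment, biodiversity protection, food, raw material,
recreation & culture). One weight unit is the base unit value
*D* = (grain yield × grain price) / 7 (CNY/ha). With class areas
*A<sub>k</sub>* and coefficients *VC<sub>kf</sub>* = *e<sub>kf</sub>* · *D*:

- static ESV: ESV<sub>s</sub> = Σ<sub>k</sub> Σ<sub>f</sub> A<sub>k</sub> VC<sub>kf</sub>
- comparable ESV: ESV<sub>c</sub> = ESV<sub>s</sub> · E<sub>an</sub> / E<sub>avg</sub>,
  where E<sub>an</sub> deflates the nominal economic level through the
  chained year-over-year GDP index back to a base year
- dynamic ESV: ESV<sub>d</sub> = ESV<sub>c</sub> · A<sub>c</sub>, with the
  logistic willingness-to-pay coefficient
  A<sub>c</sub> = 1 / (1 + e<sup>−t</sup>), t = 1/Engel − 3

**Trend mapping.** Per pixel (or per series), the Theil-Sen slope β
(median of all pairwise slopes) plus the Mann-Kendall test
(S, Var(S) = n(n−1)(2n+5)/18, continuity-corrected Z) classify each
location into significant/slight increase, no trend, or slight/significant
decrease (defaults: |β| ≥ 0.005, |Z| ≥ 2.58).

**Joinpoint regression.** A continuous segmented log-linear model
ln y<sub>t</sub> = β₀ + β₁t + Σ β<sub>i+1</sub>(t − T<sub>i</sub>)₊ + ε<sub>t</sub>
with exhaustive breakpoint search and information-criterion selection of
the number of joinpoints. Each segment is summarised by its annual percent
change APC = (e<sup>b</sup> − 1)·100 and the period by the segment-length-
weighted AAPC = (exp(Σw<sub>i</sub>b<sub>i</sub>/Σw<sub>i</sub>) − 1)·100.

**Mining vs control comparison.** Random sample points inside the study
area are labelled by containment in concession polygons, valued by
1-km-buffer means, and compared with the Mann-Whitney U test (plus an
optional t-test); a 10-km grid aggregation supports coarse-scale mapping.

**Synthetic data.** A seeded generator produces every input — annual
land-use rasters with concession-driven mining expansion and optional
restoration, socioeconomic series, piecewise log-linear test series — so
the full pipeline runs end to end with no external data.

## Worked example

```bash
python examples/03_joinpoint_apc.py
```

prints (abridged):

```
control area (true breaks (1997, 2005, 2009), true APCs (1.09, 0.43, 1.01, 0.51)):
  selected breakpoints: [1996]
  APC 1990-1996: +1.05%/yr (95% CI +0.88 to +1.21, p=0.000)
  APC 1996-2020: +0.61%/yr (95% CI +0.58 to +0.64, p=0.000)
  AAPC 1990-2020: +0.69%/yr (95% CI +0.67 to +0.72)

mining area (true breaks (1996, 1999, 2007), true APCs (0.0, 0.78, 0.09, -0.67)):
  selected breakpoints: [2006]
  APC 1990-2006: +0.23%/yr (95% CI +0.18 to +0.28, p=0.000)
  APC 2006-2020: -0.63%/yr (95% CI -0.69 to -0.57, p=0.000)
  AAPC 1990-2020: -0.17%/yr (95% CI -0.19 to -0.15)
```

The control series grows ≈0.7 %/yr across 1990–2020 while the mining
series is flat and then declines after the mid-2000s — the AAPC signs
capture the net 30-year contrast even where the small noisy kinks inside
each regime are merged by model selection. The other examples cover the
valuation chain (`01`), per-pixel trend maps (`02`), and the full
simulate→value→trend→joinpoint→compare pipeline (`04`), which is also
available as a CLI: `esvtrend run-all --outdir out --seed 0`.

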