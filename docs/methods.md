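# Methods

## The phenological model

Winter wheat development is driven by thermal time alone. From the sowing
date (September 15 of the year before harvest, the regional standard) the
model accumulates growing degree days

    GDD(d) = Σ_{i=sowing..d} max(T_mean,i − T_base, 0),    T_base = 2.5 °C,

starting on the sowing day inclusive. The harvest date is the first day on
which GDD ≥ T_h, with T_h = 2100 °C·d used for both study regions; the
crossing uses ≥, so a threshold of zero harvests on the sowing day. The
search is censored at December 31 of the harvest year — a wheat season
never spans two summers — and censored seasons are flagged and excluded
from slot means, never imputed.

Assumptions worth stating: no vernalisation requirement, no photoperiod
response, no water or nutrient limitation on development, and raw (not
smoothed) daily means in the heat sum. T_base = 2.5 °C sits between
literature values for root (3 °C) and shoot (2 °C) growth; it is below the
3.8–6.0 °C optimum reported for vernalisation, which matters when cold-day
counts are read as a vernalisation proxy.

### Growing-period length, two conventions

For a winter crop spanning New Year the classical day-of-year formula is

    V_per = JD_h + (365¼ − JD_s).

The ¼ stands in for the leap-day average and makes V_per fractional.  We
compute this "formula" value for comparability with conventional reports,
and alongside it the exact endpoint-inclusive calendar count
`(harvest − sowing).days + 1`.  The two differ by at most about one day
(e.g. sowing Sep 15 2001, harvest Aug 4 2002: 323.25 vs 324).

The per-season cold-day identity uses the exact count:

    cold_days = v_per_exact − v_day.

Using the rounded formula value instead can make the identity negative in
leap sowing years (the formula can undercount the days actually in the
period by up to two), so the exact count is the only convention under
which `0 ≤ v_day ≤ v_per` and `cold_days ≥ 0` hold structurally.  The
stand-alone arithmetic helper `cold_days(v_per, v_day)` still accepts any
integer pair, e.g. published table values 324 − 267 = 57.

### Smoothing and vegetation days

Vegetation days count the days in [sowing, harvest] whose *smoothed*
temperature strictly exceeds T_base; a day exactly at the base temperature
is a cold day.  The smoother is a centred 5-point simple moving average of
the raw daily means.  At the series edges the window truncates to the
available days (the first value of a 5-day window averages days 1–3); a
constant series is a fixed point of the smoother.  The window width is
configurable but must be odd so the window stays centred.

## Hydrological water accounting

The hydrological year runs November 1 – October 31 (DIN 4049) and is
labelled by its ending calendar year, matching harvest-year labels.  Its
winter half is November–April (the leaching period in the region), the
summer half May–October.  Only complete hydrological years are summarised;
partial years at the series edges are dropped.  Within a year,
`p_hw + p_hs = p_ha` holds exactly because both halves are summed from the
same array in the same order.  The winter share `p_hw / p_ha` is kept at
full precision internally and rounded to two decimals only in report
tables; a zero annual total makes the share undefined (flagged `None`),
not zero.

`P_m-veg` sums precipitation from May 1 of the harvest year to the harvest
date, both endpoints inclusive, as are all window sums in the package.  A
harvest before May 1 yields an empty window, 0 mm and a warning.  `P_veg`
(sowing to harvest) is computed as context; `P_m-veg ≤ P_veg` whenever the
harvest is on or after May 1 of its year.

## Time-slot statistics

Metrics are means over 30-year slots (1981–2010 reference, 2041–2070
future).  The SD uses the sample (n−1) denominator — the standard
estimator for a 30-year sample of a climate process.  Between-slot deltas
are future − reference.  Two reporting conventions are honoured: the
winter-share shift is differenced on two-decimal-rounded shares (so
0.47 → 0.54 is exactly +7 points; the full-precision shift is reported
alongside), and the harvest advance is also expressed as
`round(days / 7)` weeks, half away from zero.

## The synthetic weather generator

The generator emulates regionalised scenario series at daily resolution
with exactly the statistical structure the analysis measures, and nothing
more:

* **Temperature** = annual mean + uniform warming offset + one cosine
  harmonic + AR(1) residual.  Defaults: 9.6 °C annual mean, 8.2 °C
  amplitude (16.4 °C annual range, the western-region value; 9.25 °C for
  the eastern presets), peak at day-of-year 200 (late July), lag-one
  autocorrelation 0.7 and stationary residual SD 3 °C — typical for daily
  mean-temperature anomalies in the region.  `ar1_sigma` is the
  *stationary* SD; innovations are scaled by √(1−φ²).  Warming scenarios
  add +1/+2/+3 °C uniformly; an optional per-season offset exists but
  defaults to zero, since the scenarios are characterised purely by their
  temperature gradient.
* **Precipitation**: two-state Markov occurrence (defaults
  p(wet|dry) = 0.30, p(wet|wet) = 0.60, giving a stationary wet-day
  fraction of 3/7) with Gamma(shape 0.75) amounts.  The per-season gamma
  scales are solved analytically from the expected wet-day counts so that
  E[annual total] and E[winter share] hit their targets; the season
  lengths used are the long-run means 181.25 d (winter, including the
  leap day) and 184 d (summer).  With symmetric occurrence and a 0.5
  share the two scales therefore differ by ~1.5 %, reflecting the real
  length asymmetry.  A share target of exactly 0 or 1 combined with an
  occurrence chain that still wets the opposite season is rejected as
  infeasible rather than silently missed.
* Default totals/shares per preset follow the published regional
  statistics (e.g. western reference 705 mm at share 0.47; +2 °C scenario
  711 mm at 0.54).  One integer seed drives every draw; identical
  (config, seed) pairs regenerate bit-identical series.

What the generator does **not** emulate: multi-day synoptic persistence
beyond AR(1)/first-order-Markov, seasonally varying temperature variance,
temperature–precipitation cross-correlation, extremes, and the published
interannual SDs (SD-affecting knobs exist but are not calibrated to
them).  Passing tests therefore demonstrate that the *analysis chain* is
correct and that its qualitative responses to warming and seasonal
redistribution match the published findings; they do not validate the
model against real station records.

## Numerical choices and degenerate inputs

* Dates are true calendar dates throughout; day-of-year numbers appear
  only inside the V_per formula.
* Missing days are a hard error; an opt-in gap fill linearly interpolates
  gaps of ≤3 days and flags every filled day in the validation report.
* Float equality in the water-budget identity is exact by construction
  (same summation order), not tolerance-based.
* Rounding half away from zero is used wherever a convention is needed
  (weeks, fractional V_per), implemented explicitly rather than via
  banker's rounding.
* Empty metric vectors are an error; a single value yields a mean with an
  undefined (None) SD; a zero baseline makes percent change undefined.

## Problem sizes

The test suite and the acceptance script run entirely on generated data:
30-year slots (~11 300 days each) for the end-to-end comparisons, a
~200-year series for the Monte-Carlo calibration check, and 100
single-season series for the heat-sum oracle equivalence check.  The full
suite completes in a few seconds on one CPU.

## Known limitations

* The phenology is a one-parameter heat-sum model; it reproduces 30-year
  mean harvest dates well but individual years can be off by days to
  weeks, so all reported quantities are slot means.
* Censoring couples the slot means: in a climate where some seasons never
  reach the heat sum, excluding them biases V_per low in the colder slot.
  Under the default presets no season is censored.
* The winter-share shift convention (differencing rounded shares) can
  differ from the full-precision shift by up to one percentage point;
  both are reported.
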