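# Methods

## The dose model

The package computes an average daily dose (ADD),

```
ADD = C · IR · EF · k / BW        [mg/kg-day]
```

with concentration `C`, intake rate `IR`, exposure factor `EF` (exposure
duration / averaging time, in [0, 1]), body weight `BW` and an explicit
unit-conversion multiplier `k` applied to the `C·IR` product.  ADD is the
plain time-averaged dose over the exposure period; no lifetime averaging
is performed (that would be a lifetime average daily dose, a different
quantity with different data demands).

**The unit-conversion multiplier is deliberately explicit.**  For air
inhalation (`C` in µg/m³, `IR` in m³/day) the natural value is `k = 1e-3`
(µg → mg).  For soil ingestion (`C` in mg/kg, `IR` in mg of soil/day) the
physically standard conversion would be `k = 1e-6` (mg soil → kg soil),
but the packaged community-scenario fixture reproduces its reference dose
magnitudes (3.91×10⁻⁴ … 5.06 mg/kg-day) only under `k = 1e-3`.  Rather
than silently adopting either convention, `k` is a required field of
`DoseParameters`; the fixture records `1e-3` and this note records that
the standard alternative would scale all of its doses down by 10³.
Nothing else in the analysis depends on the choice: scores, trends,
normalised percentages and dose *ratios* are invariant to `k`.

**Display convention.**  Scenario reports round doses the way the
reference table prints them: magnitudes ≥ 0.01 to two decimals (0.23,
5.06), smaller magnitudes to three significant figures in scientific
notation (9.10×10⁻³, 3.91×10⁻⁴), ties away from zero.  A uniform
three-significant-figure rule was considered and rejected because it
prints 0.225 where the reference table prints 0.23.  Dose ratios are
reported both from full-precision doses and from display-rounded doses;
the latter matches how ratios are quoted from a printed table (e.g.
12,941 vs 12,952 at full precision) and is the default in
`ScenarioReport.ratio`.

## Environmental-justice indicators

* **Poverty**: the fraction of residents whose income-to-poverty ratio
  over the past 12 months is strictly below 1.5 (`ratio < 1.5`; the
  boundary value does not count).
* **Race/ethnicity**: the non-white population fraction, taken as a
  single input column; upstream aggregation of race categories is left
  to the data provider or generator.

Each fraction maps to a score 1–10 by even binning of [0, 1]:
score *k* covers `[(k−1)/10, k/10)`, half-open, with the top bin closed
at 1.0.  The closure convention is not dictated by the scoring idea
itself; half-open bins are the standard choice that covers [0, 1] exactly
once, and the implementation commits to it.

## Age, body weight, intake rate

Tract weighted average age is the share-weighted sum of group
representative ages: the interval midpoint for bounded groups, a
configurable `open_ended_value` (default 90 years) for the open-ended top
group — the value used in the worked example this convention comes from.
Pooling is sex-then-tract: mean over tracts within each sex, then mean of
the per-sex means.

The pooled age (default `age_mode="pooled"`) selects one (body weight,
intake rate) pair from an age-interval lookup table and applies it to
every tract, mirroring the use of one national average age.  Because the
source narrative is ambiguous about whether the lookup was national or
per-tract, `age_mode="per_tract"` is also provided, where each tract's
own weighted age drives the lookup; tracts with unusable age data are
skipped with a logged warning in that mode (in pooled mode they simply
do not contribute to the pooled age).

The packaged lookup table is **illustrative, not a handbook
reproduction**: five age strata with plausible values (80 kg / 16 m³-day
adult), present so the pipeline runs and tests are self-contained.  Real
analyses should load their own table; `validate_table` checks that any
table tiles the age axis from 0 with a final open-ended stratum and
positive values.

## Mixtures

Relative potency factors are ratios of inhalation unit risks to the
index chemical's unit risk.  A unit risk given as a range is collapsed to
its midpoint — benzene's published range 2.2×10⁻⁶–7.8×10⁻⁶ per µg/m³
becomes 5×10⁻⁶, making the RPF of 1,3-butadiene (3×10⁻⁵) equal 6 and that
of acetaldehyde (2.2×10⁻⁶) equal 0.44.  The mixture dose is the
RPF-weighted sum of component doses (index chemical equivalent dose),
which assumes components do not interact; no interaction model is
offered.  Cumulative *layers* (index chemical alone, plus the second
chemical, plus the third, …) are pointwise non-decreasing by
construction and feed the same stratification machinery as single
chemicals.

## Tract pipeline conventions

* Exposure factor defaults to 1 nationwide (continuous exposure to
  ambient air); it is a single configurable scalar, since per-tract
  exposure-factor data are rarely available.
* Stratum means are unweighted arithmetic means over tracts; no
  population weighting.
* Strata with poverty score above 7 (default) or fewer than `min_n`
  tracts are excluded from reported trends — high-poverty strata are
  typically too sparse to interpret — but `apply_exclusion` returns them
  in a side table rather than discarding them.
* Normalisation divides each stratum mean by the per-chemical maximum
  and multiplies by 100, so each chemical's trend peaks at exactly 100;
  the operation is idempotent.
* Surfaces are 10×10 grids over (poverty score, race score); empty cells
  carry an explicit missing marker, never zero, because zero is a valid
  dose.  Counts are always fully populated and sum to the number of
  scored tracts.
* Rows that fail validation when reading a tract CSV are rejected with
  their line numbers (strict mode raises; lenient mode skips and logs).

## The synthetic generator

Real nationwide inputs — tract-level air-toxics concentrations and
multi-year census demographics — cannot be redistributed with a package,
so `ejdose.synthetic` generates datasets with the structure the analysis
assumes:

* non-white fraction `R ~ Beta(0.9, 2.2)` (skewed toward mostly-white
  tracts, mean ≈ 0.29);
* poverty fraction `P = expit(−0.6 + 0.55 · logit(R) + ε)`,
  `ε ~ N(0, 0.6²)` — a logit-linear link expressing the well-documented
  positive coupling of the two indicators (sample correlation ≈ 0.5)
  without asserting their true joint distribution; values are clipped to
  [0, 1] with a logged count (the link keeps them interior, so the clip
  is a guard, not a mechanism);
* concentrations `Cⱼ = exp(mⱼ + aⱼR + bⱼP + ηⱼ)`, `ηⱼ ~ N(0, sⱼ²)`, for
  six pollutants representative of vehicular and industrial emissions
  (acetaldehyde, benzene, 1,3-butadiene, cyanide, toluene, diesel
  particulate matter).  Default log-means are plausible ambient levels
  (e.g. benzene 1.4 µg/m³); default effects (`a` 0.4–1.0, `b`
  0.25–0.6 per unit fraction, noise s.d. 0.3–0.35) are sized so that
  mean doses rise by tens of percent across the observed score range,
  the magnitude reported in nationwide tract analyses;
* grouped age-by-sex shares jittered around a national-style template
  and renormalised.

Everything derives from one integer seed via `numpy.random.default_rng`
and is bit-reproducible, including the CSV bytes written by
`ejdose simulate`.

**What the generator does not emulate** — and therefore what passing
tests do not establish about real data: spatial autocorrelation between
neighbouring tracts, realistic marginal distributions of real pollutant
fields, population-size heterogeneity, missing-data patterns, or any
causal structure behind the demographic–concentration association.  Tests
on synthetic data verify that the pipeline *recovers structure that is
present* (monotone dose–score trends under positive effects, their
absence under zero effects) and computes its summaries exactly; they say
nothing about the size or shape of trends in any real release.

## Verification set-up

The test suite checks the fixture's four doses and quoted ratio exactly
as displayed; verifies grouped means and surfaces against an independent
brute-force accumulation on 100 synthetic tracts (exact match); checks
strict monotone trend recovery across scores 1–7 for all six chemicals
at 5000 tracts under clearly positive effects (log-effects 0.8 on race
and 0.6 on poverty, noise s.d. 0.3, fixed seed); and checks the
zero-effect null by regressing stratum means on score across 12
replicates of 800 tracts, requiring the per-chemical mean slope to be
statistically indistinguishable from zero.  Problem sizes were chosen so
the whole suite runs in a few seconds while leaving the stochastic
checks comfortable margins.

## Known limitations

* Dose additivity for mixtures; no chemical interactions.
* One exposure factor for all tracts; exposure-duration heterogeneity
  (plausibly higher in burdened communities) is not modelled.
* Descriptive statistics only — no inference on trends, no uncertainty
  propagation through the dose equation (a Monte-Carlo layer over
  scenario parameters would be a natural extension).
* The unit-conversion convention of the scenario fixture is adopted for
  fidelity to its reference values, not derived from first principles
  (see above).
* No geospatial structure: tracts are exchangeable rows.
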