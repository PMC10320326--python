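# Methods

`demosurv` implements the standard analysis chain for mortality in an open
demographic-surveillance cohort: episode-based person-time, rates and
ratios, abridged period life tables and Kaplan–Meier survival with delayed
entry, STL seasonality/trend decomposition, and random-effects
quantification of geographic heterogeneity.  A synthetic-cohort generator
with fully known hazards provides ground truth for every stage.

## Person-time and the Lexis grid

A residency episode is one individual's continuous spell of residence in
one location.  Entry to risk is the latest of birth, in-migration and the
study start; exit is the earliest of death, out-migration and the study
end.  Under the **standard** rule, the gap between an out-migration and a
subsequent in-migration is excluded from risk time (only survivors of the
gap are observed to return, so counting it would bias rates downward).
Under the **MADIMAH** rule, gaps strictly shorter than 180 days are counted
as risk time, attributed to the previous residence location; this can only
increase person-years, so MADIMAH rates are never above standard ones for
the same deaths.

Conventions (the inputs do not dictate them, so they are fixed here):

* all date arithmetic is in exact days; durations convert to years by
  /365.25;
* an interval `[entry, exit)` is half-open: an episode ending in death on
  date *d* contributes exposure up to but not including *d*, and the death
  is attributed to the Lexis cell containing the last exposed day (this
  prevents double counting at split boundaries and keeps deaths out of
  zero-exposure cells);
* episodes that run to the study end are clipped to an exclusive bound of
  `study_end + 1 day`, so the final calendar day counts as exposure;
* the day-labelled analysis bands 0–28 d and 29–365 d are implemented as
  `[0, 29)` and `[29, 366)` days so the printed inclusive upper bounds
  hold; year-labelled bands start at `round(365.25 × years)` days;
* the 180-day MADIMAH comparison is strict (`< 180`);
* a death dated inside an included MADIMAH gap (possible only with
  inconsistent input) is not counted as an event and is logged.

Splitting is vectorized: each interval is cut at every age-band crossing,
analysis-period boundary and (optionally) calendar-month boundary; a
day-by-day classification loop serves as the test oracle, agreeing on
deaths exactly and on person-years to within one day.

## Rates, ratios, standardization, Whipple's index

Rates are deaths per 1000 person-years with exact (Garwood) Poisson
confidence intervals on the count — the sources this package mirrors
report no intervals, so the CI method is an internal choice.  Display
rounding (1 d.p. for rates, whole percents for declines) is separate from
the full-precision values.  Mortality ratios (deaths per 1000 live births
in the same period) are provided for under-5 indicators; they can diverge
from rates when birth rates trend, because numerator deaths are not all
drawn from the denominator cohort — a property the tests demonstrate by
simulation.  Direct standardization weights stratum rates by a normalized
reference age–sex structure supplied as an input file (synthetic runs use
their own mid-study person-time structure as the reference).  Whipple's
index uses the classical UN definition: among reported ages 23–62,
`500 × (count divisible by 5) / total`; 100 is no heaping, 500 maximal.

## Survival and life expectancy

The Kaplan–Meier estimator runs on the age scale with delayed entry: an
interval `(entry age, exit age, event)` joins the risk set after its entry
age, so people enumerated or in-migrating in adulthood do not inflate
early-age survival.  The median is the smallest age with S ≤ 0.5.  The
implementation is direct (product-limit with risk sets from sorted entry
and exit ages); `lifelines` with its `entry` argument is the independent
oracle in the tests.

The abridged period life table uses the classical conversion
`nqx = n·nMx / (1 + (n − nax)·nMx)` with radix 100,000, an open-ended last
interval (`nqx = 1`, `nLx = lx / nMx`) and nax defaults of 0.1 y for the
infant interval, 1.5 y for 1–4 y, n/2 elsewhere — all overridable; the age
grid defaults to <1, 1–4, then 5-year bands to 85+.  These conventions are
declared defaults, not inferences about any particular study's choices.
Closure identities (Σndx = l0, Tx reverse-cumulative, ex = Tx/lx) hold
exactly and are asserted in tests; with a constant hazard μ on a fine grid
e0 reproduces 1/μ to better than 1%.

## Seasonality and trend

Monthly death/person-year series per age group must be contiguous.  The
decomposition is additive STL on the per-1000 rate scale (a log option
exists), period 12, with the seasonal smoother span defaulting to 121
months — statsmodels' STL has no literal "periodic" setting, so a long
span approximates averaging the seasonal pattern across years; a robust
flag is passed through.  Peak/trough months come from the average seasonal
component per calendar month, ties broken to the earliest month with a
logged warning.

Period differences are tested with a negative-binomial (NB2) regression of
yearly counts on period with a log person-time offset (the offset makes
rates, not raw counts, the estimand); seasonality change is a
likelihood-ratio comparison of month+period versus month×period on monthly
counts.  NB nests Poisson as the dispersion α → 0, so any NB fit whose
likelihood falls below the Poisson GLM's, or whose α collapses to the
boundary, triggers a logged Poisson fallback — on equidispersed synthetic
counts the fallback is the common path.  Significance is 0.05 two-sided
throughout with no multiplicity adjustment across age groups, documented
as such.

## Geographic heterogeneity

The heterogeneity model is a log-link Poisson GLMM: deaths per
(age band × sex × location) cell, fixed effects for the seven analysis
bands and sex, log person-time offset, and a Normal random intercept per
location.  Estimation is maximum likelihood with adaptive Gauss–Hermite
quadrature (15 nodes): with a log link, each location's integrand depends
on its data only through its death total and offset-weighted fixed-effect
mean, so the 1-D integral is centred at the per-location posterior mode
(Newton) and scaled by the local curvature before quadrature.  No
installed Python package fits Poisson GLMMs by ML, hence the in-package
estimator; R's `lme4::glmer` (nAGQ = 15) is the independent oracle in the
test suite and agrees to ~4 decimals on the shared fixture.

The SD of the location effects σ quantifies heterogeneity; `exp(1.96·σ)`
approximates the multiplicative interval about the median location rate
containing 95% of location rates.  The between-location LR test uses the
boundary-corrected 50:50 mixture of χ²₀ and χ²₁ (σ = 0 lies on the
parameter-space edge); a plain χ²₁ option is provided.  The z-test for
equality of two periods' SDs uses delta-method standard errors from the
numerical Hessian at the optimum; when an estimate sits at the boundary
the SE is undefined and the z-test is reported as NaN with a logged note.

Quintile map classes use pooled empirical quantile breaks across all
location-period rates, applied unchanged to every period, each rate taking
the lowest class whose upper break is ≥ the rate (ties deterministic).
Classification is *not* invariant to rescaling rate units unless the
breaks are rescaled identically — tested as a negative case.  Rendering
against polygons is out of scope; outputs are class-assignment tables.

## The synthetic cohort generator

The generator defines the study conditions for every end-to-end check.
Hazards are piecewise-constant within age band × sex × calendar period
(× month for the seasonal stratum); event times are drawn from competing
exponential clocks (death, out-migration) with change points at every
band/period/month boundary, so the analytic stratum rate
(`expected_rate`) is exact, and fixed seeds give byte-identical outputs.

Defaults, chosen once as the conditions of a rural East African
surveillance site:

* **hazard schedule**: seven analysis bands × two sexes × four 4-year
  periods, with high neonatal mortality (~280–380/1000 PYO) declining
  steeply after the first period, per-1000 rates of order 6 → 2 at ages
  1–4 y and 70–96 at 75+ (see `DEFAULT_SCHEDULE`);
* **baseline population** 20,000 (roughly one tenth of a large HDSS site,
  a size at which the full pipeline runs in seconds), with ages drawn from
  a stable-population density l(a)·e^(−g·a), g = 0.028/y — a growing,
  young population; a stationary structure (g = 0) is available;
* **births**: Poisson with rate 0.032 per baseline person-year, entering
  at birth (no demographic feedback);
* **migration**: out-migration 0.08/person-year, 60% of out-migrants
  return after a gap drawn from a half/half mixture of Uniform(30, 179)
  and Uniform(180, 540) days — mass on both sides of the 180-day rule —
  re-entering the same location; fresh in-migrants at 0.01/baseline
  person-year with ages Uniform(0, 60);
* **locations**: 15, with Normal(0, 0.08) effects on the log-rate scale
  drawn once per simulation;
* **seasonality**: a mean-one 12-point cosine profile (peak July,
  peak-to-mean ratio 1.5) applied to ages 1–4 y in the first period only —
  mean one preserves annualized rates while planting a detectable
  component.

Event instants are continuous; recorded event dates are `floor(t) + 1`
("recorded at the following day boundary"), so every death carries at
least one day of exposure under the half-open convention.

What the generator does **not** emulate: enumeration-round observation
error (events are recorded exactly), household/GPS structure, pregnancy
surveillance, age misreporting or heaping, under-ascertainment of neonatal
deaths, and feedback of population size on birth numbers.  Passing tests
therefore validate the *computational* pipeline and estimator calibration,
not robustness to the measurement problems of real surveillance data.

## Problem sizes and numerical choices

Test and acceptance runs use baseline populations of 2,500–50,000 and
replicate counts of 60–200, sizes at which the Monte-Carlo tolerances
asserted (3 SEs for rate recovery, ±0.02 for the median recovered location
SD, 3 binomial SEs for test sizes) are meaningful while the whole suite
runs in a few minutes.  Detecting a location SD of 0.08 with 15 locations
needs roughly the full person-time of a large site per period; at one
tenth scale a single end-to-end fit often lands on the σ = 0 boundary, so
estimator calibration is assessed on cell-level replicates at full
per-period person-time (planted SD 0.08, median recovered within ±0.02),
and similarly the seasonal peak-month identification is exact on planted
(noise-free) profiles but not guaranteed on a 4-year window of sparse
counts.  Degenerate inputs are errors, not silent results: zero
person-years in a closed life-table interval, non-contiguous monthly
series, overlapping episodes, single-location heterogeneity fits, and
nqx > 1 is clamped with a warning.

## Known limitations

* The GLMM assumes Normal location effects and Poisson counts; it does not
  model spatial autocorrelation (no CAR/BYM) or smooth across locations.
* Delta-method SEs for σ are unreliable near the boundary; z-tests
  involving boundary fits are reported as undefined rather than guessed.
* The NB→Poisson fallback means dispersion is not estimated when the data
  are near-equidispersed; model labels in the output state which family
  was used.
* Mortality ratios use period live births as printed registries do; no
  cohort linkage of deaths to their birth cohort is attempted.
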